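"""End-to-end study drivers: simulate -> detect -> evaluate -> summarize.

Three studies mirror the simulation design of the underlying analysis
(1,000 bp genomes, Ne = 1, equal base frequencies):

* ``single``  -- triplets (n = 3) conditioned on exactly one recombination
  event, pairwise diversity 0.01-0.2, r in {1e-4, 1e-3}; localization
  error, power/specificity by event type, and the five-feature table.
* ``multi``   -- n = 10 samples with 1-10 events (Type-I-free ARGs),
  diversity up to 0.3, r in {1e-3, 2e-3, 5e-3}; sub-ARG
  nearest-breakpoint localization error.
* ``phylo``   -- multi-style simulations whose alignments are sliced at
  true or detected breakpoints over a window grid, with per-site
  interpolated Robinson-Foulds error of the reconstructed local trees.

Every study derives per-replicate RNG streams deterministically from a
single master seed, so reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from recbreak import io as rio
from recbreak.detect import run_all_detectors
from recbreak.evaluate import (
    method_error_single,
    multi_breakpoint_errors,
    power_specificity,
    precision,
    summarize_errors,
)
from recbreak.features import build_feature_table, triplet_features
from recbreak.phylo import reconstruct_local_tree, rf_profile, slice_alignment
from recbreak.simulate import (
    RejectionCapExceeded,
    SimulationConfig,
    TYPE_I,
    simulate_arg,
    simulate_sequences,
)

__all__ = [
    "TABLE1_SINGLE_DIVERSITIES",
    "TABLE1_MULTI_DIVERSITIES",
    "TABLE1_SINGLE_RATES",
    "TABLE1_MULTI_RATES",
    "run_single_study",
    "run_multi_study",
    "run_phylo_study",
    "make_fixtures",
]

#: Simulation grid of the study design.
TABLE1_SINGLE_DIVERSITIES = (0.01, 0.025, 0.05, 0.075, 0.1, 0.125, 0.15, 0.175, 0.2)
TABLE1_MULTI_DIVERSITIES = (0.01, 0.1, 0.15, 0.2, 0.25, 0.3)
TABLE1_SINGLE_RATES = (1e-4, 1e-3)
TABLE1_MULTI_RATES = (1e-3, 2e-3, 5e-3)

METHODS = ("maxchi", "threeseq", "gardlike")


def _spawn_rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _best_event(events, method):
    if not events:
        return None
    if method == "gardlike":
        return max(events, key=lambda e: e.statistic)
    return min(events, key=lambda e: (e.pvalue, -e.statistic))


def run_single_study(
    diversities=TABLE1_SINGLE_DIVERSITIES,
    recomb_rates=TABLE1_SINGLE_RATES,
    replicates=50,
    seed=0,
    alpha=0.05,
    permutations=1000,
    edge_margin=400,
    outdir=None,
):
    """Single-breakpoint triplet study.

    ``replicates`` is the number per (diversity, rate) setting.  Returns a
    dict of DataFrames: ``per_replicate`` (one row per simulation with
    per-method detection flags, localization errors and profile
    precisions), ``error_summary`` (mean +/- SEM by method and event type,
    restricted to true breakpoints at least ``edge_margin`` bp from the
    alignment ends), ``power_specificity`` and ``features``.
    """
    settings = [(pi, r) for pi in diversities for r in recomb_rates]
    rngs = _spawn_rngs(seed, len(settings) * replicates)
    rows = []
    sim_features = {}
    idx = 0
    for pi, r in settings:
        cfg = SimulationConfig(
            sample_size=3, recomb_rate=r, diversity=pi,
            min_events=1, max_events=1, child_is_sample=True,
        )
        for rep in range(replicates):
            rng = rngs[idx]
            sim_id = idx
            idx += 1
            arg = simulate_arg(cfg, rng)
            ev = arg.events[0]
            aln = simulate_sequences(arg, rng=rng)
            res = run_all_detectors(
                aln, alpha=alpha, num_permutations=permutations,
                max_breakpoints=1, gard_stride=1, rng=rng,
            )
            row = {
                "sim_id": sim_id,
                "diversity_cfg": pi,
                "recomb_rate": r,
                "breakpoint": ev.breakpoint,
                "event_type": ev.event_type,
                "pi_hat": aln.pairwise_diversity(),
                "edge_ok": edge_margin <= ev.breakpoint <= aln.length - edge_margin,
            }
            for method in METHODS:
                events = res[method]
                row[f"detected_{method}"] = bool(events)
                row[f"error_{method}"] = method_error_single(events, ev.breakpoint)
                best = _best_event(events, method)
                row[f"precision_{method}"] = (
                    precision(best.profile) if best is not None else np.nan
                )
            if ev.event_type != TYPE_I:
                sim_features[sim_id] = triplet_features(aln, arg)
            rows.append(row)
    per_rep = pd.DataFrame(rows)

    long_err = per_rep.melt(
        id_vars=["sim_id", "event_type", "edge_ok", "diversity_cfg"],
        value_vars=[f"error_{m}" for m in METHODS],
        var_name="method", value_name="error",
    )
    long_err["method"] = long_err["method"].str.removeprefix("error_")
    long_err["type_group"] = np.where(
        long_err["event_type"] == TYPE_I, "I", "II & III"
    )
    summary = summarize_errors(
        long_err[long_err["edge_ok"]], by=("method", "type_group")
    )

    det = per_rep.melt(
        id_vars=["sim_id", "event_type", "diversity_cfg"],
        value_vars=[f"detected_{m}" for m in METHODS],
        var_name="method", value_name="detected",
    )
    det["method"] = det["method"].str.removeprefix("detected_")
    ps = power_specificity(det, by=("method", "diversity_cfg"))
    ps_overall = power_specificity(det, by=("method",))

    # feature/regression table on the same estimand as the error summary
    # (true breakpoint at least edge_margin bp from the alignment ends):
    # edge proximity mechanically caps or inflates localization error in a
    # way none of the five predictors can represent
    features = build_feature_table(
        sim_features,
        long_err.loc[long_err["edge_ok"], ["sim_id", "method", "error"]],
    )

    out = {
        "per_replicate": per_rep,
        "errors_long": long_err,
        "error_summary": summary,
        "power_specificity": ps,
        "power_specificity_overall": ps_overall,
        "features": features,
    }
    if outdir is not None:
        _write_tables(out, outdir, "single")
    return out


def run_multi_study(
    diversities=TABLE1_MULTI_DIVERSITIES,
    recomb_rates=TABLE1_MULTI_RATES,
    replicates=20,
    seed=0,
    alpha=0.05,
    permutations=1000,
    gard_stride=10,
    max_breakpoints=10,
    keep_objects=False,
    outdir=None,
):
    """Multiple-breakpoint study (n = 10, 1-10 events, no Type I events).

    Localization error uses sub-ARG nearest-breakpoint matching for the
    pairwise and triplet methods and full-ARG matching for the AICc scan.
    With ``keep_objects`` the simulated (arg, alignment, detections)
    triples are returned for downstream slicing experiments.
    """
    settings = [(pi, r) for pi in diversities for r in recomb_rates]
    rngs = _spawn_rngs(seed, len(settings) * replicates)
    rows, err_frames, objects = [], [], []
    idx = 0
    for pi, r in settings:
        cfg = SimulationConfig(
            sample_size=10, recomb_rate=r, diversity=pi,
            min_events=1, max_events=max_breakpoints, exclude_type1=True,
        )
        for rep in range(replicates):
            rng = rngs[idx]
            sim_id = idx
            idx += 1
            try:
                arg = simulate_arg(cfg, rng)
            except RejectionCapExceeded:
                continue
            aln = simulate_sequences(arg, rng=rng)
            res = run_all_detectors(
                aln, alpha=alpha, num_permutations=permutations,
                max_breakpoints=max_breakpoints, gard_stride=gard_stride, rng=rng,
            )
            errs = multi_breakpoint_errors(res, arg, sim_id=sim_id)
            errs["diversity_cfg"] = pi
            errs["recomb_rate"] = r
            err_frames.append(errs)
            row = {"sim_id": sim_id, "diversity_cfg": pi, "recomb_rate": r,
                   "n_events": arg.num_events}
            for method in METHODS:
                row[f"detected_{method}"] = bool(res[method])
            rows.append(row)
            if keep_objects:
                objects.append((sim_id, pi, r, arg, aln, res))
    per_rep = pd.DataFrame(rows)
    err_frames = [f for f in err_frames if len(f)]
    err_records = (
        pd.concat(err_frames, ignore_index=True) if err_frames else pd.DataFrame()
    )
    if len(err_records):
        err_records["false_positive"] = err_records["false_positive"].astype(bool)
        valid = err_records.loc[~err_records["false_positive"]]
        per_sim = (
            valid.groupby(["method", "matched_type", "sim_id", "diversity_cfg"])["error"]
            .mean()
            .reset_index()
        )
        summary = summarize_errors(per_sim, by=("method", "matched_type"))
    else:
        per_sim = pd.DataFrame()
        summary = pd.DataFrame()
    power = (
        per_rep.melt(
            id_vars=["sim_id", "diversity_cfg"],
            value_vars=[f"detected_{m}" for m in METHODS],
            var_name="method", value_name="detected",
        )
        .assign(method=lambda d: d["method"].str.removeprefix("detected_"))
        .groupby(["method", "diversity_cfg"])["detected"]
        .agg(power="mean", n="count")
        .reset_index()
    )
    out = {
        "per_replicate": per_rep,
        "error_records": err_records,
        "per_sim_errors": per_sim,
        "summary": summary,
        "power": power,
    }
    if keep_objects:
        out["objects"] = objects
    if outdir is not None:
        _write_tables(out, outdir, "multi")
    return out


def phylo_eval_replicate(aln, arg, detections, windows=(0, 50, 100, 200),
                         min_segment=20):
    """Slicing strategies for one replicate: rows of mean per-site RF.

    Sources are the true breakpoints and each detection method's inferred
    breakpoints, crossed with the exclusion-window grid, plus the unsliced
    full-alignment baseline.  A method without detections contributes the
    baseline for all windows.
    """
    L = aln.length
    tree_cache = {}

    def seg_tree(seg):
        if seg not in tree_cache:
            sub = type(aln)(aln.ids, aln.matrix[:, seg[0]:seg[1]])
            tree_cache[seg] = reconstruct_local_tree(sub)
        return tree_cache[seg]

    def run(bps, window):
        plan, _ = slice_alignment(aln, bps, window, min_segment=min_segment)
        if plan.is_empty():
            return None
        trees = [seg_tree(s) for s in plan.segments]
        prof = rf_profile(trees, plan, arg)
        return prof.mean, prof.per_tree_mean(arg)

    baseline_mean, baseline_tree = run([], 0)
    rows = [
        {"source": "baseline", "window": 0, "mean_rf": baseline_mean,
         "per_tree_rf": baseline_tree, "n_breakpoints": 0}
    ]
    sources = {"true": arg.breakpoints}
    for method in METHODS:
        pts = sorted(
            {
                int(round(c))
                for ev in detections.get(method, [])
                for c in ev.breakpoint_candidates()
            }
        )
        sources[method] = [b for b in pts if 0 < b < L]
    for source, bps in sources.items():
        for w in windows:
            if not bps:
                mean_rf, tree_rf = baseline_mean, baseline_tree
            else:
                got = run(bps, w)
                if got is None:  # everything excluded; fall back to baseline
                    mean_rf, tree_rf = baseline_mean, baseline_tree
                else:
                    mean_rf, tree_rf = got
            rows.append(
                {"source": source, "window": w, "mean_rf": mean_rf,
                 "per_tree_rf": tree_rf, "n_breakpoints": len(bps)}
            )
    return rows


def run_phylo_study(
    diversities=(0.1, 0.15, 0.2, 0.25, 0.3),
    recomb_rates=(1e-3, 2e-3),
    replicates=10,
    seed=0,
    windows=(0, 50, 100, 200),
    min_segment=20,
    alpha=0.05,
    permutations=1000,
    gard_stride=10,
    outdir=None,
    multi_result=None,
):
    """Phylogenetic-reconstruction study over slicing strategies.

    Either simulates its own multiple-breakpoint data sets or reuses the
    ``objects`` of a previous :func:`run_multi_study` call.  Returns the
    per-replicate long table and a (source, window, diversity) summary.
    """
    if multi_result is None:
        multi_result = run_multi_study(
            diversities=diversities, recomb_rates=recomb_rates,
            replicates=replicates, seed=seed, alpha=alpha,
            permutations=permutations, gard_stride=gard_stride,
            keep_objects=True,
        )
    rows = []
    for sim_id, pi, r, arg, aln, res in multi_result["objects"]:
        for rec in phylo_eval_replicate(aln, arg, res, windows, min_segment):
            rec.update({"sim_id": sim_id, "diversity_cfg": pi, "recomb_rate": r})
            rows.append(rec)
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby(["source", "window", "diversity_cfg"])[["mean_rf", "per_tree_rf"]]
        .mean()
        .reset_index()
    )
    out = {"per_replicate": per_rep, "summary": summary}
    if outdir is not None:
        _write_tables(out, outdir, "phylo")
    return out


def make_fixtures(seed=12345, outdir="fixtures"):
    """Small deterministic fixture set: triplet alignments of each event
    type with truth files, and one 10-taxon multi-event alignment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {}
    for wanted in ("I", "II", "III"):
        cfg = SimulationConfig(
            sample_size=3, recomb_rate=1e-3, diversity=0.15,
            min_events=1, max_events=1, child_is_sample=True,
        )
        while True:
            arg = simulate_arg(cfg, rng)
            if arg.events[0].event_type == wanted:
                break
        aln = simulate_sequences(arg, rng=rng)
        stem = outdir / f"triplet_type{wanted}"
        rio.write_fasta(aln, f"{stem}.fasta")
        rio.write_events(arg, f"{stem}.events.tsv")
        rio.write_local_trees(arg, f"{stem}.trees.nwk", f"{stem}.intervals.tsv")
        paths[f"triplet_type{wanted}"] = stem
    cfg = SimulationConfig(
        sample_size=10, recomb_rate=2e-3, diversity=0.2,
        min_events=2, max_events=10, exclude_type1=True,
    )
    arg = simulate_arg(cfg, rng)
    aln = simulate_sequences(arg, rng=rng)
    stem = outdir / "multi_n10"
    rio.write_fasta(aln, f"{stem}.fasta")
    rio.write_events(arg, f"{stem}.events.tsv")
    rio.write_local_trees(arg, f"{stem}.trees.nwk", f"{stem}.intervals.tsv")
    paths["multi_n10"] = stem
    return paths


def _write_tables(tables: dict, outdir, prefix: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(outdir / f"{prefix}_{name}.csv", index=False)
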