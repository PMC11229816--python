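"""Genomic features explaining breakpoint-localization accuracy.

For a single-breakpoint triplet simulation the recombinant child C and its
two parental sequences are known from the ARG: P is the sample whose
lineage the child's left-side material first joins, Q the corresponding
sample for the right side.  When both sides trace to the same sample (a
Type II event in a triplet), that sample is P and the remaining sample is
Q, so that P/Q-likeness of sites is still defined.

A site is *informative* when C matches exactly one of P and Q, and
*consistent* when the matched parent is the true contributor of the
child's material at that site (the side's source sample); recurrent or
back mutations make sites inconsistent.  The five regression predictors
derived per simulation are: realized pairwise diversity, recombination
type (II reference), mean distance between informative sites and the true
breakpoint, and the natural logs of 1 + the consistent and inconsistent
informative-site counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from recbreak.detect import informative_labels
from recbreak.simulate import ARG, Alignment, TYPE_I

__all__ = [
    "true_triplet_roles",
    "label_informative_sites",
    "mean_informative_distance",
    "triplet_features",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "diversity",
    "is_type3",
    "mean_informative_distance",
    "log_consistent",
    "log_inconsistent",
]


def true_triplet_roles(arg: ARG) -> dict:
    """True child/parent roles of a single-event triplet ARG.

    The child is the unique sample below the recombinant lineage; the
    left/right source samples are the child's nearest neighbors (smallest
    pairwise TMRCA) in the local trees flanking the breakpoint.
    """
    if arg.config.sample_size != 3 or len(arg.events) != 1:
        raise ValueError("true roles are defined for single-event triplet ARGs")
    ev = arg.events[0]
    if len(ev.child_samples) != 1:
        raise ValueError("recombinant lineage is not a single sample")
    child = next(iter(ev.child_samples))
    b = ev.breakpoint
    left_tree = arg.tree_at(b - 0.5)
    right_tree = arg.tree_at(b + 0.5)
    others = [s for s in range(3) if s != child]
    s_left = min(others, key=lambda s: left_tree.tmrca(child, s))
    s_right = min(others, key=lambda s: right_tree.tmrca(child, s))
    p = s_left
    q = s_right if s_right != s_left else next(o for o in others if o != p)
    return {"child": child, "p": p, "q": q, "s_left": s_left, "s_right": s_right}


def label_informative_sites(aln: Alignment, arg: ARG, roles: dict | None = None):
    """Per-site labels of a single-breakpoint triplet alignment.

    Returns a DataFrame with 1-based ``position``, ``parent`` ('P' or 'Q',
    i.e. which parent the child matches at that informative site) and
    ``consistent`` (whether the matched parent is the side's true source).
    """
    if roles is None:
        roles = true_triplet_roles(arg)
    b = arg.events[0].breakpoint
    pos, steps = informative_labels(
        aln.matrix[roles["child"]], aln.matrix[roles["p"]], aln.matrix[roles["q"]]
    )
    matched = np.where(steps == 1, roles["p"], roles["q"])
    true_source = np.where(pos <= b, roles["s_left"], roles["s_right"])
    return pd.DataFrame(
        {
            "position": pos,
            "parent": np.where(steps == 1, "P", "Q"),
            "consistent": matched == true_source,
        }
    )


def mean_informative_distance(positions, true_breakpoint: float) -> float:
    """Mean |site - breakpoint| over informative sites (bp)."""
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("no informative sites")
    return float(np.mean(np.abs(positions - true_breakpoint)))


def triplet_features(aln: Alignment, arg: ARG) -> dict:
    """The five regression predictors of one single-breakpoint simulation.

    Returns NaN for the distance when no informative site exists (flagged
    via ``n_informative == 0``).
    """
    roles = true_triplet_roles(arg)
    labels = label_informative_sites(aln, arg, roles)
    b = arg.events[0].breakpoint
    n_cons = int(labels["consistent"].sum())
    n_incons = int(len(labels) - n_cons)
    dist = (
        mean_informative_distance(labels["position"].to_numpy(), b)
        if len(labels)
        else float("nan")
    )
    return {
        "event_type": arg.events[0].event_type,
        "diversity": aln.pairwise_diversity(),
        "mean_informative_distance": dist,
        "n_consistent": n_cons,
        "n_inconsistent": n_incons,
        "n_informative": n_cons + n_incons,
        "log_consistent": float(np.log1p(n_cons)),
        "log_inconsistent": float(np.log1p(n_incons)),
    }


def total_informative_sites(aln: Alignment, child: int, p: int, q: int) -> int:
    """Total triplet-informative site count (multi-breakpoint setting)."""
    pos, _ = informative_labels(aln.matrix[child], aln.matrix[p], aln.matrix[q])
    return int(pos.size)


def build_feature_table(sim_features, errors: pd.DataFrame) -> pd.DataFrame:
    """Assemble the PLSR design: one row per (simulation, method).

    ``sim_features`` maps sim_id -> the dict from :func:`triplet_features`;
    ``errors`` is a long table with columns (sim_id, method, error).  Type I
    simulations and rows without a detected event (NaN error) or without
    informative sites are excluded.
    """
    rows = []
    for _, r in errors.iterrows():
        feat = sim_features.get(r["sim_id"])
        if feat is None or feat["event_type"] == TYPE_I:
            continue
        if not np.isfinite(r["error"]) or feat["n_informative"] == 0:
            continue
        rows.append(
            {
                "sim_id": r["sim_id"],
                "method": r["method"],
                "error": float(r["error"]),
                "diversity": feat["diversity"],
                "event_type": feat["event_type"],
                "is_type3": 1.0 if feat["event_type"] == "III" else 0.0,
                "mean_informative_distance": feat["mean_informative_distance"],
                "log_consistent": feat["log_consistent"],
                "log_inconsistent": feat["log_inconsistent"],
            }
        )
    return pd.DataFrame(rows)
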