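"""Scoring of detections against ARG truth.

Localization error is the base-pair distance between an inferred breakpoint
and the true one.  In the single-breakpoint setting the true breakpoint is
unique; in the multiple-breakpoint setting each reported event is matched
against the breakpoints *visible to the sequences it involves* (the
sub-ARG of the reported pair/triplet for the pairwise and triplet methods,
the full ARG for the alignment-wide AICc scan) and scored against the
nearest one.  Precision is the reciprocal of the positional variance of a
detector's normalized site-wise breakpoint-probability profile: a point
mass is maximally precise (capped at the per-site quantization variance of
1/12) and a uniform profile minimally so.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from recbreak.detect import DetectedEvent
from recbreak.simulate import ARG, extract_sub_arg, TYPE_I, TYPE_II, TYPE_III

__all__ = [
    "localization_error_single",
    "method_error_single",
    "multi_breakpoint_errors",
    "localization_error_multi",
    "precision",
    "power_specificity",
    "summarize_errors",
]

#: Precision cap for (near-)point-mass profiles: reciprocal of the 1/12
#: within-site quantization variance.
MAX_PRECISION = 12.0


def localization_error_single(event: DetectedEvent, true_breakpoint: float) -> float:
    """Distance (bp) from the event's nearest reported breakpoint to the truth."""
    return min(abs(c - true_breakpoint) for c in event.breakpoint_candidates())


def method_error_single(events, true_breakpoint: float) -> float:
    """Smallest localization error over a method's reported events (NaN if none)."""
    if not events:
        return float("nan")
    return min(localization_error_single(e, true_breakpoint) for e in events)


def precision(profile: np.ndarray) -> float:
    """Reciprocal positional variance of a site-wise breakpoint profile.

    The profile is treated as a probability distribution over site
    positions 1..L; an all-zero profile is undefined (NaN).
    """
    profile = np.asarray(profile, dtype=float)
    tot = profile.sum()
    if tot <= 0:
        return float("nan")
    if abs(tot - 1.0) > 1e-6:
        raise ValueError("profile must be normalized to sum to 1")
    pos = np.arange(1, profile.size + 1, dtype=float)
    mean = float(np.dot(profile, pos))
    var = float(np.dot(profile, pos**2) - mean**2)
    if var < 1.0 / MAX_PRECISION:
        return MAX_PRECISION
    return 1.0 / var


def _nearest(bps, types, x):
    i = int(np.argmin([abs(b - x) for b in bps]))
    return bps[i], types[i]


def multi_breakpoint_errors(results: dict, arg: ARG, sim_id=0) -> pd.DataFrame:
    """Per-inferred-breakpoint error records for a multi-event ARG.

    For each reported triplet (pairwise) event the 3-sample (2-sample)
    sub-ARG is extracted; if it contains no visible recombination the
    report is a false positive and contributes no error term.  Otherwise
    every reported breakpoint interval contributes the distance from its
    midpoint to the nearest visible breakpoint, labeled with the matched
    true event's type.  The AICc scan is matched against the full ARG.
    """
    full_bps = arg.breakpoints
    type_of = {}
    for e in arg.events:
        type_of.setdefault(e.breakpoint, e.event_type)
    rows = []
    sub_cache = {}
    for method, events in results.items():
        for ev in events:
            if method == "gardlike":
                bps, types = full_bps, [type_of[b] for b in full_bps]
                if not bps:
                    rows.append({"sim_id": sim_id, "method": method,
                                 "false_positive": True, "error": np.nan,
                                 "matched_type": None})
                    continue
            else:
                key = tuple(sorted(set(ev.sequences)))
                if key not in sub_cache:
                    sub_cache[key] = extract_sub_arg(arg, key)
                sub = sub_cache[key]
                if not sub.breakpoints:
                    rows.append({"sim_id": sim_id, "method": method,
                                 "false_positive": True, "error": np.nan,
                                 "matched_type": None})
                    continue
                bps = sub.breakpoints
                types = [type_of[b] for b in bps]
            for mid in ev.breakpoint_candidates():
                b, ty = _nearest(bps, types, mid)
                rows.append({"sim_id": sim_id, "method": method,
                             "false_positive": False,
                             "error": float(abs(mid - b)),
                             "matched_type": ty})
    return pd.DataFrame(rows, columns=["sim_id", "method", "false_positive",
                                       "error", "matched_type"])


def localization_error_multi(results: dict, arg: ARG) -> dict:
    """Mean per-simulation localization error per method (NaN if no valid report)."""
    df = multi_breakpoint_errors(results, arg)
    out = {}
    for method in results:
        sub = df[(df["method"] == method) & (~df["false_positive"])]
        out[method] = float(sub["error"].mean()) if len(sub) else float("nan")
    return out


def power_specificity(records: pd.DataFrame, by=("method",)) -> pd.DataFrame:
    """Power and specificity per method (optionally stratified).

    ``records`` must contain columns ``method``, ``event_type`` (the
    simulation's true type) and ``detected``.  Detections of Type I events
    are false positives, so specificity = 1 - detection rate on Type I
    replicates; power is the detection rate on Type II (III) replicates.
    Strata without replicates are omitted.
    """
    rows = []
    for keys, grp in records.groupby(list(by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        for ty, name in [(TYPE_I, "specificity"), (TYPE_II, "power_type2"),
                         (TYPE_III, "power_type3")]:
            sub = grp[grp["event_type"] == ty]
            if len(sub) == 0:
                row[name] = np.nan
                row[f"n_{name}"] = 0
                continue
            rate = float(sub["detected"].mean())
            row[name] = 1.0 - rate if ty == TYPE_I else rate
            row[f"n_{name}"] = int(len(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_errors(errors: pd.DataFrame, by=("method", "event_type")) -> pd.DataFrame:
    """Mean +/- SEM localization error by stratum (finite errors only)."""
    sub = errors[np.isfinite(errors["error"])]
    out = (
        sub.groupby(list(by))["error"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")
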