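"""Which genomic features drive breakpoint-localization error?

Fits, per detection method, a five-predictor partial least squares
regression of localization error on realized diversity, recombination type
(Type II reference), mean informative-site distance to the breakpoint, and
log counts of consistent/inconsistent informative sites; decomposes the
explained variance by predictor and bootstraps coefficient intervals.
Reads the feature table written by 01_single_breakpoint.py (or re-runs the
study when absent).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from recbreak.features import FEATURE_COLUMNS
from recbreak.pipeline import run_single_study
from recbreak.plsr import bootstrap_coefficients, explained_variance, fit_plsr


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", default="results/single_features.csv")
    ap.add_argument("--replicates", type=int, default=100)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bootstrap", type=int, default=1000)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    path = Path(args.features)
    if path.exists():
        feats = pd.read_csv(path)
    else:
        print("feature table not found; running the single-breakpoint study")
        feats = run_single_study(replicates=args.replicates, seed=args.seed)["features"]

    out = {}
    rows = []
    rng = np.random.default_rng(args.seed)
    for method in ("maxchi", "threeseq", "gardlike"):
        sub = feats[feats["method"] == method]
        if len(sub) < 20 or sub["error"].nunique() < 3:
            print(f"{method}: only {len(sub)} usable rows; skipping the fit "
                  "(increase --replicates)")
            continue
        X = sub[FEATURE_COLUMNS].to_numpy()
        y = sub["error"].to_numpy()
        fit = fit_plsr(X, y, 5, FEATURE_COLUMNS)
        pj = explained_variance(fit)
        ci = bootstrap_coefficients(X, y, 5, R=args.bootstrap, rng=rng,
                                    feature_names=FEATURE_COLUMNS)
        ci.insert(0, "method", method)
        rows.append(ci)
        out[method] = {
            "n": int(len(sub)),
            "k": fit.k,
            "total_explained_variance": fit.total_r2,
            "per_predictor": pj,
        }
        print(f"{method}: n={len(sub)} total explained variance "
              f"{100*fit.total_r2:.1f}%")
        for name, v in sorted(pj.items(), key=lambda kv: -kv[1]):
            print(f"    {name:28s} {100*v:5.1f}%")

    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "plsr_coefficients.csv", index=False
        )
    (outdir / "plsr_explained_variance.json").write_text(json.dumps(out, indent=2))
    print(f"\ntables -> {outdir.resolve()}")


if __name__ == "__main__":
    main()
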