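#!/usr/bin/env python
"""Correlate hit abundance with pooled pollution measurements.

Pools the synthetic surveys by per-survey Box-Cox + z-scoring, matches each
sample to its nearest measurement within 400 km (with a sensitivity table
over radii), and reports the Spearman correlation and repeated-median trend
of final hit counts against the pooled pollution scale. Outputs under
<out-dir>/pollution/.
"""

import argparse
import json
import pathlib

from plastimine.pollution import (
    correlate_pollution,
    match_pollution,
    pool_surveys,
    radius_sensitivity,
)
from plastimine.search import HitTable
from plastimine.synthetic import GeneratorConfig, generate_geo_metadata, generate_pollution_surveys


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=pathlib.Path, default=pathlib.Path("results"))
    ap.add_argument("--radius-km", type=float, default=400.0)
    args = ap.parse_args()

    cfg = GeneratorConfig(seed=args.seed)
    meta = generate_geo_metadata(cfg)
    surveys = generate_pollution_surveys(cfg, meta)
    final = HitTable.from_tsv(args.out_dir / "search" / "final_hits.tsv")
    counts = (
        final.frame.groupby("sample_id").size()
        .reindex(meta["sample_id"], fill_value=0)
        .astype(float)
    )

    pooled = pool_surveys(surveys)
    matched = match_pollution(meta, pooled, args.radius_km)
    corr, trend = correlate_pollution(matched, counts)
    sensitivity = radius_sensitivity(meta, pooled, counts, [200.0, 400.0, 800.0, 1600.0])

    out = args.out_dir / "pollution"
    out.mkdir(parents=True, exist_ok=True)
    pooled.to_csv(out / "pooled_points.tsv", sep="\t", index=False)
    matched.to_csv(out / f"matches_{int(args.radius_km)}km.tsv", sep="\t", index=False)
    sensitivity.to_csv(out / "radius_sensitivity.tsv", sep="\t", index=False)
    (out / "correlation.json").write_text(
        json.dumps(
            {
                "radius_km": args.radius_km,
                "n_matched": int(matched["pooled_z"].notna().sum()),
                "spearman_rho": corr.rho,
                "p_value": corr.p_value,
                "repeated_median_slope": trend.slope,
                "repeated_median_intercept": trend.intercept,
                "generator_target_rho": cfg.target_rho,
            },
            indent=2,
        )
        + "\n"
    )

    n_matched = int(matched["pooled_z"].notna().sum())
    print(f"pooled {len(pooled)} points from {cfg.n_surveys} surveys "
          f"(per-survey Box-Cox lambdas: "
          f"{sorted(round(l, 2) for l in pooled['boxcox_lambda'].unique())})")
    print(f"matched {n_matched}/{len(meta)} samples within {args.radius_km:.0f} km")
    print(f"Spearman(hits, pooled pollution) = {corr.rho:.3f} (p = {corr.p_value:.2g}); "
          f"generator target was {cfg.target_rho}")
    print(f"repeated-median trend: slope {trend.slope:.2f}, intercept {trend.intercept:.2f}")
    print(sensitivity.to_string(index=False))
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
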