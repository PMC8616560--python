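#!/usr/bin/env python
"""Percent vacuolar-to-total fluorescence across replicated cell fields.

Simulates three independent replicates of ~25 cells whose vacuoles hold a
designed 40% of the cell's fluorescence, runs the mask-based quantification
(median background outside all cells, corrected sums over vacuole and cell
masks), and aggregates per-replicate means into the grand mean +/- SD.

Expected outcome: grand mean within a few percentage points of the designed
40%, SD across replicates near zero.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from golgikin.synthetic import SimConfig, simulate_cell_image
from golgikin.vacuolar import batch_vacuolar_summary, vacuolar_percentages

DESIGNED_FRACTION = 0.40


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/02_vacuolar"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    frames = []
    for rep in range(3):
        cfg = SimConfig(image_shape=(512, 512), seed=args.seed * 100 + rep)
        image, cells, vacs, _ = simulate_cell_image(cfg, 25, DESIGNED_FRACTION)
        frames.append(vacuolar_percentages(image, cells, vacs, replicate_id=f"rep{rep + 1}"))
    records = pd.concat(frames, ignore_index=True)
    summary = batch_vacuolar_summary(records)

    records.to_csv(args.out / "per_cell.csv", index=False)
    (args.out / "summary.json").write_text(
        json.dumps(
            {
                "designed_pct": 100 * DESIGNED_FRACTION,
                "grand_mean_pct": summary.grand_mean,
                "sd_across_replicates_pct": summary.sd_across_replicates,
                "per_replicate_mean": summary.per_replicate_mean.to_dict(),
                "n_cells": summary.n_cells,
                "seed": args.seed,
            },
            indent=2,
        )
        + "\n"
    )
    print(
        f"designed 40.0% -> recovered grand mean {summary.grand_mean:.2f}% "
        f"(SD across replicates {summary.sd_across_replicates:.2f}%, n={summary.n_cells} cells)"
    )
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
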