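#!/usr/bin/env python
"""Single-compartment kinetics of a two-marker maturation movie.

Simulates a 2 min movie (2 s frames) of 16 compartments carrying two
markers with identical pulse timing, runs tracking, trace extraction, track
selection, normalization, and writes per-track peak-to-peak times plus the
peak-aligned averaged trace with its 95% CI band.

Expected outcome: median peak-to-peak time within one frame (2 s) of zero,
and the two averaged channels peaking together at t = 0.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from golgikin.pipeline import analyze_movie
from golgikin.plots import plot_averaged_trace
from golgikin.synthetic import MarkerSpec, SimConfig, simulate_maturation_movie


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/03_kinetics"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(image_shape=(160, 160), n_puncta=16, seed=args.seed)
    markers = [MarkerSpec("Erd1", 0.0, 10.0), MarkerSpec("Mnn9", 0.0, 10.0)]
    movie, _ = simulate_maturation_movie(cfg, markers)
    report = analyze_movie(movie, reference_channel="Erd1")
    res = report.pairwise["Mnn9"]

    res.per_track.to_csv(args.out / "peak_to_peak.csv", index=False)
    if report.averaged is not None:
        avg = report.averaged
        df = pd.DataFrame({"time_s": avg.times, "n_tracks": avg.n_per_timepoint})
        for ch, name in enumerate(avg.channel_names):
            df[f"mean_{name}"] = avg.mean[ch]
            df[f"ci_low_{name}"] = avg.ci_low[ch]
            df[f"ci_high_{name}"] = avg.ci_high[ch]
        df.to_csv(args.out / "averaged_trace.csv", index=False)
        plot_averaged_trace(avg, args.out / "averaged_trace.png")
    (args.out / "summary.json").write_text(
        json.dumps(
            {
                "median_dt_s": res.median,
                "n_tracks": res.n,
                "sign_convention": "dt > 0 means Mnn9 peaks after Erd1",
                "seed": args.seed,
            },
            indent=2,
        )
        + "\n"
    )
    print(f"{res.n} analyzable tracks; median peak-to-peak Erd1 -> Mnn9 = {res.median:+.1f} s")
    print(f"tables and figure written to {args.out}")


if __name__ == "__main__":
    main()
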