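#!/usr/bin/env python
"""Normalize FRET traces and summarize CDK1 activity per genotype.

Applies the min/max-rescaled channel ratio F(t) to every trace, averages
per genotype on the union time grid, and reports pre-GVBD activation-peak
recovery for control traces. Writes fret_mean_control.csv and
fret_mean_mutant.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from oointegrity import fret


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fret_dir = args.data_dir / "fret"
    labels = json.loads((fret_dir / "fret_labels.json").read_text())
    traces = {"control": [], "mutant": []}
    hits, n_ctrl = 0, 0
    for p in sorted(fret_dir.glob("*.csv")):
        tr = fret.normalize_fret(fret.read_trace_csv(p))
        arche = labels[p.stem]["archetype"]
        traces[arche].append(tr)
        if arche == "control":
            n_ctrl += 1
            if abs(fret.pre_event_peak(tr)
                   - labels[p.stem]["peak_index"]) <= 2:
                hits += 1
    for grp, trs in traces.items():
        mean = fret.summarize_trace(trs)
        mean.to_csv(args.out / f"fret_mean_{grp}.csv", index=False)
        m = mean["mean_F"].to_numpy()
        print(f"{grp}: {len(trs)} traces; mean F excursion above early "
              f"baseline {np.nanmax(m[:160]) - np.nanmedian(m[:40]):.2f}")
    print(f"pre-GVBD peak recovered within ±2 samples in "
          f"{hits}/{n_ctrl} control traces")


if __name__ == "__main__":
    main()
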