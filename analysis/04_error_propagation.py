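#!/usr/bin/env python
"""How alignment error propagates to other vertebral levels.

Reads the per-acquisition table written by 03_run_experiment.py, rebuilds
the acquisition-level x measured-level median-TRE matrix per CT
resolution, and regresses TRE on inter-spinous distance.  Under the
rigid-spine assumption a good alignment at the scanned level stays
clinically usable at the directly adjacent levels and degrades linearly
with distance beyond them.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spinenav.evaluation import (
    PropagationMatrix,
    cumulative_level_distances,
    fit_tre_vs_distance,
)
from spinenav.phantom import DEFAULT_GAPS_MM

BASE = Path(__file__).resolve().parent.parent / "results"
IN = BASE / "experiment" / "per_acquisition.csv"
OUT = BASE / "propagation"


def main() -> None:
    if not IN.exists():
        raise SystemExit(f"{IN} missing - run analysis/03_run_experiment.py first")
    df = pd.read_csv(IN)
    levels = sorted(df["level"].unique())
    gaps_cranial = tuple(reversed(DEFAULT_GAPS_MM))
    distances = cumulative_level_distances(gaps_cranial)
    OUT.mkdir(parents=True, exist_ok=True)

    for res, sub in df.groupby("resolution_mm"):
        cells = np.zeros((len(levels), len(levels)))
        for i, li in enumerate(levels):
            at_i = sub[sub["level"] == li]
            for j, lj in enumerate(levels):
                cells[i, j] = at_i[f"tre_L{lj}_mm"].median()
        mat = PropagationMatrix(levels=levels, cells=cells)
        mat.to_frame().to_csv(OUT / f"propagation_{res:g}mm.csv")
        fit = fit_tre_vs_distance(mat, distances)
        diag = np.diag(cells).mean()
        adjacent = np.mean([cells[i, j] for i in range(6) for j in range(6)
                            if abs(i - j) == 1])
        print(f"{res:g} mm CT: slope {fit.slope:.4f} mm/mm, intercept "
              f"{fit.intercept:.2f} mm; median TRE on-diagonal {diag:.2f} mm, "
              f"adjacent levels {adjacent:.2f} mm")
    print(f"matrices written to {OUT}")


if __name__ == "__main__":
    main()
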