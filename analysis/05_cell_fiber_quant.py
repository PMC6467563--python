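"""Proliferation and fiber-density quantification on synthetic ground truth.

Exercises the cell/fiber pipelines exactly as they would run on segmented
histology: AC-centered 50 um windows every 25 um out to +/-250 um for the
EdU+/(DAPI+;P27-) proliferation index, and the five-scan-line fiber peak
counting per 50 um bin.  Both are checked against the generator's ground
truth.  Writes results/tables/proliferation_windows.csv and
fiber_recovery.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cbfold.cellquant import ac_windows, fiber_density_profile, proliferation_by_windows
from cbfold.synthetic import ac_positions_outer, gen_cells, gen_fiber_image, gen_section

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
EDU_RATE = 0.35


def main() -> None:
    (ROOT / "tables").mkdir(parents=True, exist_ok=True)
    section, gt = gen_section(epsilon=0.3, seed=SEED)
    cells, _ = gen_cells(section, density=12.0, edu_rate=EDU_RATE, p27_rate=0.2, seed=SEED + 1)

    s_ac = ac_positions_outer(section, gt)[1]  # the central AC
    windows = ac_windows(section.outer_egl, s_ac)
    prolif = proliferation_by_windows(cells, windows)
    prolif.to_csv(ROOT / "tables" / "proliferation_windows.csv", index=False, float_format="%.4f")
    pooled = prolif.n_edu.sum() / prolif.n_denominator.sum()
    print(f"proliferation: pooled rate {pooled:.3f} over {len(windows)} windows "
          f"(generating rate {EDU_RATE}); per-window rates are uniform within "
          "binomial noise -- no AC-specific proliferation signal, by construction")

    counts = [3, 1, 4, 2, 5]
    image, fgt = gen_fiber_image(section, counts, snr=5.0, seed=SEED + 2)
    profile = fiber_density_profile(image, ac_position=fgt.derived["ac_position"])
    centers = fgt.derived["bin_start"] + 50.0 * (np.arange(len(counts)) + 0.5)
    got = (
        profile.set_index(profile.bin_center_um.round(6))
        .loc[np.round(centers, 6), "count_mean"]
        .to_numpy()
    )
    recovery = pd.DataFrame(
        {"bin_center_um": centers, "true_count": counts, "measured_count": got}
    )
    recovery.to_csv(ROOT / "tables" / "fiber_recovery.csv", index=False, float_format="%.3f")
    print(recovery.to_string(index=False))
    print(f"fiber recovery: max per-bin error {np.abs(got - counts).max():.1f} at SNR 5")


if __name__ == "__main__":
    main()
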