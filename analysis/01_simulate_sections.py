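"""Generate the synthetic midsagittal sections the downstream analyses measure.

One half section per embryonic stage E15.5-E18.5 (eps = 0, 0.3, 0.6, 0.9
through the model's time course), written as contour CSVs + manifests with
ground truth, into results/sections/.
"""

import sys
from pathlib import Path

from cbfold.contour import write_section
from cbfold.model import epsilon_of_time
from cbfold.synthetic import gen_section

OUT = Path(__file__).resolve().parents[1] / "results" / "sections"
STAGES = (15.5, 16.5, 17.5, 18.5)
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, stage in enumerate(STAGES):
        eps = epsilon_of_time(stage)
        section, gt = gen_section(epsilon=eps, seed=SEED + i)
        prefix = f"stage_{stage:g}"
        manifest = write_section(OUT, section, prefix=prefix)
        gt.save(OUT / f"{prefix}_ground_truth.json")
        print(
            f"E{stage:g}: eps = {eps:.1f}, outer EGL {section.outer_egl.arc_length:.0f} um, "
            f"{len(section.ac_positions)} ACs -> {manifest.name}"
        )
    print(f"\nwrote {len(STAGES)} sections under {OUT}")


if __name__ == "__main__":
    main()
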