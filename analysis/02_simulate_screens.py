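#!/usr/bin/env python
"""Simulate the 7N PAM depletion screens.

Generates read-level FASTQ datasets for the two screen formats under the
planted recognition model (G required at PAM position 5, A preferred 3:1
at position 7):

* interference mode — strong selection, as in the in vivo plasmid
  transformation screen (recognized variants barely survive);
* cleavage mode — partial digestion, as in the in vitro screen
  (recognized variants keep a larger uncleaved fraction).

FASTQ files go to scratch/screens/ (large, regenerable); the truth
records go alongside them.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cascreen import simulate as sim

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "screens"
N_MOLECULES = 200_000  # ~12x mean depth per library member
SEED = 11


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    modes = {
        "interference": sim.planted_nnnngna_model(recognized_survival=0.05),
        "cleavage": sim.planted_nnnngna_model(recognized_survival=0.30),
    }
    for name, model in modes.items():
        out = SCRATCH / name
        out.mkdir(exist_ok=True)
        res = sim.simulate_screen(
            model, N_MOLECULES, N_MOLECULES,
            out_exp=out / "exp.fastq.gz", out_ctrl=out / "ctrl.fastq.gz",
            out_truth=out / "truth.json", seed=SEED)
        print(f"{name}: {N_MOLECULES} molecules/sample -> "
              f"{res.exp_path.name}, {res.ctrl_path.name} "
              f"(recognized survival {model.recognized_survival})")
    print(f"wrote datasets under {SCRATCH}")


if __name__ == "__main__":
    main()
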