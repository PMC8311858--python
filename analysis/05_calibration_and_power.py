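"""Monte-Carlo calibration and power of the statistical battery.

Under the all-null design every model should reject at ~5%; under the
planted strong effects the qualitative result pattern should be detected
in the large majority of replicates while truly null components (sham arm,
control ROIs) stay at the false-positive floor.  This driver runs reduced
replicate counts for a quick look; the full-size studies (500 null / 200
effect replicates) run in the test suite and acceptance script.

Writes both rate tables under results/analysis/05_calibration/.
"""

import sys
from pathlib import Path

from connseg.simulation_study import effect_recovery_study, type_one_error_study

OUT = Path("results/analysis/05_calibration")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11


def main() -> None:
    null_report = type_one_error_study(n_reps=100, base_seed=SEED, T=60)
    print("type-I error at alpha=0.05 (all planted effects zero, T=60):")
    print(null_report.to_string(index=False), "\n")

    effect_report = effect_recovery_study(n_reps=50, base_seed=SEED, T=1000)
    print("detection of the planted effect pattern (T=1000):")
    print(effect_report.to_string(index=False))

    OUT.mkdir(parents=True, exist_ok=True)
    null_report.to_csv(OUT / "type_one_error.tsv", sep="\t", index=False)
    effect_report.to_csv(OUT / "effect_detection.tsv", sep="\t", index=False)
    print(f"\nwrote rate tables to {OUT}")


if __name__ == "__main__":
    main()
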