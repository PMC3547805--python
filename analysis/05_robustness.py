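"""Hazard ratios with vs without unlinked deaths.

Fits the piecewise-exponential education models on a single-wave cohort
twice — excluding unlinked deaths and including the pragmatically
allocated ones — under (a) the default, education-independent unlinking
and (b) strongly education-differential unlinking. The first leaves
hazard ratios essentially unchanged; the second shifts them well outside
the non-differential band, demonstrating when relative-mortality
estimates can and cannot be trusted under incomplete linkage. Writes
results under results/robustness/.
"""

import sys
from pathlib import Path

from cohortbridge.studies import hr_robustness_study

SEED = 20_2000
OUT = Path(__file__).resolve().parent.parent / "results" / "robustness"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for label, differential in (("nondifferential", False),
                                ("differential", True)):
        res = hr_robustness_study(seed=SEED, differential=differential)
        comp = res["comparison"]
        comp.to_csv(OUT / f"hr_comparison_{label}.csv", index=False)
        print(f"{label}: max |HR_incl - HR_excl| = "
              f"{res['max_abs_difference']:.3f}")
        cols = ["level", "hr_excl", "ci_low_excl", "ci_high_excl",
                "hr_incl", "ci_low_incl", "ci_high_incl", "abs_difference"]
        print(comp[cols].round(3).to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
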