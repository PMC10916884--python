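#!/usr/bin/env python
"""Agreement analyses: grading kappa and Bland–Altman of model predictions.

Quantifies (a) agreement between grades assigned from measured vs. true
ratios with linearly weighted Cohen's kappa, and (b) agreement between
cross-validated model predictions and observed acuity with Bland–Altman
limits of agreement and a bias-trend regression.  Writes
results/agreement.json and results/bland_altman.png.
"""

import json
from pathlib import Path

from foveaspec.agreement import bland_altman, plot_bland_altman, weighted_kappa
from foveaspec.grading import GRADE_TO_INDEX, GRADES
from foveaspec.io import read_cohort_csv
from foveaspec.model import FIXED_SPEC, fit_linear_model

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    eyes_path = OUT / "eyes.csv"
    if not eyes_path.exists():
        raise SystemExit("run 02_measure_eyes.py first")
    eyes = read_cohort_csv(eyes_path)

    a = [GRADE_TO_INDEX[g] for g in eyes["grade_true"].astype(str)]
    b = [GRADE_TO_INDEX[g] for g in eyes["grade"].astype(str)]
    kap = weighted_kappa(a, b, len(GRADES))

    combined = fit_linear_model(eyes, FIXED_SPEC)
    ba = bland_altman(combined.cv_predictions, eyes["bcva_logmar"].to_numpy())
    OUT.mkdir(exist_ok=True)
    plot_bland_altman(ba, str(OUT / "bland_altman.png"))

    payload = {
        "grading": {
            "observed_agreement": kap.observed_agreement,
            "weighted_kappa": kap.kappa,
        },
        "bland_altman": {
            "bias": ba.bias,
            "sd": ba.sd,
            "loa": [ba.loa_lower, ba.loa_upper],
            "trend": None if ba.trend is None else {
                "slope": ba.trend.slope, "intercept": ba.trend.intercept,
                "F": ba.trend.f_statistic, "DFn": ba.trend.dfn,
                "DFd": ba.trend.dfd, "p": ba.trend.p_value,
            },
        },
    }
    (OUT / "agreement.json").write_text(json.dumps(payload, indent=2))

    print(f"grading agreement (measured vs. true ratios): "
          f"{100 * kap.observed_agreement:.1f}%, weighted kappa {kap.kappa:.3f}")
    print(f"Bland–Altman: bias {ba.bias:+.4f} logMAR, "
          f"LOA [{ba.loa_lower:+.3f}, {ba.loa_upper:+.3f}]")
    if ba.trend is not None:
        print(f"  bias trend: y = {ba.trend.slope:.3f}x "
              f"{ba.trend.intercept:+.3f} (F={ba.trend.f_statistic:.2f}, "
              f"DFd={ba.trend.dfd}, p={ba.trend.p_value:.2g})")
    print(f"wrote {OUT / 'agreement.json'} and {OUT / 'bland_altman.png'}")


if __name__ == "__main__":
    main()
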