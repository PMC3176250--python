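"""The published ten-item screening instrument and its printed
operating characteristics, as input data.

These are the printed weights, score-band edges, band likelihood
ratios, and validation metrics of the Student Information Form
Predictive Tool developed on a cohort of 2919 Shanghai sixth graders.
They serve as fixed inputs for worked examples and cross-checks; the
package reproduces the construction *procedure*, not these exact
numbers (the original raw data are not public).
"""

from __future__ import annotations

from .instrument import ScoreTable

#: Protective-positive per-level weights of the published instrument.
PUBLISHED_SCORE_TABLE = ScoreTable(
    entries={
        "gender_item": {"female": 0.0, "male": 0.60},
        "family_feeling": {"4_to_7": 0.0, "1": 0.96, "2": 0.94, "3": 0.76},
        "ridiculed": {"never": 0.0, "rarely": -0.13, "sometimes": -0.26,
                      "regularly": -1.00},
        "ignored": {"never": 0.0, "rarely": -0.25, "sometimes": -0.47,
                    "regularly": -0.92},
        "weekend_homework": {"five_plus_h": 0.0, "none_lt1h": 0.41,
                             "1_to_2h": 0.52, "3_to_4h": 0.36},
        "math_difficulty": {"never": 0.0, "rarely": -0.43, "sometimes": -0.64,
                            "regularly": -1.03},
        "appetite": {"not_good": 0.0, "somewhat_good": 0.73, "always_good": 0.78},
        "sleep_hours": {"gt_8h": 0.0, "7_to_8h": -0.16, "lt_7h": -0.80},
        "same_sex_friends": {"no": 0.0, "yes": 0.41},
        "karaoke_bars": {"two_plus": 0.0, "none": 0.47, "one": 0.70},
    },
    rounding=2,
)

#: Score-band edges of the published likelihood-ratio table
#: (bands: <=0, (0,1], (1,1.5], (1.5,2], (2,2.5], (2.5,3], >3).
PUBLISHED_BAND_EDGES = (0.0, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Printed band likelihood ratios, lowest score band first.
PUBLISHED_BAND_LRS = (6.85, 2.46, 1.16, 0.83, 0.48, 0.22, 0.11)

#: Printed validation-sample operating characteristics at cutoff 1
#: (score > 1 defines a negative test).
PUBLISHED_VALIDATION = {
    "auc": 0.755,
    "calibration_slope": 0.976,
    "sensitivity": 0.480,
    "specificity": 0.860,
    "ppv": 0.431,
    "npv": 0.882,
    "lr_pos": 3.414,
    "lr_neg": 0.605,
    "dor": 5.638,
    "prevalence": 0.184,
    "cutoff": 1.0,
    "fraction_negative": 0.798,
    #: observed maladjustment risk in the lowest (<=0) and highest (>3) bands
    "risk_lowest_band": 0.601,
    "risk_highest_band": 0.024,
}
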