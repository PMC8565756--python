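"""Published reference constants for the Jiangxi double-cropped rice study.

These are inert look-up values for comparison plots, reports and tests;
nothing in the fitting pipeline reads them.  ``LITERATURE_CURVES``
collects leaf- or plant-based critical N dilution curves reported for
other Chinese rice regions.
"""

from typing import NamedTuple


class PublishedCurve(NamedTuple):
    a: float
    b: float
    r2: float


#: Season-level curves fitted to the calibration trial (2019 data).
PUBLISHED_SEASON_CURVES = {
    "early": PublishedCurve(a=2.66, b=0.79, r2=0.88),
    "late": PublishedCurve(a=7.46, b=1.42, r2=0.91),
}

#: Single-variety curve parameters, 2019 calibration year (no R2 printed).
PUBLISHED_VARIETY_CURVES_2019 = {
    "Zhongjiazao 17": {"a": 2.83, "b": 0.83},
    "Changliangyou 173": {"a": 2.57, "b": 0.69},
    "Taiyouhang 1573": {"a": 6.58, "b": 1.29},
    "Fumeizhan": {"a": 6.92, "b": 1.33},
}

#: Single-variety curves for the 2020 season.
PUBLISHED_VARIETY_CURVES_2020 = {
    "Zhongjiazao 17": PublishedCurve(a=2.47, b=0.67, r2=0.83),
    "Changliangyou 173": PublishedCurve(a=2.62, b=0.66, r2=0.82),
    "Taiyouhang 1573": PublishedCurve(a=2.38, b=0.35, r2=0.92),
    "Fumeizhan": PublishedCurve(a=2.07, b=0.39, r2=0.99),
}

#: Holdout-trial validation statistics: variety -> (RMSE %N, n-RMSE %).
PUBLISHED_VALIDATION = {
    "Zaoxian 618": (0.59, 19.45),
    "Ganxin 203": (0.54, 19.25),
    "Taiyou 398": (0.24, 10.78),
    "Wufengyou T025": (0.41, 19.49),
}

#: Which validation varieties belong to which season.
VALIDATION_SEASONS = {
    "early": ("Zaoxian 618", "Ganxin 203"),
    "late": ("Taiyou 398", "Wufengyou T025"),
}

#: Whole-plant-based curves from other rice regions (region -> curves).
LITERATURE_CURVES = {
    "Northern China rice": [PublishedCurve(a=1.96, b=0.56, r2=0.87)],
    "Double-cropped rice, China (early)": [PublishedCurve(a=3.37, b=0.44, r2=0.82)],
    "Double-cropped rice, China (late)": [PublishedCurve(a=3.69, b=0.34, r2=0.78)],
    "Rice-wheat rotation, Central China": [PublishedCurve(a=3.33, b=0.26, r2=0.86)],
}
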