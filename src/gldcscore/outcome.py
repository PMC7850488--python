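"""Clinical-outcome line, severity bands, colony yields and prenatal prediction.

The linear model WMMS = slope * COS + intercept is fitted to homozygous
patient mutations whose human and mouse WMMS agree.  Evaluating the line at
the clinical cutoff COS = 5 gives the WMMS threshold separating attenuated
from severe neurological disease (1.3 for the published line
y = 0.76 x - 2.5).  Mouse-colony genotype counts convert to prenatal
lethality as the shortfall of homozygotes against the Mendelian expectation
of 25%, and the in-vivo anchors — 26% prenatal fatality at WMMS -0.87 and a
90% cap at WMMS 10 — interpolate linearly to predict outcomes for any
mutation in the validated score range.  Formate supplementation of dams
rescues prenatal death back to the attenuated level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "OutcomeModel",
    "CosWmmsRegression",
    "ColonyCounts",
    "OutcomePrediction",
    "fit_cos_wmms",
    "classify_wmms",
    "prenatal_lethality",
    "predict_outcomes",
    "mendelian_chisq",
    "MendelianTestResult",
]

#: Validated WMMS anchors and phenotype levels from the two engineered strains.
WMMS_LOWER = -0.87  # attenuated anchor (A394V-like)
WMMS_UPPER = 10.0  # upper validated bound
FATALITY_LOWER = 26.0  # % prenatal fatality at the lower anchor
FATALITY_UPPER = 90.0  # % cap at the upper bound
HYDROCEPHALUS_BASELINE = 31.0  # % post-natal hydrocephalus, attenuated anchor
FORMATE_FATALITY = 29.0  # % prenatal fatality after formate rescue
FORMATE_HYDROCEPHALUS = 34.0  # % hydrocephalus after formate rescue
COS_CUTOFF = 5.0  # clinical attenuated/severe cutoff


@dataclass(frozen=True)
class OutcomeModel:
    """The line WMMS = slope * COS + intercept and the derived threshold."""

    slope: float
    intercept: float
    r_squared: float = float("nan")
    cos_cutoff: float = COS_CUTOFF
    n: int = 0

    @property
    def wmms_threshold(self) -> float:
        """WMMS at the clinical cutoff — the attenuated/severe transition."""
        return self.slope * self.cos_cutoff + self.intercept

    def wmms_at(self, cos: float) -> float:
        return self.slope * float(cos) + self.intercept


class CosWmmsRegression(BaseEstimator, RegressorMixin):
    """Least-squares line of WMMS on clinical outcome score (sklearn-style).

    ``fit(cos, wmms)`` accepts 1-D arrays (or a single-column 2-D ``X``).
    Fitted attributes: ``slope_``, ``intercept_``, ``r_squared_``.
    """

    def __init__(self, cos_cutoff: float = COS_CUTOFF):
        self.cos_cutoff = cos_cutoff

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError(f"{x.size} COS values vs {y.size} WMMS values")
        if x.size < 3:
            raise ValueError("need at least 3 (COS, WMMS) pairs")
        if np.ptp(x) == 0:
            raise ValueError("COS values are constant; slope undefined")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.n_obs_ = int(x.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.slope_ * np.asarray(X, dtype=float).reshape(-1) + self.intercept_

    def to_model(self) -> OutcomeModel:
        check_is_fitted(self, "slope_")
        return OutcomeModel(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            cos_cutoff=self.cos_cutoff,
            n=self.n_obs_,
        )


def fit_cos_wmms(pairs, cos_cutoff: float = COS_CUTOFF) -> OutcomeModel:
    """Fit the WMMS-on-COS line from (cos, wmms) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (cos, wmms) tuples")
    return CosWmmsRegression(cos_cutoff=cos_cutoff).fit(arr[:, 0], arr[:, 1]).to_model()


def classify_wmms(
    wmms: float,
    model: OutcomeModel | None = None,
    *,
    lower: float = WMMS_LOWER,
    upper: float = WMMS_UPPER,
) -> str:
    """Classify a WMMS as attenuated / severe / out_of_range.

    Attenuated: [lower, threshold] (both edges inclusive — the validated
    attenuated anchor itself must classify attenuated); severe:
    (threshold, upper]; anything outside [lower, upper] is out_of_range,
    beyond the score interval validated in mice.
    """
    threshold = model.wmms_threshold if model is not None else 1.3
    w = float(wmms)
    if w < lower or w > upper:
        return "out_of_range"
    # small tolerance so a score printed exactly at the threshold (1.3)
    # classifies attenuated despite floating-point slope*cutoff rounding
    return "attenuated" if w <= threshold + 1e-9 else "severe"


@dataclass(frozen=True)
class ColonyCounts:
    """Genotype counts from a heterozygote-intercross colony."""

    n_wildtype: int
    n_het: int
    n_hom: int

    def __post_init__(self) -> None:
        if min(self.n_wildtype, self.n_het, self.n_hom) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_wildtype + self.n_het + self.n_hom

    @property
    def fractions(self) -> tuple[float, float, float]:
        """Observed genotype percentages (wt, het, hom)."""
        if self.n_total == 0:
            raise ValueError("empty colony")
        t = self.n_total
        return (
            100.0 * self.n_wildtype / t,
            100.0 * self.n_het / t,
            100.0 * self.n_hom / t,
        )


def prenatal_lethality(counts: ColonyCounts, *, expected_hom: float = 0.25) -> float:
    """Percent prenatal lethality from the homozygote shortfall.

    100 * (1 - observed_hom_fraction / expected_hom), floored at 0.  With the
    Mendelian expectation of 25%, a colony yielding homozygotes at 2.5%
    corresponds to 90% prenatal lethality.
    """
    if counts.n_total == 0:
        raise ValueError("empty colony")
    if expected_hom <= 0:
        raise ValueError("expected homozygote fraction must be positive")
    observed = counts.n_hom / counts.n_total
    return max(0.0, 100.0 * (1.0 - observed / expected_hom))


@dataclass(frozen=True)
class OutcomePrediction:
    wmms: float
    outcome_class: str  # attenuated | severe | out_of_range
    prenatal_fatality_pct: float | None
    hydrocephalus_pct: float | None
    formate: bool
    #: hydrocephalus may appear at any WMMS unless pups die before symptoms show
    hydrocephalus_caveat: bool = True


def predict_outcomes(
    wmms: float,
    *,
    formate: bool = False,
    model: OutcomeModel | None = None,
) -> OutcomePrediction:
    """Predict pre/post-natal disease outcome from a WMMS.

    Without formate, prenatal fatality interpolates linearly between the
    validated anchors (WMMS -0.87 -> 26%) and (WMMS 10 -> 90%, the cap);
    post-natal hydrocephalus is reported at the attenuated baseline of 31%
    (no interpolant for it is supportable — see the caveat flag).  With
    formate supplementation of dams, prenatal fatality is rescued to 29% and
    hydrocephalus to 34% regardless of WMMS.  Scores outside the validated
    [-0.87, 10] interval yield an out_of_range prediction with no numbers.
    """
    w = float(wmms)
    if w < WMMS_LOWER or w > WMMS_UPPER:
        return OutcomePrediction(
            wmms=w,
            outcome_class="out_of_range",
            prenatal_fatality_pct=None,
            hydrocephalus_pct=None,
            formate=formate,
        )
    cls = classify_wmms(w, model)
    if formate:
        fatality = FORMATE_FATALITY
        hydro = FORMATE_HYDROCEPHALUS
    else:
        frac = (w - WMMS_LOWER) / (WMMS_UPPER - WMMS_LOWER)
        fatality = FATALITY_LOWER + frac * (FATALITY_UPPER - FATALITY_LOWER)
        hydro = HYDROCEPHALUS_BASELINE
    return OutcomePrediction(
        wmms=w,
        outcome_class=cls,
        prenatal_fatality_pct=fatality,
        hydrocephalus_pct=hydro,
        formate=formate,
    )


@dataclass(frozen=True)
class MendelianTestResult:
    statistic: float
    df: int
    p: float
    significant: bool

    @property
    def conclusion(self) -> str:
        return (
            "significant at 0.05" if self.significant else "not significant at 0.05"
        )


def mendelian_chisq(
    counts: ColonyCounts, ratio: tuple[float, float, float] = (1.0, 2.0, 1.0)
) -> MendelianTestResult:
    """Pearson goodness-of-fit of genotype counts against a Mendelian ratio.

    Expected frequencies default to 1:2:1 (25% wt, 50% het, 25% hom);
    df = categories - 1.
    """
    if counts.n_total == 0:
        raise ValueError("empty colony")
    ratio = np.asarray(ratio, dtype=float)
    if (ratio <= 0).any():
        raise ValueError("expected ratio entries must be positive")
    observed = np.array([counts.n_wildtype, counts.n_het, counts.n_hom], dtype=float)
    expected = ratio / ratio.sum() * counts.n_total
    res = stats.chisquare(observed, expected)
    return MendelianTestResult(
        statistic=float(res.statistic),
        df=len(observed) - 1,
        p=float(res.pvalue),
        significant=bool(res.pvalue < 0.05),
    )
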