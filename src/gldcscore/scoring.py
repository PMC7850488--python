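"""MMS and WMMS computation, clinically-weighted training, concordance.

MMS (multiparametric mutation score) is the signed sum of the binary
indicators: every parameter weighs +1 except the conserved-substitution
indicator, which weighs -1.  WMMS replaces the unit weights with per-parameter
coefficients obtained by ordinary least squares against clinical outcome
scores (COS, 0-12) of homozygous patient mutations, with benign control
polymorphisms anchored at COS 0.  The trained intercept is stored but, by
default, excluded from the score, so an all-zero indicator vector scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_is_fitted

from .parameters import ParameterRegistry, ParameterVector

__all__ = [
    "MutationScore",
    "WeightSet",
    "ClinicalOutcome",
    "CollinearityError",
    "compute_mms",
    "WmmsWeightModel",
    "train_weights",
    "compute_wmms",
    "bin_mms",
    "score_concordance",
]

MMS_BANDS = {"zero": (0, 0), "mild": (1, 2), "moderate": (3, 4), "severe": (5, None)}


@dataclass(frozen=True)
class MutationScore:
    label: str
    mms: int
    wmms: float
    species: str = "mouse"


@dataclass(frozen=True)
class ClinicalOutcome:
    """Clinical outcome score (COS) of one homozygous mutation, 0-12."""

    label: str
    cos: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cos <= 12.0:
            raise ValueError(f"COS {self.cos} outside [0, 12]")


@dataclass
class WeightSet:
    """Trained per-parameter coefficients producing WMMS."""

    coefficients: dict[str, float]
    intercept: float = 0.0
    n_cases: int = 0
    n_controls: int = 0

    @property
    def names(self) -> list[str]:
        return list(self.coefficients)


class CollinearityError(ValueError):
    """Design matrix is rank-deficient; carries the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; dependent/duplicate columns: {self.columns}"
        )


def compute_mms(
    v: ParameterVector, registry: ParameterRegistry, *, clamp: bool = False
) -> int:
    """Signed sum of binary indicators: +1 each, -1 for conserved substitution.

    ``clamp=True`` floors the result at 0 (the convention used in
    theoretical-mutation tables, where the minimum score is set to 0).
    """
    v.check_complete(registry)
    signs = registry.signs
    s = sum(signs[name] * val for name, val in v.values.items())
    return max(s, 0) if clamp else s


def _rank_deficient_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Identify a minimal-ish set of columns causing rank deficiency via QR."""
    _, r, piv = scipy.linalg.qr(X, pivoting=True)
    diag = np.abs(np.diag(r)) if r.ndim == 2 else np.abs(r[:1])
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


class WmmsWeightModel(BaseEstimator, RegressorMixin):
    """Clinically-weighted mutation-score model (sklearn-style estimator).

    Ordinary least squares of clinical outcome scores on the binary
    parameter matrix.  After :meth:`fit`, ``coef_`` holds one weight per
    parameter and ``intercept_`` the fitted intercept; :meth:`wmms` returns
    the weighted score  sum_p w_p x_p  (intercept excluded unless
    ``include_intercept=True``), while :meth:`predict` returns the full
    regression prediction including the intercept.

    Parameters
    ----------
    include_intercept : bool
        Whether :meth:`wmms` adds the fitted intercept (default False).
    allow_rank_deficient : bool
        If False (default), exact collinearity in the design matrix raises
        :class:`CollinearityError` naming the offending columns.
    """

    def __init__(self, include_intercept: bool = False, allow_rank_deficient: bool = False):
        self.include_intercept = include_intercept
        self.allow_rank_deficient = allow_rank_deficient

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else None
        Xa = np.asarray(X, dtype=float)
        ya = np.asarray(y, dtype=float)
        if Xa.ndim != 2:
            raise ValueError("X must be 2-D (mutations x parameters)")
        if Xa.shape[0] != ya.shape[0]:
            raise ValueError(f"X has {Xa.shape[0]} rows but y has {ya.shape[0]}")
        names = (
            [str(c) for c in X_df.columns]
            if X_df is not None
            else [f"p{i}" for i in range(Xa.shape[1])]
        )
        if not self.allow_rank_deficient:
            centered = np.column_stack([Xa, np.ones(len(Xa))])
            if np.linalg.matrix_rank(centered) < centered.shape[1]:
                cols = _rank_deficient_columns(centered, names + ["<intercept>"])
                raise CollinearityError(cols)
        lr = LinearRegression().fit(Xa, ya)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xa.shape[1]
        self.coef_ = lr.coef_
        self.intercept_ = float(lr.intercept_)
        self.n_obs_ = int(Xa.shape[0])
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def wmms(self, X):
        """Weighted multiparametric mutation score(s) for indicator rows."""
        check_is_fitted(self, "coef_")
        s = np.asarray(X, dtype=float) @ self.coef_
        if self.include_intercept:
            s = s + self.intercept_
        return s

    def to_weightset(self, n_cases: int = 0, n_controls: int = 0) -> WeightSet:
        check_is_fitted(self, "coef_")
        return WeightSet(
            coefficients={n: float(w) for n, w in zip(self.feature_names_in_, self.coef_)},
            intercept=self.intercept_,
            n_cases=n_cases,
            n_controls=n_controls,
        )


def train_weights(
    X: pd.DataFrame, y, *, n_cases: int | None = None, n_controls: int | None = None
) -> WeightSet:
    """Train per-parameter weights by OLS against clinical outcome scores.

    ``X`` is the binary parameter matrix (rows: homozygous patient mutations
    plus benign controls), ``y`` the COS values (controls at 0).
    Deterministic; rank deficiency raises :class:`CollinearityError`.
    """
    model = WmmsWeightModel().fit(X, y)
    ya = np.asarray(y, dtype=float)
    if n_cases is None:
        n_cases = int((ya > 0).sum())
    if n_controls is None:
        n_controls = int((ya == 0).sum())
    return model.to_weightset(n_cases=n_cases, n_controls=n_controls)


def compute_wmms(
    v: ParameterVector, w: WeightSet, *, include_intercept: bool = False
) -> float:
    """Weighted score of one mutation:  sum_p w_p x_p  (+ intercept if asked)."""
    if set(v.values) != set(w.coefficients):
        missing = set(w.coefficients) - set(v.values)
        extra = set(v.values) - set(w.coefficients)
        raise ValueError(
            f"{v.label}: parameter names do not match weights "
            f"(missing={sorted(missing)}, extra={sorted(extra)})"
        )
    s = sum(w.coefficients[name] * val for name, val in v.values.items())
    if include_intercept:
        s += w.intercept
    return float(s)


def bin_mms(scores) -> dict[str, int]:
    """Count MMS values per severity band: 0 / 1-2 mild / 3-4 moderate / >=5 severe.

    Scores below 0 (possible before clamping, via the conserved-substitution
    indicator) fall into the ``"zero"`` band, matching the clamp-at-0 table
    convention.  Counts always sum to the input size.
    """
    counts = {band: 0 for band in MMS_BANDS}
    for s in scores:
        si = int(s)
        if si != s:
            raise ValueError(f"MMS values must be integers, got {s}")
        if si <= 0:
            counts["zero"] += 1
        elif si <= 2:
            counts["mild"] += 1
        elif si <= 4:
            counts["moderate"] += 1
        else:
            counts["severe"] += 1
    return counts


def score_concordance(pairs, *, decimals: int = 2) -> float:
    """Fraction of (hWMMS, mWMMS) pairs that agree exactly after rounding.

    Printed WMMS values carry two decimals, hence the default rounding.
    Returns NaN for an empty input.
    """
    pairs = list(pairs)
    if not pairs:
        return float("nan")
    n_eq = sum(
        1 for h, m in pairs if round(float(h), decimals) == round(float(m), decimals)
    )
    return n_eq / len(pairs)
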