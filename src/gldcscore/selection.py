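"""Ranked-prediction models for choosing mutations to engineer in mice.

Two models are provided:

* **Attenuated ranking** — among mouse counterparts of prevalent attenuated
  human mutations, Score A rewards a high mouse WMMS (min-max normalized so
  the top candidate scores 1 and the bottom 0) and Score B rewards agreement
  between mouse and human WMMS (1 for no difference, 0 for the cohort-maximal
  difference).  Candidates are ranked by the sum.
* **Severe five-criterion model** — a mutation scores one point for each of:
  mouse WMMS at or above the severe threshold (9.94 in the GLDC analysis),
  residue conserved between species, mouse WMMS equal to the human WMMS, the
  substitution not introducing a proline, and location in the active-site
  region.  The handful of theoretical mutations reaching 5/5 are the severe
  engineering candidates.

Double mutations are explicitly unsupported: the parameter weights are
trained on single-point mutations only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import ActiveSiteAnnotation
from .sequences import MissenseMutation

__all__ = [
    "AttenuatedRanking",
    "SevereCriteria",
    "WelchResult",
    "rank_attenuated",
    "score_severe_criteria",
    "severe_criteria_table",
    "compare_active_site",
    "reject_double_mutation",
]

#: Mouse WMMS threshold anchored at the lead severe candidate.
SEVERE_WMMS_THRESHOLD = 9.94


@dataclass
class AttenuatedRanking:
    """Per-candidate Score A / Score B table with competition ranks."""

    table: pd.DataFrame  # columns: label, mwmms, hwmms, score_a, score_b, total, rank

    @property
    def top(self) -> str:
        return str(self.table.iloc[0]["label"])


def rank_attenuated(candidates) -> AttenuatedRanking:
    """Rank attenuated-disease candidates by Score A + Score B.

    ``candidates``: iterable of ``(label, mwmms, hwmms)`` or a DataFrame with
    those columns.  Score A = (mWMMS - min) / (max - min); Score B =
    1 - |mWMMS - hWMMS| / max|mWMMS - hWMMS| over the cohort (1 when every
    difference is 0).  Ties share the better (competition) rank; row order
    breaks ties deterministically by label.
    """
    if isinstance(candidates, pd.DataFrame):
        df = candidates[["label", "mwmms", "hwmms"]].copy()
    else:
        df = pd.DataFrame(list(candidates), columns=["label", "mwmms", "hwmms"])
    if len(df) < 2:
        raise ValueError("ranking needs at least 2 candidates")
    m = df["mwmms"].astype(float)
    lo, hi = m.min(), m.max()
    df["score_a"] = 0.5 if hi == lo else (m - lo) / (hi - lo)
    diff = (m - df["hwmms"].astype(float)).abs()
    dmax = diff.max()
    df["score_b"] = 1.0 if dmax == 0 else 1.0 - diff / dmax
    df["total"] = df["score_a"] + df["score_b"]
    df = df.sort_values(["total", "label"], ascending=[False, True], kind="stable")
    df["rank"] = (
        df["total"].rank(method="min", ascending=False).astype(int)
    )
    return AttenuatedRanking(df.reset_index(drop=True))


@dataclass(frozen=True)
class SevereCriteria:
    """The five binary severe-candidate criteria and their sum."""

    label: str
    wmms_threshold: int
    species_conserved: int
    wmms_aligned: int
    no_proline: int
    active_site: int

    @property
    def total(self) -> int:
        return (
            self.wmms_threshold
            + self.species_conserved
            + self.wmms_aligned
            + self.no_proline
            + self.active_site
        )


def score_severe_criteria(
    m: MissenseMutation,
    mwmms: float,
    hwmms: float | None,
    active_site: ActiveSiteAnnotation | frozenset | set,
    threshold: float = SEVERE_WMMS_THRESHOLD,
    *,
    decimals: int = 2,
) -> SevereCriteria:
    """Score one mouse mutation against the five severe-model criteria.

    ``hwmms`` is ``None`` when the residue is not conserved in human, which
    zeroes both the conservation and the score-alignment criteria.
    Reachability by single-nucleotide substitution is implicit for mutations
    produced by enumeration.
    """
    if active_site is None:
        raise ValueError("active-site annotation is required")
    conserved = int(hwmms is not None)
    aligned = int(
        conserved and round(float(mwmms), decimals) == round(float(hwmms), decimals)
    )
    return SevereCriteria(
        label=m.label,
        wmms_threshold=int(float(mwmms) >= threshold),
        species_conserved=conserved,
        wmms_aligned=aligned,
        no_proline=int(m.alt_aa != "P"),
        active_site=int(m.protein_position in active_site),
    )


def severe_criteria_table(rows) -> pd.DataFrame:
    """Criteria matrix for many mutations, one row per SevereCriteria."""
    recs = [
        {
            "label": c.label,
            "wmms_threshold": c.wmms_threshold,
            "species_conserved": c.species_conserved,
            "wmms_aligned": c.wmms_aligned,
            "no_proline": c.no_proline,
            "active_site": c.active_site,
            "total": c.total,
        }
        for c in rows
    ]
    return pd.DataFrame(recs).sort_values(
        ["total", "label"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class WelchResult:
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float


def compare_active_site(scores_in, scores_out) -> WelchResult:
    """Welch two-sample t-test of WMMS inside vs outside the active site.

    Unpaired, two-tailed, unequal variances (Satterthwaite degrees of
    freedom) — appropriate because the two groups' variances differ.
    """
    a = np.asarray(list(scores_in), dtype=float)
    b = np.asarray(list(scores_out), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


def reject_double_mutation(labels) -> None:
    """Refuse multi-mutation haplotypes (e.g. 'G561R,S562F').

    The parameter weights were trained on proteins carrying single point
    mutations, so a combined score for a double mutation is undefined.
    """
    raise ValueError(
        f"cannot score {labels!r}: the utilized parameter weights were trained "
        "on proteins with single-point mutations, so double mutations cannot "
        "be assigned a WMMS"
    )
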