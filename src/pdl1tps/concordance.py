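"""Rater-concordance statistics for TPS score tables.

A score table holds, per slide, the automated TPS and m >= 2 visual TPS
values.  The module provides Lin's concordance correlation coefficient
(the original population-moment estimator), the Pearson coefficient, the
mean absolute error, dichotomized agreement rates (OPA/NPA/PPA) at the
clinical cut-off, the per-slide inter-rater variability

    Δ = mean over unordered rater pairs of |TPS_i − TPS_j|,

the median consolidation of visual scores, restricted-concordance curves
(metrics recomputed on the slides whose Δ stays below a threshold), and
the leave-one-out-median analysis comparing each of the four scores with
the per-slide median of the remaining three.

Undefined statistics (constant inputs, empty strata) are returned as NaN
and written to CSV as empty cells — never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .scoring import POSITIVE, pdl1_status


@dataclass
class ConcordanceReport:
    """Agreement between a reference and a test score vector.

    NaN marks an undefined statistic (e.g. NPA without reference-negative
    slides, or coefficients on a constant vector).
    """

    lcc: float
    pcc: float
    mae: float
    opa: float = np.nan
    npa: float = np.nan
    ppa: float = np.nan
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "lcc": self.lcc, "pcc": self.pcc, "mae": self.mae,
            "opa": self.opa, "npa": self.npa, "ppa": self.ppa, "n": self.n,
        }


def _as_arrays(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    return x, y


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    2·cov(x, y) / (var(x) + var(y) + (mean(x) − mean(y))²) with population
    (1/n) moments; 1 iff x == y elementwise.  NaN for constant input.
    """
    x, y = _as_arrays(x, y)
    if len(x) < 2:
        raise ValueError("need at least 2 paired scores")
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def pearson(x, y) -> float:
    """Pearson correlation coefficient; NaN for constant input."""
    x, y = _as_arrays(x, y)
    if len(x) < 2:
        raise ValueError("need at least 2 paired scores")
    if x.var() == 0 or y.var() == 0:
        return float("nan")
    from scipy import stats

    return float(stats.pearsonr(x, y).statistic)


def mae(x, y) -> float:
    """Mean absolute error between paired scores, in percent TPS."""
    x, y = _as_arrays(x, y)
    return float(np.mean(np.abs(x - y)))


def agreement_at_cutoff(reference, test, cutoff: float = 25.0) -> tuple[float, float, float]:
    """(OPA, NPA, PPA) of dichotomized status calls.

    The *first* argument is the reference: NPA/PPA condition on its
    negative/positive calls.  With a = both positive, d = both negative,
    b = reference positive only, c = test positive only:
    OPA = (a+d)/n, NPA = d/(c+d), PPA = a/(a+b).  An empty stratum yields
    NaN.
    """
    reference, test = _as_arrays(reference, test)
    if not 0.0 < cutoff < 100.0:
        raise ValueError("cutoff must lie strictly inside (0, 100)")
    ref_pos = np.array([pdl1_status(v, cutoff) == POSITIVE for v in reference])
    test_pos = np.array([pdl1_status(v, cutoff) == POSITIVE for v in test])
    a = int(np.sum(ref_pos & test_pos))
    b = int(np.sum(ref_pos & ~test_pos))
    c = int(np.sum(~ref_pos & test_pos))
    d = int(np.sum(~ref_pos & ~test_pos))
    n = a + b + c + d
    opa = (a + d) / n if n else float("nan")
    npa = d / (c + d) if (c + d) else float("nan")
    ppa = a / (a + b) if (a + b) else float("nan")
    return opa, npa, ppa


def inter_rater_delta(scores) -> float:
    """Mean absolute pairwise difference among one slide's visual scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("inter-rater variability needs at least 2 scores")
    diffs = [abs(a - b) for a, b in combinations(scores, 2)]
    return float(np.mean(diffs))


def consolidate_median(scores) -> float:
    """Consolidated visual score: the per-slide median (even counts use the
    mean of the central pair)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to consolidate")
    return float(np.median(scores))


def compare_scores(reference, test, cutoff: float = 25.0) -> ConcordanceReport:
    """Full concordance report of a test score against a reference score."""
    reference, test = _as_arrays(reference, test)
    opa, npa, ppa = agreement_at_cutoff(reference, test, cutoff)
    return ConcordanceReport(
        lcc=lin_ccc(reference, test),
        pcc=pearson(reference, test),
        mae=mae(reference, test),
        opa=opa, npa=npa, ppa=ppa, n=len(reference),
    )


@dataclass
class ScoreTable:
    """Per-slide automated and visual TPS values.

    ``visual`` has shape (n_slides, m raters); ``automated`` has length
    n_slides.  NaN marks a missing/undefined score; slides with any missing
    value are excluded from the statistics that need them.
    """

    slide_ids: list[str]
    visual: np.ndarray
    automated: np.ndarray

    def __post_init__(self):
        self.visual = np.asarray(self.visual, dtype=float)
        self.automated = np.asarray(self.automated, dtype=float)
        if self.visual.ndim != 2 or self.visual.shape[0] != len(self.slide_ids):
            raise ValueError("visual must be (n_slides, m_raters)")
        if self.automated.shape != (len(self.slide_ids),):
            raise ValueError("automated must have one score per slide")
        with np.errstate(invalid="ignore"):
            bad = ((self.visual < 0) | (self.visual > 100)).any() or (
                (self.automated < 0) | (self.automated > 100)
            ).any()
        if bad:
            raise ValueError("scores must lie in [0, 100] or be NaN")

    @property
    def m_raters(self) -> int:
        return self.visual.shape[1]

    def complete_rows(self) -> np.ndarray:
        return np.isfinite(self.visual).all(axis=1) & np.isfinite(self.automated)

    def deltas(self) -> np.ndarray:
        """Per-slide inter-rater variability Δ of the visual scores."""
        if self.m_raters < 2:
            raise ValueError("Δ needs at least 2 raters")
        return np.array([inter_rater_delta(row) for row in self.visual])

    def consolidated(self) -> np.ndarray:
        return np.array([consolidate_median(row) for row in self.visual])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"slide_id": self.slide_ids})
        for j in range(self.m_raters):
            df[f"tps_rater_{j + 1}"] = self.visual[:, j]
        df["tps_auto"] = self.automated
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ScoreTable":
        rater_cols = sorted(c for c in df.columns if c.startswith("tps_rater_"))
        return cls(
            slide_ids=[str(s) for s in df["slide_id"]],
            visual=df[rater_cols].to_numpy(dtype=float),
            automated=df["tps_auto"].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls.from_dataframe(pd.read_csv(path))


def evaluate_table(table: ScoreTable, cutoff: float = 25.0) -> ConcordanceReport:
    """Automated TPS vs the consolidated (median) visual score."""
    keep = table.complete_rows()
    return compare_scores(
        table.consolidated()[keep], table.automated[keep], cutoff
    )


@dataclass
class RestrictedPoint:
    threshold: float
    included_fraction: float
    report: ConcordanceReport | None


def restricted_concordance(
    table: ScoreTable, delta_grid, cutoff: float = 25.0
) -> list[RestrictedPoint]:
    """Concordance of automated vs consolidated visual TPS, restricted to
    slides whose inter-rater variability Δ stays below each threshold.

    Each point carries the fraction of slides included; subsets smaller
    than 2 slides yield a ``None`` report (undefined, flagged).
    """
    keep = table.complete_rows()
    deltas = table.deltas()[keep]
    ref = table.consolidated()[keep]
    auto = table.automated[keep]
    points = []
    for thr in delta_grid:
        sel = deltas <= thr
        frac = float(np.mean(sel)) if len(sel) else float("nan")
        if sel.sum() < 2:
            points.append(RestrictedPoint(float(thr), frac, None))
        else:
            points.append(
                RestrictedPoint(float(thr), frac, compare_scores(ref[sel], auto[sel], cutoff))
            )
    return points


def leave_one_out_median(table: ScoreTable, cutoff: float = 25.0) -> dict[str, ConcordanceReport]:
    """Each score source vs the per-slide median of the remaining sources.

    The automated score and the m visual scores are treated symmetrically
    (m + 1 sources, hence m + 1 reports; the study design is 3 visual + 1
    automated = 4).
    """
    keep = table.complete_rows()
    sources = {f"rater_{j + 1}": table.visual[keep, j] for j in range(table.m_raters)}
    sources["automated"] = table.automated[keep]
    names = list(sources)
    reports = {}
    for name in names:
        others = np.stack([sources[o] for o in names if o != name], axis=1)
        ref = np.median(others, axis=1)
        reports[name] = compare_scores(ref, sources[name], cutoff)
    return reports


def pairwise_reports(table: ScoreTable, cutoff: float = 25.0) -> pd.DataFrame:
    """All ordered source pairs (rows = reference) with Lcc/Pcc/MAE and
    OPA/NPA/PPA, the layout of the study's pairwise agreement tables."""
    keep = table.complete_rows()
    sources = {f"rater_{j + 1}": table.visual[keep, j] for j in range(table.m_raters)}
    sources["automated"] = table.automated[keep]
    rows = []
    for ref_name, ref in sources.items():
        for test_name, test in sources.items():
            if ref_name == test_name:
                continue
            rep = compare_scores(ref, test, cutoff)
            rows.append({"reference": ref_name, "test": test_name, **rep.as_dict()})
    return pd.DataFrame(rows)


def restricted_to_dataframe(points: list[RestrictedPoint]) -> pd.DataFrame:
    rows = []
    for p in points:
        row = {"delta_threshold": p.threshold, "included_fraction": p.included_fraction}
        row.update(p.report.as_dict() if p.report is not None else
                   {k: np.nan for k in ("lcc", "pcc", "mae", "opa", "npa", "ppa", "n")})
        rows.append(row)
    return pd.DataFrame(rows)
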