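"""Cohort-level nonparametric statistics.

The analysis layer mirrors a standard two-group inpatient comparison:
Shapiro-Wilk normality screening (annotation only — the comparisons stay
nonparametric regardless), Mann-Whitney U tests for the five rest-activity
rhythm indicators, chi-square / Fisher exact tests for categorical
variables, and Spearman rank correlations between the indicators and the
clinical scores (Barthel Index over everyone, 4AT over the group it was
administered to).

Conventions (the upstream study reports only p-values, so these are this
package's documented choices, not inferred ones):

* U statistic reported as ``min(U_a, U_b)``; midrank tie handling.
* Mann-Whitney p: exact by full enumeration when ``n_a + n_b <= 12`` and
  the pooled sample is tie-free, otherwise the normal approximation with
  tie and continuity correction.
* Spearman p: exact by permutation enumeration for ``n <= 7``, otherwise
  the t approximation.
* Quartiles by linear interpolation between order statistics.
* Two-sided tests throughout; alpha = .05; no multiplicity adjustment by
  default (``adjust="holm"`` is available).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    ActirhythmError,
    ConstantSeriesError,
    InsufficientGroupSizeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

RAR_VARIABLES = ("IS", "IV", "M10", "L5", "RA")
EXACT_MW_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 7

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "CategoricalResult",
    "NormalityResult",
    "StudyReport",
    "mann_whitney",
    "spearman",
    "compare_categorical",
    "normality_screen",
    "run_study",
]


@dataclass
class ComparisonResult:
    variable: str
    groups: tuple[str, str]
    medians: tuple[float, float]
    iqrs: tuple[tuple[float, float], tuple[float, float]]
    ns: tuple[int, int]
    test_name: str
    statistic: float  # min(U_a, U_b)
    p_value: float
    p_adjusted: float | None = None


@dataclass
class CorrelationResult:
    metric: str
    score: str
    rho: float
    p_value: float
    n: int
    method: str
    p_adjusted: float | None = None


@dataclass
class CategoricalResult:
    test_name: str
    statistic: float
    p_value: float
    note: str = ""


@dataclass
class NormalityResult:
    variable: str
    group: str
    W: float
    p_value: float
    n: int


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return float(med), (float(q1), float(q3))


def _mw_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumeration of all assignments.

    Valid only for tie-free pooled samples (the caller checks); p is the
    fraction of the C(n, n_a) group assignments whose U is at least as
    extreme (|U - mu|) as observed.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, na = pooled.size, a.size
    mu = na * (n - na) / 2.0
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for combo in itertools.combinations(range(n), na):
        u = ranks[list(combo)].sum() - na * (na + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


def mann_whitney(a, b, variable: str = "", groups: tuple[str, str] = ("A", "B")) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two samples.

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with tie and continuity correction.  Reports per-group
    median and IQR alongside the test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientGroupSizeError(
            f"insufficient group size: n={a.size} vs n={b.size} (need >= 2 each)"
        )
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MW_MAX_N and not ties:
        u_a, p = _mw_exact_p(a, b)
        test_name = "Mann-Whitney U (exact)"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u_a, p = float(res.statistic), float(res.pvalue)
        test_name = "Mann-Whitney U (normal approx., tie/continuity corrected)"
    u_min = min(u_a, a.size * b.size - u_a)
    med_a, iqr_a = _median_iqr(a)
    med_b, iqr_b = _median_iqr(b)
    return ComparisonResult(
        variable=variable,
        groups=groups,
        medians=(med_a, med_b),
        iqrs=(iqr_a, iqr_b),
        ns=(a.size, b.size),
        test_name=test_name,
        statistic=float(u_min),
        p_value=min(float(p), 1.0),
    )


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho (permute one rank vector)."""
    n = rx.size
    cx = rx - rx.mean()
    denom = math.sqrt((cx**2).sum() * ((ry - ry.mean()) ** 2).sum())
    perms = np.array(list(itertools.permutations(ry)))
    rhos = (perms - ry.mean()) @ cx / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, metric: str = "", score: str = "") -> CorrelationResult:
    """Spearman rank correlation with two-sided p.

    Pairs with a missing value are dropped (and reflected in ``n``); rho
    is the Pearson correlation of midranks; p is exact by permutation for
    n <= 7, otherwise the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValidationError(f"need >= 4 complete pairs, got {n}")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.unique(rx).size == 1 or np.unique(ry).size == 1:
        raise ConstantSeriesError("undefined correlation: zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _spearman_exact_p(rx, ry, rho)
        method = "exact permutation"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "t approximation"
    return CorrelationResult(metric=metric, score=score, rho=rho, p_value=p, n=n, method=method)


def compare_categorical(table, method: str = "auto") -> CategoricalResult:
    """Chi-square (no continuity correction) or Fisher exact test of a 2xk table.

    ``method="auto"`` uses chi-square, switching to the Fisher exact test
    (two-sided by the point-probability rule) for 2x2 tables with any
    expected cell below 5; the choice is logged.
    """
    table = np.asarray(table)
    if table.ndim != 2 or np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValidationError("table must be a 2-D array of nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("zero margin in contingency table")
    expected = sps.contingency.expected_freq(table)
    if method == "auto":
        method = "fisher" if table.shape == (2, 2) and expected.min() < 5 else "chi2"
        logger.info("compare_categorical: min expected %.2f -> %s", expected.min(), method)
    if method == "fisher":
        if table.shape != (2, 2):
            raise ValidationError("Fisher exact test requires a 2x2 table")
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return CategoricalResult("Fisher exact", float(odds), float(p), note="statistic = odds ratio")
    if method != "chi2":
        raise ValidationError(f"unknown method {method!r}")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return CategoricalResult("chi-square", float(chi2), float(p))


def normality_screen(x, variable: str = "", group: str = "") -> NormalityResult:
    """Shapiro-Wilk screen (annotation only; the pipeline stays nonparametric)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ActirhythmError(f"not applicable: need n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ActirhythmError("not applicable: constant sample")
    w, p = sps.shapiro(x)
    return NormalityResult(variable=variable, group=group, W=float(w), p_value=float(p), n=x.size)


# ---------------------------------------------------------------------------
# Study report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Group-contrast and correlation blocks for one cohort."""

    comparisons: list[ComparisonResult]
    correlations: list[CorrelationResult]
    normality: list[NormalityResult]
    groups: tuple[str, str]
    alpha: float
    adjust: str | None
    notes: list[str] = field(default_factory=list)

    def _p(self, r) -> float:
        return r.p_adjusted if r.p_adjusted is not None else r.p_value

    def significant(self, variable: str) -> bool:
        for r in self.comparisons:
            if r.variable == variable:
                return self._p(r) < self.alpha
        raise KeyError(variable)

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for r in self.comparisons:
            row = {
                "variable": r.variable,
                f"{r.groups[0]}_median_iqr": _fmt_med_iqr(r.medians[0], r.iqrs[0]),
                f"{r.groups[1]}_median_iqr": _fmt_med_iqr(r.medians[1], r.iqrs[1]),
                "U": r.statistic,
                "p": round(r.p_value, 4),
                "significant": self._p(r) < self.alpha,
            }
            if r.p_adjusted is not None:
                row["p_holm"] = round(r.p_adjusted, 4)
            rows.append(row)
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        rows = []
        for r in self.correlations:
            row = {
                "score": r.score,
                "metric": r.metric,
                "rho": round(r.rho, 3),
                "p": round(r.p_value, 4),
                "n": r.n,
                "significant": self._p(r) < self.alpha,
            }
            if r.p_adjusted is not None:
                row["p_holm"] = round(r.p_adjusted, 4)
            rows.append(row)
        return pd.DataFrame(rows)

    def normality_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"variable": r.variable, "group": r.group, "W": round(r.W, 4),
                 "p": round(r.p_value, 4), "n": r.n}
                for r in self.normality
            ]
        )

    def to_text(self) -> str:
        lines = [
            f"Rest-activity rhythm group comparison ({self.groups[0]} vs {self.groups[1]})",
            f"alpha = {self.alpha}; adjustment = {self.adjust or 'none'}",
            "",
            "Group contrasts (median (IQR), Mann-Whitney U):",
            self.comparison_table().to_string(index=False),
            "",
            "Spearman correlations with clinical scores:",
            self.correlation_table().to_string(index=False),
            "",
            "Normality screen (Shapiro-Wilk; annotation only):",
            self.normality_table().to_string(index=False),
        ]
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def _fmt_med_iqr(med: float, iqr: tuple[float, float]) -> str:
    return f"{med:.2f} ({iqr[0]:.2f}-{iqr[1]:.2f})"


def _holm(results) -> None:
    from statsmodels.stats.multitest import multipletests

    pvals = [r.p_value for r in results]
    if not pvals:
        return
    _, adj, _, _ = multipletests(pvals, method="holm")
    for r, p in zip(results, adj):
        r.p_adjusted = float(p)


def run_study(cohort: pd.DataFrame, alpha: float = 0.05, adjust: str | None = None) -> StudyReport:
    """Full statistical layer on a joined cohort + metrics table.

    ``cohort`` needs columns ``participant_id, group, barthel_index,
    four_at`` (4AT NaN where not administered) plus the five indicators
    ``IS, IV, M10, L5, RA``.  Produces the group-contrast block (median
    (IQR) per group + Mann-Whitney p per indicator), the correlation
    block (Barthel Index vs each indicator over everyone; 4AT vs each
    indicator over participants with a 4AT), and a Shapiro-Wilk
    annotation block.  No multiplicity adjustment by default (noted in
    the report); ``adjust="holm"`` applies Holm within each family.
    """
    required = {"participant_id", "group", "barthel_index", "four_at", *RAR_VARIABLES}
    missing = required - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    if cohort["participant_id"].duplicated().any():
        raise ValidationError("duplicate participant_id")
    labels = sorted(cohort["group"].unique())
    if len(labels) != 2:
        raise ValidationError(f"exactly two groups required, got {labels}")
    ga = cohort[cohort["group"] == labels[0]]
    gb = cohort[cohort["group"] == labels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise InsufficientGroupSizeError(
            f"insufficient group size: {labels[0]} n={len(ga)}, {labels[1]} n={len(gb)}"
        )

    comparisons = [
        mann_whitney(ga[v].to_numpy(), gb[v].to_numpy(), variable=v, groups=(labels[0], labels[1]))
        for v in RAR_VARIABLES
    ]
    correlations = []
    for v in RAR_VARIABLES:
        correlations.append(
            spearman(cohort[v], cohort["barthel_index"], metric=v, score="barthel_index")
        )
    has_4at = cohort["four_at"].notna()
    if has_4at.sum() >= 4:
        sub = cohort[has_4at]
        for v in RAR_VARIABLES:
            correlations.append(spearman(sub[v], sub["four_at"], metric=v, score="four_at"))
    else:
        logger.warning("4AT present for %d participants (<4); correlation block skipped",
                       int(has_4at.sum()))

    normality = []
    for v in RAR_VARIABLES:
        for label, g in ((labels[0], ga), (labels[1], gb)):
            try:
                normality.append(normality_screen(g[v].to_numpy(), variable=v, group=label))
            except ActirhythmError as exc:
                logger.warning("normality screen skipped for %s/%s: %s", v, label, exc)

    notes = []
    if adjust is None:
        notes.append("p-values unadjusted for multiplicity (design choice; use adjust='holm' to change)")
    elif adjust == "holm":
        _holm(comparisons)
        _holm([c for c in correlations if c.score == "barthel_index"])
        _holm([c for c in correlations if c.score == "four_at"])
        notes.append("Holm adjustment applied within each test family")
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    n_4at = int(has_4at.sum())
    notes.append(f"4AT correlations computed over the {n_4at} participants with a 4AT score")
    return StudyReport(
        comparisons=comparisons,
        correlations=correlations,
        normality=normality,
        groups=(labels[0], labels[1]),
        alpha=alpha,
        adjust=adjust,
        notes=notes,
    )
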