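"""Donor-level group statistics.

Two-group comparisons follow a normality-gated routing rule: if both
groups are consistent with a Gaussian (Shapiro–Wilk at alpha=0.05), an
unpaired two-sided Student's t-test is used, otherwise the
Mann–Whitney U test.  The age × LPS factorial design is analysed with a
two-way ANOVA with interaction, using Type II sums of squares because
the cohorts are unbalanced (16 young vs 14 old donors).  Significance
symbols follow the ns/*/**/***/**** convention at
p ≤ 0.05 / 0.01 / 0.001 / 0.0001.

qPCR fold changes use the 2^−ΔΔCt method: Ct values of the target gene
are normalized to a reference gene (ΔCt) and then to a calibrator
condition (ΔΔCt); fold change is 2 to the minus ΔΔCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ConfigError


class AnalysisError(ValueError):
    """Raised when a statistical analysis cannot be carried out."""


@dataclass(frozen=True)
class DonorRecord:
    """One donor × treatment observation."""

    donor_id: str
    age_group: str                 # young | old
    gender: str                    # female | male
    treatment: str                 # control | LPS | antiCD11c | Mg2plus | uncoated
    adherent_density_mm2: float
    rolling_density_mm2: float
    mean_velocity_um_s: float = float("nan")


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    test_name: str                 # t_unpaired | mann_whitney_u
    statistic: float
    p_value: float
    group_summaries: tuple[GroupSummary, GroupSummary]
    significance_symbol: str


@dataclass(frozen=True)
class AnovaResult:
    factor_p_values: dict[str, float]    # age, lps, interaction
    f_statistics: dict[str, float]
    design_counts: dict[tuple[str, str], int]


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


def significance_symbol(p: float) -> str:
    """ns above 0.05; then one star per decade down to 0.0001."""
    if np.isnan(p):
        return "ns"
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _summary(values: np.ndarray) -> GroupSummary:
    n = len(values)
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GroupSummary(mean=float(values.mean()), sem=sem, n=n)


def normality_gate(samples: list[float], alpha: float = 0.05) -> bool:
    """Shapiro–Wilk decision: True if consistent with a Gaussian.

    Degenerate inputs (n < 3 or zero variance) cannot support the
    Gaussian assumption and return False, routing the caller to the
    rank-based test.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size < 3:
        warnings.warn("n < 3: normality cannot be assessed; treating as "
                      "non-normal", stacklevel=2)
        return False
    if arr.std() == 0:
        return False
    _, p = sps.shapiro(arr)
    return bool(p > alpha)


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.

    Exact enumeration for small samples (both n ≤ 8, no ties), else the
    tie-corrected normal approximation with continuity correction.
    """
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(
    a: list[float],
    b: list[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> GroupComparison:
    """Normality-gated two-group comparison.

    Unpaired two-sided Student's t-test (equal-variance classic form by
    default, Welch via ``welch=True``) when both groups pass the
    Shapiro–Wilk gate; Mann–Whitney U otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, g in (("a", a), ("b", b)):
        if g.size < 3:
            raise AnalysisError(
                f"group {name!r} has n={g.size} < 3 observations"
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        both_normal = normality_gate(a, alpha) and normality_gate(b, alpha)
    if both_normal:
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        name = "t_unpaired"
        stat, p = float(stat), float(p)
    else:
        stat, p = _mann_whitney(a, b)
        name = "mann_whitney_u"
    return GroupComparison(
        test_name=name,
        statistic=stat,
        p_value=p,
        group_summaries=(_summary(a), _summary(b)),
        significance_symbol=significance_symbol(p),
    )


def two_way_anova_age_lps(
    records: list[DonorRecord],
    response: str = "adherent_density_mm2",
) -> AnovaResult:
    """Two-way ANOVA with interaction on the age × LPS 2×2 design.

    Type II sums of squares handle the unbalanced cohort sizes.  All
    four design cells (young/old × control/LPS) must be non-empty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = [r for r in records if r.treatment in ("control", "LPS")]
    df = pd.DataFrame({
        "age": [r.age_group for r in rows],
        "lps": [r.treatment for r in rows],
        "y": [getattr(r, response) for r in rows],
    })
    counts: dict[tuple[str, str], int] = {}
    for age in ("young", "old"):
        for trt in ("control", "LPS"):
            n = int(((df.age == age) & (df.lps == trt)).sum())
            if n == 0:
                raise AnalysisError(
                    f"empty design cell: age={age}, treatment={trt}"
                )
            counts[(age, trt)] = n
    if df["y"].nunique() == 1:
        # no variance anywhere: no factor explains anything
        zero = {"age": 0.0, "lps": 0.0, "interaction": 0.0}
        one = {"age": 1.0, "lps": 1.0, "interaction": 1.0}
        return AnovaResult(factor_p_values=one, f_statistics=zero,
                           design_counts=counts)
    model = smf.ols("y ~ C(age) * C(lps)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    key = {"C(age)": "age", "C(lps)": "lps", "C(age):C(lps)": "interaction"}
    pvals, fstats = {}, {}
    for row_name, out_name in key.items():
        pvals[out_name] = float(table.loc[row_name, "PR(>F)"])
        fstats[out_name] = float(table.loc[row_name, "F"])
    return AnovaResult(
        factor_p_values=pvals, f_statistics=fstats, design_counts=counts,
    )


def lps_response_ratio(stimulated: float, control: float) -> float:
    """Relative adhesion after stimulation: stimulated / control.

    Percent increase is (ratio - 1) * 100.
    """
    if control <= 0:
        raise AnalysisError(
            "control density must be positive to form a response ratio"
        )
    return stimulated / control


def percent_increase(stimulated: float, control: float) -> float:
    return (lps_response_ratio(stimulated, control) - 1.0) * 100.0


def ddct_fold_change(
    ct_target: float,
    ct_reference: float,
    calibrator_delta_ct: float,
    gene: str = "",
) -> ExpressionResult:
    """2^−ΔΔCt relative expression.

    ΔCt = Ct(target) − Ct(reference); ΔΔCt = ΔCt − ΔCt(calibrator);
    fold change = 2^(−ΔΔCt).  One PCR cycle of difference doubles or
    halves the fold change.
    """
    for name, v in (("ct_target", ct_target), ("ct_reference", ct_reference),
                    ("calibrator_delta_ct", calibrator_delta_ct)):
        if not np.isfinite(v):
            raise ConfigError(f"{name} must be finite, got {v}")
    dct = ct_target - ct_reference
    ddct = dct - calibrator_delta_ct
    return ExpressionResult(
        gene=gene,
        delta_ct=dct,
        delta_delta_ct=ddct,
        fold_change=float(2.0 ** (-ddct)),
    )


def response_variance_by_group(
    ratios: dict[str, list[float]],
) -> dict[str, float]:
    """Sample variance of per-donor LPS response ratios per age group.

    Captures whether one cohort responds homogeneously (small variance)
    while the other is heterogeneous.
    """
    out: dict[str, float] = {}
    for group, values in ratios.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise AnalysisError(
                f"group {group!r} needs n >= 2 to estimate a variance"
            )
        out[group] = float(arr.var(ddof=1))
    return out
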