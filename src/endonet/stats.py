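"""Three-group endophenotype statistics.

An endophenotype is a heritable, quantifiable marker present both in
affected individuals and in their unaffected relatives. Operationally, a
metric shows an endophenotype pattern when a one-way ANOVA over the three
groups is significant, the group means are ordered monotonically
CON > SIB > ASC (or the reverse for a reversed pattern), and the ASC-vs-CON
planned comparison is significant; the SIB-vs-CON comparison is reported
but not required.

ANOVA can be computed either from raw per-subject values or from printed
summary statistics (group means, SDs and sizes), which are algebraically
equivalent. t-tests use the Student (pooled-variance) form, matching
df = n1 + n2 - 2. No multiple-comparison correction is applied anywhere;
reports annotate the number of tests performed instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ENDOPHENOTYPE_GROUPS = ("CON", "SIB", "ASC")


def load_demographics_summary() -> pd.DataFrame:
    """Packaged demographic summary table of the emulated matched cohort.

    Rows give the group mean, sample SD and size for each matching measure
    (age, IQ scales, autism-trait questionnaires) of the three 14-subject
    groups. Feeding a measure's rows to :func:`anova_from_summary`
    reconstructs the matching F statistic from the summaries alone.
    """
    from importlib import resources

    with resources.files("endonet.data").joinpath(
        "cohort_demographics_summary.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def anova_for_measure(demographics: pd.DataFrame, measure: str) -> AnovaResult:
    """Summary-statistics ANOVA for one measure of a demographics table."""
    rows = demographics[demographics["measure"] == measure]
    if rows.empty:
        raise ValueError(f"unknown measure {measure!r}")
    return anova_from_summary(
        rows["mean"].to_numpy(), rows["sd"].to_numpy(), rows["n"].to_numpy()
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def _as_group_arrays(sample: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]):
    if isinstance(sample, Mapping):
        labels = list(sample.keys())
        arrays = [np.asarray(sample[k], dtype=float) for k in labels]
    else:
        labels = [str(i) for i in range(len(sample))]
        arrays = [np.asarray(g, dtype=float) for g in sample]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for lab, arr in zip(labels, arrays):
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(f"group {lab!r} needs at least 2 finite values")
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite values in group {lab!r}")
    return labels, arrays


def oneway_anova(sample: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    F = MSB / MSW with (k-1, N-k) degrees of freedom. Degenerate inputs are
    resolved explicitly: zero between- and within-group variance gives
    F = 0, p = 1; zero within- with positive between-group variance gives
    F = +inf, p = 0.
    """
    _, arrays = _as_group_arrays(sample)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    sds = np.array([a.std(ddof=1) for a in arrays])
    return anova_from_summary(means, sds, ns)


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> AnovaResult:
    """One-way ANOVA reconstructed from group means, sample SDs and sizes.

    SSB = sum n_g (m_g - grand)^2 with the size-weighted grand mean, and
    SSW = sum (n_g - 1) sd_g^2; identical to :func:`oneway_anova` on the raw
    data the summaries came from.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not means.shape == sds.shape == ns.shape or means.ndim != 1:
        raise ValueError("means, sds and ns must be equal-length vectors")
    if means.size < 2:
        raise ValueError("need at least 2 groups")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("standard deviations must be non-negative")
    k = means.size
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    df_within = n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_between, df_within, 1.0)
        return AnovaResult(float("inf"), df_between, df_within, 0.0)
    f = (ssb / df_between) / (ssw / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p)


def summarize(
    sample: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Group means, sample SDs and sizes as a table (rows in group order)."""
    labels, arrays = _as_group_arrays(sample)
    return pd.DataFrame(
        {
            "group": labels,
            "mean": [a.mean() for a in arrays],
            "sd": [a.std(ddof=1) for a in arrays],
            "n": [a.size for a in arrays],
        }
    ).set_index("group")


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Student's pooled-variance two-sample t-test, two-sided.

    df = n_a + n_b - 2. With zero pooled variance the statistic is 0 (equal
    means) or signed infinity (unequal means).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    delta = a.mean() - b.mean()
    if pooled == 0.0:
        if delta == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float(np.sign(delta)) * float("inf"), df, 0.0)
    t = delta / np.sqrt(pooled * (1 / a.size + 1 / b.size))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p)


def condition_correlation(
    table: pd.DataFrame | np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of a per-subject metric across conditions.

    ``table`` is subjects x conditions with no missing cells. Returns the
    C x C correlation and two-sided p-value matrices; entries involving a
    constant condition are NaN.
    """
    frame = (
        table
        if isinstance(table, pd.DataFrame)
        else pd.DataFrame(np.asarray(table, dtype=float))
    )
    if frame.isna().any().any():
        raise ValueError("missing cells in the condition table")
    if frame.shape[0] < 3 or frame.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 conditions")
    cols = frame.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    np.fill_diagonal(p.values, np.nan)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if j <= i:
                continue
            x = frame[ci].to_numpy(float)
            y = frame[cj].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = sps.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[ci, cj] = r.loc[cj, ci] = rij
            p.loc[ci, cj] = p.loc[cj, ci] = pij
    return r, p


@dataclass(frozen=True)
class PatternResult:
    """Endophenotype classification of a three-group comparison."""

    label: str  # endophenotype | reversed_endophenotype | nonlinear | none
    anova: AnovaResult
    t_asc_con: TTestResult
    t_sib_con: TTestResult
    means: dict[str, float]


def endophenotype_pattern(
    sample: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> PatternResult:
    """Classify a metric's three-group structure.

    ``endophenotype``: significant ANOVA, means strictly ordered
    CON > SIB > ASC, and a significant ASC-vs-CON t-test (the SIB-vs-CON
    test is reported but not required). ``reversed_endophenotype``: the same
    with the ordering inverted. ``nonlinear``: significant ANOVA without a
    monotone ordering (or without the planned comparison). ``none``
    otherwise.
    """
    missing = [g for g in ENDOPHENOTYPE_GROUPS if g not in sample]
    if missing:
        raise ValueError(f"missing groups: {missing}")
    groups = {g: np.asarray(sample[g], dtype=float) for g in ENDOPHENOTYPE_GROUPS}
    anova = oneway_anova(groups)
    t_asc = two_sample_t(groups["ASC"], groups["CON"])
    t_sib = two_sample_t(groups["SIB"], groups["CON"])
    means = {g: float(v.mean()) for g, v in groups.items()}

    label = "none"
    if anova.p < alpha:
        decreasing = means["CON"] > means["SIB"] > means["ASC"]
        increasing = means["CON"] < means["SIB"] < means["ASC"]
        if decreasing and t_asc.p < alpha:
            label = "endophenotype"
        elif increasing and t_asc.p < alpha:
            label = "reversed_endophenotype"
        else:
            label = "nonlinear"
    return PatternResult(label=label, anova=anova, t_asc_con=t_asc, t_sib_con=t_sib, means=means)
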