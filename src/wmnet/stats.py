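"""Hub identification and group-level statistics.

Hubs are the top decile of regions by group-averaged nodal betweenness.
Group differences use one-way ANOVA (omnibus F over the three groups) with
Bonferroni-corrected pairwise post hoc t tests, or ANCOVA adjusting for
age, sex and education; brain-behaviour associations use partial
correlation with the same covariates.

``anova_from_summary`` recovers the omnibus F statistic from per-group
means, SDs and sample sizes alone, which is exactly the information a
demographics table prints, so published tables can be checked without raw
data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import RegionAtlas

__all__ = [
    "HubReport",
    "GroupComparison",
    "identify_hubs",
    "anova_oneway",
    "anova_from_summary",
    "chi_square",
    "ancova_group_effect",
    "partial_correlation",
    "encode_sex",
    "adjust_pvalues",
]

@dataclass
class HubReport:
    """Top-fraction regions by group-mean betweenness, sorted descending."""

    group: str
    hub_regions: list[tuple[str, float]]
    cutoff_rank: int

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.hub_regions]


@dataclass
class GroupComparison:
    """Omnibus group test for one metric, with optional Bonferroni post hocs.

    ``posthoc`` maps a pair name like ``"NC-aMCI"`` to its Bonferroni-
    adjusted p value (min(1, 3 * raw p)); it is filled only when the omnibus
    p is below ``alpha``.
    """

    metric: str
    F: float
    p: float
    df: tuple[int, int]
    group_means: dict[str, float] = field(default_factory=dict)
    group_sds: dict[str, float] = field(default_factory=dict)
    group_ns: dict[str, int] = field(default_factory=dict)
    posthoc: dict[str, float] = field(default_factory=dict)
    adjusted_for: tuple[str, ...] = ()


def identify_hubs(
    betweenness_by_subject: np.ndarray,
    atlas: RegionAtlas,
    group: str = "",
    fraction: float = 0.10,
) -> HubReport:
    """Regions in the top ``fraction`` of group-averaged betweenness.

    ``betweenness_by_subject`` is (n_subjects, n_regions); betweenness is
    averaged across the group's subjects, and the ceil(fraction * N) highest
    regions are returned in descending order.  A tie exactly at the cutoff
    is broken toward the lower region index, with a warning.
    """
    b = np.atleast_2d(np.asarray(betweenness_by_subject, dtype=float))
    if b.shape[0] < 1 or b.size == 0:
        raise ValueError("identify_hubs requires at least one subject")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if b.shape[1] != atlas.n_regions:
        raise ValueError(
            f"betweenness has {b.shape[1]} regions but atlas has {atlas.n_regions}"
        )
    mean_b = b.mean(axis=0)
    n_hubs = math.ceil(fraction * atlas.n_regions)
    # stable sort on (-betweenness, index): ties keep the lower region index
    order = np.lexsort((np.arange(atlas.n_regions), -mean_b))
    cutoff_val = mean_b[order[n_hubs - 1]]
    if n_hubs < atlas.n_regions and mean_b[order[n_hubs]] == cutoff_val:
        warnings.warn(
            f"tie at the hub cutoff (betweenness={cutoff_val:g}); "
            "keeping the lower region index",
            stacklevel=2,
        )
    hubs = [(atlas.labels[i], float(mean_b[i])) for i in order[:n_hubs]]
    return HubReport(group=group, hub_regions=hubs, cutoff_rank=n_hubs)


def _group_stats(values: Mapping[str, np.ndarray]) -> tuple[dict, dict, dict]:
    means = {g: float(np.mean(v)) for g, v in values.items()}
    sds = {g: float(np.std(v, ddof=1)) for g, v in values.items()}
    ns = {g: int(len(v)) for g, v in values.items()}
    return means, sds, ns


def _posthoc_bonferroni(values: Mapping[str, np.ndarray], alpha: float) -> dict[str, float]:
    """Pairwise t tests on the pooled within-group error, Bonferroni adjusted."""
    groups = list(values)
    k = len(groups)
    n = sum(len(v) for v in values.values())
    msw = sum((len(v) - 1) * np.var(v, ddof=1) for v in values.values()) / (n - k)
    n_pairs = k * (k - 1) // 2
    out: dict[str, float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = groups[i], groups[j]
            v1, v2 = values[g1], values[g2]
            se = math.sqrt(msw * (1 / len(v1) + 1 / len(v2)))
            t = (np.mean(v1) - np.mean(v2)) / se
            p_raw = 2 * sps.t.sf(abs(t), n - k)
            out[f"{g1}-{g2}"] = min(1.0, n_pairs * p_raw)
    return out


def anova_oneway(
    values: Mapping[str, Sequence[float]], metric: str = "", alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA across groups with Bonferroni post hoc pairwise t tests.

    The post hoc tests (pooled-error pairwise t, p adjusted by the number of
    pairs) run only when the omnibus p is below ``alpha``.
    """
    arrs = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(arrs) < 2 or any(len(v) < 2 for v in arrs.values()):
        raise ValueError("anova_oneway needs >= 2 groups with >= 2 observations each")
    if all(np.var(v) == 0 for v in arrs.values()):
        raise ValueError("zero within-group variance in every group; F undefined")
    f, p = sps.f_oneway(*arrs.values())
    k = len(arrs)
    n = sum(len(v) for v in arrs.values())
    means, sds, ns = _group_stats(arrs)
    cmp_ = GroupComparison(
        metric=metric, F=float(f), p=float(p), df=(k - 1, n - k),
        group_means=means, group_sds=sds, group_ns=ns,
    )
    if cmp_.p < alpha:
        cmp_.posthoc = _posthoc_bonferroni(arrs, alpha)
    return cmp_


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, float]:
    """Omnibus F (and p) recovered from per-group means, SDs and sizes.

    Uses the classical decomposition: the between-group sum of squares about
    the weighted grand mean, and the within-group sum of squares rebuilt
    from the sample SDs, sum((n_g - 1) sd_g^2).  Agrees exactly with
    ``anova_oneway`` when the summaries are exact.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = len(means)
    if k < 2 or len(sds) != k or len(ns) != k:
        raise ValueError("need >= 2 groups with matching means/sds/ns")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds < 0) or (np.all(sds == 0) and len(set(means.tolist())) > 1):
        raise ValueError("invalid SDs for the stated means")
    n = ns.sum()
    grand = float((ns * means).sum() / n)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, int(n - k)
    if ssw == 0:
        raise ValueError("zero within-group variance; F undefined")
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), p


def chi_square(table: Sequence[Sequence[int]]) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    t = np.asarray(table, dtype=float)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    stat, p, dof, expected = sps.chi2_contingency(t, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected count of zero in contingency table")
    return float(stat), float(p), int(dof)


def encode_sex(sex: Sequence[str]) -> np.ndarray:
    """0/1 encoding of sex for covariate adjustment (M=0, F=1)."""
    mapping = {"M": 0.0, "F": 1.0}
    try:
        return np.array([mapping[s] for s in sex], dtype=float)
    except KeyError as e:
        raise ValueError(f"unknown sex code {e.args[0]!r}; expected 'M' or 'F'") from None


def _design(covariates: pd.DataFrame | Mapping[str, Sequence[float]] | None, n: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(n))
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = encode_sex(cov["sex"].tolist())
    return cov.astype(float)


def _check_full_rank(x: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # find the first column linearly dependent on its predecessors
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) < j + 1:
                raise ValueError(f"design matrix rank-deficient: column {names[j]!r} is collinear")
        raise ValueError("design matrix rank-deficient")


def ancova_group_effect(
    values: Sequence[float],
    groups: Sequence[str],
    covariates: pd.DataFrame | Mapping[str, Sequence[float]] | None = None,
    metric: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Partial F test for the group factor, adjusting for covariates.

    Fits the linear model metric ~ group + covariates and compares it with
    the covariates-only model (a Type-III style test of the group factor):

        F = ((RSS_reduced - RSS_full) / (k - 1)) / (RSS_full / df_resid)

    With no covariates this reduces exactly to the one-way ANOVA F.
    """
    y = np.asarray(values, dtype=float)
    groups = list(groups)
    n = len(y)
    levels = sorted(set(groups))
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    cov = _design(covariates, n)
    dummies = np.column_stack([
        [1.0 if g == lev else 0.0 for g in groups] for lev in levels[1:]
    ])
    names = ["intercept"] + [f"group[{lev}]" for lev in levels[1:]] + list(cov.columns)
    x_full = np.column_stack([np.ones(n), dummies, cov.to_numpy()] if len(cov.columns) else [np.ones(n), dummies])
    if n <= x_full.shape[1]:
        raise ValueError("more parameters than observations")
    _check_full_rank(x_full, names)
    x_red = np.column_stack([np.ones(n), cov.to_numpy()]) if len(cov.columns) else np.ones((n, 1))

    def rss(x: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    rss_full = rss(x_full)
    rss_red = rss(x_red)
    df1 = k - 1
    df2 = n - x_full.shape[1]
    if rss_red <= 1e-12 * float(y @ y):
        # covariates-only model already fits (numerically) perfectly: the
        # group factor explains nothing beyond it
        f, p = 0.0, 1.0
    else:
        f = max(((rss_red - rss_full) / df1) / (rss_full / df2), 0.0)
        p = float(sps.f.sf(f, df1, df2))
    arrs = {g: y[np.array(groups) == g] for g in levels}
    means, sds, ns = _group_stats(arrs)
    cmp_ = GroupComparison(
        metric=metric, F=float(f), p=p, df=(df1, df2),
        group_means=means, group_sds=sds, group_ns=ns,
        adjusted_for=tuple(cov.columns),
    )
    if p < alpha and all(len(v) >= 2 for v in arrs.values()):
        cmp_.posthoc = _posthoc_bonferroni(arrs, alpha)
    return cmp_


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | Mapping[str, Sequence[float]] | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are regressed on the covariates (plus an intercept); the
    Pearson correlation of the residuals is returned with a t-based p value
    on n - 2 - n_covariates degrees of freedom.  With no covariates this is
    the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    cov = _design(covariates, n)
    n_cov = len(cov.columns)
    if n <= n_cov + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={n_cov})")
    z = np.column_stack([np.ones(n), cov.to_numpy()]) if n_cov else np.ones((n, 1))
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - n_cov
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def adjust_pvalues(pvals: Sequence[float], method: str = "none") -> np.ndarray:
    """Multiple-comparison adjustment across regions: none, bonferroni or fdr."""
    p = np.asarray(pvals, dtype=float)
    if method == "none":
        return p
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if method == "fdr":
        return sps.false_discovery_control(p, method="bh")
    raise ValueError(f"unknown adjustment method {method!r}")
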