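"""Cohort-level connectome analysis as a fit-once model object.

``ConnectomeCohortModel`` holds the subjects and the analysis settings;
``fit()`` runs construction -> metrics -> null normalization -> hubs ->
group statistics and returns a ``ConnectomeCohortResults`` carrying every
table the analysis produces, with a ``summary()`` in the spirit of
statsmodels results objects.

The stages mirror a standard weighted-connectome study: build each
subject's thresholded FN*FA/volume network; compute Cp, Lp, Eg, Eloc and
nodal betweenness; normalize Cp and Lp against degree-preserving random
networks to get gamma, lambda and sigma; identify per-group hubs (top 10%
of group-mean betweenness); compare metrics across groups (ANCOVA with
age, sex and education by default, or plain one-way ANOVA); and correlate
betweenness with cognitive scores, within each patient group, for the
regions showing significant group differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .construction import GROUPS, SubjectConnectivity, build_weight_matrix
from .io import SCORE_COLUMNS, load_subject, read_subject_table
from .metrics import GLOBAL_METRIC_NAMES, betweenness, global_metrics
from .nulls import small_worldness
from .stats import (
    GroupComparison,
    HubReport,
    adjust_pvalues,
    ancova_group_effect,
    anova_oneway,
    identify_hubs,
    partial_correlation,
)

__all__ = ["ConnectomeCohortModel", "ConnectomeCohortResults"]

DEFAULT_COVARIATES = ("age", "sex", "education")


class ConnectomeCohortModel:
    """Weighted white-matter network analysis for a three-group cohort.

    Parameters
    ----------
    subjects
        The cohort's :class:`SubjectConnectivity` records.
    fn_threshold
        Minimum streamline count for an edge to survive (inclusive).
    n_nulls, swaps_per_edge
        Size of the degree-preserving null ensemble per subject and the
        rewiring intensity; ``n_nulls=0`` skips small-world normalization.
    hub_fraction
        Fraction of regions reported as hubs (top of group-mean betweenness).
    stats_mode
        ``"ancova"`` (default; adjusts for ``covariates``) or ``"anova"``.
    nodal_adjust
        Multiple-comparison mode across regions: none (default),
        bonferroni, or fdr.
    correlate_all_regions
        Correlate scores with every region instead of only the regions with
        significant group differences.
    """

    def __init__(
        self,
        subjects: Sequence[SubjectConnectivity],
        *,
        atlas: RegionAtlas | None = None,
        fn_threshold: int = 3,
        n_nulls: int = 100,
        swaps_per_edge: int = 10,
        hub_fraction: float = 0.10,
        stats_mode: str = "ancova",
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        nodal_adjust: str = "none",
        correlate_all_regions: bool = False,
        alpha: float = 0.05,
        seed: int = 0,
    ):
        if not subjects:
            raise ValueError("model needs at least one subject")
        self.subjects = list(subjects)
        self.atlas = atlas or self.subjects[0].atlas
        if self.atlas is None:
            raise ValueError("an atlas is required (none attached to subjects)")
        if stats_mode not in ("anova", "ancova"):
            raise ValueError(f"stats_mode must be 'anova' or 'ancova', got {stats_mode!r}")
        groups_present = {s.group for s in self.subjects}
        if len(groups_present) < 2:
            raise ValueError(f"need >= 2 groups, found {sorted(groups_present)}")
        self.fn_threshold = fn_threshold
        self.n_nulls = n_nulls
        self.swaps_per_edge = swaps_per_edge
        self.hub_fraction = hub_fraction
        self.stats_mode = stats_mode
        self.covariates = tuple(covariates)
        self.nodal_adjust = nodal_adjust
        self.correlate_all_regions = correlate_all_regions
        self.alpha = alpha
        self.seed = seed

    @classmethod
    def from_table(cls, table_path: str | Path, atlas: RegionAtlas, base_dir=None, **kwargs):
        """Build the model from a subject table of file paths on disk."""
        table_path = Path(table_path)
        df = read_subject_table(table_path)
        base = Path(base_dir) if base_dir is not None else table_path.parent
        errors = []
        subjects = []
        for _, row in df.iterrows():
            try:
                subjects.append(load_subject(row, atlas, base))
            except Exception as e:  # collected, reported together
                errors.append((str(row.get("subject_id", "?")), str(e)))
        if errors:
            msgs = "; ".join(f"{sid}: {err}" for sid, err in errors)
            raise ValueError(f"{len(errors)} subject(s) failed to load: {msgs}")
        return cls(subjects, atlas=atlas, **kwargs)

    @classmethod
    def from_cohort_spec(cls, spec, with_scores: bool = True, **kwargs):
        """Build the model directly from a synthetic-cohort specification."""
        from .cohort import generate_cohort

        subjects, ground_truth = generate_cohort(spec, with_scores=with_scores)
        model = cls(subjects, atlas=spec.atlas(), **kwargs)
        model.ground_truth = ground_truth
        return model

    # -- fitting ---------------------------------------------------------

    def fit(self) -> "ConnectomeCohortResults":
        atlas = self.atlas
        networks = [build_weight_matrix(s, self.fn_threshold) for s in self.subjects]

        global_rows = []
        nodal = np.empty((len(self.subjects), atlas.n_regions))
        for idx, (s, net) in enumerate(zip(self.subjects, networks)):
            if self.n_nulls >= 1:
                gm = small_worldness(
                    net,
                    n_nulls=self.n_nulls,
                    swaps_per_edge=self.swaps_per_edge,
                    seed=self.seed + idx,
                )
            else:
                gm = global_metrics(net)
            global_rows.append({"subject_id": s.subject_id, "group": s.group, **gm.as_dict()})
            nodal[idx] = betweenness(net).betweenness

        gdf = pd.DataFrame(global_rows)
        ndf = pd.DataFrame(nodal, columns=list(atlas.labels))
        ndf.insert(0, "subject_id", [s.subject_id for s in self.subjects])
        ndf.insert(1, "group", [s.group for s in self.subjects])

        covariate_df = self._covariate_frame()
        groups = np.array([s.group for s in self.subjects])

        global_cmp = [
            self._compare(gdf[m].to_numpy(), groups, covariate_df, m)
            for m in GLOBAL_METRIC_NAMES
            if np.isfinite(gdf[m]).all() and gdf[m].nunique() > 1
        ]

        hubs = {
            g: identify_hubs(nodal[groups == g], atlas, group=g, fraction=self.hub_fraction)
            for g in GROUPS
            if (groups == g).any()
        }

        nodal_cmp = self._nodal_comparisons(nodal, groups, covariate_df)
        correlations = self._correlations(nodal, groups, covariate_df, nodal_cmp)

        return ConnectomeCohortResults(
            model=self,
            global_metrics=gdf,
            nodal_betweenness=ndf,
            global_comparisons=global_cmp,
            nodal_comparisons=nodal_cmp,
            hubs=hubs,
            correlations=correlations,
            networks=networks,
        )

    # -- helpers ---------------------------------------------------------

    def _covariate_frame(self) -> pd.DataFrame | None:
        if self.stats_mode != "ancova" or not self.covariates:
            return None
        cols = {}
        for c in self.covariates:
            cols[c] = [getattr(s, c) for s in self.subjects]
        return pd.DataFrame(cols)

    def _compare(self, values, groups, covariate_df, metric) -> GroupComparison:
        by_group = {g: values[groups == g] for g in GROUPS if (groups == g).any()}
        if self.stats_mode == "ancova":
            return ancova_group_effect(
                values, groups, covariates=covariate_df, metric=metric, alpha=self.alpha
            )
        return anova_oneway(by_group, metric=metric, alpha=self.alpha)

    def _nodal_comparisons(self, nodal, groups, covariate_df) -> pd.DataFrame:
        rows = []
        for j, label in enumerate(self.atlas.labels):
            vals = nodal[:, j]
            if np.allclose(vals.var(), 0):
                continue
            cmp_ = self._compare(vals, groups, covariate_df, label)
            row = {
                "region": label,
                "region_id": j + 1,
                "F": cmp_.F,
                "p": cmp_.p,
            }
            for pair, padj in cmp_.posthoc.items():
                row[f"p_{pair}"] = padj
            for g, m in cmp_.group_means.items():
                row[f"mean_{g}"] = m
            rows.append(row)
        df = pd.DataFrame(rows)
        if len(df):
            df["p_adjusted"] = adjust_pvalues(df["p"].to_numpy(), self.nodal_adjust)
            df["adjust_method"] = self.nodal_adjust
        return df

    def _correlations(self, nodal, groups, covariate_df, nodal_cmp) -> pd.DataFrame:
        """Betweenness-score partial correlations within each patient group."""
        if len(nodal_cmp) == 0:
            return pd.DataFrame()
        if self.correlate_all_regions:
            regions = list(nodal_cmp["region"])
        else:
            sig = nodal_cmp[nodal_cmp["p_adjusted"] < self.alpha]
            regions = list(sig["region"])
        rows = []
        label_to_col = {lab: i for i, lab in enumerate(self.atlas.labels)}
        for g in ("SCD", "aMCI"):
            mask = groups == g
            if mask.sum() < 3:
                continue
            cov_g = covariate_df[mask].reset_index(drop=True) if covariate_df is not None else None
            for region in regions:
                x = nodal[mask, label_to_col[region]]
                for score in SCORE_COLUMNS:
                    y = np.array([s.scores.get(score, np.nan) for s in self.subjects])[mask]
                    if np.isnan(y).any():
                        continue
                    try:
                        r, p = partial_correlation(x, y, cov_g)
                    except ValueError:
                        continue
                    rows.append(
                        {"group": g, "region": region, "score": score,
                         "r": r, "p": p, "n": int(mask.sum())}
                    )
        return pd.DataFrame(rows)


@dataclass
class ConnectomeCohortResults:
    """Fitted tables of the cohort analysis.

    Attributes
    ----------
    global_metrics
        One row per subject: Cp, Lp, Eg, Eloc (+ gamma/lambda/sigma).
    nodal_betweenness
        One row per subject, one column per region.
    global_comparisons
        :class:`GroupComparison` per global metric.
    nodal_comparisons
        Region-wise group tests on betweenness.
    hubs
        Per-group :class:`HubReport` (top decile of mean betweenness).
    correlations
        Partial betweenness-score correlations in the patient groups.
    """

    model: ConnectomeCohortModel
    global_metrics: pd.DataFrame
    nodal_betweenness: pd.DataFrame
    global_comparisons: list[GroupComparison]
    nodal_comparisons: pd.DataFrame
    hubs: Mapping[str, HubReport]
    correlations: pd.DataFrame
    networks: list = field(default_factory=list, repr=False)

    def comparison(self, metric: str) -> GroupComparison:
        for c in self.global_comparisons:
            if c.metric == metric:
                return c
        raise KeyError(f"no comparison for metric {metric!r}")

    def group_mean(self, metric: str, group: str) -> float:
        g = self.global_metrics
        return float(g.loc[g["group"] == group, metric].mean())

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.global_comparisons:
            row = {"metric": c.metric, "F": c.F, "p": c.p}
            for pair, padj in c.posthoc.items():
                row[f"p_{pair}"] = padj
            for g in GROUPS:
                if g in c.group_means:
                    row[f"mean_{g}"] = c.group_means[g]
                    row[f"sd_{g}"] = c.group_sds[g]
            rows.append(row)
        return pd.DataFrame(rows)

    def plot_global_metrics(self, metrics=("Lp", "Eg", "Eloc", "Cp"), axes=None):
        """Per-group bar/error summaries (mean +/- SD) of global metrics.

        Returns the matplotlib axes; creates a figure if none are given.
        """
        import matplotlib.pyplot as plt

        metrics = [m for m in metrics if m in self.global_metrics.columns]
        if axes is None:
            _, axes = plt.subplots(1, len(metrics), figsize=(3 * len(metrics), 3))
        axes = np.atleast_1d(axes)
        groups = [g for g in GROUPS if (self.global_metrics["group"] == g).any()]
        for ax, metric in zip(axes, metrics):
            means = [self.group_mean(metric, g) for g in groups]
            sds = [
                float(self.global_metrics.loc[self.global_metrics["group"] == g, metric].std(ddof=1))
                for g in groups
            ]
            ax.bar(groups, means, yerr=sds, capsize=3, color=["#4c72b0", "#dd8452", "#c44e52"])
            ax.set_title(metric)
        return axes

    def summary(self) -> str:
        m = self.model
        lines = []
        w = 86
        lines.append("Weighted White-Matter Connectome Cohort Analysis".center(w))
        lines.append("=" * w)
        counts = self.global_metrics.groupby("group")["subject_id"].count()
        lines.append(
            "Subjects: "
            + ", ".join(f"{g}={counts.get(g, 0)}" for g in GROUPS if counts.get(g, 0))
        )
        lines.append(
            f"FN threshold: {m.fn_threshold}   nulls/subject: {m.n_nulls}   "
            f"stats: {m.stats_mode}"
            + (f" (covariates: {', '.join(m.covariates)})" if m.stats_mode == "ancova" else "")
        )
        lines.append("-" * w)
        lines.append("Global metrics (group mean +/- SD; group test)")
        header = f"{'metric':<8}" + "".join(
            f"{g:>20}" for g in GROUPS if counts.get(g, 0)
        ) + f"{'F':>9}{'p':>9}"
        lines.append(header)
        for c in self.global_comparisons:
            row = f"{c.metric:<8}"
            for g in GROUPS:
                if g in c.group_means:
                    cell = f"{c.group_means[g]:.4g}+/-{c.group_sds[g]:.2g}"
                    row += f"{cell:>20}"
            row += f"{c.F:>9.3f}{c.p:>9.4f}"
            lines.append(row)
        lines.append("-" * w)
        for g, hub in self.hubs.items():
            lines.append(f"Hubs [{g}] (top {m.hub_fraction:.0%} betweenness): "
                         + ", ".join(hub.labels))
        if len(self.nodal_comparisons):
            sig = self.nodal_comparisons[self.nodal_comparisons["p_adjusted"] < m.alpha]
            lines.append("-" * w)
            lines.append(
                f"Regions with significant betweenness group differences "
                f"(adjust: {m.nodal_adjust}): "
                + (", ".join(sig["region"]) if len(sig) else "none")
            )
        if len(self.correlations):
            sigc = self.correlations[self.correlations["p"] < m.alpha]
            lines.append(
                "Significant betweenness-score partial correlations: "
                + (
                    "; ".join(
                        f"{r.group} {r.region}~{r.score} r={r.r:.2f} p={r.p:.3f}"
                        for r in sigc.itertuples()
                    )
                    if len(sigc)
                    else "none"
                )
            )
        lines.append("=" * w)
        return "\n".join(lines)
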