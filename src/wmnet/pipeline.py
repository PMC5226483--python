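"""End-to-end pipeline: read inputs, fit the cohort model, write outputs.

A run is fully described by a :class:`RunConfig` (loadable from YAML); all
randomness flows from its ``master_seed`` and every run writes a manifest
sufficient to reproduce it byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import RegionAtlas, aal90, load_atlas
from .construction import GROUPS
from .io import load_subject, read_subject_table, write_edge_file, write_node_file
from .model import ConnectomeCohortModel, ConnectomeCohortResults

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("wmnet")


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults follow the standard recipe)."""

    subject_table: str = "subjects.csv"
    atlas_path: str | None = None  # default: bundled AAL-90
    output_dir: str = "wmnet_out"
    fn_threshold: int = 3
    n_nulls: int = 100
    swaps_per_edge: int = 10
    hub_fraction: float = 0.10
    stats_mode: str = "ancova"
    covariates: tuple[str, ...] = ("age", "sex", "education")
    nodal_adjust: str = "none"
    correlate_all_regions: bool = False
    alpha: float = 0.05
    master_seed: int = 0
    skip_bad: bool = False
    threads: int = 1  # results are independent of thread count

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        return d


def _load_atlas(config: RunConfig) -> RegionAtlas:
    return load_atlas(config.atlas_path) if config.atlas_path else aal90()


def run_pipeline(config: RunConfig) -> ConnectomeCohortResults:
    """Run construction -> metrics -> nulls -> hubs -> statistics and write
    all result tables under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = _load_atlas(config)

    table_path = Path(config.subject_table)
    df = read_subject_table(table_path)
    base = table_path.parent
    subjects, failures = [], []
    for _, row in df.iterrows():
        sid = str(row.get("subject_id", "?"))
        try:
            subjects.append(load_subject(row, atlas, base))
        except Exception as e:
            failures.append({"subject_id": sid, "error": str(e)})
            log.warning("excluded subject %s: %s", sid, e)
    if failures and not config.skip_bad:
        raise RuntimeError(
            f"{len(failures)} subject(s) failed to load (use skip_bad to continue): "
            + "; ".join(f"{f['subject_id']}: {f['error']}" for f in failures)
        )
    groups_present = sorted({s.group for s in subjects})
    for g in GROUPS:
        log.info("group %s: %d subjects", g, sum(s.group == g for s in subjects))
    if len(groups_present) < 2:
        raise RuntimeError(f"fewer than 2 usable groups present: {groups_present}")

    model = ConnectomeCohortModel(
        subjects,
        atlas=atlas,
        fn_threshold=config.fn_threshold,
        n_nulls=config.n_nulls,
        swaps_per_edge=config.swaps_per_edge,
        hub_fraction=config.hub_fraction,
        stats_mode=config.stats_mode,
        covariates=config.covariates,
        nodal_adjust=config.nodal_adjust,
        correlate_all_regions=config.correlate_all_regions,
        alpha=config.alpha,
        seed=config.master_seed,
    )
    results = model.fit()
    write_results(results, out, config, failures)
    return results


def write_results(
    results: ConnectomeCohortResults,
    out: Path,
    config: RunConfig,
    failures: list | None = None,
) -> None:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    results.global_metrics.to_csv(out / "global_metrics.csv", index=False, float_format="%.10g")

    nodal_tidy = results.nodal_betweenness.melt(
        id_vars=["subject_id", "group"], var_name="region", value_name="betweenness"
    )
    nodal_tidy.to_csv(out / "nodal_metrics.csv", index=False, float_format="%.10g")

    results.comparisons_frame().to_csv(out / "group_comparison.csv", index=False, float_format="%.10g")
    results.nodal_comparisons.to_csv(out / "nodal_comparison.csv", index=False, float_format="%.10g")

    atlas = results.model.atlas
    for g, hub in results.hubs.items():
        pd.DataFrame(hub.hub_regions, columns=["region", "mean_betweenness"]).to_csv(
            out / f"hubs_{g}.csv", index=False, float_format="%.10g"
        )
        # BrainNet-style node file: hub membership as color, betweenness as size
        groups = results.nodal_betweenness["group"].to_numpy()
        mean_b = results.nodal_betweenness.loc[groups == g, list(atlas.labels)].mean(axis=0).to_numpy()
        colors = np.array([1.0 + (lab in hub.labels) for lab in atlas.labels])
        write_node_file(out / f"hubs_{g}.node", atlas, sizes=mean_b, colors=colors)

    if results.networks:
        groups = np.array([s.group for s in results.model.subjects])
        for g in sorted(set(groups)):
            mean_w = np.mean([n.weights for n, keep in zip(results.networks, groups == g) if keep], axis=0)
            from .construction import WeightedNetwork

            write_edge_file(out / f"mean_network_{g}.edge", WeightedNetwork(mean_w, atlas))

    results.correlations.to_csv(out / "correlations.csv", index=False, float_format="%.10g")

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "n_subjects": len(results.model.subjects),
        "subjects_per_group": {
            g: int(sum(s.group == g for s in results.model.subjects)) for g in GROUPS
        },
        "excluded_subjects": failures or [],
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
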