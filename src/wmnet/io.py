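"""Reading and writing the pipeline's delimited-text formats.

Connectivity matrices are plain delimited text (comma or tab), one row per
region, no header by default; an optional header row must match the atlas
labels.  Volumes are two-column (region_label, volume_mm3) tables.  The
subject table lists one subject per row with group, demographics, cognitive
scores and the paths of the three per-subject files.

Also writes BrainNet-Viewer-style ``.node`` / ``.edge`` text files so hub
results can be rendered externally.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, synthetic_centroids
from .construction import SubjectConnectivity, ValidationError, WeightedNetwork, symmetrize

__all__ = [
    "read_matrix",
    "read_volumes",
    "read_subject_table",
    "load_subject",
    "write_subject",
    "write_cohort",
    "write_node_file",
    "write_edge_file",
]

SUBJECT_COLUMNS = [
    "subject_id", "group", "age", "sex", "education",
    "MMSE", "MoCA", "AVLT_I", "AVLT_D", "AVLT_R",
    "fn_path", "fa_path", "vol_path",
]
SCORE_COLUMNS = ["MMSE", "MoCA", "AVLT_I", "AVLT_D", "AVLT_R"]


def _sniff_delim(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_matrix(path: str | Path, atlas: RegionAtlas | None = None) -> np.ndarray:
    """Read a square connectivity matrix from delimited text.

    Accepts comma- or tab-delimited values; a leading header row, if
    present, must match the atlas labels.  The matrix is symmetrized by
    averaging the two triangles (asymmetry beyond 1e-8 is an error) and the
    diagonal is zeroed.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delim(first)
    tokens = [t.strip() for t in first.strip().split(delim)]
    has_header = any(not _is_number(t) for t in tokens if t)
    if has_header:
        if atlas is not None and tuple(t for t in tokens if t) != atlas.labels:
            raise ValidationError(
                f"{path}: header row does not match atlas labels", ["matrix"]
            )
        m = np.loadtxt(path, delimiter=delim, skiprows=1)
    else:
        m = np.loadtxt(path, delimiter=delim)
    m = np.atleast_2d(m)
    if atlas is not None and m.shape != (atlas.n_regions, atlas.n_regions):
        raise ValidationError(
            f"{path}: matrix shape {m.shape} does not match atlas "
            f"({atlas.n_regions} regions)",
            ["matrix"],
        )
    return symmetrize(m, name=str(path))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_volumes(path: str | Path, atlas: RegionAtlas) -> np.ndarray:
    """Read region volumes from a two-column (label, volume_mm3) table."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["label", "volume_mm3"])
    df["label"] = df["label"].astype(str).str.strip()
    vols = df.set_index("label")["volume_mm3"]
    missing = [l for l in atlas.labels if l not in vols.index]
    if missing:
        raise ValidationError(
            f"{path}: missing volumes for regions {missing[:5]}...", ["volumes"]
        )
    return vols.loc[list(atlas.labels)].to_numpy(dtype=float)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read the cohort subject table (delimited text, header required)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: subject table missing columns {missing}", missing)
    return df


def load_subject(row: pd.Series, atlas: RegionAtlas, base_dir: str | Path = ".") -> SubjectConnectivity:
    """Materialize one subject from a subject-table row."""
    base = Path(base_dir)
    fn = read_matrix(base / row["fn_path"], atlas)
    fa = read_matrix(base / row["fa_path"], atlas)
    vols = read_volumes(base / row["vol_path"], atlas)
    return SubjectConnectivity(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        fn=fn,
        fa=fa,
        volumes=vols,
        age=float(row["age"]),
        sex=str(row["sex"]),
        education=float(row["education"]),
        scores={c: float(row[c]) for c in SCORE_COLUMNS},
        atlas=atlas,
    )


def write_subject(subject: SubjectConnectivity, out_dir: str | Path) -> dict[str, str]:
    """Write one subject's fn/fa/vol files; returns their relative paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    paths = {
        "fn_path": f"fn_{sid}.csv",
        "fa_path": f"fa_{sid}.csv",
        "vol_path": f"vol_{sid}.csv",
    }
    np.savetxt(out / paths["fn_path"], subject.fn, fmt="%.10g", delimiter=",")
    np.savetxt(out / paths["fa_path"], subject.fa, fmt="%.10g", delimiter=",")
    atlas = subject.atlas
    labels = atlas.labels if atlas is not None else [f"R{i+1}" for i in range(subject.n_regions)]
    pd.DataFrame({"label": labels, "volume_mm3": subject.volumes}).to_csv(
        out / paths["vol_path"], index=False, header=False
    )
    return paths


def write_cohort(subjects: Sequence[SubjectConnectivity], out_dir: str | Path) -> Path:
    """Write a full cohort: per-subject files plus ``subjects.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        paths = write_subject(s, out)
        rows.append({
            "subject_id": s.subject_id, "group": s.group, "age": s.age,
            "sex": s.sex, "education": s.education,
            **{c: s.scores.get(c, float("nan")) for c in SCORE_COLUMNS},
            **paths,
        })
    table = out / "subjects.csv"
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(table, index=False)
    return table


def write_node_file(
    path: str | Path,
    atlas: RegionAtlas,
    sizes: np.ndarray,
    colors: np.ndarray | None = None,
    coords: np.ndarray | None = None,
) -> None:
    """Write a BrainNet-style ``.node`` file.

    Six whitespace-delimited columns: x, y, z, color group, size, label.
    Coordinates default to the package's synthetic stand-in centroids (two
    schematic arcs, not measured anatomy).
    """
    coords = synthetic_centroids(atlas) if coords is None else np.asarray(coords)
    sizes = np.asarray(sizes, dtype=float)
    colors = np.ones(atlas.n_regions) if colors is None else np.asarray(colors)
    with open(path, "w") as fh:
        for i, label in enumerate(atlas.labels):
            x, y, z = coords[i]
            fh.write(f"{x:g}\t{y:g}\t{z:g}\t{colors[i]:g}\t{sizes[i]:.6g}\t{label}\n")


def write_edge_file(path: str | Path, net: WeightedNetwork) -> None:
    """Write the weight matrix as a tab-delimited BrainNet ``.edge`` file."""
    np.savetxt(path, net.weights, fmt="%.10g", delimiter="\t")
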