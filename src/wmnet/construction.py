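"""Weighted structural network construction from tractography matrices.

Each subject contributes a fiber-number (FN) matrix of streamline counts, a
mean fractional-anisotropy (FA) matrix, and a vector of region volumes over
a common parcellation.  An edge between regions i and j survives when its
streamline count reaches the threshold (default 3) and is weighted

    w_ij = FN_ij * FA_ij / ((V_i + V_j) / 2)

i.e. the fiber count times the mean FA of the tract, normalised by the
average volume of the two connected regions so that large regions do not
accumulate spuriously strong connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .atlas import RegionAtlas, aal90

__all__ = [
    "SubjectConnectivity",
    "WeightedNetwork",
    "ValidationError",
    "symmetrize",
    "build_weight_matrix",
    "validate_threshold_stability",
]

GROUPS = ("NC", "SCD", "aMCI")
SCORE_NAMES = ("MMSE", "MoCA", "AVLT_I", "AVLT_D", "AVLT_R")

#: tolerance for accepting and averaging away asymmetry in matrices read
#: from disk; larger asymmetry is treated as corrupt input
ASYMMETRY_TOL = 1e-8


class ValidationError(ValueError):
    """Structured validation failure; ``fields`` names the offending inputs."""

    def __init__(self, message: str, fields: Sequence[str] = ()):
        super().__init__(message)
        self.fields = tuple(fields)


def symmetrize(m: np.ndarray, tol: float = ASYMMETRY_TOL, name: str = "matrix") -> np.ndarray:
    """Average the two triangles of a nominally symmetric matrix.

    Tractography outputs are symmetric up to write-out round-off; asymmetry
    beyond ``tol`` (absolute) indicates a malformed file and raises.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{name} must be square, got shape {m.shape}", [name])
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > tol:
        raise ValidationError(
            f"{name} asymmetric beyond tolerance: max |m - m.T| = {asym:.3g} > {tol:.3g}",
            [name],
        )
    out = (m + m.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class SubjectConnectivity:
    """One subject's raw connectivity inputs plus phenotype.

    ``fn`` and ``fa`` are square, symmetric, zero-diagonal matrices over the
    atlas regions; ``volumes`` are positive region volumes in mm^3.  FA must
    be zero wherever FN is zero (no tract, no anisotropy estimate).
    """

    subject_id: str
    group: str
    fn: np.ndarray
    fa: np.ndarray
    volumes: np.ndarray
    age: float
    sex: str
    education: float
    scores: Mapping[str, float] = field(default_factory=dict)
    atlas: RegionAtlas | None = None

    def __post_init__(self) -> None:
        self.fn = np.asarray(self.fn, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.validate()

    def validate(self) -> None:
        bad: list[str] = []
        n = self.volumes.shape[0] if self.volumes.ndim == 1 else -1
        for name, m in (("fn", self.fn), ("fa", self.fa)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                bad.append(name)
        if bad or n <= 0:
            raise ValidationError(
                f"subject {self.subject_id}: fn/fa must be square matrices and "
                f"volumes a 1-d vector",
                bad + (["volumes"] if n <= 0 else []),
            )
        if not (self.fn.shape[0] == self.fa.shape[0] == n):
            raise ValidationError(
                f"subject {self.subject_id}: dimension mismatch "
                f"fn {self.fn.shape}, fa {self.fa.shape}, volumes ({n},)",
                ["fn", "fa", "volumes"],
            )
        if self.atlas is not None and self.atlas.n_regions != n:
            raise ValidationError(
                f"subject {self.subject_id}: atlas has {self.atlas.n_regions} "
                f"regions but matrices have {n}",
                ["atlas"],
            )
        if np.any(self.fn < 0):
            bad.append("fn")
        if np.any((self.fa < 0) | (self.fa > 1)):
            bad.append("fa")
        if np.any(self.volumes <= 0) or not np.all(np.isfinite(self.volumes)):
            bad.append("volumes")
        if bad:
            raise ValidationError(
                f"subject {self.subject_id}: negative FN, FA outside [0, 1], "
                f"or non-positive volume",
                bad,
            )
        for name, m in (("fn", self.fn), ("fa", self.fa)):
            if np.max(np.abs(m - m.T)) > ASYMMETRY_TOL or np.any(np.diag(m) != 0):
                raise ValidationError(
                    f"subject {self.subject_id}: {name} must be symmetric with zero diagonal",
                    [name],
                )
        if np.any((self.fn == 0) & (self.fa != 0)):
            raise ValidationError(
                f"subject {self.subject_id}: FA nonzero where FN is zero",
                ["fa"],
            )
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject_id}: unknown group {self.group!r}", ["group"]
            )

    @property
    def n_regions(self) -> int:
        return self.volumes.shape[0]


@dataclass(frozen=True)
class WeightedNetwork:
    """A symmetric, non-negative, zero-diagonal weight matrix over an atlas."""

    weights: np.ndarray
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = self.atlas.n_regions
        if w.shape != (n, n):
            raise ValidationError(
                f"weights shape {w.shape} does not match atlas ({n} regions)",
                ["weights"],
            )
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValidationError("weights must be finite and non-negative", ["weights"])
        if np.any(np.diag(w) != 0) or np.max(np.abs(w - w.T)) > 0:
            raise ValidationError("weights must be exactly symmetric with zero diagonal", ["weights"])

    @property
    def n_nodes(self) -> int:
        return self.atlas.n_regions

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1).astype(int)


def build_weight_matrix(subject: SubjectConnectivity, fn_threshold: int = 3) -> WeightedNetwork:
    """Build the subject's weighted network, keeping edges with FN >= threshold.

    The threshold is inclusive: an edge with exactly ``fn_threshold``
    streamlines survives.  Sub-threshold entries are exactly zero.
    """
    if fn_threshold < 1:
        raise ValidationError(f"fn_threshold must be >= 1, got {fn_threshold}", ["fn_threshold"])
    subject.validate()
    vols = subject.volumes
    mean_vol = (vols[:, None] + vols[None, :]) / 2.0
    w = np.where(subject.fn >= fn_threshold, subject.fn * subject.fa / mean_vol, 0.0)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0  # exact symmetry despite float ops
    atlas = subject.atlas
    if atlas is None:
        atlas = aal90() if subject.n_regions == 90 else RegionAtlas(
            labels=tuple(f"R{i + 1}" for i in range(subject.n_regions))
        )
    return WeightedNetwork(weights=w, atlas=atlas)


def validate_threshold_stability(
    subject: SubjectConnectivity, thresholds: Sequence[int] = (1, 2, 3, 4, 5)
):
    """Global metrics of one subject's network across FN thresholds.

    Returns a pandas DataFrame with one row per threshold (edge count plus
    the global metrics), used to check that conclusions do not hinge on the
    streamline cutoff.  Raising the threshold can only remove edges.
    """
    import pandas as pd

    from .metrics import global_metrics

    if len(thresholds) == 0:
        raise ValidationError("thresholds must be non-empty", ["thresholds"])
    rows = []
    for t in thresholds:
        net = build_weight_matrix(subject, fn_threshold=t)
        gm = global_metrics(net)
        rows.append({"threshold": int(t), "n_edges": net.n_edges, **gm.as_dict()})
    return pd.DataFrame(rows)
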