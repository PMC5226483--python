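"""Region parcellations for connectome analysis.

The default atlas is the 90-region cortical + subcortical AAL parcellation
(Automated Anatomical Labeling), whose regions define the nodes of every
network built by this package.  Regions alternate left/right hemisphere in
the conventional AAL numbering (``PreCG.L``, ``PreCG.R``, ``SFGdor.L`` ...),
0-based internally and 1-based in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["RegionAtlas", "aal90", "load_atlas", "synthetic_centroids"]


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered set of named brain regions.

    Parameters
    ----------
    labels
        Unique region names; their order fixes the node order of every
        matrix in the analysis.
    """

    labels: tuple[str, ...]
    name: str = "custom"
    ids: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = {l for l in self.labels if list(self.labels).count(l) > 1}
            raise ValueError(f"atlas labels must be unique; duplicated: {sorted(dupes)}")
        if not self.labels:
            raise ValueError("atlas must contain at least one region")
        if not self.ids:
            object.__setattr__(self, "ids", tuple(range(1, len(self.labels) + 1)))
        elif len(self.ids) != len(self.labels):
            raise ValueError("ids and labels must have equal length")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """0-based index of a region label."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"region {label!r} not in atlas {self.name!r}") from None

    def __len__(self) -> int:
        return self.n_regions


def _read_label_lines(lines) -> tuple[str, ...]:
    labels = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    return tuple(labels)


def aal90() -> RegionAtlas:
    """The 90-region AAL atlas (cortical + subcortical, no cerebellum)."""
    text = resources.files("wmnet.data").joinpath("aal90_labels.txt").read_text()
    return RegionAtlas(labels=_read_label_lines(text.splitlines()), name="AAL-90")


def load_atlas(path: str | Path, name: str | None = None) -> RegionAtlas:
    """Load an atlas from a plain-text file with one region label per line."""
    path = Path(path)
    labels = _read_label_lines(path.read_text().splitlines())
    return RegionAtlas(labels=labels, name=name or path.stem)


def synthetic_centroids(atlas: RegionAtlas) -> np.ndarray:
    """Synthetic stand-in region centroids for node-file visualisation.

    Returns an ``(n_regions, 3)`` array of deterministic pseudo-MNI
    coordinates: regions are laid out on two lateral arcs (left hemisphere
    x < 0, right x > 0) purely so that node files render as two hemispheres.
    These are NOT measured AAL centroids and carry no anatomical meaning.
    """
    n = atlas.n_regions
    coords = np.empty((n, 3))
    for i, label in enumerate(atlas.labels):
        right = label.endswith(".R")
        # position along an anterior-posterior arc, same for both hemispheres
        t = (i // 2) / max(1, (n - 1) // 2)
        coords[i, 0] = 45.0 if right else -45.0
        coords[i, 1] = 70.0 - 140.0 * t
        coords[i, 2] = 60.0 * np.sin(np.pi * t) - 10.0
    return np.round(coords, 2)
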