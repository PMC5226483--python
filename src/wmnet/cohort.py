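"""Synthetic three-group connectome cohorts with planted network disruption.

Generates per-subject fiber-number (FN), mean-FA and region-volume inputs
over the AAL-90 atlas, mimicking the group structure of a memory-clinic
study: normal controls (NC), subjective cognitive decline (SCD) and
amnestic mild cognitive impairment (aMCI), default sizes 36/21/33.

The base topology is a Watts-Strogatz-style small world: a ring lattice
(each region tied to its ``lattice_k`` nearest neighbours) in which each
edge is rewired to a random target with probability ``rewire_p``.  Rewired
edges are the long-range shortcuts; the disease effect is a multiplicative
attenuation of FN and FA on those shortcut edges and on edges incident to
one designated hub region (default PCUN.R, the right precuneus), graded
NC < SCD < aMCI.  This encodes disconnection of distant regions as the
planted pathology; the attenuated edge set is stored in the ground-truth
record rather than asserted as biology.

Cognitive scores follow a linear model: a group-specific intercept (set
near published memory-clinic norms) plus a slope on the subject's hub
betweenness plus Gaussian noise, so that score-network associations are
recoverable by partial correlation.

Everything is a pure function of (spec, master_seed): per-subject
generators are spawned via ``SeedSequence(master_seed, spawn_key=...)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .atlas import RegionAtlas, aal90
from .construction import GROUPS, SubjectConnectivity, ValidationError, build_weight_matrix
from .metrics import betweenness

__all__ = ["ScoreParams", "CohortSpec", "base_topology", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class ScoreParams:
    """Linear generative model for one cognitive score.

    score = intercept[group] + slope * z(hub betweenness) + N(0, noise_sd)
    """

    intercepts: Mapping[str, float]
    slope: float
    noise_sd: float


# Hub-betweenness standardisation constants: cross-subject mean and SD of
# the target region's betweenness under the default spec, measured once by
# simulation so that ``slope`` is expressed per SD of betweenness.
_B_HUB_CENTER = 140.0
_B_HUB_SCALE = 110.0


def _default_scores() -> dict[str, ScoreParams]:
    # intercepts near memory-clinic norms; the delayed-recall score carries
    # the betweenness association (slope chosen for a partial r near 0.4
    # given its noise SD: r = s / sqrt(s^2 + sd^2))
    return {
        "MMSE": ScoreParams({"NC": 28.1, "SCD": 27.9, "aMCI": 25.0}, 0.0, 2.0),
        "MoCA": ScoreParams({"NC": 26.7, "SCD": 26.0, "aMCI": 19.8}, 0.0, 2.7),
        "AVLT_I": ScoreParams({"NC": 8.9, "SCD": 7.8, "aMCI": 5.7}, 0.0, 1.6),
        "AVLT_D": ScoreParams({"NC": 10.3, "SCD": 7.9, "aMCI": 3.9}, 1.05, 2.4),
        "AVLT_R": ScoreParams({"NC": 12.5, "SCD": 10.4, "aMCI": 7.9}, 0.0, 2.5),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic three-group cohort generator."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NC": 36, "SCD": 21, "aMCI": 33}
    )
    n_regions: int = 90
    lattice_k: int = 8
    rewire_p: float = 0.1
    fn_mean: float = 20.0
    fn_dispersion: float = 5.0
    fa_beta: tuple[float, float] = (2.0, 2.0)
    fa_range: tuple[float, float] = (0.2, 0.7)
    vol_mean_mm3: float = 8000.0
    vol_log_sd: float = 0.3
    attenuation: Mapping[str, float] = field(
        default_factory=lambda: {"NC": 0.0, "SCD": 0.15, "aMCI": 0.30}
    )
    hub_region: str = "PCUN.R"
    subject_scale_sd: float = 0.15
    score_model: Mapping[str, ScoreParams] = field(default_factory=_default_scores)
    master_seed: int = 0

    def validate(self) -> None:
        bad = []
        if not all(g in GROUPS for g in self.n_per_group) or any(
            n < 1 for n in self.n_per_group.values()
        ):
            bad.append("n_per_group")
        if self.n_regions < 4:
            bad.append("n_regions")
        if not (2 <= self.lattice_k < self.n_regions) or self.lattice_k % 2:
            bad.append("lattice_k")
        if not (0.0 <= self.rewire_p <= 1.0):
            bad.append("rewire_p")
        if self.fn_mean <= 0 or self.fn_dispersion <= 0:
            bad.append("fn_distribution")
        if min(self.fa_beta) <= 0:
            bad.append("fa_beta")
        lo, hi = self.fa_range
        if not (0.0 <= lo < hi <= 1.0):
            bad.append("fa_range")
        if self.vol_mean_mm3 <= 0 or self.vol_log_sd < 0:
            bad.append("volume_distribution")
        atts = self.attenuation
        if (
            any(not (0.0 <= a < 1.0) for a in atts.values())
            or atts.get("SCD", 0.0) > atts.get("aMCI", 0.0)
            or atts.get("NC", 0.0) != 0.0
        ):
            bad.append("attenuation")
        if self.subject_scale_sd < 0:
            bad.append("subject_scale_sd")
        if self.hub_region not in self.atlas().labels:
            bad.append("hub_region")
        if bad:
            raise ValidationError(f"invalid cohort spec fields: {bad}", bad)

    def atlas(self) -> RegionAtlas:
        if self.n_regions == 90:
            return aal90()
        return RegionAtlas(labels=tuple(f"R{i + 1}" for i in range(self.n_regions)))


def base_topology(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cohort-level edge list with shortcut and hub-incidence flags.

    Builds the ring lattice, rewires each edge with probability
    ``rewire_p`` (one endpoint moved to a uniform random target, avoiding
    self-loops and duplicates), and returns ``(edges, is_long_range,
    is_hub_incident)``.  Deterministic given the spec's master seed.
    """
    n, k = spec.n_regions, spec.lattice_k
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.master_seed, spawn_key=(0,)))
    edges = [(i, (i + d) % n) for d in range(1, k // 2 + 1) for i in range(n)]
    present = {(min(a, b), max(a, b)) for a, b in edges}
    out = []
    long_range = []
    for a, b in edges:
        key = (min(a, b), max(a, b))
        rewired = False
        if rng.random() < spec.rewire_p:
            for _ in range(100):
                m = int(rng.integers(0, n))
                new = (min(a, m), max(a, m))
                if m != a and new not in present:
                    present.discard(key)
                    present.add(new)
                    key = new
                    rewired = True
                    break
        out.append(key)
        long_range.append(rewired)
    edges_arr = np.array(out, dtype=int)
    long_arr = np.array(long_range, dtype=bool)
    hub = spec.atlas().index(spec.hub_region)
    hub_arr = (edges_arr == hub).any(axis=1)
    return edges_arr, long_arr, hub_arr


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    out = rng.normal(mean, sd, size=size)
    while True:
        bad = (out < lo) | (out > hi)
        if not np.any(bad):
            return out
        out = np.where(bad, rng.normal(mean, sd, size=np.shape(out)), out)


def generate_subject(
    spec: CohortSpec,
    group: str,
    seed: int | np.random.SeedSequence,
    subject_id: str | None = None,
    with_scores: bool = True,
) -> SubjectConnectivity:
    """Draw one subject's FN/FA/volume inputs and phenotype.

    ``with_scores=False`` skips the cognitive-score stage (which requires a
    betweenness computation); the network and demographics are bit-identical
    either way because scores use an independently spawned generator.
    """
    spec.validate()
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}", ["group"])
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_net, rng_demo, rng_score = (np.random.default_rng(c) for c in ss.spawn(3))

    edges, long_range, hub_inc = base_topology(spec)
    affected = long_range | hub_inc
    att = float(spec.attenuation.get(group, 0.0))
    n = spec.n_regions
    n_e = len(edges)

    scale = float(rng_net.lognormal(mean=0.0, sigma=spec.subject_scale_sd))
    mean_fn = np.full(n_e, spec.fn_mean * scale)
    mean_fn[affected] *= 1.0 - att
    r = spec.fn_dispersion
    p = r / (r + mean_fn)
    fn_vals = rng_net.negative_binomial(r, p).astype(float)

    a, b = spec.fa_beta
    lo, hi = spec.fa_range
    fa_vals = lo + (hi - lo) * rng_net.beta(a, b, size=n_e)
    fa_vals[affected] *= 1.0 - att
    fa_vals[fn_vals == 0] = 0.0

    fn = np.zeros((n, n))
    fa = np.zeros((n, n))
    fn[edges[:, 0], edges[:, 1]] = fn_vals
    fa[edges[:, 0], edges[:, 1]] = fa_vals
    fn = fn + fn.T
    fa = fa + fa.T

    volumes = rng_net.lognormal(mean=np.log(spec.vol_mean_mm3), sigma=spec.vol_log_sd, size=n)

    age = float(_truncated_normal(rng_demo, 62.0, 9.0, 50.0, 80.0))
    education = float(_truncated_normal(rng_demo, 10.5, 4.0, 0.0, 25.0))
    sex = "F" if rng_demo.random() < 0.6 else "M"

    subject = SubjectConnectivity(
        subject_id=subject_id or f"{group}_{ss.entropy}",
        group=group,
        fn=fn,
        fa=fa,
        volumes=volumes,
        age=age,
        sex=sex,
        education=education,
        scores={},
        atlas=spec.atlas(),
    )

    if with_scores:
        net = build_weight_matrix(subject, fn_threshold=3)
        b_hub = betweenness(net).betweenness[spec.atlas().index(spec.hub_region)]
        z = (b_hub - _B_HUB_CENTER) / _B_HUB_SCALE
        scores = {}
        for name, sp in spec.score_model.items():
            scores[name] = float(
                sp.intercepts[group] + sp.slope * z + rng_score.normal(0.0, sp.noise_sd)
            )
        subject.scores = scores
    return subject


def generate_cohort(
    spec: CohortSpec, with_scores: bool = True
) -> tuple[list[SubjectConnectivity], dict]:
    """Draw the full three-group cohort plus its ground-truth record.

    The ground truth stores the attenuated edge set, the per-group
    attenuations and the score-model coefficients — the targets a pipeline
    run should recover.
    """
    spec.validate()
    edges, long_range, hub_inc = base_topology(spec)
    subjects: list[SubjectConnectivity] = []
    for gi, group in enumerate(g for g in GROUPS if g in spec.n_per_group):
        for i in range(spec.n_per_group[group]):
            ss = np.random.SeedSequence(entropy=spec.master_seed, spawn_key=(1, gi, i))
            subjects.append(
                generate_subject(
                    spec, group, ss, subject_id=f"{group}{i + 1:03d}", with_scores=with_scores
                )
            )
    ground_truth = {
        "master_seed": spec.master_seed,
        "hub_region": spec.hub_region,
        "attenuation": dict(spec.attenuation),
        "long_range_edges": edges[long_range].tolist(),
        "hub_incident_edges": edges[hub_inc].tolist(),
        "score_model": {
            name: {
                "intercepts": dict(sp.intercepts),
                "slope": sp.slope,
                "noise_sd": sp.noise_sd,
            }
            for name, sp in spec.score_model.items()
        },
        "expected_eg_order": ["NC", "SCD", "aMCI"],
    }
    return subjects, ground_truth
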