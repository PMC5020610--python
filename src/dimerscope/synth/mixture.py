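"""Seeded conformational mixtures with ground-truth component labels.

A mixture draws each frame from one of several named component
generators (helix, strand, coil, hairpin, and their two-chain variants)
by seeded categorical sampling, and returns the true per-frame component
label alongside the ensemble — the scaffolding for every recovery test
of ensemble statistics and clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import rotation_about_axis
from ..model import Conformation, Ensemble, Topology
from .backbone import (
    DihedralSpec,
    build_backbone,
    build_dimer,
    build_hairpin,
    coil_dihedrals,
    helix_dihedrals,
    strand_dihedrals,
)


def _jittered(spec: DihedralSpec, jitter_deg: float, rng: np.random.Generator
              ) -> DihedralSpec:
    if jitter_deg <= 0:
        return spec
    ang = spec.angles.copy()
    ang[:, :2] += rng.normal(0.0, jitter_deg, size=ang[:, :2].shape)
    ang = ((ang + 180.0) % 360.0) - 180.0
    ang[ang == -180.0] = 180.0
    return DihedralSpec(ang)


def _gen_helix(params: dict, rng: np.random.Generator):
    seq = params["sequence"]
    spec = _jittered(helix_dihedrals(len(seq)), params.get("jitter_deg", 3.0), rng)
    return build_backbone(seq, spec)


def _gen_strand(params: dict, rng: np.random.Generator):
    seq = params["sequence"]
    spec = _jittered(strand_dihedrals(len(seq)), params.get("jitter_deg", 3.0), rng)
    return build_backbone(seq, spec)


def _gen_coil(params: dict, rng: np.random.Generator):
    seq = params["sequence"]
    return build_backbone(seq, coil_dihedrals(len(seq), rng))


def _gen_hairpin(params: dict, rng: np.random.Generator):
    seq = params["sequence"]
    conf, top = build_hairpin(seq, tuple(params["strand1"]),
                              tuple(params["turn"]), tuple(params["strand2"]))
    jitter = params.get("jitter_deg", 0.0)
    if jitter > 0:
        # jitter as a small random rigid wobble (dihedral jitter would
        # unzip the hairpin's hydrogen-bond register)
        axis = rng.normal(size=3)
        R = rotation_about_axis(axis, rng.normal(0.0, jitter))
        conf = Conformation((conf.coords - conf.coords.mean(0)) @ R.T
                            + conf.coords.mean(0))
    return conf, top


def _paired(single_gen, params: dict, rng: np.random.Generator):
    """Two independently generated copies of a single-chain component,
    placed side by side with seeded placement noise."""
    confA, topA = single_gen(params, rng)
    confB, topB = single_gen(params, rng)
    sep = params.get("separation_nm", 1.2)
    for _ in range(60):
        axis = rng.normal(size=3)
        R = rotation_about_axis(axis, rng.uniform(0.0, 360.0))
        t = np.array([sep, 0.0, 0.0]) + rng.normal(0.0, 0.15, size=3)
        try:
            return build_dimer((confA, topA), (confB, topB), t, R)
        except ValueError:
            sep += 0.15
    raise RuntimeError("could not place dimer without clashes")


def _gen_coil_dimer(params: dict, rng: np.random.Generator):
    return _paired(_gen_coil, params, rng)


def _gen_hairpin_dimer(params: dict, rng: np.random.Generator):
    """Hairpin chain A + second hairpin chain B packed against it
    (antiparallel offset placement: chain B flipped about z)."""
    confA, topA = _gen_hairpin(params, rng)
    confB, topB = _gen_hairpin(params, rng)
    sep = params.get("separation_nm", 0.55)
    flip = rotation_about_axis([0.0, 0.0, 1.0], 180.0)
    for _ in range(60):
        wobble = rotation_about_axis(rng.normal(size=3), rng.normal(0.0, 6.0))
        t = np.array([0.0, -sep, 0.0]) + rng.normal(0.0, 0.05, size=3)
        try:
            return build_dimer((confA, topA), (confB, topB), t, wobble @ flip)
        except ValueError:
            sep += 0.1
    raise RuntimeError("could not place dimer without clashes")


COMPONENT_GENERATORS = {
    "helix": _gen_helix,
    "strand": _gen_strand,
    "coil": _gen_coil,
    "hairpin": _gen_hairpin,
    "coil_dimer": _gen_coil_dimer,
    "hairpin_dimer": _gen_hairpin_dimer,
}


@dataclass
class MixtureSpec:
    """Components as (generator name, parameter dict, weight) triples."""

    components: list[tuple[str, dict, float]]
    n_frames: int
    seed: int
    temperature_K: float = 310.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.components:
            raise ValueError("at least one component required")
        for name, _, w in self.components:
            if name not in COMPONENT_GENERATORS:
                raise KeyError(f"unknown component generator {name!r}")
            if w < 0:
                raise ValueError("component weights must be nonnegative")
        if sum(w for _, _, w in self.components) <= 0:
            raise ValueError("total component weight must be positive")


def generate_mixture(spec: MixtureSpec) -> tuple[Ensemble, np.ndarray]:
    """Draw frames from the component mixture; return ensemble + labels.

    Labels are component indices into ``spec.components``.  All
    components must produce the same topology (same chains/atoms);
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for _, _, w in spec.components], dtype=float)
    weights = weights / weights.sum()
    labels = rng.choice(len(weights), size=spec.n_frames, p=weights)

    frames: list[Conformation] = []
    topology: Topology | None = None
    for f, lab in enumerate(labels):
        name, params, _ = spec.components[lab]
        conf, top = COMPONENT_GENERATORS[name](params, rng)
        if topology is None:
            topology = top
        elif top.n_atoms != topology.n_atoms:
            raise ValueError(
                f"component {name!r} topology ({top.n_atoms} atoms) differs "
                f"from first component ({topology.n_atoms} atoms)")
        conf.frame_index = f
        frames.append(conf)
    ensemble = Ensemble(topology, frames, temperature_K=spec.temperature_K)
    return ensemble, labels
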