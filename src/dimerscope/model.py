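"""Core data model: topology, single-frame conformations, and ensembles.

All coordinates are stored internally in nanometres.  File readers and
writers convert at the boundary (PDB files are in angstroms).

A :class:`Topology` is an explicit declaration of the molecular system:
chains, residues, atoms, the main-chain/side-chain partition, aromatic
ring groups and cationic charged groups.  It deliberately carries more
chemistry than a bare PDB file does, because the downstream analyses
(main-chain RMSD clustering, side-chain contact maps, ring stacking,
cation-pi distances) all need those classifications to be unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ANGSTROM_PER_NM = 10.0

#: Atom classes used throughout the analyses.
ATOM_CLASSES = ("main_chain", "side_chain", "ligand", "hydrogen")

#: Approximate atomic masses (u) by element, for mass-weighted quantities.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904,
}


@dataclass(frozen=True)
class Atom:
    """One atom of the topology.

    ``name`` must be unique within its residue.  ``atom_class`` is one of
    :data:`ATOM_CLASSES`; ``ring_group`` / ``charged_group`` name the
    aromatic-ring or cationic group the atom belongs to, if any.
    """

    name: str
    element: str
    atom_class: str
    ring_group: str | None = None
    charged_group: str | None = None

    def __post_init__(self):
        if self.atom_class not in ATOM_CLASSES:
            raise ValueError(f"unknown atom class {self.atom_class!r}")


@dataclass(frozen=True)
class Residue:
    """A residue (or ligand 'residue'): 1-based index, 3-letter name, atoms."""

    index: int
    name: str
    atoms: tuple[Atom, ...]

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate atom names in residue {self.name}{self.index}")

    def atom_index(self, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.name == name:
                return i
        raise KeyError(f"no atom {name!r} in residue {self.name}{self.index}")


@dataclass(frozen=True)
class Chain:
    """A chain: single-character id plus its residues in sequence order."""

    chain_id: str
    residues: tuple[Residue, ...]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


class Topology:
    """Chains, residues and atoms with their analysis classifications.

    Parameters
    ----------
    chains
        Chain records in file order.  Peptide chains first, ligand
        "chains" (each ligand molecule as its own chain) after.
    homodimer
        Declare the first two chains as a homodimer (identical residue
        and atom naming); required by chain-independent RMSD.
    """

    def __init__(self, chains: Sequence[Chain], homodimer: bool = False):
        if not chains:
            raise ValueError("topology needs at least one chain")
        ids = [c.chain_id for c in chains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chain ids")
        self.chains = tuple(chains)
        self.homodimer = bool(homodimer)
        if self.homodimer:
            if len(chains) < 2:
                raise ValueError("homodimer declaration requires >= 2 chains")
            a, b = chains[0], chains[1]
            sig_a = [(r.name, tuple(at.name for at in r.atoms)) for r in a.residues]
            sig_b = [(r.name, tuple(at.name for at in r.atoms)) for r in b.residues]
            if sig_a != sig_b:
                raise ValueError("homodimer chains differ in residue/atom naming")
        self._build_index()
        self._validate_groups()

    def _build_index(self):
        flat_atoms: list[Atom] = []
        flat_chain: list[int] = []
        flat_res: list[int] = []  # global residue index (0-based, over all chains)
        res_slices: list[tuple[int, int]] = []
        res_chain: list[int] = []
        res_records: list[Residue] = []
        g = 0
        for ci, chain in enumerate(self.chains):
            for res in chain.residues:
                start = len(flat_atoms)
                for atom in res.atoms:
                    flat_atoms.append(atom)
                    flat_chain.append(ci)
                    flat_res.append(g)
                res_slices.append((start, len(flat_atoms)))
                res_chain.append(ci)
                res_records.append(res)
                g += 1
        self._atoms = tuple(flat_atoms)
        self.atom_chain = np.asarray(flat_chain, dtype=int)
        self.atom_residue = np.asarray(flat_res, dtype=int)
        self._res_slices = tuple(res_slices)
        self.residue_chain = np.asarray(res_chain, dtype=int)
        self._residues = tuple(res_records)

    def _validate_groups(self):
        for gname, idx in self.ring_groups().items():
            if len(idx) < 3:
                raise ValueError(f"ring group {gname!r} has fewer than 3 atoms")
            if len(set(self.atom_residue[idx])) != 1:
                raise ValueError(f"ring group {gname!r} spans residues")

    # -- basic accessors ------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    @property
    def n_residues(self) -> int:
        return len(self._residues)

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return self._atoms

    @property
    def residues(self) -> tuple[Residue, ...]:
        return self._residues

    def residue_atom_indices(self, global_res: int) -> np.ndarray:
        start, stop = self._res_slices[global_res]
        return np.arange(start, stop)

    def chain_index(self, chain_id: str) -> int:
        for i, c in enumerate(self.chains):
            if c.chain_id == chain_id:
                return i
        raise KeyError(f"no chain {chain_id!r}")

    def chain_residue_indices(self, chain: int | str) -> np.ndarray:
        ci = chain if isinstance(chain, int) else self.chain_index(chain)
        return np.flatnonzero(self.residue_chain == ci)

    def find_atom(self, chain_id: str, res_index: int, atom_name: str) -> int:
        """Flat index of one atom addressed by chain id, residue index, name."""
        ci = self.chain_index(chain_id)
        for g in self.chain_residue_indices(ci):
            res = self._residues[g]
            if res.index == res_index:
                start, _ = self._res_slices[g]
                return start + res.atom_index(atom_name)
        raise KeyError(f"no residue {res_index} in chain {chain_id}")

    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[a.element.upper()] for a in self._atoms])
        except KeyError as exc:
            raise KeyError(f"no mass for element {exc.args[0]!r}") from None

    def elements(self) -> list[str]:
        return [a.element for a in self._atoms]

    # -- group accessors ------------------------------------------------
    def ring_groups(self) -> dict[str, np.ndarray]:
        """Mapping ring-group name -> ordered flat atom indices."""
        groups: dict[str, list[int]] = {}
        for i, a in enumerate(self._atoms):
            if a.ring_group is not None:
                groups.setdefault(a.ring_group, []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}

    def charged_groups(self) -> dict[str, np.ndarray]:
        groups: dict[str, list[int]] = {}
        for i, a in enumerate(self._atoms):
            if a.charged_group is not None:
                groups.setdefault(a.charged_group, []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}

    # -- selections -----------------------------------------------------
    def select(self, atom_class: str | Iterable[str] | None = None,
               chain: str | Iterable[str] | None = None,
               heavy_only: bool = False) -> np.ndarray:
        """Topology-ordered flat indices matching an atom-class and/or chain filter.

        ``atom_class`` and ``chain`` accept a single value or an iterable;
        ``heavy_only`` additionally drops hydrogens (element H).
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_class is not None:
            classes = {atom_class} if isinstance(atom_class, str) else set(atom_class)
            unknown = classes - set(ATOM_CLASSES)
            if unknown:
                raise ValueError(f"unknown atom class(es): {sorted(unknown)}")
            mask &= np.array([a.atom_class in classes for a in self._atoms])
        if chain is not None:
            wanted = {chain} if isinstance(chain, str) else set(chain)
            known = {c.chain_id for c in self.chains}
            unknown = wanted - known
            if unknown:
                raise ValueError(f"unknown chain(s): {sorted(unknown)}")
            cidx = {self.chain_index(c) for c in wanted}
            mask &= np.isin(self.atom_chain, list(cidx))
        if heavy_only:
            mask &= np.array([a.element.upper() != "H" for a in self._atoms])
        return np.flatnonzero(mask)

    def peptide_chain_indices(self) -> list[int]:
        """Chains containing at least one main-chain atom."""
        out = []
        for ci in range(len(self.chains)):
            sel = (self.atom_chain == ci)
            if any(self._atoms[i].atom_class == "main_chain" for i in np.flatnonzero(sel)):
                out.append(ci)
        return out

    def ligand_chain_indices(self) -> list[int]:
        out = []
        for ci in range(len(self.chains)):
            idx = np.flatnonzero(self.atom_chain == ci)
            if len(idx) and all(self._atoms[i].atom_class in ("ligand", "hydrogen")
                                for i in idx):
                if any(self._atoms[i].atom_class == "ligand" for i in idx):
                    out.append(ci)
        return out


@dataclass
class Conformation:
    """One frame: (n_atoms, 3) coordinates in nm referencing a shared topology."""

    coords: np.ndarray
    frame_index: int = 0
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Conformation":
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation)
        return Conformation(xyz, self.frame_index, self.box)


@dataclass
class Ensemble:
    """Ordered frames + per-frame weights + a temperature tag.

    Weights default to uniform and are normalised to sum to one.  The
    temperature (K) is carried along for free-energy surfaces.
    """

    topology: Topology
    frames: list[Conformation]
    weights: np.ndarray | None = None
    temperature_K: float = 310.0

    def __post_init__(self):
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame {f.frame_index}: {f.coords.shape[0]} coords vs "
                    f"{n} topology atoms")
        if self.weights is None:
            self.weights = np.full(len(self.frames), 1.0 / len(self.frames))
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.frames),):
                raise ValueError("one weight per frame required")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            total = w.sum()
            if total <= 0:
                raise ValueError("weights must sum to a positive value")
            self.weights = w / total
        assert abs(self.weights.sum() - 1.0) < 1e-9

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinate array (nm)."""
        return np.stack([f.coords for f in self.frames])

    def subset(self, frame_indices: Sequence[int]) -> "Ensemble":
        idx = list(frame_indices)
        if not idx:
            raise ValueError("empty frame subset")
        w = self.weights[idx]
        return Ensemble(self.topology, [self.frames[i] for i in idx],
                        weights=w / w.sum(), temperature_K=self.temperature_K)
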