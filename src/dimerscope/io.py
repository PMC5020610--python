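"""Readers and writers: multi-model PDB files and topology declarations.

PDB parsing and serialisation are delegated to biotite; this module maps
between biotite atom arrays and the package's explicit :class:`Topology`
declaration, converting angstrom file coordinates to the internal nm unit.

The topology declaration is a YAML document because PDB records alone do
not carry the main-chain/side-chain partition, ring groups or charged
groups the analyses need.
"""

from __future__ import annotations

import numpy as np
import yaml

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .model import ANGSTROM_PER_NM, Atom, Chain, Conformation, Ensemble, Residue, Topology

# PDB coordinate field is %8.3f: representable range in angstrom
_PDB_COORD_MAX = 9999.999


# ---------------------------------------------------------------------------
# topology declaration (YAML)
# ---------------------------------------------------------------------------

def topology_to_dict(top: Topology) -> dict:
    chains = []
    for chain in top.chains:
        residues = []
        for res in chain.residues:
            atoms = []
            for a in res.atoms:
                rec: dict = {"name": a.name, "element": a.element, "class": a.atom_class}
                if a.ring_group is not None:
                    rec["ring_group"] = a.ring_group
                if a.charged_group is not None:
                    rec["charged_group"] = a.charged_group
                atoms.append(rec)
            residues.append({"index": res.index, "name": res.name, "atoms": atoms})
        chains.append({"id": chain.chain_id, "residues": residues})
    return {"homodimer": top.homodimer, "chains": chains}


def topology_from_dict(doc: dict) -> Topology:
    chains = []
    for cdoc in doc["chains"]:
        residues = []
        for rdoc in cdoc["residues"]:
            atoms = tuple(
                Atom(adoc["name"], adoc["element"], adoc["class"],
                     adoc.get("ring_group"), adoc.get("charged_group"))
                for adoc in rdoc["atoms"])
            residues.append(Residue(int(rdoc["index"]), rdoc["name"], atoms))
        chains.append(Chain(cdoc["id"], tuple(residues)))
    return Topology(chains, homodimer=bool(doc.get("homodimer", False)))


def write_topology(top: Topology, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(topology_to_dict(top), fh, sort_keys=False)


def read_topology(path) -> Topology:
    with open(path) as fh:
        return topology_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

def read_multi_model_pdb(path, topology: Topology, temperature_K: float = 310.0) -> Ensemble:
    """Read a multi-MODEL PDB file into an :class:`Ensemble`.

    Every atom declared in ``topology`` must appear (matched by chain id,
    residue number and atom name) in every model; models with missing or
    extra declared atoms raise with the offending model and atom named.
    Coordinates are converted angstrom -> nm; weights are uniform.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack, coords in angstrom
    if stack.stack_depth() < 1:
        raise ValueError(f"{path}: no models found")

    key_to_pos: dict[tuple[str, int, str], int] = {}
    for pos in range(stack.array_length()):
        key = (str(stack.chain_id[pos]), int(stack.res_id[pos]), str(stack.atom_name[pos]))
        key_to_pos.setdefault(key, pos)

    order = np.empty(topology.n_atoms, dtype=int)
    i = 0
    for chain in topology.chains:
        for res in chain.residues:
            for atom in res.atoms:
                key = (chain.chain_id, res.index, atom.name)
                if key not in key_to_pos:
                    raise ValueError(
                        f"{path}: declared atom {atom.name} of "
                        f"{res.name}{res.index} chain {chain.chain_id} "
                        f"missing from file")
                order[i] = key_to_pos[key]
                i += 1

    frames = []
    for m in range(stack.stack_depth()):
        xyz = stack.coord[m][order] / ANGSTROM_PER_NM
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"{path}: non-finite coordinates in model {m + 1}")
        frames.append(Conformation(xyz, frame_index=m))
    return Ensemble(topology, frames, temperature_K=temperature_K)


def write_multi_model_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (coordinates in angstrom)."""
    top = ensemble.topology
    n = top.n_atoms

    array = bst.AtomArray(n)
    chain_ids, res_ids, res_names, atom_names, elements, hetero = [], [], [], [], [], []
    for chain in top.chains:
        is_ligand = all(a.atom_class in ("ligand", "hydrogen")
                        for r in chain.residues for a in r.atoms)
        for res in chain.residues:
            for atom in res.atoms:
                chain_ids.append(chain.chain_id)
                res_ids.append(res.index)
                res_names.append(res.name)
                atom_names.append(atom.name)
                elements.append(atom.element.upper())
                hetero.append(is_ligand)
    array.chain_id = np.array(chain_ids, dtype="U4")
    array.res_id = np.array(res_ids, dtype=int)
    array.res_name = np.array(res_names, dtype="U5")
    array.atom_name = np.array(atom_names, dtype="U6")
    array.element = np.array(elements, dtype="U2")
    array.hetero = np.array(hetero, dtype=bool)

    coords = ensemble.coordinates() * ANGSTROM_PER_NM
    if np.any(np.abs(coords) > _PDB_COORD_MAX):
        raise ValueError("coordinates exceed the fixed-width PDB coordinate field")

    stack = bst.AtomArrayStack(ensemble.n_frames, n)
    for ann in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(ann, getattr(array, ann))
    stack.coord = coords

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
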