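"""Full-analysis orchestration: one ensemble in, a directory of tables out.

``run_full_analysis`` executes the complete analysis battery on an input
ensemble (from a multi-model PDB + topology declaration, or from a named
synthetic preset): secondary-structure summary and per-residue profile,
Daura clustering with top-k cluster statistics, cluster-1 interface
analyses, the (Rg, H-bond number) free-energy surface with basin table,
strand-length distribution, the four contact-probability maps, and — when
a ligand is present — ligand-residue contacts, stacking statistics,
inter-ring torsion PDFs and the cation-pi distance PDF, plus split-half
convergence diagnostics.  Every output is a TSV (or the cluster-centre
multi-model PDB) listed in a manifest with SHA-256 checksums; all
randomness is seeded, so a rerun with the same config reproduces the
manifest byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Conformation, Ensemble
from .io import write_multi_model_pdb, write_topology
from . import secstruct
from . import cluster as clustering
from . import interactions
from . import ensemble_stats as stats
from . import ccs as ccsmod
from .synth import (HIAPP_SEQUENCE, MixtureSpec, egcg_like_ligand,
                    generate_mixture, attach_ligand, place_ligand_ring)

logger = logging.getLogger("dimerscope.pipeline")

FLOAT_FMT = "%.10g"


@dataclass
class AnalysisConfig:
    """Parameters of one full-analysis run (YAML-serialisable)."""

    output_dir: str = "dimerscope_out"
    input_pdb: str | None = None
    topology: str | None = None
    preset: str | None = None          # synthetic preset instead of input files
    n_frames: int = 120
    seed: int = 0
    temperature_K: float = 310.0
    cluster_cutoff_nm: float = 0.35
    contact_cutoff_nm: float = 0.50
    top_k: int = 6
    rg_bin_width_nm: float = 0.02
    hbond_bin_width: float = 1.0
    ccs_n_orientations: int = 100
    ccs_n_points: int = 2000
    fes_bins: int = 24                 # per axis for the stacking FES

    def validate(self):
        for name in ("cluster_cutoff_nm", "contact_cutoff_nm",
                     "rg_bin_width_nm", "hbond_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.preset is None and (self.input_pdb is None or self.topology is None):
            raise ValueError("either a preset or input_pdb + topology is required")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


# ---------------------------------------------------------------------------
# synthetic presets
# ---------------------------------------------------------------------------

_HAIRPIN_PARAMS = {
    "sequence": HIAPP_SEQUENCE,
    "strand1": (8, 16), "turn": (17, 24), "strand2": (25, 33),
    "jitter_deg": 8.0,
}


def _preset_base(name: str, n_frames: int, seed: int, temperature_K: float):
    if name in ("hairpin-dimer", "hairpin-dimer+ligand"):
        spec = MixtureSpec(
            [("hairpin_dimer", dict(_HAIRPIN_PARAMS), 0.55),
             ("coil_dimer", {"sequence": HIAPP_SEQUENCE}, 0.45)],
            n_frames=n_frames, seed=seed, temperature_K=temperature_K)
    elif name in ("coil-dimer", "coil-dimer+ligand"):
        spec = MixtureSpec(
            [("coil_dimer", {"sequence": HIAPP_SEQUENCE}, 1.0)],
            n_frames=n_frames, seed=seed, temperature_K=temperature_K)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return generate_mixture(spec)


def _add_ligand(ensemble: Ensemble, seed: int) -> Ensemble:
    """Attach the three-ring ligand to every frame at seeded stacking
    geometries on the C-terminal tyrosine ring of chain A: a mixture of
    parallel, perpendicular and unstacked placements."""
    rng = np.random.default_rng(seed)
    target = None
    frames = []
    top_with = None
    for frame in ensemble.frames:
        lig = egcg_like_ligand(torsion_12_deg=float(rng.uniform(40, 140)),
                               torsion_23_deg=float(rng.uniform(20, 160)))
        span = frame.coords.max(axis=0) - frame.coords.min(axis=0)
        sys_conf, sys_top = attach_ligand(
            (frame, ensemble.topology), lig,
            translation=frame.coords.mean(axis=0) + span + 3.0)
        if target is None:
            names = [n for n in sys_top.ring_groups()
                     if sys_top.atoms[sys_top.ring_groups()[n][0]].atom_class
                     == "side_chain" and n.startswith("A")]
            target = sorted(names)[-1]  # highest-numbered chain-A aromatic ring
        mode = rng.choice(3, p=[0.4, 0.4, 0.2])
        if mode == 0:
            d, a = float(rng.normal(0.42, 0.02)), float(rng.uniform(0, 15))
        elif mode == 1:
            d, a = float(rng.normal(0.60, 0.03)), float(rng.uniform(80, 90))
        else:
            d, a = float(rng.uniform(0.9, 1.4)), float(rng.uniform(0, 90))
        d = min(max(d, 0.35), 1.5)
        placed = None
        for attempt in range(20):
            try:
                placed = place_ligand_ring((sys_conf, sys_top), "ring1", target,
                                           d, a, seed=int(rng.integers(2 ** 31)))
                break
            except ValueError:
                d += 0.02
        if placed is None:
            placed = sys_conf
        placed.frame_index = frame.frame_index
        frames.append(placed)
        top_with = sys_top
    return Ensemble(top_with, frames, weights=ensemble.weights,
                    temperature_K=ensemble.temperature_K)


def build_preset(name: str, n_frames: int, seed: int,
                 temperature_K: float = 310.0) -> tuple[Ensemble, np.ndarray]:
    """Construct a named synthetic preset ensemble + ground-truth labels."""
    ens, labels = _preset_base(name, n_frames, seed, temperature_K)
    if name.endswith("+ligand"):
        ens = _add_ligand(ens, seed + 1)
    return ens, labels


# ---------------------------------------------------------------------------
# table helpers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _matrix_df(matrix: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(matrix)
    df.columns = [str(c + 1) for c in df.columns]
    df.insert(0, "residue", np.arange(1, matrix.shape[0] + 1))
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# the full analysis
# ---------------------------------------------------------------------------

def run_full_analysis(config: AnalysisConfig,
                      ensemble: Ensemble | None = None) -> Path:
    """Run every analysis stage and write the output table set.

    ``ensemble`` may be supplied directly (e.g. from a generator); when
    omitted it is built from the config's preset or input files.  Returns
    the output directory; a ``manifest.json`` lists all outputs with
    SHA-256 checksums.  Any stage failure raises with the stage name.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "analysis.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: list[Path] = []
    stage = "setup"
    try:
        logger.info("config: %s", json.dumps(asdict(config), sort_keys=True))
        if ensemble is None:
            if config.preset is not None:
                stage = "preset"
                ensemble, _labels = build_preset(config.preset, config.n_frames,
                                                 config.seed, config.temperature_K)
            else:
                stage = "read_input"
                from .io import read_multi_model_pdb, read_topology
                top = read_topology(config.topology)
                ensemble = read_multi_model_pdb(config.input_pdb, top,
                                                config.temperature_K)
        top = ensemble.topology
        has_ligand = len(top.select(atom_class="ligand")) > 0
        logger.info("ensemble: %d frames, %d atoms, ligand=%s",
                    ensemble.n_frames, top.n_atoms, has_ligand)

        # -- secondary structure ---------------------------------------
        stage = "secondary_structure"
        assign = secstruct.assign_ss(ensemble)
        prof = secstruct.ss_profile(assign, ensemble.weights)
        _write_tsv(pd.DataFrame({
            "class": secstruct.COLLAPSED_CLASSES,
            "probability": prof.ensemble_mean}), outdir / "ss_summary.tsv")
        outputs.append(outdir / "ss_summary.tsv")
        rows = []
        for k, g in enumerate(prof.res_global):
            res = top.residues[g]
            for ci, cname in enumerate(secstruct.COLLAPSED_CLASSES):
                rows.append({"chain": top.chains[int(assign.res_chain[k])].chain_id,
                             "residue": res.index, "name": res.name,
                             "class": cname,
                             "probability": prof.per_residue[k, ci]})
        _write_tsv(pd.DataFrame(rows), outdir / "ss_profile.tsv")
        outputs.append(outdir / "ss_profile.tsv")
        logger.info("ss: class means %s",
                    np.array2string(prof.ensemble_mean, precision=4))

        stage = "strand_lengths"
        pdf = secstruct.strand_length_pdf(assign)
        _write_tsv(pd.DataFrame(
            {"length": list(pdf.probabilities),
             "probability": list(pdf.probabilities.values())}),
            outdir / "strand_length.tsv")
        outputs.append(outdir / "strand_length.tsv")

        # -- clustering -------------------------------------------------
        stage = "clustering"
        if top.homodimer:
            M = clustering.rmsd_matrix(ensemble)
            result = clustering.daura_cluster(M, config.cluster_cutoff_nm)
            k = min(config.top_k, result.n_clusters)
            rows, centers = clustering.cluster_summary(result, ensemble, k)
            _write_tsv(pd.DataFrame(rows), outdir / "clusters.tsv")
            outputs.append(outdir / "clusters.tsv")
            write_multi_model_pdb(centers, outdir / "cluster_centers.pdb")
            outputs.append(outdir / "cluster_centers.pdb")
            logger.info("clustering: %d clusters, top population %.3f",
                        result.n_clusters, result.populations[0])

            # cluster-1 detail: SS profile + inter-chain interface map
            stage = "cluster1_detail"
            members = result.clusters[0][1]
            sub = ensemble.subset(members)
            a1 = secstruct.assign_ss(sub)
            p1 = secstruct.ss_profile(a1, sub.weights)
            rows = []
            for kk, g in enumerate(p1.res_global):
                res = top.residues[g]
                for ci, cname in enumerate(secstruct.COLLAPSED_CLASSES):
                    rows.append({"chain": top.chains[int(a1.res_chain[kk])].chain_id,
                                 "residue": res.index, "class": cname,
                                 "probability": p1.per_residue[kk, ci]})
            _write_tsv(pd.DataFrame(rows), outdir / "cluster1_ss_profile.tsv")
            outputs.append(outdir / "cluster1_ss_profile.tsv")
            cm1 = interactions.contact_probability(
                sub, "MC-MC", "inter", config.contact_cutoff_nm)
            _write_tsv(_matrix_df(cm1.matrix), outdir / "cluster1_contact_mcmc_inter.tsv")
            outputs.append(outdir / "cluster1_contact_mcmc_inter.tsv")

            # CCS of cluster-1 centre structure
            stage = "ccs"
            res_ccs = ccsmod.ccs_projection(
                ensemble.frames[result.clusters[0][0]], top.elements(),
                seed=config.seed, n_orientations=config.ccs_n_orientations,
                n_points=config.ccs_n_points)
            _write_tsv(pd.DataFrame([{
                "frame": result.clusters[0][0], "ccs_A2": res_ccs.ccs_A2,
                "se_A2": res_ccs.se_A2}]), outdir / "ccs_cluster1.tsv")
            outputs.append(outdir / "ccs_cluster1.tsv")
            logger.info("ccs: cluster-1 centre %.1f +/- %.1f A^2",
                        res_ccs.ccs_A2, res_ccs.se_A2)

        # -- free-energy surface ---------------------------------------
        stage = "free_energy_surface"
        rg = stats.rg_series(ensemble, top.select(atom_class=("main_chain",
                                                              "side_chain")))
        hb = interactions.hbond_count(ensemble).astype(float)
        x_edges = np.arange(rg.min() - 1e-9,
                            rg.max() + config.rg_bin_width_nm, config.rg_bin_width_nm)
        y_edges = np.arange(hb.min() - 0.5, hb.max() + config.hbond_bin_width + 0.5,
                            config.hbond_bin_width)
        if len(x_edges) < 2:
            x_edges = np.array([rg.min() - 0.01, rg.min() + 0.01])
        grid = stats.fes2d(np.column_stack([rg, hb]), bins=(x_edges, y_edges),
                           temperature_K=ensemble.temperature_K,
                           weights=ensemble.weights, x_name="Rg_nm",
                           y_name="hbond_count")
        rows = []
        for i, xc in enumerate(grid.x_centers):
            for j, yc in enumerate(grid.y_centers):
                rows.append({"Rg_nm": xc, "hbonds": yc,
                             "G_kcal_mol": ("masked" if grid.G.mask[i, j]
                                            else float(grid.G[i, j]))})
        _write_tsv(pd.DataFrame(rows), outdir / "fes_rg_hbonds.tsv")
        outputs.append(outdir / "fes_rg_hbonds.tsv")
        basins = stats.find_basins(grid, depth_threshold=0.2)
        _write_tsv(pd.DataFrame(basins, columns=["Rg_nm", "hbonds", "G_kcal_mol"]),
                   outdir / "basins.tsv")
        outputs.append(outdir / "basins.tsv")

        # -- contact maps -----------------------------------------------
        stage = "contact_maps"
        n_pep = len(top.peptide_chain_indices())
        for mode in ("MC-MC", "SC-SC"):
            tag = mode.replace("-", "").lower()
            if n_pep >= 2:
                cm = interactions.contact_probability(
                    ensemble, mode, "inter", config.contact_cutoff_nm)
                _write_tsv(_matrix_df(cm.matrix), outdir / f"contact_{tag}_inter.tsv")
                outputs.append(outdir / f"contact_{tag}_inter.tsv")
            cm = interactions.contact_probability(
                ensemble, mode, "intra", config.contact_cutoff_nm)
            _write_tsv(_matrix_df(cm.matrix), outdir / f"contact_{tag}_intra.tsv")
            outputs.append(outdir / f"contact_{tag}_intra.tsv")

        # -- ligand analyses --------------------------------------------
        if has_ligand:
            stage = "ligand_contacts"
            per_res, per_ring = interactions.ligand_residue_contacts(
                ensemble, config.contact_cutoff_nm)
            pep_res = np.concatenate([top.chain_residue_indices(c)
                                      for c in top.peptide_chain_indices()])
            _write_tsv(pd.DataFrame({
                "chain": [top.chains[int(top.residue_chain[g])].chain_id
                          for g in pep_res],
                "residue": [top.residues[g].index for g in pep_res],
                "name": [top.residues[g].name for g in pep_res],
                "contact_probability": per_res}),
                outdir / "ligand_residue_contacts.tsv")
            outputs.append(outdir / "ligand_residue_contacts.tsv")
            _write_tsv(pd.DataFrame(
                [{"ring": r, **v} for r, v in sorted(per_ring.items())]),
                outdir / "ligand_ring_contacts.tsv")
            outputs.append(outdir / "ligand_ring_contacts.tsv")

            stage = "stacking"
            events, summary = interactions.stacking_statistics(ensemble)
            _write_tsv(pd.DataFrame([summary]), outdir / "stacking_summary.tsv")
            outputs.append(outdir / "stacking_summary.tsv")
            samples = interactions.stacking_samples(events)
            if len(samples):
                sgrid = stats.fes2d(samples, bins=config.fes_bins,
                                    temperature_K=ensemble.temperature_K,
                                    x_name="centroid_distance_nm",
                                    y_name="plane_angle_deg")
                rows = []
                for i, xc in enumerate(sgrid.x_centers):
                    for j, yc in enumerate(sgrid.y_centers):
                        rows.append({"distance_nm": xc, "angle_deg": yc,
                                     "G_kcal_mol": ("masked" if sgrid.G.mask[i, j]
                                                    else float(sgrid.G[i, j]))})
                _write_tsv(pd.DataFrame(rows), outdir / "stacking_fes.tsv")
                outputs.append(outdir / "stacking_fes.tsv")

            stage = "ring_torsions"
            rows = []
            for pair in (("ring1", "ring2"), ("ring2", "ring3"), ("ring1", "ring3")):
                centers, dens = interactions.ring_pair_torsion_pdf(
                    ensemble, pair[0], pair[1])
                for c, d in zip(centers, dens):
                    rows.append({"pair": f"{pair[0]}-{pair[1]}",
                                 "angle_deg": c, "density": d})
            _write_tsv(pd.DataFrame(rows), outdir / "ring_torsion_pdf.tsv")
            outputs.append(outdir / "ring_torsion_pdf.tsv")

            stage = "cation_pi"
            if top.charged_groups():
                centers, dens = interactions.cation_pi_pdf(ensemble)
                _write_tsv(pd.DataFrame({"distance_nm": centers, "density": dens}),
                           outdir / "cation_pi_pdf.tsv")
                outputs.append(outdir / "cation_pi_pdf.tsv")
        else:
            logger.info("no ligand declared: ligand-dependent tables skipped")

        # -- convergence -------------------------------------------------
        stage = "convergence"
        metrics = {"rg": lambda e: stats.rg_series(
            e, e.topology.select(atom_class=("main_chain", "side_chain"))),
            "hbonds": lambda e: interactions.hbond_count(e).astype(float)}
        conv = stats.split_half_convergence(ensemble, metrics)
        _write_tsv(pd.DataFrame([{"metric": k, "jsd": v} for k, v in conv.items()]),
                   outdir / "convergence.tsv")
        outputs.append(outdir / "convergence.tsv")
        logger.info("convergence: %s", conv)

        # -- manifest ----------------------------------------------------
        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return outdir
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# condition contrast
# ---------------------------------------------------------------------------

def compare_conditions(run_without: Path | str, run_with: Path | str,
                       output_dir: Path | str) -> Path:
    """Difference tables between two completed runs (with minus without).

    Emits per-class secondary-structure deltas, contact-map difference
    matrices and strand-length PDF deltas.  Raises when the two runs were
    binned or sized differently.
    """
    a, b = Path(run_without), Path(run_with)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    sa = pd.read_csv(a / "ss_summary.tsv", sep="\t")
    sb = pd.read_csv(b / "ss_summary.tsv", sep="\t")
    if list(sa["class"]) != list(sb["class"]):
        raise ValueError("secondary-structure class sets differ between runs")
    delta = sb.copy()
    delta["probability"] = sb["probability"] - sa["probability"]
    delta = delta.rename(columns={"probability": "delta_probability"})
    _write_tsv(delta, out / "ss_summary_delta.tsv")

    for name in ("contact_mcmc_inter.tsv", "contact_mcmc_intra.tsv",
                 "contact_scsc_inter.tsv", "contact_scsc_intra.tsv"):
        fa, fb = a / name, b / name
        if not (fa.exists() and fb.exists()):
            continue
        ma = pd.read_csv(fa, sep="\t")
        mb = pd.read_csv(fb, sep="\t")
        if ma.shape != mb.shape:
            raise ValueError(f"{name}: matrix shapes differ between runs")
        d = mb.copy()
        cols = [c for c in ma.columns if c != "residue"]
        d[cols] = mb[cols] - ma[cols]
        _write_tsv(d, out / name.replace(".tsv", "_delta.tsv"))

    la = pd.read_csv(a / "strand_length.tsv", sep="\t")
    lb = pd.read_csv(b / "strand_length.tsv", sep="\t")
    lengths = sorted(set(la["length"]) | set(lb["length"]))
    da = dict(zip(la["length"], la["probability"]))
    db = dict(zip(lb["length"], lb["probability"]))
    _write_tsv(pd.DataFrame({
        "length": lengths,
        "delta_probability": [db.get(L, 0.0) - da.get(L, 0.0) for L in lengths]}),
        out / "strand_length_delta.tsv")
    return out
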