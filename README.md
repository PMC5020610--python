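# dimerscope

Conformational-ensemble analysis for small peptide homodimers, with or
without bound small-molecule ligands.

Intrinsically disordered peptides such as amylin-like sequences populate
broad conformational ensembles; dimerisation is the first step of their
aggregation, and polyphenol ligands can remodel the dimer ensemble away
from β-sheet-rich states. Characterising such an ensemble requires a
battery of coupled analyses — secondary structure, conformational
clustering, inter-chain contacts, free-energy surfaces, ring-stacking
geometry, collision cross sections — applied consistently to the same
set of frames. This package implements that battery as a reusable
library, a pipeline and a CLI, together with synthetic-ensemble
generators that provide exact ground truth for testing every stage.

## What it computes

* **Secondary structure** — a Kabsch–Sander (DSSP-style) assignment from
  backbone hydrogen-bond energies, including inter-chain bridges, with
  an 8-class assignment collapsed to 6 reporting classes (helix, sheet,
  bridge, turn, bend, coil), per-residue profiles and strand-length
  distributions.
* **Clustering** — greedy neighbour-count (Daura) clustering on
  main-chain RMSD that is invariant to the chain labelling of a
  homodimer, with cluster populations, centre structures and per-cluster
  analyses.
* **Interactions** — residue–residue contact maps (main-chain/side-chain,
  inter/intra-chain), geometric hydrogen-bond counts, ligand–residue
  contact statistics, aromatic ring stacking (parallel / T-shaped),
  cation–π distances and ligand inter-ring torsions.
* **Ensemble statistics** — radius of gyration, 2-D free-energy surfaces
  G = −RT ln P with persistence-based basin detection, split-half
  convergence diagnostics, replica-ladder utilities.
* **Collision cross section** — an orientation-averaged projection
  approximation with a deterministic union-area bound.
* **Synthetic ensembles** — seeded generators for ideal helices,
  strands, β-hairpins, random coils, two-chain assemblies, mixtures with
  known composition, and ligand rings planted at controlled stacking
  geometries.

## Quick start

Run the full analysis battery on a built-in synthetic preset:

```sh
dimerscope run --preset hairpin-dimer --n-frames 40 --seed 7 --out run_apo
dimerscope run --preset coil-dimer+ligand --n-frames 40 --seed 7 --out run_lig
dimerscope compare run_apo run_lig --out run_delta
```

`run` writes a directory of TSV tables (`ss_summary.tsv`,
`clusters.tsv`, `fes_rg_hbonds.tsv`, contact maps, ligand/stacking
tables when a ligand is present, …), the top cluster centres as a
multi-model PDB, and a `manifest.json` with SHA-256 checksums of every
output. Identical inputs and seeds reproduce the manifest byte for
byte. `compare` writes difference tables (second run minus first).

Real data enters through a multi-model PDB plus a YAML topology
declaration (chains, residues, atom classes, ring and charged groups):

```sh
dimerscope synth --preset coil-dimer --n-frames 10 --seed 0 --out ens.pdb
dimerscope run --pdb ens.pdb --topology ens.topology.yaml --out run_pdb
```

Individual analyses are available as subcommands (`ss`, `cluster`,
`contacts`, `hbonds`, `stacking`, `fes`, `ccs`); exit code 2 marks a
usage error and 3 an analysis/data error. `dimerscope config` prints a
YAML configuration with every default, which can be edited and passed
back as `dimerscope run config.yaml`.

## Worked example (Python)

```python
from dimerscope.pipeline import build_preset
from dimerscope import secstruct, cluster

ens, labels = build_preset("hairpin-dimer", n_frames=40, seed=7)
prof = secstruct.ss_profile(secstruct.assign_ss(ens), ens.weights)
print(dict(zip(secstruct.COLLAPSED_CLASSES, prof.ensemble_mean.round(3))))
result = cluster.cluster_ensemble(ens)
print(result.n_clusters, result.populations[:3].round(3))
```

prints (seed 7, 40 frames):

```
{'helix': 0.003, 'sheet': 0.36, 'bridge': 0.008, 'turn': 0.063,
 'bend': 0.137, 'coil': 0.428}
18 [0.575 0.025 0.025]
```

— the β-hairpin sub-population dominates the sheet signal and collapses
into a single majority cluster, while the coil frames scatter into
singletons.

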