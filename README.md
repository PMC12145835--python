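# allopath

Allosteric-communication analysis of protein conformational ensembles,
plus the standard trajectory descriptor battery, with synthetic fixture
generators so that every stage is testable without running MD.

The core analysis chain:

1. **Torsion extraction** — φ, ψ, χ1–χ4 time series per residue from a
   structure + ensemble (multi-model PDB natively; DCD/XTC via MDAnalysis
   when installed).
2. **Mutual information** — plug-in MI (nats) between residue torsion
   distributions on a fixed 24-bin circular histogram, aggregated per
   residue pair (max over torsion channels by default).
3. **Allosteric graph** — edges are the top 10 % of eligible pair MI values
   (ties included; short sequence separations excluded), edge weight
   `-ln(MI / MI_max)`.
4. **Pathways** — Dijkstra minimum-weight (= maximum MI-product) paths from
   configured source residues to all sinks with Cα separation > 10 Å.
5. **Pipelines** — single-linkage clustering of pathways by mean
   nearest-residue Cα proximity (7 Å), ranked by population.
6. **Hub scores** — number of pathways through each residue (endpoints
   included), exported as CSV and as a B-factor-annotated PDB.

Descriptors: Kabsch superposition, RMSD series, two-pass RMSF,
neighbor-counting (GROMOS-style) conformational clustering at an RMSD
cutoff, Cα PCA with extreme-conformation interpolation, residue–residue
contact frequencies with inclusive percentage filters, and pairwise
Coulomb + Lennard-Jones interaction energies (plain 1.2 nm truncation,
Lorentz–Berthelot combining).

## CLI

```sh
# synthetic fixtures with serialized ground truth
allopath generate torsion --residues 60 --frames 5000 \
    --relay 5,13,21,29,37,45,52,58 --coupling 0.9 --seed 7 --out fixture
allopath generate cartesian --helices 4 --length 20 --frames 50 \
    --sigma 0.2 --seed 1 --out bundle

# analyses from a YAML config (see allopath.workflow.WorkflowConfig
# for every key and its default)
allopath allostery -c config.yaml
allopath descriptors -c config.yaml
```

Minimal allostery config:

```yaml
structure: fixture/structure.pdb
torsion_table: fixture/torsions.csv   # or trajectories: [traj.pdb]
sources: ["A:6"]
receptor_chain: A
output_dir: out
```

Each run writes per-analysis CSV/JSON outputs and a `manifest.json` that
lists every emitted file with its SHA-256; reruns with identical inputs
are byte-identical.

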