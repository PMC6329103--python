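# ensdyn

Essential dynamics of multi-model structural ensembles (NMR-style PDB
entries), with companion sequence-signal and cloning utilities:

* **ensemble I/O** — multi-model PDB reading (model splitting, cross-model
  atom intersection, altloc/hydrogen handling), PDB writing, and the
  plain-text NMD (NMWiz) mode-file dialect;
* **superposition** — closed-form Kabsch rigid-body fits (reflection
  corrected), per-model RMSD, per-residue RMSF, optional iterative
  alignment onto the running mean;
* **essential dynamics** — structure-per-row conformation matrix, PCA of
  the coordinate covariance, variance fractions, conformer projections,
  per-residue mode amplitudes, and open/closed conformer classification by
  inter-domain distance (or mode projection);
* **sequence features** — simplified consensus scanners for bipartite NLS
  and leucine-rich NES motifs, feature-to-structure mapping, bundled human
  eIF2-alpha annotations (externally predicted: NLS 182–216 score 4.2, NES
  anchor 168, phosphosites S51/S158), in-silico PCR and HindIII/XbaI
  restriction digests;
* **exposure** — deterministic Shrake–Rupley SASA (golden-spiral
  quadrature), a CA-only burial proxy, and a one-sided permutation test
  for "region less exposed in closed conformers";
* **synthetic data** — fully seeded two-domain ensembles with planted
  twist/bend modes (and planted open/closed groups), motif-bearing protein
  sequences, and PCR templates with known product lengths — ground truth
  for every pipeline stage;
* **pipeline** — one-command orchestration producing a superposed PDB, an
  NMD file, a TSV report and masking tables.

## CLI

A single executable `ensdyn` with subcommands:

```bash
# principal displacement modes of a multi-model PDB
ensdyn modes --pdb 1q8k.pdb --n-modes 10 --domain-split 182 \
    --out-nmd modes.nmd --out-report report.tsv

# open/closed exposure comparison of a residue span
ensdyn masking --pdb 1q8k.pdb --span 182:216 --domain-split 182 --out mask.tsv

# sequence scanners and cloning checks
ensdyn scan-nls --fasta eif2a.fasta --cutoff 4
ensdyn scan-nes --fasta eif2a.fasta
ensdyn pcr --template cdna.fasta --fwd CGCAAGCTTCCGGGTCTAAGTTGTAGA \
    --rev CGCTCTAGACACAAAGTTAATCTTCAGC --digest HindIII,XbaI

# synthetic fixtures with ground-truth sidecars
ensdyn synth ensemble --spec spec.yaml --out fixtures/ens

# full pipeline from a YAML config
ensdyn run --config config.yaml
```

Exit codes: 0 success, 2 usage error, 1 runtime error.

## Notes

* Coordinates are in Angstrom; residue numbering is 1-based as printed in
  PDB records; sequence spans are 1-based inclusive (BED output converts
  to 0-based half-open).
* The NLS/NES scanners are deliberately simple consensus implementations
  and do not reproduce external predictors (cNLS Mapper, NetNES); use the
  bundled annotation set to carry externally predicted coordinates.
* PCA "normalization" defaults to column mean-centring; unit-variance
  column scaling is available via `scaling=unit_variance`.
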