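# refstab

Reference-gene stability validation for RT-qPCR Cq data.

`refstab` implements the standard candidate-reference-gene workflow on a
complete genes × samples table of quantification cycles (Cq):

- **Relative quantification** — per gene, `RQ = E ** (minCq − Cq)` with the
  lowest-Cq sample as reference, using assay-specific amplification bases
  `E` (2 = 100% efficiency) or a perfect-doubling `E = 2` assumption.
- **geNorm** — pairwise-ratio M values, stepwise exclusion ranking (the two
  final genes share the `1/2` tie), per-sample normalization factors and the
  pairwise-variation curve `V(n, n+1)` with the 0.15 rule-of-thumb cutoff
  for the optimal number of reference genes.
- **NormFinder-style model-based estimation** — two-way-residual variance
  estimates with contamination correction; in grouped designs, intergroup
  deviations with variance shrinkage. Rankings are the contract; absolute
  stability values differ between circulating implementations.
- **BestKeeper** — raw-Cq descriptives, >1.5-cycle SD exclusion, the
  per-sample geometric-mean index, Pearson correlation of each gene with
  the index, and both the correlation-based and SD-based rankings.
- **Comparative ΔCt** — mean SD of pairwise Cq differences (algebraically
  identical to the geNorm M value at `E = 2`).
- **Comprehensive rank** — geometric mean of the four raw-Cq method ranks,
  emulating the popular web aggregator; reported with an advisory caveat.
- **Ranking comparison** — per-gene rank change between two rankings
  (tie sets measured to their nearest member) with unchanged/minor/major
  classification and pooled summary statistics.
- **Synthetic data** — a latent log2-abundance simulator with designed
  stability structure and two study-like presets (`fs1`: 14 genes, three
  culture groups of 4/4/3; `cis`: 14 genes, six ungrouped samples), both
  with four assays whose efficiency is >10% off perfect doubling.

A central use case is quantifying how much rankings shift when assay
efficiencies are ignored (`E = 2`) versus corrected — the package ships a
transcription of a published two-dataset rank table
(`src/refstab/data/published_rankings.tsv`) whose replay reproduces the
study's headline numbers: 20/28 geNorm ranks changed (71%, 16 major) and
14/28 NormFinder ranks changed (50%, 5 major).

Note on the RQ exponent: some sources print the reciprocal form
`E ** (Cq − minCq)`. The two conventions negate the log-quantities
elementwise, which leaves every SD/variance-based stability value and every
ranking unchanged (property-tested); `refstab` uses the `≤ 1` convention.

## CLI

```sh
# simulate a study-like dataset (long-layout Cq with triplicates)
refstab simulate --preset fs1 --seed 42 --out data/fs1

# run every method in corrected and E=2 mode, write TSV report + run.log
refstab validate --cq data/fs1/cq.csv --layout long \
    --eff data/fs1/efficiency.csv --groups data/fs1/groups.csv \
    --efficiency-mode both --normfinder-mode auto --out report/

# compare two rank tables (columns: gene, rank; ties printed like 1/2)
refstab compare --a ranks_corrected.tsv --b ranks_e2.tsv

# replay the published-ranking fixture and verify its summary statistics
refstab table2-check
```

Input formats: wide Cq CSV/TSV (first column `gene`, one column per
sample), long Cq (`sample,gene,replicate,cq`; technical replicates are
averaged), efficiency table (`gene,efficiency`, base or percent via
`--efficiency-unit`), groups table (`sample,group`). Matrices must be
complete; missing cells are an error, never imputed.

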