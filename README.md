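# oncostruct

Protein-structural analysis of cancer missense mutations.

Tumor sequencing yields millions of somatic missense mutations, most of
them passengers. `oncostruct` is a Python library for asking, gene by
gene, whether a protein's observed mutations carry the two structural
signatures of cancer-driving activity:

* **Enrichment in structurally damaging mutations.** Tumor suppressors
  are typically inactivated by loss-of-function mutations that
  destabilize the protein fold.
* **Clustering in three-dimensional space.** Oncogenes are typically
  activated by gain-of-function mutations concentrated at specific
  sites, producing spatial hotspots on the structure.

The library maps mutation tables onto PDB/mmCIF structures (including
predicted models with per-residue pLDDT confidence), consumes
FoldX-style ΔΔG tables, and ranks candidate tumor-suppressor and
oncogene genes. It is intended for computational biologists working
with cancer variant datasets and protein structure collections.

## The two core statistics

**ΔΔG_rank.** For a protein with predicted stability changes ΔΔG for
all *n* possible missense substitutions, each substitution gets

```
ΔΔG_rank = (rank(|ΔΔG|) − 1) / (n − 1)
```

with average ranks for ties: 0 is the mildest possible substitution of
that protein, 1 the most destabilizing, and the mean over the complete
landscape is exactly 0.5. The gene-level statistic is the **ΔΔG_rank
difference**: mean ΔΔG_rank of observed mutations minus the mean over
possible-but-unobserved ones, tested with a two-sided two-sample
Wilcoxon (Mann-Whitney) test and Bonferroni-corrected at α/N over the N
genes tested. Positive, significant differences indicate selection for
structurally damaging mutations.

**EDC (Extent of Disease Clustering).** For every residue of a subunit,
take the Cα:Cα distance to each mutated residue other than itself and
keep the nearest, D_min. With D̄ = mean log D_min computed separately
over mutated ("disease") and unmutated residues,

```
EDC = D̄_non-disease / D̄_disease
```

EDC > 1 means mutations cluster in space; random scatter gives EDC ≈ 1.
Recurrent mutations (seen ≥ 7 times) at five or more residues are
required for a reported value, and residues of predicted models with
pLDDT < 70 are excluded from both sides of the ratio.

Supporting machinery includes solvent accessibility (Shrake–Rupley
SASA, RSA against the Tien et al. 2013 maxima, interior ≤ 0.3 <
interface < 0.5 ≤ surface), DSSP output parsing with a Cα-geometry
fallback, sequence-to-chain mapping (>90 % identity over ≥ 50
residues), chain selection by resolution then assembly size,
single-nucleotide reachability of substitutions, and a synthetic-data
generator that produces structures, landscapes and labelled mutation
cohorts for end-to-end testing.

## Worked example

```python
import numpy as np
from oncostruct import SyntheticSpec, compute_edc, generate_chain

line = np.zeros((5, 3)); line[:, 0] = 3.8 * np.arange(5)
print(compute_edc(line, {1, 2}, min_disease_residues=2).edc)
print(compute_edc(line, {1, 5}, min_disease_residues=2).edc)
```

```
1.4473802840257186
0.575479645058231
```

On a five-residue chain, mutations at two adjacent residues give
EDC ≈ 1.447 (clustered: every mutated residue has a near mutated
neighbour), while the same two mutations at opposite ends give
EDC ≈ 0.575 (anti-clustered). The `examples/` directory has one short
script per capability — rank-normalization, EDC, gene-level
enrichment, residue context, cohort recovery and the full pipeline —
each printing the numbers it computes. The pipeline is also exposed as
a small CLI:

```bash
oncostruct simulate --out bundle --n-genes 10 --seed 1
oncostruct run --out results --structures bundle/structures \
    --stability bundle/stability.csv --mutations bundle/mutations.tsv
```

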