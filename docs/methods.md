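# Methods

## Scope and model

`oncostruct` analyses protein-level missense mutation sets on protein
structures. A protein is represented by one subunit (chain) of one
selected structure; all positions are on the protein's own 1-based
residue axis, and the caller supplies one canonical protein per gene
(isoform resolution is out of scope). Two per-gene signals are derived:

1. **ΔΔG_rank difference** — selection for structurally damaging
   mutations, computed against the gene's own complete substitution
   landscape so that proteins with very different intrinsic stability
   sensitivities are comparable.
2. **EDC** — spatial clustering of (recurrent) mutations on the Cα
   trace of the subunit.

Both are intentionally simple, assumption-light statistics: the
ΔΔG_rank difference assumes all possible substitutions are equally
likely a priori (no trinucleotide-context mutational null model), and
EDC treats each mutated residue equally regardless of how many distinct
variants or samples hit it beyond the recurrence filter.

## Structure handling

Structures are read with biotite (PDB and mmCIF). Only standard
amino-acid residues enter the residue axis; hetero compounds, waters
and modified residues are dropped, and NMR-style multi-model files
contribute their first model only, mirroring the single-conformer
treatment of crystallographic and predicted models. Residues without a
Cα are retained but excluded from all distance computations.

Mapping a protein sequence onto a chain uses a global alignment with
free end gaps (match +1, mismatch −1, gap open −10, extend −0.5);
identity is computed over aligned non-gap columns. A chain is accepted
when identity exceeds 90 % over at least 50 aligned residues. When a
residue maps to several chains, the chain from the highest-resolution
structure wins, ties broken by larger assembly, then lexicographic
structure id for determinism (the last tie-break is this package's own
choice; the rest follows standard practice for redundant structure
selection). Predicted models carry pLDDT in the B-factor column;
residues with pLDDT < 70 are excluded from EDC (exactly 70 is kept),
while experimental structures use all residues.

## Solvent accessibility and secondary structure

SASA is computed by sphere sampling (Shrake–Rupley, probe 1.4 Å, 960
points per atom by default; both exposed in config) over the model's
atoms via biotite. RSA divides residue SASA by the theoretical maximum
ASA of Tien et al. (2013); the Miller (1987) scale is available as a
config alternative and the scale used is recorded in every output row.
Location classes follow the RSA bands: interior RSA ≤ 0.3, interface
0.3 < RSA < 0.5, surface RSA ≥ 0.5. Because "interface" is more
conventionally defined by burial upon complex formation, an alternative
`delta_rsa` mode calls interface where RSA(isolated chain) −
RSA(assembly) > 0 and falls back to interior/surface bands elsewhere;
the band rule is the default and the two modes are not reconciled —
they answer slightly different questions and the output records which
was used.

Secondary structure comes from classic-format DSSP output files when
supplied, collapsed 8→3 states as H/G/I → helix, E/B → strand, else
other (the full 8-state code is retained in the output). Without DSSP
output, an approximate Cα-geometry assigner is used and flagged in the
output's provenance column: five-residue windows vote helix when
d(i,i+3) < 6 Å and d(i,i+4) < 7.2 Å (ideal helix: 5.1/6.2 Å), strand
when d(i,i+3) > 9 Å and d(i,i+4) > 12 Å, other otherwise. It is a
fallback for Cα-only models, not a DSSP replacement — it has no
hydrogen-bond energies and misclassifies irregular geometry.

## Stability landscapes

FoldX-style outputs (variant token + energy per replicate line) and
generic delimited tables (`protein_id, position, ref_aa, alt_aa, ddg[,
replicate]`) are both accepted. Replicates are averaged arithmetically;
disagreement on a position's reference amino acid is a hard error. For
proteins covered by several overlapping models, ΔΔG is averaged per
variant over the models containing it, recording the per-variant model
count.

ΔΔG_rank uses absolute ΔΔG, ranked ascending with average ranks for
ties, normalized as (rank − 1)/(n − 1). Average-tie ranking is the only
scheme under which the landscape mean is exactly 0.5 for every table
(the sum of average ranks is always n(n+1)/2), which is the property
that makes 0.5 the no-selection expectation for observed mutation sets.
The background ("all possible") set is whatever the stability table
contains; when restriction to single-nucleotide-reachable substitutions
is requested without a coding sequence, reachability is computed
codon-agnostically (union over all codons of the reference amino acid)
and flagged. Observed mutations missing from the landscape are dropped
from stability analyses and counted in the coverage report.

## EDC

For each kept residue, D_min is the distance to the nearest kept
mutated residue other than itself; D̄ is the mean of log D_min over
mutated and unmutated residues separately, and EDC is their ratio.
Natural log is used computationally, but the ratio is base-invariant
(verified numerically in the tests). A mutated residue's D_min
excluding itself means a lone mutated residue would be undefined; the
≥ 5 mutated-residue threshold prevents that case, and proteins below
the threshold are skipped with a logged reason rather than scored.
Zero distances (duplicate coordinates) raise an error to surface data
problems instead of being clamped. Distances never cross subunits:
EDC is computed within the selected chain.

The recurrent variant of the analysis first keeps mutations seen at
least 7 times (inclusive), collapses them to distinct residues, then
applies the same computation.

## Statistics

The two-sample Wilcoxon test enumerates the exact null distribution of
U over all assignments of the pooled values (valid under ties) when the
pooled size is ≤ 16 (config-exposed; C(16,8) = 12,870 assignments), and
uses the tie-corrected normal approximation with continuity correction
above it. Two-sided p-values are twice the smaller tail, capped at 1.
Fisher's exact test reports the sample (cross-product) odds ratio —
infinite with a zero cross-product cell — alongside the exact
conditional two-sided p. Gene-level significance uses Bonferroni:
p ≤ α/N with N the number of genes actually tested per structure
source, computed from the data at hand rather than hard-coded.

Candidate ranking: the damage table keeps positive-difference genes
ordered by the most significant p across structure sources, ties broken
by |difference| then name; the clustering table orders proteins by
recurrent EDC descending. The overlap of the two top-50 lists flags
genes with both signatures (in real data these tend to be genes with
dual oncogene/TSG annotations).

## Synthetic data

The generator emulates the statistical shape of the real inputs, not
their biology:

* **Chains.** `line` and `ideal_helix` (rise/radius scaled so
  consecutive Cα spacing is exactly 3.8 Å) are analytic references; the
  default `compact_random_walk` grows a self-avoiding walk (≥ 3.5 Å
  between non-consecutive residues) with a centroid-seeking bias
  (80 % of steps take the most centripetal valid candidate of 40),
  giving globule-like compactness. Sequences are uniform over the 20
  amino acids.
* **Landscapes.** |ΔΔG| is log-normal (μ=0, σ=1 on the log scale,
  median 1 kcal/mol) with 20 % of signs flipped negative — a skewed,
  outlier-heavy distribution with the bulk under ~3 kcal/mol.
* **Cohorts.** Default 200 residues and 120 observed variants per gene;
  TSG-like genes draw 75 % of observed variants from above the 0.7
  quantile of |ΔΔG|; oncogene-like genes draw variants only at the 5 %
  of residues nearest a random center; neutral genes draw uniformly.
  Recurrence is zero-truncated geometric with mean 3, so the ≥ 7 filter
  keeps roughly the top decile of variants. Effect sizes were chosen
  once to be strong but not degenerate — label recovery is expected
  near, not at, AUC 1.0.

What passing synthetic tests does **not** show: the generator has no
mutational signature structure (no trinucleotide context), no
correlation between ΔΔG and spatial position, no ascertainment bias in
which proteins have structures, and uniform amino-acid composition.
Results on real cohorts additionally depend on those factors.

## Problem sizes and numerical choices

The test and acceptance suites run at desk scale as this package's own
verification conditions: EDC null calibration uses 1,000 uniform
mutation sets (10 of 200 residues) across 10 compact chains; clustered
detection uses 200 sets; oracle equivalence uses 100 random EDC
instances (n ≤ 60), all tie-free Wilcoxon split patterns to pooled size
8 plus 50 tied samples to size 12, and all 2×2 tables with total ≤ 12;
label recovery uses a 200-gene cohort. EDC equals its brute-force
oracle to 1e−12; rank means are exact to 1e−12; SASA convergence is
checked at the 2 % level when doubling sampling points.

Degenerate inputs are errors, not silent repairs: empty structures,
zero-margin contingency tables, sub-threshold mutation counts (skip
with reason), duplicate coordinates, inconsistent replicate references.

## Known limitations

* The ΔΔG_rank difference inherits the limitations of predicted ΔΔG
  values; individual-variant predictions can deviate widely from
  experiment even when ensemble trends are right.
* Pan-protein analysis ignores tissue specificity and per-gene
  mutational null models; both are explicitly out of scope.
* The geometric secondary-structure fallback is approximate and should
  not be used where DSSP output is obtainable.
* The CLI orchestrates single-source runs (one structure provenance at
  a time); combining experimental and predicted sources into one
  ranking is done through the library API (`rank_candidates`).
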