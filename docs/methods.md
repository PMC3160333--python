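# Methods

`c1census` re-implements, as a tested pipeline over synthetic data with
known ground truth, the computational procedures used to study C1
(one-carbon) metabolism in SAR11 (*Candidatus* Pelagibacter ubique)
marine bacteria: a metagenomic gene-frequency census by reciprocal best
hits normalised to the single-copy marker recA, ortholog
presence/absence profiling, distance-tree paralog classification, and
the physiology analytics (radiotracer kinetics, luminescence ATP
assays) used to test whether these cells oxidise C1 compounds for
energy without assimilating them ("methylovory").

## Protein similarity search

All BLASTP-shaped stages run on one primitive: optimal Smith–Waterman
local alignment under affine gap penalties, scored with BLOSUM62
(gap open 11, gap extend 1; a gap of length L costs
`open + (L-1)·extend`; the ambiguity code X scores 0 against every
residue). Alignment itself is delegated to Biopython's
`PairwiseAligner`; the test suite checks its scores against an
independent brute-force Gotoh dynamic program on random sequence pairs.
Significance uses the Karlin–Altschul form

    E = k · m · n · exp(−λ·S)

with the published gapped-BLOSUM62 constants λ = 0.267, k = 0.041,
query length m and **total database residue count n recomputed per
database**, so E-values double exactly when a database is duplicated.
No word-seeding heuristics, composition statistics or masking are
applied — every pair is aligned exactly, which is affordable at the
problem sizes used here (≲10⁴ reads per site, ≲10² database proteins)
and keeps scores strictly optimal. "Best hit" means lowest E-value,
ties broken by higher raw score, then lexicographic subject id; best
hits are therefore unique and deterministic.

## Reciprocal best-hit census and recA normalisation

Peptide reads are assigned to focal gene families in three stages with
the thresholds E ≤ 1e-5 (gene → site peptides), E ≤ 10 (peptide →
combined focal+decoy database, best match must be focal), and E ≤ 1e-5
(peptide → full proteome of the query strain, best match must be the
original query gene, not a paralog). Because the stage-3 best hit is
unique, a peptide is counted for at most one panel gene. Per-site hit
counts H_g are normalised as

    P_g = (L_recA / L_g) · (H_g / H_recA)

with lengths in base pairs (3 × protein residues; only the ratio
matters). P_g estimates per-genome copy frequency because fragment
counts scale with dosage × length and the formula divides length back
out. Sites with fewer than 5 recA hits are removed before any
cross-site summary. Summaries are box-plot five-number summaries:
type-7 (linear-interpolation) quartiles, whiskers at the most extreme
values within 1.5 IQR of the quartiles, values beyond reported as
outlier sites.

## Synthetic data model

The generators emulate the *statistical structure* of the study's real
inputs, not their sequence content.

**Reference sets.** Each gene family starts from a random ancestral
protein (default 80–120 residues; the marker family plays the recA
role). Focal strains carry copies mutated at half the ortholog
divergence (default: ~5% pairwise between strains); decoy taxa carry
copies at 60% divergence; paralog pairs add a second family member at
35% divergence present in every focal strain. Evolution is i.i.d.
point substitution to a uniformly chosen different residue — no rate
heterogeneity, no indels, no realistic substitution process. What the
model must deliver (and what the constructor enforces, rejecting
parameter sets that break it) is the divergence ordering
read-vs-source < paralog < decoy with enough margin that best-hit
assignment is resolvable. With the defaults and 60-residue fragments
the probability that a paralog-derived read out-scores its true source
is ~1e-5; the narrower spacing of 5%/25% at 30-residue fragments was
measured to flip ~3 reads per 1000, which is why the wider defaults
were chosen. Fragment length 60 reflects that environmental peptides
called from ~900-bp shotgun reads are comfortably this long; no claim
is made about the real read-length distribution.

**Metagenomes.** Reads choose a focal source strain uniformly and a
gene with probability ∝ copy_number × length, start uniformly along the
gene (clamped to whole-gene reads for short genes), and carry 5%
read-vs-gene substitutions; a configurable fraction comes from decoy
proteomes. Every read has exactly one truth record (source gene and
strain), which the tests join against the pipeline's per-peptide log.

**Tracer curves.** Cumulative oxidised/incorporated label is
`V·τ(t) + ε` with τ linear up to the saturation time (default 3 h,
sampled hourly for 8 points) and then an exponential approach to the
plateau with a deliberately sharp scale (0.01 h), emulating an
exhausted substrate pool; the killed (formalin) control has zero true
rate under the same noise. Noise is additive Gaussian (default
0.0005 nmol — "error bars smaller than the symbols"). Default true
rates are v_ox = 1.4, v_inc = 0.6 nmol·(10¹⁰ cells)⁻¹·h⁻¹ (30%
incorporated, the sugar-like regime) in vials of 4 mL at 4×10⁷
cells/mL.

**Plates.** Standard wells lie on a true line (luminescence =
slope·conc + intercept); sample wells are generated by inverting the
per-cell conversion from true zeptogram-per-cell treatment means
(defaults 48/16/160 for T/N/P, the methanol-assay pattern) with
replicate noise on the zg/cell scale, triplicate wells, 6×10⁶ cells
and 20 µL assayed per well.

What passing on these data does **not** show: robustness to indels or
alignment-length heterogeneity, to compositional bias, to non-Gaussian
counting noise, or to real taxonomic structure — the decoys are a
homogeneous 60%-divergence cloud, far simpler than NR.

## Rate estimation and fate partition

The "initial linear part" of a cumulative curve is formalised as the
longest prefix of timepoints, anchored at the first sample, whose OLS
fit reaches r² ≥ 0.95 (minimum 3 points; a perfectly fitted or flat
prefix counts as r² = 1). If no prefix qualifies the first three points
are used and the estimate is flagged. The rule is deterministic and
monotone, recovers the generating rate exactly on noiseless curves with
the default sampling design, and within a few percent at default
noise. Slopes are scaled per 10¹⁰ cells; live rates are killed-control
corrected with clamping at zero. Substrate fate is reported as
100·v_inc/(v_inc+v_ox) from the corrected rates (an endpoint-based
variant can be derived from the same curves, but the rate framing is
the default because both rates come from the same well-defined linear
window).

## ATP quantification and significance

Luminescence converts to ATP via the fitted standard line, then to mass
with the ATP molar mass 507.18 g/mol, reported as zeptograms (10⁻²¹ g)
per cell. Treatment effects are tested with a pooled-variance Student's
t-test from triplicate summary statistics (n = 3 per group). The
default alternative is one-sided (treatment > control): the scientific
question is whether a compound *stimulated* ATP production, and with
summary tables rounded to integer zeptograms the one-sided test is also
the variant that reproduces the curated panels' significance pattern
exactly (the DMSP row, 23±3 vs 16±1, sits at p ≈ 0.019 two-sided but
p ≈ 0.0093 one-sided at the printed precision). Two-sided and Welch
variants are available via arguments. Groups with both SDs zero and
equal means are degenerate and reported not significant.

## Trees and paralog classification

Distances are p-distances (mismatches over compared columns, pairwise
deletion of gap columns). Neighbor joining uses the Saitou–Nei Q
criterion; ties break on the lexicographically smallest pair of cluster
labels (each cluster labelled by its smallest leaf), making the result
a pure function of the labelled matrix — invariant to input row order,
which index-based tie-breaking is not. Negative branch-length estimates
are clamped to zero with a warning. NJ recovers topology and branch
lengths exactly from additive matrices (property-tested against random
trees and cross-checked against scikit-bio's implementation).
Bootstrap support is the percentage of column-resampled replicate trees
containing each internal bipartition; nodes below a support threshold
(default 60%) can be contracted, grandchildren absorbing the contracted
branch length. Paralog queries are classified on the unrooted topology:
among all splits, the smallest query-containing side with at least one
reference leaf decides the subgroup (equally small sides must agree,
otherwise "unknown") — a root-invariant reading of "smallest enclosing
reference-monophyletic clade".

## Ortholog profiles

Cross-proteome orthology is called by reciprocal best hits at E ≤ 1e-5
(symmetric by construction). Presence/absence matrices carry a
provenance field distinguishing RBH-derived matrices from the curated
fixture that ships with the package: the C1-metabolism gene complement
of strains HTCC1062, HTCC1002 and HTCC7211 (21 families across 6
pathway groups), in which the three glutathione-dependent formaldehyde
oxidation genes (gfa, GD-FALDH, FGH) are unique to HTCC7211. Published
multi-genome clustering pipelines (MCL over all-vs-all BLAST) are not
re-implemented; RBH is the deliberate simplification and the provenance
field records which route produced a matrix.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations for
interactive runs: metagenome recovery uses 4 sites × 5000 reads against
3 focal + 3 decoy proteomes of 12 families (≈2 million exact pairwise
alignments, about a minute), kinetics recovery uses 50 seeded
replicates, NJ consistency 20 random 4–8-taxon trees. Every stochastic
component takes an explicit seed; identical seeds give byte-identical
FASTA/TSV outputs.

## Known limitations

- E-value calibration uses fixed published λ/k rather than per-matrix
  estimation; absolute E-values are conventional, and only thresholding
  and ordering matter downstream.
- The substitution model has no indels, so synthetic family members are
  positionally aligned by construction; MSA construction is out of
  scope and aligned input is assumed for tree building.
- The taxonomy stage models "NR" as focal + decoy proteomes of equal
  size; real databases are vastly larger and more structured.
- Fate partition assumes both channels share the vial and cell count;
  isotope dilution and Michaelis–Menten kinetics are not modelled.
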