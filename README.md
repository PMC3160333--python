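# c1census

A census of C1-metabolism gene families in marine metagenomes, with the
physiology analytics used to test "methylovory" — energy production by
one-carbon oxidation without biomass assimilation — in SAR11
(*Candidatus* Pelagibacter ubique), the most abundant heterotrophic
bacteria in the ocean.

The package is aimed at microbial ecologists who want a small, fully
tested, ground-truthed implementation of four linked analyses:

1. **Gene-frequency census** — assign environmental peptide reads to
   focal-strain genes by a three-stage reciprocal best-hit (RBB)
   procedure (forward search at E ≤ 1e-5, taxonomy check at E ≤ 10,
   paralog-excluding back check at E ≤ 1e-5), then express per-site hit
   counts relative to the single-copy marker recA:

   P_g = (L_recA / L_g) · (H_g / H_recA)

   so P_g ≈ copies of gene *g* per genome in the sampled population.
   Sites with fewer than 5 recA hits are dropped.
2. **Ortholog profiles** — presence/absence of gene families across
   strain proteomes by reciprocal best hits, including the curated
   C1 gene complement of strains HTCC1062 / HTCC1002 / HTCC7211.
3. **Paralog trees** — neighbor-joining on p-distances with bootstrap
   support, low-support collapsing, and root-invariant classification
   of query paralogs among labelled reference subgroups.
4. **Physiology** — oxidation/incorporation rates from the initial
   linear part of radiotracer time courses (killed-control corrected,
   per 10¹⁰ cells) with substrate-fate partitioning, and per-cell ATP
   quantification from luminescence plates with fold-change and
   Student's-t significance calls.

Because the original environmental inputs are not shipped anywhere, a
first-class synthetic-data module generates every input with known
ground truth — proteomes with engineered ortholog/paralog/decoy
divergences, metagenomes at known gene dosages, saturating tracer
curves, luminescence plates — so every pipeline stage is tested against
the truth labels it was generated from.

## Worked example

Generate a metagenome whose site "G2" carries gene g03 at twice the
dosage of recA, run the census, and recover the planted ratio:

```python
from c1census import abundance as ab, rbb, synthetic_data as syn

ref = syn.generate_reference_set(n_focal=3, n_decoy=3,
                                 genes_per_proteome=12, paralog_pairs=1,
                                 seed=2011, gene_length_jitter=0)
site = syn.SiteSpec("G2", {"recA": 1, "g03": 2, "g01": 1, "g01b": 1},
                    decoy_fraction=0.2, n_fragments=2000, seed=2012)
reads, truth = syn.generate_metagenome(ref, [site])
counts, log = rbb.run_rbb(ref, syn.reads_by_site(reads),
                          ["recA", "g03", "g01", "g01b"])
lengths = ab.protein_lengths_bp(ref.focal_proteomes["FOC01"])
for rec in ab.abundance_table(counts, lengths):
    print(f"{rec.gene_id:5} H_g={rec.H_g:4d}  P_g={rec.P_g:.3f}")
```

```
g01   H_g= 323  P_g=0.961
g01b  H_g= 324  P_g=0.964
g03   H_g= 617  P_g=1.836
recA  H_g= 336  P_g=1.000
```

P_g for g03 comes out at 1.84 — the planted 2:1 dosage within sampling
error at 2000 reads — while the paralog trap pair (g01/g01b, 35%
diverged) lands at 1:1 with no cross-credited reads (check
`log.merge(truth, on="read_id")`). The same flow is available from the
shell: `c1census simulate refs`, `c1census rbb`, `c1census abundance`,
plus `c1census tree / kinetics / atp / profile`.

The numbered drivers under `analysis/` run the full story end to end
(simulate → census → profiles → trees → kinetics → ATP) and write
their tables under `results/`:

```bash
for s in analysis/0*.py; do python "$s"; done
```

For instance `analysis/05_tracer_kinetics.py` prints, for simulated
methanol (true oxidation rate 0.50, ~4% incorporated) and pyruvate
(true 1.40, 30% incorporated):

```
substrate        ox rate    true   inc %  true %
methanol           0.496    0.50    3.51    3.85
pyruvate           1.378    1.40   29.21   30.00
```

i.e. the estimator reads the C1-vs-sugar fate contrast straight off the
synthetic curves, and `analysis/06_atp_assay.py` reproduces the curated
ATP panels' pattern: every C1/methylated compound except formate
significantly raises cellular ATP (methanol 3.0-fold, TMAO 2.4-fold),
and among alcohols only the short-chain primary ones (ethanol,
1-propanol) do.

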