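"""Generate every synthetic input the downstream analyses consume.

Writes reference proteomes (3 focal SAR11-like strains, 3 decoy taxa, one
paralog pair as a best-hit trap), a 6-site synthetic metagenome with known
per-site gene dosages, tracer time-course pairs for four substrates, and a
noiseless + noisy ATP plate.  Everything is seeded, so re-running
reproduces the files byte for byte.
"""

from pathlib import Path

from c1census import records
from c1census import synthetic_data as syn

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 2011

# --- reference proteomes ---------------------------------------------------
ref = syn.generate_reference_set(n_focal=3, n_decoy=3, genes_per_proteome=12,
                                 paralog_pairs=1, seed=SEED,
                                 gene_length_mean=80, gene_length_jitter=0)
records.write_protein_fasta(ref.all_records(), OUT / "reference_proteomes.fasta")
print(f"reference set: {len(ref.focal_proteomes)} focal strains, "
      f"{len(ref.decoy_proteomes)} decoy taxa, paralog pair {sorted(ref.paralog_groups[0])}")

# --- metagenome: dosage gradient + two low-coverage sites -------------------
dosages = [("G1", 1, 1), ("G2", 1, 2), ("G3", 2, 1), ("G4", 4, 1)]
sites = [
    syn.SiteSpec(site_id, {"recA": c_r, "g03": c_g, "g01": 1, "g01b": 1},
                 decoy_fraction=0.2, n_fragments=2000, seed=SEED + i)
    for i, (site_id, c_r, c_g) in enumerate(dosages)
]
# sparse sites that should fall to the marker-depth filter downstream
sites += [
    syn.SiteSpec("SPARSE1", {"recA": 1, "g03": 1}, n_fragments=8, seed=SEED + 90),
    syn.SiteSpec("SPARSE2", {"recA": 1, "g03": 2}, n_fragments=6, seed=SEED + 91),
]
reads, truth = syn.generate_metagenome(ref, sites)
records.write_reads_fasta(reads, OUT / "metagenome_reads.fasta")
records.write_truth_table(reads, OUT / "metagenome_truth.tsv")
print(f"metagenome: {len(reads)} peptide reads across {len(sites)} sites "
      f"(true g03:recA dosage ratios 1, 2, 0.5, 0.25)")

# --- tracer time courses ----------------------------------------------------
substrates = {
    # v_ox, v_inc (nmol per 1e10 cells per hour): C1 compounds barely
    # incorporate; sugars/organic acids assimilate ~30%
    "methanol": (0.50, 0.02),
    "tma": (3.82, 0.10),
    "formaldehyde": (0.01, 0.0003),
    "pyruvate": (1.40, 0.60),
}
for i, (name, (v_ox, v_inc)) in enumerate(substrates.items()):
    p = syn.TracerParams(v_ox=v_ox, v_inc=v_inc, seed=SEED + 10 + i,
                         noise_sd=0.0005 if v_ox > 0.1 else 0.000005)
    live, killed = syn.generate_tracer_timecourse(p)
    syn.timecourse_frame(live, killed).to_csv(OUT / f"tracer_{name}.tsv",
                                              sep="\t", index=False)
print(f"tracer: live/killed pairs for {', '.join(substrates)}")

# --- ATP plate ---------------------------------------------------------------
plate = syn.generate_atp_plate(syn.PlateParams(seed=SEED + 40, replicate_sd=2.0))
plate.data.to_csv(OUT / "atp_plate.tsv", sep="\t", index=False)
print("ATP plate: 5 standards + T/N/P triplicates (true 48/16/160 zg per cell)")
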