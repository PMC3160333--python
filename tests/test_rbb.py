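"""Three-stage reciprocal best-hit assignment, verified against truth labels."""

import numpy as np
import pytest

from c1census import homology, rbb
from c1census import synthetic_data as syn
from c1census.records import DECOY, FOCAL, PeptideRead, ProteinRecord

CFG = rbb.RbbConfig()


def _verbatim_read(ref, strain, gene, start=5, length=30, read_id="pep1",
                   site="S"):
    rec = ref.gene(strain, gene)
    return PeptideRead(read_id=read_id, site_id=site,
                       seq=rec.seq[start:start + length])


class TestForwardSearch:
    def test_verbatim_peptide_retained(self, small_reference):
        query = small_reference.gene("FOC01", "recA")
        pep = _verbatim_read(small_reference, "FOC01", "recA")
        filler = [PeptideRead(f"f{i}", "S", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
                  for i in range(5)]
        kept = rbb.forward_search(query, [pep] + filler, CFG)
        assert pep in kept

    def test_unrelated_random_peptide_excluded(self, small_reference):
        """The best chance local score of a random peptide cannot reach
        E <= 1e-5 at this database size; checked by direct computation."""
        rng = np.random.default_rng(42)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        random_pep = PeptideRead("rand", "S", "".join(rng.choice(aas, 30)))
        query = small_reference.gene("FOC01", "recA")
        pool = [random_pep] + [
            PeptideRead(f"f{i}", "S", "".join(rng.choice(aas, 30)))
            for i in range(20)
        ]
        n_residues = sum(len(p) for p in pool)
        score = homology.raw_score(query.seq, random_pep.seq)
        assert homology.evalue(score, len(query.seq), n_residues) > 1e-5
        kept = rbb.forward_search(query, pool, CFG)
        assert random_pep not in kept

    def test_empty_peptide_set_gives_empty_list(self, small_reference):
        query = small_reference.gene("FOC01", "recA")
        assert rbb.forward_search(query, [], CFG) == []


class TestTaxonomyCheck:
    def test_truth_labels_decide_focal_vs_decoy(self, small_reference):
        site = syn.SiteSpec("TX", {"recA": 1, "g02": 1}, decoy_fraction=0.4,
                            n_fragments=60, seed=31)
        reads, truth = syn.generate_metagenome(small_reference, [site])
        labels = dict(zip(truth["read_id"], truth["source_strain"]))
        nr = small_reference.all_records()
        for read in reads:
            expected = labels[read.read_id].startswith("FOC")
            assert rbb.taxonomy_check(read, nr, CFG) == expected

    def test_no_hit_at_all_is_false_not_error(self):
        nr = [ProteinRecord("x", "DEC01", DECOY, "WWWWWWWWWW")]
        pep = PeptideRead("p", "S", "CCCCCCCCCCCCC")
        assert rbb.taxonomy_check(pep, nr, CFG) is False

    def test_engineered_tie_resolved_deterministically(self):
        """A peptide exactly equidistant from a focal and a decoy copy is
        decided by the tie rule (lexicographic subject id), not at random."""
        seq = "MKVLAWWFAEMKVLAWWFAEMKVLAWWFAE"
        nr = [ProteinRecord("geneA", "FOC01", FOCAL, seq),
              ProteinRecord("geneA", "DEC01", DECOY, seq)]
        pep = PeptideRead("p", "S", seq[:20])
        # "geneA|DEC01" < "geneA|FOC01", so the decoy wins the tie
        assert rbb.taxonomy_check(pep, nr, CFG) is False
        assert rbb.taxonomy_check(pep, list(reversed(nr)), CFG) is False


class TestBackCheck:
    def test_read_from_gene_without_paralogs_passes(self, small_reference):
        pep = _verbatim_read(small_reference, "FOC01", "g04")
        proteome = small_reference.focal_proteomes["FOC01"]
        assert rbb.back_check(pep, "g04", proteome, CFG) is True

    def test_paralog_read_assigned_to_paralog_not_query(self, small_reference):
        """A read truly from paralog g01b must fail the back check for g01
        (and pass it for g01b): paralogs are never cross-credited."""
        pep = _verbatim_read(small_reference, "FOC01", "g01b")
        proteome = small_reference.focal_proteomes["FOC01"]
        assert rbb.back_check(pep, "g01", proteome, CFG) is False
        assert rbb.back_check(pep, "g01b", proteome, CFG) is True

    def test_read_without_focal_hit_fails(self, small_reference):
        pep = PeptideRead("p", "S", "CCCCCCCCCCCCCCCCCCCC")
        proteome = small_reference.focal_proteomes["FOC01"]
        assert rbb.back_check(pep, "g04", proteome, CFG) is False

    def test_query_absent_from_proteome_is_error(self, small_reference):
        pep = _verbatim_read(small_reference, "FOC01", "g04")
        with pytest.raises(ValueError, match="absent"):
            rbb.back_check(pep, "nope", small_reference.focal_proteomes["FOC01"], CFG)


class TestRunRbb:
    def test_dosage_ratio_recovered(self, small_reference):
        """2:1 dosage at equal gene lengths gives H_g/H_recA near 2."""
        site = syn.SiteSpec("RR", {"recA": 1, "g03": 2}, n_fragments=2500,
                            seed=77)
        reads, _ = syn.generate_metagenome(small_reference, [site])
        counts, _ = rbb.run_rbb(small_reference, syn.reads_by_site(reads),
                                ["recA", "g03"])
        h = counts["RR"]
        assert h["g03"] / h["recA"] == pytest.approx(2.0, rel=0.10)

    def test_marker_only_panel_counts_only_marker(self, small_reference):
        site = syn.SiteSpec("MO", {"recA": 1, "g03": 1}, n_fragments=100, seed=5)
        reads, _ = syn.generate_metagenome(small_reference, [site])
        counts, _ = rbb.run_rbb(small_reference, syn.reads_by_site(reads), ["recA"])
        assert set(counts["MO"]) == {"recA"}

    def test_all_decoy_reads_give_zero_counts(self, small_reference):
        site = syn.SiteSpec("AD", {}, decoy_fraction=0.5, n_fragments=200, seed=6)
        reads, truth = syn.generate_metagenome(small_reference, [site])
        assert truth["source_strain"].str.startswith("DEC").all()
        counts, _ = rbb.run_rbb(small_reference, syn.reads_by_site(reads),
                                ["recA", "g03"])
        assert counts["AD"] == {"recA": 0, "g03": 0}

    def test_removing_decoy_reads_leaves_counts_unchanged(self, small_reference):
        site = syn.SiteSpec("DR", {"recA": 1, "g03": 1}, decoy_fraction=0.3,
                            n_fragments=600, seed=15)
        reads, truth = syn.generate_metagenome(small_reference, [site])
        focal_ids = set(truth.loc[truth["source_strain"].str.startswith("FOC"),
                                  "read_id"])
        with_decoys, _ = rbb.run_rbb(small_reference, syn.reads_by_site(reads),
                                     ["recA", "g03"])
        focal_only = [r for r in reads if r.read_id in focal_ids]
        without, _ = rbb.run_rbb(small_reference, syn.reads_by_site(focal_only),
                                 ["recA", "g03"])
        assert with_decoys["DR"] == without["DR"]

    def test_counted_reads_match_truth_and_paralogs_never_miscredited(
            self, small_reference):
        site = syn.SiteSpec("PT", {"recA": 1, "g01": 1, "g01b": 1},
                            decoy_fraction=0.2, n_fragments=900, seed=23)
        reads, truth = syn.generate_metagenome(small_reference, [site])
        counts, log = rbb.run_rbb(small_reference, syn.reads_by_site(reads),
                                  ["recA", "g01", "g01b"])
        merged = log.merge(truth, on="read_id")
        counted = merged[merged["counted_gene"].notna()]
        assert len(counted) > 0
        precision = (counted["counted_gene"] == counted["source_gene"]).mean()
        assert precision >= 0.95
        # paralog-trap reads must never be credited to the wrong paralog
        paralogs = counted[counted["source_gene"].isin(["g01", "g01b"])]
        assert (paralogs["counted_gene"] == paralogs["source_gene"]).all()

    def test_peptide_counted_for_at_most_one_gene(self, small_reference):
        site = syn.SiteSpec("U1", {"recA": 1, "g01": 1, "g01b": 1},
                            n_fragments=300, seed=29)
        reads, _ = syn.generate_metagenome(small_reference, [site])
        _, log = rbb.run_rbb(small_reference, syn.reads_by_site(reads),
                             ["recA", "g01", "g01b"])
        assert log["read_id"].is_unique  # one verdict per peptide

    def test_missing_panel_gene_is_error(self, small_reference):
        with pytest.raises(ValueError, match="absent"):
            rbb.run_rbb(small_reference, {}, ["recA", "nope"])

    def test_marker_must_be_in_panel(self, small_reference):
        with pytest.raises(ValueError, match="marker"):
            rbb.run_rbb(small_reference, {}, ["g03"])


def test_counts_frame_round_trip():
    counts = {"S1": {"recA": 7, "g01": 3}, "S2": {"recA": 0, "g01": 1}}
    frame = rbb.counts_frame(counts)
    assert rbb.counts_from_frame(frame) == counts
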