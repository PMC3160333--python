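"""Three-stage reciprocal best-hit assignment of peptides to focal genes.

Stage 1 (forward): each panel gene is searched against a site's peptide
pool; peptides hitting at E <= 1e-5 become candidates for that gene.

Stage 2 (taxonomy): each candidate peptide is searched against the combined
focal + decoy protein database (the "NR" role) at a permissive E <= 10; the
peptide survives only if its best match belongs to a focal strain.

Stage 3 (back check): the peptide is searched against the full proteome of
the strain owning the query gene at E <= 1e-5; it is credited to the query
gene only if that gene — not a paralog — is the best match.  Because a best
hit is unique, a peptide is counted for at most one panel gene.

The per-site result is the hit-count table H_g feeding recA normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from c1census import homology
from c1census.homology import DEFAULT_SCHEME, ScoringScheme
from c1census.records import FOCAL, PeptideRead, ProteinRecord
from c1census.synthetic_data import ReferenceSet

#: site_id -> gene_id -> number of peptides passing all three stages
HitCounts = dict[str, dict[str, int]]


@dataclass(frozen=True)
class RbbConfig:
    forward_evalue: float = 1e-5
    taxonomy_evalue: float = 10.0
    back_evalue: float = 1e-5
    focal_strain_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if min(self.forward_evalue, self.taxonomy_evalue, self.back_evalue) <= 0:
            raise ValueError("E-value thresholds must be positive")


def forward_search(query_gene: ProteinRecord, peptides: list[PeptideRead],
                   cfg: RbbConfig = RbbConfig(),
                   scheme: ScoringScheme = DEFAULT_SCHEME) -> list[PeptideRead]:
    """Peptides hit by the gene query at E <= forward threshold.

    The database for the E-value is the site's peptide pool itself.
    """
    if not peptides:
        return []
    hits = homology.search(query_gene, [(p.read_id, p.seq) for p in peptides],
                           scheme, cfg.forward_evalue)
    keep = {h.subject_id for h in hits}
    return [p for p in peptides if p.read_id in keep]


def taxonomy_check(peptide: PeptideRead, nr_db: list[ProteinRecord],
                   cfg: RbbConfig = RbbConfig(),
                   scheme: ScoringScheme = DEFAULT_SCHEME) -> bool:
    """True iff the peptide's best match in the combined database is focal.

    No hit at all under the permissive threshold simply fails the check.
    """
    best = homology.best_hit((peptide.read_id, peptide.seq), nr_db, scheme,
                             cfg.taxonomy_evalue)
    if best is None:
        return False
    taxon = {r.full_id: r.taxon for r in nr_db}[best.subject_id]
    return taxon == FOCAL


def back_check(peptide: PeptideRead, original_query: str,
               focal_proteome: list[ProteinRecord],
               cfg: RbbConfig = RbbConfig(),
               scheme: ScoringScheme = DEFAULT_SCHEME) -> bool:
    """True iff the original query gene is the peptide's best focal match."""
    if original_query not in {r.gene_id for r in focal_proteome}:
        raise ValueError(f"query gene {original_query!r} absent from the proteome")
    best = homology.best_hit((peptide.read_id, peptide.seq),
                             [(r.gene_id, r.seq) for r in focal_proteome],
                             scheme, cfg.back_evalue)
    return best is not None and best.subject_id == original_query


def run_rbb(ref: ReferenceSet, peptides_by_site: dict[str, list[PeptideRead]],
            gene_panel: list[str], cfg: RbbConfig | None = None,
            scheme: ScoringScheme = DEFAULT_SCHEME,
            query_strain: str | None = None) -> tuple[HitCounts, pd.DataFrame]:
    """Run all three stages for every site and panel gene.

    ``query_strain`` names the focal strain whose proteins serve as queries
    and as the back-check database (defaults to the first focal strain).
    Returns per-site hit counts plus a per-peptide log of stage outcomes.
    """
    if cfg is None:
        cfg = RbbConfig(focal_strain_ids=frozenset(ref.focal_proteomes))
    if query_strain is None:
        query_strain = sorted(ref.focal_proteomes)[0]
    if ref.marker_gene_id not in gene_panel:
        raise ValueError(f"marker gene {ref.marker_gene_id!r} must be in the panel")
    proteome = ref.focal_proteomes[query_strain]
    known = {r.gene_id for r in proteome}
    missing = set(gene_panel) - known
    if missing:
        raise ValueError(f"panel gene(s) absent from reference: {sorted(missing)}")
    queries = {g: ref.gene(query_strain, g) for g in gene_panel}
    nr_db = ref.all_records()
    back_db = [(r.gene_id, r.seq) for r in proteome]

    counts: HitCounts = {}
    log_rows = []
    for site_id in sorted(peptides_by_site):
        peptides = peptides_by_site[site_id]
        counts[site_id] = {g: 0 for g in gene_panel}
        forward_pass: dict[str, set[str]] = {}
        for g in gene_panel:
            for p in forward_search(queries[g], peptides, cfg, scheme):
                forward_pass.setdefault(p.read_id, set()).add(g)
        by_id = {p.read_id: p for p in peptides}
        for read_id in sorted(forward_pass):
            peptide = by_id[read_id]
            genes = forward_pass[read_id]
            tax_ok = taxonomy_check(peptide, nr_db, cfg, scheme)
            counted = None
            back_best = None
            if tax_ok:
                best = homology.best_hit((peptide.read_id, peptide.seq), back_db,
                                         scheme, cfg.back_evalue)
                back_best = best.subject_id if best is not None else None
                if back_best in genes:
                    counted = back_best
                    counts[site_id][counted] += 1
            log_rows.append({
                "site_id": site_id, "read_id": read_id,
                "forward_genes": ",".join(sorted(genes)),
                "taxonomy_ok": tax_ok, "back_best": back_best,
                "counted_gene": counted,
            })
    log = pd.DataFrame(log_rows, columns=["site_id", "read_id", "forward_genes",
                                          "taxonomy_ok", "back_best", "counted_gene"])
    return counts, log


def counts_frame(counts: HitCounts) -> pd.DataFrame:
    rows = [{"site_id": s, "gene_id": g, "hits": h}
            for s in sorted(counts) for g, h in sorted(counts[s].items())]
    return pd.DataFrame(rows, columns=["site_id", "gene_id", "hits"])


def counts_from_frame(frame: pd.DataFrame) -> HitCounts:
    out: HitCounts = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["site_id"]), {})[str(row["gene_id"])] = int(row["hits"])
    return out
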