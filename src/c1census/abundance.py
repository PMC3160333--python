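"""recA-normalised relative gene frequencies and cross-site summaries.

A gene's per-site hit count depends on its dosage *and* its length (long
genes intercept more metagenome fragments), so raw counts are normalised to
the single-copy marker recA:

    P_g = (L_recA / L_g) * (H_g / H_recA)

where L are gene lengths in base pairs and H are RBB hit counts at the
site.  P_g estimates the per-genome copy frequency of gene g in the
sampled population: 1 means one copy per genome, below 1 a subpopulation
carries it, above 1 multiple copies.  Sites with fewer than five marker
hits carry too little signal and are dropped before summarising.

Protein lengths from FASTA are converted to base pairs as 3 x residues;
only the length *ratio* enters P_g, so the convention is cosmetic and is
recorded in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from c1census.rbb import HitCounts

LENGTH_CONVENTION = "bp = 3 * amino-acid residues (stop codon excluded)"


@dataclass(frozen=True)
class AbundanceRecord:
    site_id: str
    gene_id: str
    H_g: int
    H_recA: int
    L_g: int       # base pairs
    L_recA: int    # base pairs
    P_g: float


@dataclass(frozen=True)
class AbundanceSummary:
    """Box-plot style five-number summary of P_g across sites."""

    gene_id: str
    n_sites: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outlier_sites: tuple[str, ...]


def relative_abundance(h_g: int, h_reca: int, l_g: int, l_reca: int) -> float:
    """P_g = (L_recA/L_g) * (H_g/H_recA)."""
    if h_reca <= 0:
        raise ValueError("H_recA must be positive; filter low-marker sites first "
                         "(see filter_sites)")
    if l_g <= 0 or l_reca <= 0:
        raise ValueError("gene lengths must be positive")
    if h_g < 0:
        raise ValueError("hit counts must be non-negative")
    return (l_reca / l_g) * (h_g / h_reca)


def filter_sites(counts: HitCounts, marker_gene: str = "recA",
                 min_marker_hits: int = 5) -> HitCounts:
    """Drop sites with fewer than ``min_marker_hits`` hits to the marker."""
    kept: HitCounts = {}
    removed = []
    for site, genes in counts.items():
        if genes.get(marker_gene, 0) >= min_marker_hits:
            kept[site] = dict(genes)
        else:
            removed.append(site)
    if removed:
        warnings.warn(f"removed {len(removed)} site(s) with < {min_marker_hits} "
                      f"marker hits: {sorted(removed)}", stacklevel=2)
    if not kept:
        warnings.warn("no sites passed the marker-hit filter", stacklevel=2)
    return kept


def abundance_table(counts: HitCounts, lengths_bp: dict[str, int],
                    marker_gene: str = "recA") -> list[AbundanceRecord]:
    """P_g for every gene at every (already filtered) site.

    Sites without marker hits are skipped with a warning rather than
    producing undefined records.
    """
    records = []
    for site in sorted(counts):
        genes = counts[site]
        h_reca = genes.get(marker_gene, 0)
        if h_reca <= 0:
            warnings.warn(f"site {site!r} has no marker hits; skipped", stacklevel=2)
            continue
        for gene in sorted(genes):
            records.append(AbundanceRecord(
                site_id=site, gene_id=gene, H_g=genes[gene], H_recA=h_reca,
                L_g=lengths_bp[gene], L_recA=lengths_bp[marker_gene],
                P_g=relative_abundance(genes[gene], h_reca,
                                       lengths_bp[gene], lengths_bp[marker_gene]),
            ))
    return records


def abundance_frame(records: list[AbundanceRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records])
    frame.attrs["length_convention"] = LENGTH_CONVENTION
    return frame


def summarize(records: list[AbundanceRecord]) -> list[AbundanceSummary]:
    """Per-gene box-plot summary: type-7 quartiles, 1.5*IQR whiskers.

    Whiskers sit at the most extreme observed values within 1.5 interquartile
    ranges of the quartiles; values beyond are reported as outlier sites.
    """
    by_gene: dict[str, list[AbundanceRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    out = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        vals = np.array([r.P_g for r in recs], dtype=float)
        q25, med, q75 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        iqr = q75 - q25
        lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = tuple(r.site_id for r in recs
                         if r.P_g < lo_fence or r.P_g > hi_fence)
        out.append(AbundanceSummary(
            gene_id=gene, n_sites=len(vals), median=float(med),
            q25=float(q25), q75=float(q75),
            whisker_low=float(inside.min()), whisker_high=float(inside.max()),
            outlier_sites=outliers,
        ))
    return out


def summary_frame(summaries: list[AbundanceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = vars(s).copy()
        row["outlier_sites"] = ",".join(row["outlier_sites"])
        rows.append(row)
    return pd.DataFrame(rows)


def protein_lengths_bp(records) -> dict[str, int]:
    """Gene lengths in bp (3 x residues) keyed by gene id."""
    return {r.gene_id: 3 * len(r.seq) for r in records}
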