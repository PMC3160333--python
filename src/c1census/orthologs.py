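"""Ortholog presence/absence profiling across strain proteomes.

Orthology between two proteomes is called by reciprocal best hits (RBH):
genes a (in A) and b (in B) are orthologs iff b is a's best hit in B and a
is b's best hit in A, both at a significant E-value.  Presence/absence of
curated gene families across genomes is held in a boolean matrix whose
provenance field records whether it came from RBH calls or from a curated
fixture; a shipped fixture encodes the C1-metabolism gene complement of
the three SAR11 Ia strains (HTCC1062, HTCC1002, HTCC7211), in which only
HTCC7211 carries the three-gene glutathione-dependent formaldehyde
oxidation pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from c1census import homology
from c1census.homology import DEFAULT_SCHEME, ScoringScheme
from c1census.records import ProteinRecord

RBH = "rbh"
CURATED = "curated-fixture"


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean gene-family x genome matrix with pathway row labels."""

    data: pd.DataFrame            # index: family id, columns: genome ids, bool
    pathways: dict[str, str]      # family id -> pathway group label
    provenance: str = RBH

    def __post_init__(self):
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("family and genome labels must be unique")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.data.columns)


def _best_map(proteome_a: list[ProteinRecord], proteome_b: list[ProteinRecord],
              scheme: ScoringScheme, evalue_max: float) -> dict[str, str]:
    db = [(r.gene_id, r.seq) for r in proteome_b]
    out = {}
    for rec in proteome_a:
        best = homology.best_hit((rec.gene_id, rec.seq), db, scheme, evalue_max)
        if best is not None:
            out[rec.gene_id] = best.subject_id
    return out


def rbh_orthologs(proteome_a: list[ProteinRecord], proteome_b: list[ProteinRecord],
                  scheme: ScoringScheme = DEFAULT_SCHEME,
                  evalue_max: float = 1e-5) -> list[tuple[str, str]]:
    """Reciprocal-best-hit gene pairs between two proteomes."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    ab = _best_map(proteome_a, proteome_b, scheme, evalue_max)
    ba = _best_map(proteome_b, proteome_a, scheme, evalue_max)
    return sorted((a, b) for a, b in ab.items() if ba.get(b) == a)


def presence_matrix(families: list[tuple[str, dict[str, str | None]]],
                    genomes: list[str], pathways: dict[str, str] | None = None,
                    provenance: str = RBH) -> PresenceMatrix:
    """Build the matrix from (family id, per-genome representative) entries.

    A genome shows ``True`` for a family iff its representative is not None.
    """
    seen = set()
    rows = {}
    for fam, reps in families:
        if fam in seen:
            raise ValueError(f"duplicate family id {fam!r}")
        seen.add(fam)
        rows[fam] = [reps.get(g) is not None for g in genomes]
    data = pd.DataFrame.from_dict(rows, orient="index", columns=genomes, dtype=bool)
    return PresenceMatrix(data=data, pathways=pathways or {}, provenance=provenance)


def unique_to(matrix: PresenceMatrix, genome: str) -> list[str]:
    """Families present in ``genome`` and absent from every other genome."""
    if genome not in matrix.data.columns:
        raise KeyError(f"unknown genome {genome!r}")
    others = [g for g in matrix.genomes if g != genome]
    mask = matrix.data[genome]
    if others:
        mask = mask & ~matrix.data[others].any(axis=1)
    return list(matrix.data.index[mask])


def homolog_genome_count(matrix: PresenceMatrix, family: str) -> int:
    """Number of genomes carrying at least one member of the family."""
    if family not in matrix.data.index:
        raise KeyError(f"unknown family {family!r}")
    return int(matrix.data.loc[family].sum())


def load_c1_presence() -> PresenceMatrix:
    """Curated C1-metabolism presence/absence across the three SAR11 strains."""
    with resources.files("c1census.data").joinpath("c1_gene_presence.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    genomes = [c for c in raw.columns if c not in ("pathway", "family")]
    data = raw.set_index("family")[genomes].apply(lambda col: col.str.strip() == "+")
    pathways = dict(zip(raw["family"], raw["pathway"]))
    return PresenceMatrix(data=data, pathways=pathways, provenance=CURATED)


def matrix_from_proteomes(proteomes: dict[str, list[ProteinRecord]],
                          reference_genome: str,
                          scheme: ScoringScheme = DEFAULT_SCHEME,
                          evalue_max: float = 1e-5) -> PresenceMatrix:
    """Presence matrix of one genome's gene families across all genomes,
    using RBH against the reference genome's proteome."""
    genomes = sorted(proteomes)
    fams = [r.gene_id for r in proteomes[reference_genome]]
    reps: dict[str, dict[str, str | None]] = {f: {} for f in fams}
    for genome in genomes:
        if genome == reference_genome:
            for f in fams:
                reps[f][genome] = f
            continue
        pairs = dict(rbh_orthologs(proteomes[reference_genome], proteomes[genome],
                                   scheme, evalue_max))
        for f in fams:
            reps[f][genome] = pairs.get(f)
    return presence_matrix([(f, reps[f]) for f in fams], genomes, provenance=RBH)
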