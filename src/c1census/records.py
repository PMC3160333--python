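"""Sequence records and their plain-text (FASTA/TSV) representations.

Protein headers follow ``>geneID|strainID|taxon=<focal|decoy>`` and peptide
read headers follow ``>readID site=<site_id>`` so that round-trips through
FASTA preserve the metadata the pipeline needs.  Truth labels for synthetic
reads travel in a separate TSV, never in the FASTA itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FOCAL = "focal"
DECOY = "decoy"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its strain and taxon assignment.

    ``gene_id`` is unique within a strain; orthologous genes share the same
    id across strains, which is what lets synthetic truth tables name their
    source gene unambiguously together with ``strain_id``.
    """

    gene_id: str
    strain_id: str
    taxon: str  # FOCAL or DECOY
    seq: str

    @property
    def full_id(self) -> str:
        return f"{self.gene_id}|{self.strain_id}"

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PeptideRead:
    """An environmental peptide fragment, optionally with truth labels."""

    read_id: str
    site_id: str
    seq: str
    source_gene: str | None = None
    source_strain: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=f"{r.gene_id}|{r.strain_id}|taxon={r.taxon}", description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, strain_id, taxon_field = rec.id.split("|")
        out.append(
            ProteinRecord(
                gene_id=gene_id,
                strain_id=strain_id,
                taxon=taxon_field.removeprefix("taxon="),
                seq=str(rec.seq),
            )
        )
    return out


def write_reads_fasta(reads: Iterable[PeptideRead], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.read_id, description=f"site={r.site_id}")
        for r in reads
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_reads_fasta(path: str | Path) -> list[PeptideRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        site = ""
        for token in rec.description.split():
            if token.startswith("site="):
                site = token.removeprefix("site=")
        out.append(PeptideRead(read_id=rec.id, site_id=site, seq=str(rec.seq)))
    return out


def write_truth_table(reads: Iterable[PeptideRead], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "site_id": r.site_id,
                "source_gene": r.source_gene,
                "source_strain": r.source_strain,
            }
            for r in reads
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
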