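"""Protein local-alignment search with Karlin–Altschul E-values.

This is the BLASTP-shaped primitive behind every stage of the reciprocal
best-hit pipeline: optimal Smith–Waterman local alignment under affine gap
penalties (via Biopython's :class:`~Bio.Align.PairwiseAligner`) scored with
BLOSUM62, with significance expressed as an E-value

    E = k * m * n * exp(-lambda * S)

where ``S`` is the raw alignment score, ``m`` the query length and ``n`` the
total number of residues in the searched database.  Defaults use the
published gapped BLOSUM62 statistics (lambda = 0.267, k = 0.041) with gap
open 11 and gap extend 1; a gap of length L costs ``open + (L-1)*extend``.

No seeding heuristics, composition statistics or masking are applied: every
query/subject pair is aligned exactly, which is affordable at the problem
sizes this package targets and keeps the scores strictly optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from c1census.records import ProteinRecord

#: the 20 standard residues plus X (ambiguous, scores 0 against everything)
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_AA = STANDARD_AA | {"X"}

# published gapped BLOSUM62 / (11,1) statistics
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@lru_cache(maxsize=1)
def _blosum62_with_neutral_x():
    mat = substitution_matrices.load("BLOSUM62")
    arr = mat.copy()
    for aa in arr.alphabet:
        arr["X", aa] = 0.0
        arr[aa, "X"] = 0.0
    return arr


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus the E-value statistics they imply."""

    gap_open: int = 11
    gap_extend: int = 1
    lam: float = DEFAULT_LAMBDA
    k: float = DEFAULT_K
    matrix_name: str = "BLOSUM62"

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("E-value constants lambda and k must be positive")

    @property
    def matrix(self):
        if self.matrix_name != "BLOSUM62":
            return substitution_matrices.load(self.matrix_name)
        return _blosum62_with_neutral_x()


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentHit:
    """A scored local alignment between a query and a subject sequence.

    Spans are 0-based half-open intervals on the respective sequences; an
    empty alignment (no positive-scoring pair) has score 0 and empty spans.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    query_span: tuple[int, int] = (0, 0)
    subject_span: tuple[int, int] = (0, 0)


def validate_sequence(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - ALLOWED_AA
    if bad:
        raise ValueError(
            f"{name} contains non-amino-acid symbol(s): {', '.join(sorted(bad))}"
        )


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="local")
    al.substitution_matrix = scheme.matrix
    al.open_gap_score = -float(scheme.gap_open)
    al.extend_gap_score = -float(scheme.gap_extend)
    return al


def raw_score(q: str, s: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Optimal Smith–Waterman local score (score only; no traceback)."""
    validate_sequence(q, "query")
    validate_sequence(s, "subject")
    return int(round(_aligner(scheme).score(q, s)))


def bit_score(raw: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    return (scheme.lam * raw - math.log(scheme.k)) / math.log(2.0)


def evalue(raw: int, query_len: int, db_residues: int,
           scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """E = k * m * n * exp(-lambda * S) for the given search space."""
    return scheme.k * query_len * db_residues * math.exp(-scheme.lam * raw)


def local_align(q: str, s: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                query_id: str = "query", subject_id: str = "subject") -> AlignmentHit:
    """Align two sequences locally and report score, spans and statistics.

    The E-value here treats the single subject as the whole database
    (``n = len(s)``); :func:`search` recomputes E against the full database
    size.  A pair with no positive-scoring residue match yields the empty
    alignment with raw score 0.
    """
    validate_sequence(q, "query")
    validate_sequence(s, "subject")
    al = _aligner(scheme)
    score = int(round(al.score(q, s)))
    if score <= 0:
        return AlignmentHit(query_id, subject_id, 0, bit_score(0, scheme),
                            evalue(0, len(q), len(s), scheme))
    aln = al.align(q, s)[0]
    qblocks, sblocks = aln.aligned
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]), int(sblocks[-1][1]))
    return AlignmentHit(query_id, subject_id, score, bit_score(score, scheme),
                        evalue(score, len(q), len(s), scheme),
                        query_span=qspan, subject_span=sspan)


def search(query: ProteinRecord | tuple[str, str], db, scheme: ScoringScheme = DEFAULT_SCHEME,
           evalue_max: float = 1e-5, compute_spans: bool = False) -> list[AlignmentHit]:
    """Search one query against a protein database.

    ``query`` may be a :class:`ProteinRecord` or an ``(id, seq)`` pair and
    ``db`` an iterable of the same.  Hits with ``E <= evalue_max`` are
    returned sorted by ascending E-value, then descending raw score, then
    subject id, so the ordering (and hence "best hit") is deterministic.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    qid, qseq = _as_pair(query)
    validate_sequence(qseq, f"query {qid}")
    entries = [_as_pair(d) for d in db]
    if not entries:
        raise ValueError("database is empty")
    n_residues = sum(len(seq) for _, seq in entries)
    al = _aligner(scheme)
    hits = []
    for sid, sseq in entries:
        score = int(round(al.score(qseq, sseq)))
        if score <= 0:
            continue
        e = evalue(score, len(qseq), n_residues, scheme)
        if e <= evalue_max:
            if compute_spans:
                hit = local_align(qseq, sseq, scheme, qid, sid)
                hit = AlignmentHit(qid, sid, score, bit_score(score, scheme), e,
                                   hit.query_span, hit.subject_span)
            else:
                hit = AlignmentHit(qid, sid, score, bit_score(score, scheme), e)
            hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    return hits


def best_hit(query, db, scheme: ScoringScheme = DEFAULT_SCHEME,
             evalue_max: float = 1e-5) -> AlignmentHit | None:
    """Best database match under the deterministic ordering, or None."""
    hits = search(query, db, scheme, evalue_max)
    return hits[0] if hits else None


def hits_table(query, db, scheme: ScoringScheme = DEFAULT_SCHEME,
               evalue_max: float = 1e-5) -> pd.DataFrame:
    """Conventional 12-column tabular hit report (1-based inclusive coords)."""
    qid, qseq = _as_pair(query)
    entries = {sid: sseq for sid, sseq in (_as_pair(d) for d in db)}
    rows = []
    for h in search(query, db, scheme, evalue_max, compute_spans=True):
        ident, length, mismatches, gap_opens = _alignment_stats(
            qseq, entries[h.subject_id], scheme)
        rows.append({
            "query": qid, "subject": h.subject_id,
            "pident": round(ident, 2), "length": length,
            "mismatches": mismatches, "gapopens": gap_opens,
            "qstart": h.query_span[0] + 1, "qend": h.query_span[1],
            "sstart": h.subject_span[0] + 1, "send": h.subject_span[1],
            "evalue": h.evalue, "bitscore": round(h.bit_score, 1),
        })
    return pd.DataFrame(rows, columns=["query", "subject", "pident", "length",
                                       "mismatches", "gapopens", "qstart", "qend",
                                       "sstart", "send", "evalue", "bitscore"])


def _alignment_stats(q: str, s: str, scheme: ScoringScheme):
    aln = _aligner(scheme).align(q, s)[0]
    qb, sb = aln.aligned
    matches = mismatches = aligned_cols = 0
    for (q0, q1), (s0, s1) in zip(qb, sb):
        for off in range(q1 - q0):
            aligned_cols += 1
            if q[q0 + off] == s[s0 + off]:
                matches += 1
            else:
                mismatches += 1
    gap_opens = (len(qb) - 1)
    gap_cols = 0
    for i in range(1, len(qb)):
        gap_cols += (qb[i][0] - qb[i - 1][1]) + (sb[i][0] - sb[i - 1][1])
    length = aligned_cols + gap_cols
    pident = 100.0 * matches / length if length else 0.0
    return pident, length, mismatches, gap_opens


def _as_pair(rec) -> tuple[str, str]:
    if isinstance(rec, ProteinRecord):
        return rec.full_id, rec.seq
    rid, seq = rec
    return rid, seq
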