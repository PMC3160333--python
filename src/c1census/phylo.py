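"""Distance trees with bootstrap support for paralog classification.

Builds neighbor-joining trees (Saitou–Nei Q-criterion, deterministic ties,
negative branch lengths clamped to zero) from p-distances over a protein
alignment, attaches bootstrap support by column resampling, collapses
poorly supported nodes, and classifies query paralogs by their placement
among labelled reference sequences — the workflow behind sorting a family
of paralogous aminomethyltransferases into functional subgroups (DmdA-like,
GcvT, unknown).

Trees are :class:`Bio.Phylo.BaseTree.Tree` objects rooted at an arbitrary
trifurcation (the usual representation of an unrooted NJ tree); support
values live on internal nodes and are written as internal node labels in
Newick output.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import Phylo, SeqIO
from Bio.Phylo import BaseTree

GAP = "-"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class Msa:
    """A protein multiple sequence alignment (equal-length rows)."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("alignment labels must be unique")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must all have the same length")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "Msa":
        idx = rng.integers(0, self.n_cols, size=self.n_cols)
        return Msa(self.labels, tuple("".join(row[i] for i in idx) for row in self.rows))

    @classmethod
    def from_fasta(cls, path) -> "Msa":
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(tuple(labels), tuple(rows))


def p_distance_matrix(msa: Msa) -> np.ndarray:
    """Pairwise p-distances: mismatches / compared columns, with pairwise
    deletion of columns where either sequence has a gap."""
    if msa.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    arrs = [np.frombuffer(row.encode(), dtype="S1") for row in msa.rows]
    gaps = [a == GAP.encode() for a in arrs]
    n = msa.n_seqs
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"sequences {msa.labels[i]!r} and {msa.labels[j]!r} share no "
                    "gap-free columns")
            d[i, j] = d[j, i] = np.count_nonzero(arrs[i][ok] != arrs[j][ok]) / m
    return d


def neighbor_joining(d: np.ndarray, labels: list[str] | tuple[str, ...]) -> BaseTree.Tree:
    """Neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion break on the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf), which makes
    the result a function of the labelled matrix alone — invariant to input
    row order.  Negative branch-length estimates are clamped to zero (the
    deficit is reported as a warning).  The returned tree is rooted at the
    final trifurcation.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if n != len(labels):
        raise ValueError("labels do not match matrix size")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")

    nodes = [BaseTree.Clade(name=str(lab)) for lab in labels]
    reps = [str(lab) for lab in labels]  # cluster label = smallest leaf label
    d = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qmin = q[iu].min()
        tol = 1e-10 * (abs(qmin) + 1.0)
        ties = [(i, j) for i, j in zip(*iu) if q[i, j] <= qmin + tol]
        i, j = min(ties, key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))))
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li), _clamp(lj)
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent = BaseTree.Clade(clades=[nodes[i], nodes[j]])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
    # final trifurcation: solve the three pendant lengths exactly
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, ln in zip(nodes, (la, lb, lc)):
        node.branch_length = _clamp(ln)
    root = BaseTree.Clade(clades=list(nodes))
    return BaseTree.Tree(root=root, rooted=False)


def _clamp(length: float) -> float:
    if length < 0:
        if length < -1e-9:
            warnings.warn(f"negative branch length {length:.3g} clamped to 0",
                          stacklevel=3)
        return 0.0
    return float(length)


def nj_tree(msa: Msa) -> BaseTree.Tree:
    return neighbor_joining(p_distance_matrix(msa), msa.labels)


def bipartitions(tree: BaseTree.Tree, taxa: tuple[str, ...]) -> set[frozenset[str]]:
    """Non-trivial splits, canonicalised as the side excluding taxa[0]."""
    all_taxa = frozenset(taxa)
    anchor = sorted(all_taxa)[0]
    out = set()
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if len(side) < 2 or len(all_taxa - side) < 2:
            continue  # trivial split
        if anchor in side:
            side = all_taxa - side
        out.add(side)
    return out


def bootstrap_support(msa: Msa, n_replicates: int = 100, seed: int = 0) -> BaseTree.Tree:
    """NJ tree from the full alignment with % bootstrap support per node.

    Columns are resampled with replacement; support for each internal edge
    is the percentage of replicate trees containing the same bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(msa)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        rep = msa.resample_columns(rng)
        for split in bipartitions(nj_tree(rep), msa.labels):
            counts[split] = counts.get(split, 0) + 1
    all_taxa = frozenset(msa.labels)
    anchor = sorted(all_taxa)[0]
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if len(side) < 2 or len(all_taxa - side) < 2:
            continue
        if anchor in side:
            side = all_taxa - side
        clade.confidence = 100.0 * counts.get(side, 0) / n_replicates
    return tree


def collapse_low_support(tree: BaseTree.Tree, min_support: float = 60.0) -> BaseTree.Tree:
    """Contract internal edges whose support is below ``min_support``.

    Returns a new (possibly multifurcating) tree; the input is unchanged.
    """
    out = copy.deepcopy(tree)
    changed = True
    while changed:
        changed = False
        for parent in out.get_nonterminals():
            for child in list(parent.clades):
                if child.is_terminal() or child.confidence is None:
                    continue
                if child.confidence < min_support:
                    # contract the edge: grandchildren attach to the parent,
                    # absorbing the contracted branch length
                    for grandchild in child.clades:
                        if grandchild.branch_length is not None and \
                                child.branch_length is not None:
                            grandchild.branch_length += child.branch_length
                    idx = parent.clades.index(child)
                    parent.clades[idx:idx + 1] = child.clades
                    changed = True
    return out


def classify_paralogs(tree: BaseTree.Tree, reference_labels: dict[str, str],
                      queries: list[str] | None = None) -> dict[str, str]:
    """Assign each unlabelled leaf to a reference subgroup by tree placement.

    The tree is treated as unrooted: every edge splits the leaves in two,
    and the query's enclosing clades are the split sides containing it.
    The smallest such side holding at least one reference leaf decides —
    if its references (and, on ties, those of every equally small side)
    agree on one subgroup the query joins it, otherwise it is
    ``"unknown"``.  ``queries`` defaults to every non-reference leaf;
    naming a leaf absent from the tree is an error.
    """
    terminals = {t.name: t for t in tree.get_terminals()}
    missing = set(reference_labels) - set(terminals)
    if missing:
        raise KeyError(f"reference leaves absent from tree: {sorted(missing)}")
    if queries is None:
        queries = [n for n in terminals if n not in reference_labels]
    all_leaves = frozenset(terminals)
    sides = {all_leaves}
    for clade in tree.find_clades():
        if clade is tree.root:
            continue
        below = frozenset(t.name for t in clade.get_terminals())
        sides.add(below)
        sides.add(all_leaves - below)
    result = {}
    for name in queries:
        if name not in terminals:
            raise KeyError(f"query leaf {name!r} absent from tree")
        enclosing = [s for s in sides
                     if name in s and any(r in s for r in reference_labels)]
        smallest = min(len(s) for s in enclosing)
        groups = set()
        for s in enclosing:
            if len(s) == smallest:
                groups |= {reference_labels[r] for r in s & set(reference_labels)}
        result[name] = groups.pop() if len(groups) == 1 else UNKNOWN
    return result


def to_newick(tree: BaseTree.Tree) -> str:
    buf = StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue()


def read_newick(text: str) -> BaseTree.Tree:
    return Phylo.read(StringIO(text), "newick")
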