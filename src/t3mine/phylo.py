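"""Distance-based phylogenetics: K80 and Jukes-Cantor distances, neighbor
joining, and nonparametric bootstrap.

The workflow mirrors classic distance phylogenetics of marker genes:
pairwise evolutionary distances are computed from a pre-aligned multi-FASTA
— the Kimura two-parameter (K80) correction for nucleotide alignments
(transitions P and transversions Q corrected separately),

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

and the 20-state Jukes-Cantor correction for protein alignments
(p = mismatch fraction),

    d = -(19/20) ln(1 - 20 p / 19)

— then a neighbor-joining tree is built (Saitou-Nei Q-criterion,
deterministic tie-breaking, negative branches clamped to zero), and internal
branches receive bootstrap supports: the percentage of column-resampled
replicate trees containing each bipartition of the full-data tree.

Gap and ambiguous columns are pairwise-deleted by default (complete deletion
is available).  Distances past the model's saturation point (log argument
<= 0) raise SaturationError, or are flagged infinite inside a matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Literal

import numpy as np
from Bio import SeqIO
from skbio import TreeNode

__all__ = [
    "MSA",
    "DistanceMatrix",
    "PhyloTree",
    "SaturationError",
    "k80_distance",
    "jc_protein_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "write_newick",
    "read_newick",
]

NUCLEOTIDES = frozenset("ACGT")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class SaturationError(ValueError):
    """Observed divergence exceeds the distance model's correctable range."""


@dataclass(frozen=True)
class MSA:
    """A multiple alignment: unique taxon labels, equal-length rows, '-' gaps."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MSA":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(tuple(taxa), tuple(rows))

    def resample_columns(self, rng: np.random.Generator) -> "MSA":
        """Bootstrap replicate: columns drawn with replacement."""
        idx = rng.integers(0, self.length, size=self.length)
        return MSA(self.taxa, tuple("".join(r[i] for i in idx) for r in self.rows))


@dataclass
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        finite = self.d[np.isfinite(self.d)]
        if np.isnan(self.d).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if (np.diag(self.d) != 0).any() or (finite < 0).any():
            raise ValueError("distances must be nonnegative with zero diagonal")


@dataclass
class PhyloTree:
    """An unrooted NJ tree (held rooted at a trifurcation for serialization).

    Internal node names carry integer bootstrap supports when present; raw
    per-bipartition support fractions live in ``supports``.
    """

    tree: TreeNode
    taxa: tuple[str, ...]
    supports: dict[frozenset, float] | None = None
    n_replicates: int = 0
    skipped_replicates: int = 0
    negative_branch_deficit: float = 0.0

    def to_newick(self) -> str:
        buf = StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def bipartitions(self) -> set[frozenset]:
        return bipartitions(self.tree, self.taxa)

    def support_report(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "skipped_replicates": self.skipped_replicates,
            "bipartitions": [
                {"side": sorted(side), "support_fraction": frac}
                for side, frac in sorted(
                    (self.supports or {}).items(), key=lambda kv: sorted(kv[0])
                )
            ],
        }


def _comparable(a: str, b: str, alphabet: frozenset) -> list[tuple[str, str]]:
    return [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in alphabet and y in alphabet
    ]


def k80_distance(a: str, b: str, on_saturation: str = "raise") -> float:
    """Kimura two-parameter distance between aligned nucleotide rows.

    Gap/N/ambiguity columns are pairwise-deleted.  Raises SaturationError
    (or returns inf with on_saturation='inf') when a log argument is <= 0.
    """
    if len(a) != len(b):
        raise ValueError("aligned rows differ in length")
    pairs = _comparable(a, b, NUCLEOTIDES)
    if not pairs:
        raise ValueError("no comparable (non-gap, non-N) columns")
    n = len(pairs)
    p = sum(1 for x, y in pairs if (x, y) in TRANSITIONS) / n
    q = sum(1 for x, y in pairs if x != y and (x, y) not in TRANSITIONS) / n
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        if on_saturation == "inf":
            return math.inf
        raise SaturationError(
            f"K80 saturated: P={p:.4f}, Q={q:.4f} (log arguments {w1:.4f}, {w2:.4f})"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def jc_protein_distance(a: str, b: str, on_saturation: str = "raise") -> float:
    """20-state Jukes-Cantor distance between aligned protein rows."""
    if len(a) != len(b):
        raise ValueError("aligned rows differ in length")
    pairs = _comparable(a, b, AMINO_ACIDS)
    if not pairs:
        raise ValueError("no comparable (non-gap, non-ambiguous) columns")
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    w = 1.0 - 20.0 * p / 19.0
    if w <= 0:
        if on_saturation == "inf":
            return math.inf
        raise SaturationError(f"JC saturated: p={p:.4f} >= 19/20")
    return -(19.0 / 20.0) * math.log(w)


_DISTANCE_FUNCS = {"k80": (k80_distance, NUCLEOTIDES), "jc_protein": (jc_protein_distance, AMINO_ACIDS)}


def distance_matrix(
    msa: MSA,
    model: Literal["k80", "jc_protein"] = "k80",
    deletion: Literal["pairwise", "complete"] = "pairwise",
    on_saturation: str = "inf",
) -> DistanceMatrix:
    """All pairwise distances; saturated pairs flagged infinite (or raised)."""
    func, alphabet = _DISTANCE_FUNCS[model]
    rows = msa.rows
    if deletion == "complete":
        keep = [
            i
            for i in range(msa.length)
            if all(r[i].upper() in alphabet for r in rows)
        ]
        rows = tuple("".join(r[i] for i in keep) for r in rows)
    n = msa.n_taxa
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            dij = func(rows[i], rows[j], on_saturation=on_saturation)
            d[i, j] = d[j, i] = dij
            if math.isinf(dij):
                saturated.append((msa.taxa[i], msa.taxa[j]))
    return DistanceMatrix(msa.taxa, d, saturated)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion are broken by the lexicographically smallest
    (representative taxon) pair, the representative of a cluster being its
    smallest leaf label.  Negative branch lengths are clamped to zero and
    the total clamped deficit recorded.
    """
    dm.validate()
    if not np.isfinite(dm.d).all():
        raise ValueError("distance matrix contains infinite (saturated) entries")
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    reps: list[str] = list(dm.taxa)
    D = dm.d.astype(float).copy()
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        # R[i]+R[j] is computed once so Q stays exactly symmetric in floats
        Q = (m - 2) * D - (R[:, None] + R[None, :])
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [
            (tuple(sorted((reps[i], reps[j]))), i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if Q[i, j] == qmin
        ]
        _, i, j = min(candidates)
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to every remaining cluster
        dk = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dk[keep]])
        D = np.column_stack([D, np.append(dk[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # three-point formulas for the final trifurcation
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    root = TreeNode(children=[a, b, c])
    return PhyloTree(tree=root, taxa=dm.taxa, negative_branch_deficit=deficit)


def bipartitions(tree: TreeNode, taxa: tuple[str, ...]) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree.

    Each split is represented by the side NOT containing the lexicographically
    smallest taxon, so representations are comparable across trees.
    """
    all_taxa = frozenset(taxa)
    anchor = min(all_taxa)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(all_taxa) - 2:
            out.add(side)
    return out


def bootstrap_support(
    msa: MSA,
    n_replicates: int = 1000,
    distance: Literal["k80", "jc_protein"] = "k80",
    seed: int = 0,
    deletion: Literal["pairwise", "complete"] = "pairwise",
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap supports on internal nodes.

    Support of a bipartition = percentage of successful replicates whose NJ
    tree contains it.  A replicate with a saturated pair (or no comparable
    columns) is skipped and counted in ``skipped_replicates``.  The whole
    procedure is a deterministic function of (msa, n_replicates, seed).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    dm = distance_matrix(msa, distance, deletion, on_saturation="inf")
    if dm.saturated_pairs:
        raise SaturationError(f"saturated pairs in full alignment: {dm.saturated_pairs}")
    base = neighbor_joining(dm)
    base_splits = base.bipartitions()

    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in base_splits}
    ok = skipped = 0
    for _ in range(n_replicates):
        rep = msa.resample_columns(rng)
        try:
            rdm = distance_matrix(rep, distance, deletion, on_saturation="inf")
            if rdm.saturated_pairs:
                raise SaturationError("saturated replicate")
            rtree = neighbor_joining(rdm)
        except (SaturationError, ValueError):
            skipped += 1
            continue
        ok += 1
        rsplits = rtree.bipartitions()
        for s in base_splits:
            if s in rsplits:
                counts[s] += 1

    supports = {s: (counts[s] / ok if ok else 0.0) for s in base_splits}
    all_taxa = frozenset(msa.taxa)
    anchor = min(all_taxa)
    for node in base.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_taxa - side
        if side in supports:
            node.name = str(round(100.0 * supports[side]))
    base.supports = supports
    base.n_replicates = n_replicates
    base.skipped_replicates = skipped
    return base


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    t = TreeNode.read(str(path), format="newick")
    taxa = tuple(sorted(tip.name for tip in t.tips()))
    return PhyloTree(tree=t, taxa=taxa)


def write_support_json(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(tree.support_report(), fh, indent=2)
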