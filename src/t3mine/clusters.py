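"""T3SS component detection and gene-cluster assembly.

Components of the type III secretion apparatus are conserved enough to find
by protein local alignment: each gene product in a proteome is aligned
(Smith-Waterman, affine gaps, BLOSUM62 by default) against a reference panel
of component sequences named in the rsp/rsc/rop nomenclature (rsp =
rhizosphere-expressed secretion protein, rsc = rsp conserved, rop = effector).
Hits passing identity/coverage thresholds are chained along the genome by
single linkage (gap <= max_gap) into candidate T3SS clusters, each reported
with its span, the component roles present, and the conserved-core
components it is missing.

The packaged panel (``data/t3ss_panel.synthetic.fasta``) carries SYNTHETIC
sequences: the component names and role vocabulary are real, the residues
are generated, and the file is a swappable stand-in for a curated panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .genome import AnnotatedGenome

__all__ = [
    "PanelEntry",
    "ReferencePanel",
    "ComponentHit",
    "T3SSCluster",
    "AlignmentError",
    "CORE_COMPONENTS",
    "ROLES",
    "local_align",
    "load_panel",
    "default_panel",
    "find_components",
    "assemble_clusters",
]

# Conserved core every T3SS cluster report is checked against: the nine
# structural components plus the two cluster-resident regulators.
CORE_COMPONENTS = (
    "rscV", "rscN", "rscQAB", "rscR", "rscS", "rscT", "rscU", "rscC", "rscJ",
    "rspL", "rspR",
)

ROLES = ("regulatory", "structural-conserved", "structural-nonconserved", "effector")


class AlignmentError(ValueError):
    """A sequence contains a residue the substitution matrix cannot score."""


@dataclass(frozen=True)
class PanelEntry:
    name: str
    role: str
    sequence: str


@dataclass(frozen=True)
class ReferencePanel:
    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names in panel")
        for e in self.entries:
            if e.role not in ROLES:
                raise ValueError(f"unknown role {e.role!r} for {e.name}")

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str) -> PanelEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    percent_identity: float
    coverage: float  # fraction of the second (reference) sequence spanned
    aligned_a: str
    aligned_b: str


@dataclass(frozen=True)
class ComponentHit:
    gene_id: str
    component_name: str
    role: str
    alignment_score: float
    percent_identity: float
    query_coverage: float


@dataclass(frozen=True)
class T3SSCluster:
    contig_id: str
    member_hits: tuple[ComponentHit, ...]
    start: int
    end: int
    present_roles: tuple[str, ...]
    missing_components: tuple[str, ...]

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # First gap residue costs gap_open, each further residue gap_extend.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Affine gap costs: a gap of length L costs gap_open + (L-1)*gap_extend.
    percent_identity is identical columns over aligned columns (gap columns
    included, the BLAST convention); coverage is the fraction of ``b``
    spanned by the local alignment.
    """
    if not a or not b:
        raise AlignmentError("empty sequence")
    a, b = a.upper().rstrip("*"), b.upper().rstrip("*")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    for seq in (a, b):
        for sym in seq:
            if sym not in alphabet:
                raise AlignmentError(f"residue {sym!r} not in {matrix} alphabet")
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(0.0, 0.0, 0.0, "", "")
    aln = alignments[0]
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    pid = 100.0 * counts.identities / ncols if ncols else 0.0
    b_blocks = aln.aligned[1]
    cov = (b_blocks[-1][1] - b_blocks[0][0]) / len(b) if len(b_blocks) else 0.0
    a_txt, b_txt = _aligned_strings(a, b, aln)
    return AlignmentResult(float(aln.score), pid, cov, a_txt, b_txt)


def _aligned_strings(a: str, b: str, aln) -> tuple[str, str]:
    """Gapped alignment rows reconstructed from the aligned block indices."""
    a_blocks, b_blocks = aln.aligned
    out_a, out_b = [], []
    for k, ((a0, a1), (b0, b1)) in enumerate(zip(a_blocks, b_blocks)):
        if k:
            pa0, pa1 = a_blocks[k - 1]
            pb0, pb1 = b_blocks[k - 1]
            out_a.append(a[pa1:a0] + "-" * (b0 - pb1))
            out_b.append("-" * (a0 - pa1) + b[pb1:b0])
        out_a.append(a[a0:a1])
        out_b.append(b[b0:b1])
    return "".join(out_a), "".join(out_b)


def load_panel(path: str | Path) -> ReferencePanel:
    """Read a panel FASTA whose headers are ``name|role``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 2:
            raise ValueError(f"panel header {rec.id!r} is not 'name|role'")
        entries.append(PanelEntry(parts[0], parts[1], str(rec.seq).upper()))
    return ReferencePanel(tuple(entries))


def default_panel() -> ReferencePanel:
    """The packaged synthetic T3SS component panel."""
    with resources.as_file(
        resources.files("t3mine").joinpath("data/t3ss_panel.synthetic.fasta")
    ) as p:
        return load_panel(p)


def find_components(
    genome: AnnotatedGenome,
    panel: ReferencePanel | None = None,
    min_identity: float = 30.0,
    min_coverage: float = 0.5,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[ComponentHit]:
    """Best panel component per gene, thresholded on identity and coverage.

    One gene maps to at most one component (its highest-scoring panel entry);
    one component may legitimately hit several genes — all are reported, in
    genome order.
    """
    if panel is None:
        panel = default_panel()
    if not (0 <= min_identity <= 100) or not (0 < min_coverage <= 1):
        raise ValueError("thresholds out of range")
    hits: list[ComponentHit] = []
    order = {f.gene_id: (f.contig_id, f.start) for f in genome.cds_features}
    for f in genome.cds_features:
        protein = genome.protein_of(f.gene_id)
        if not protein:
            continue
        best: tuple[float, PanelEntry, AlignmentResult] | None = None
        for entry in panel:
            res = local_align(protein, entry.sequence, matrix, gap_open, gap_extend)
            if best is None or res.score > best[0]:
                best = (res.score, entry, res)
        if best is None:
            continue
        _, entry, res = best
        if res.percent_identity >= min_identity and res.coverage >= min_coverage:
            hits.append(
                ComponentHit(
                    gene_id=f.gene_id,
                    component_name=entry.name,
                    role=entry.role,
                    alignment_score=res.score,
                    percent_identity=res.percent_identity,
                    query_coverage=res.coverage,
                )
            )
    hits.sort(key=lambda h: order[h.gene_id])
    return hits


def assemble_clusters(
    hits: list[ComponentHit],
    genome: AnnotatedGenome,
    max_gap: int = 5000,
) -> list[T3SSCluster]:
    """Single-linkage chaining of component hits along each contig.

    Successive hits whose inter-gene gap is <= max_gap bp join the same
    cluster; intervening non-panel genes are allowed and do not break a
    chain.  Output is independent of input hit order.
    """
    coords = {h.gene_id: genome.get_cds(h.gene_id) for h in hits}
    ordered = sorted(hits, key=lambda h: (coords[h.gene_id].contig_id, coords[h.gene_id].start))
    clusters: list[T3SSCluster] = []
    run: list[ComponentHit] = []

    def flush() -> None:
        if not run:
            return
        members = tuple(run)
        feats = [coords[h.gene_id] for h in members]
        present = tuple(sorted({h.role for h in members}))
        have = {h.component_name for h in members}
        clusters.append(
            T3SSCluster(
                contig_id=feats[0].contig_id,
                member_hits=members,
                start=feats[0].start,
                end=max(f.end for f in feats),
                present_roles=present,
                missing_components=tuple(c for c in CORE_COMPONENTS if c not in have),
            )
        )
        run.clear()

    prev = None
    for h in ordered:
        f = coords[h.gene_id]
        if prev is not None and (
            f.contig_id != prev.contig_id or f.start - prev.end - 1 > max_gap
        ):
            flush()
        run.append(h)
        prev = f
    flush()
    return clusters
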