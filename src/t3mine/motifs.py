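"""Degenerate hrp-box motif scanning in promoter regions.

The hrp box is the promoter element bound by the sigma factor HrpL/RspL and
marks genes under T3SS-regulon control.  Two renderings of the consensus
circulate: the screening form ``xGGAACx[N15-16]CCACxxAG`` (the default here,
with ``x`` read as any nucleotide) and the shorter classical consensus
``GGAACC-N15/16-CCACNNA``, shipped as a named alternative.  A motif pattern
is an ordered list of fixed IUPAC blocks separated by variable-length
spacers; every (start position, spacer assignment) that matches is a distinct
hit.  A hit is tied to its downstream gene by ``gene_distance``, the number
of bases between the end of the match and the start codon; the biological
screen keeps hits with 30 <= gene_distance <= 300.

Scanning is on the coding strand of the upstream region only (promoter
elements are read directionally by the sigma factor).  ``N`` in the genome
never matches any motif symbol, including wildcard positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Union

import pandas as pd

from .genome import AnnotatedGenome, UpstreamRegion, extract_upstream

__all__ = [
    "Spacer",
    "MotifPattern",
    "HrpBoxHit",
    "HRP_BOX_SCREEN",
    "HRP_BOX_CONSENSUS",
    "PATTERNS",
    "DEFAULT_MIN_DIST",
    "DEFAULT_MAX_DIST",
    "scan_region",
    "screen_genome",
    "write_hits_tsv",
    "write_hits_bed",
]

# IUPAC nucleotide codes -> the set of concrete genome bases they accept.
# Deliberately excludes 'N' on the genome side: an ambiguous assembly base
# matches nothing.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

DEFAULT_MIN_DIST = 30
DEFAULT_MAX_DIST = 300


@dataclass(frozen=True)
class Spacer:
    """Variable-length run of arbitrary bases between fixed motif blocks."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_len <= self.max_len):
            raise ValueError(f"bad spacer range {self.min_len}..{self.max_len}")


Element = Union[str, Spacer]


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        fixed = [e for e in self.elements if isinstance(e, str)]
        if not fixed:
            raise ValueError("pattern needs at least one fixed element")
        for e in fixed:
            bad = set(e.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC symbols in {e!r}: {sorted(bad)}")

    @property
    def min_span(self) -> int:
        return sum(len(e) if isinstance(e, str) else e.min_len for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(len(e) if isinstance(e, str) else e.max_len for e in self.elements)

    def spacer_assignments(self) -> Iterator[tuple[int, ...]]:
        """All combinations of spacer lengths, in lexicographic order."""
        spacers = [e for e in self.elements if isinstance(e, Spacer)]

        def rec(i: int, acc: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
            if i == len(spacers):
                yield acc
                return
            for ln in range(spacers[i].min_len, spacers[i].max_len + 1):
                yield from rec(i + 1, acc + (ln,))

        yield from rec(0, ())


# Screening motif: x GGAAC x [N15-16] CCAC x x A G, with x = any base.
HRP_BOX_SCREEN = MotifPattern("hrp_box_screen", ("NGGAACN", Spacer(15, 16), "CCACNNAG"))
# Classical consensus: GGAACC [N15/16] CCACNNA.
HRP_BOX_CONSENSUS = MotifPattern("hrp_box_consensus", ("GGAACC", Spacer(15, 16), "CCACNNA"))

PATTERNS = {p.name: p for p in (HRP_BOX_SCREEN, HRP_BOX_CONSENSUS)}


@dataclass(frozen=True)
class HrpBoxHit:
    """One motif occurrence in an upstream region (1-based inclusive coords)."""

    gene_id: str
    match_start: int
    match_end: int
    matched_sequence: str
    spacer_len: int
    gene_distance: int


def _match_fixed(region: str, pos0: int, element: str, max_mismatches: int) -> bool:
    """Check a fixed IUPAC block against region starting at 0-based pos0."""
    mism = 0
    for j, sym in enumerate(element):
        base = region[pos0 + j]
        if base not in IUPAC[sym]:
            mism += 1
            if mism > max_mismatches:
                return False
    return True


def scan_region(
    region: UpstreamRegion,
    pattern: MotifPattern = HRP_BOX_SCREEN,
    min_dist: int = DEFAULT_MIN_DIST,
    max_dist: int = DEFAULT_MAX_DIST,
    max_mismatches_per_element: int = 0,
) -> list[HrpBoxHit]:
    """Every (start, spacer-assignment) match whose gene_distance is in range.

    Overlapping matches are all reported; only bit-identical (start, spacers)
    pairs are unique by construction.  Hits are ordered by (match_start,
    spacer lengths); the order is deterministic.
    """
    if not (0 <= min_dist <= max_dist):
        raise ValueError("need 0 <= min_dist <= max_dist")
    seq = region.sequence.upper()
    n = len(seq)
    hits: list[HrpBoxHit] = []
    for start0 in range(n):
        for spacers in pattern.spacer_assignments():
            span = pattern.min_span + sum(spacers) - sum(
                e.min_len for e in pattern.elements if isinstance(e, Spacer)
            )
            end0 = start0 + span  # exclusive
            if end0 > n:
                continue
            gene_distance = n - end0
            if not (min_dist <= gene_distance <= max_dist):
                continue
            pos = start0
            it = iter(spacers)
            ok = True
            for elem in pattern.elements:
                if isinstance(elem, Spacer):
                    pos += next(it)
                else:
                    if not _match_fixed(seq, pos, elem, max_mismatches_per_element):
                        ok = False
                        break
                    pos += len(elem)
            if ok:
                hits.append(
                    HrpBoxHit(
                        gene_id=region.gene_id,
                        match_start=start0 + 1,
                        match_end=end0,
                        matched_sequence=seq[start0:end0],
                        spacer_len=sum(spacers),
                        gene_distance=gene_distance,
                    )
                )
    return hits


def screen_genome(
    genome: AnnotatedGenome,
    pattern: MotifPattern = HRP_BOX_SCREEN,
    min_dist: int = DEFAULT_MIN_DIST,
    max_dist: int = DEFAULT_MAX_DIST,
    window: int | None = None,
    max_mismatches_per_element: int = 0,
) -> pd.DataFrame:
    """Scan the upstream window of every CDS; one row per gene with >= 1 hit.

    The window defaults to max_dist + max motif span, so a motif whose 3' end
    sits exactly max_dist from the start codon is still inside the window.
    best_hit per gene = smallest gene_distance, ties broken by smallest
    match_start.  Returns a DataFrame with genomic coordinates of the best
    hit alongside region-local ones.
    """
    if window is None:
        window = max_dist + pattern.max_span
    rows = []
    for f in genome.cds_features:
        region = extract_upstream(genome, f.gene_id, window)
        hits = scan_region(region, pattern, min_dist, max_dist, max_mismatches_per_element)
        if not hits:
            continue
        best = min(hits, key=lambda h: (h.gene_distance, h.match_start))
        g_start, g_end = _region_to_genomic(f, len(region), best.match_start, best.match_end)
        rows.append(
            {
                "gene_id": f.gene_id,
                "contig_id": f.contig_id,
                "strand": f.strand,
                "n_hits": len(hits),
                "match_start": best.match_start,
                "match_end": best.match_end,
                "genomic_start": g_start,
                "genomic_end": g_end,
                "matched_sequence": best.matched_sequence,
                "spacer_len": best.spacer_len,
                "gene_distance": best.gene_distance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "contig_id", "strand", "n_hits", "match_start", "match_end",
            "genomic_start", "genomic_end", "matched_sequence", "spacer_len",
            "gene_distance",
        ],
    )


def _region_to_genomic(cds, region_len: int, match_start: int, match_end: int) -> tuple[int, int]:
    """Map 1-based region coordinates to 1-based genomic (start <= end)."""
    if cds.strand == "+":
        origin = cds.start - region_len - 1  # genomic pos of region coord 0
        return origin + match_start, origin + match_end
    # region coord i sits at genomic cds.end + region_len - i + 1
    a = cds.end + region_len - match_end + 1
    b = cds.end + region_len - match_start + 1
    return a, b


def write_hits_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_hits_bed(table: pd.DataFrame, path: str | Path) -> None:
    """Best hits as BED6 (0-based half-open genomic intervals)."""
    with open(path, "w") as fh:
        for _, r in table.iterrows():
            fh.write(
                f"{r.contig_id}\t{r.genomic_start - 1}\t{r.genomic_end}\t"
                f"hrp_box:{r.gene_id}\t{r.n_hits}\t{r.strand}\n"
            )
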