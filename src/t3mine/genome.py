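"""Annotated-genome I/O and strand-aware promoter extraction.

A genome is a set of contigs plus CDS features with 1-based inclusive
coordinates (the GenBank/GFF3 convention; all coordinate arithmetic in this
package assumes it).  Upstream (promoter) regions are returned on the coding
strand of the downstream gene, written 5'->3' and ending immediately before
the start codon, which is what a sigma-factor binding-site scan needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CDSFeature",
    "AnnotatedGenome",
    "UpstreamRegion",
    "GenomeValidationError",
    "GenomeParseError",
    "read_genome",
    "read_genbank",
    "read_fasta_gff3",
    "write_genbank",
    "write_gff3",
    "write_fasta",
    "write_protein_fasta",
    "extract_upstream",
    "reverse_complement",
]

BACTERIAL_TABLE = 11

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GenomeValidationError(ValueError):
    """A feature violates the genome's structural invariants."""


class GenomeParseError(ValueError):
    """An input file could not be parsed under the named standard."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CDSFeature:
    """One protein-coding gene: 1-based inclusive coordinates, start <= end."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    protein: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class UpstreamRegion:
    """Promoter-side sequence of a gene, on its coding strand, 5'->3'.

    The last base of ``sequence`` is the base at genomic distance 1 from the
    start codon on the coding strand.
    """

    gene_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotatedGenome:
    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    cds_features: list[CDSFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(set(self.contigs)) != len(self.contigs):
            raise GenomeValidationError("duplicate contig ids")
        for f in self.cds_features:
            if f.contig_id not in self.contigs:
                raise GenomeValidationError(
                    f"CDS {f.gene_id!r} references unknown contig {f.contig_id!r}"
                )
            if not (1 <= f.start <= f.end <= len(self.contigs[f.contig_id])):
                raise GenomeValidationError(
                    f"CDS {f.gene_id!r} coordinates {f.start}..{f.end} outside "
                    f"contig {f.contig_id!r} (length {len(self.contigs[f.contig_id])})"
                )
            if f.strand not in ("+", "-"):
                raise GenomeValidationError(f"CDS {f.gene_id!r}: bad strand {f.strand!r}")
        ids = [f.gene_id for f in self.cds_features]
        if len(set(ids)) != len(ids):
            raise GenomeValidationError("duplicate gene ids")

    def get_cds(self, gene_id: str) -> CDSFeature:
        for f in self.cds_features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(f"no CDS with gene_id {gene_id!r}")

    def cds_nucleotides(self, gene_id: str) -> str:
        """Coding-strand nucleotide sequence of a CDS."""
        f = self.get_cds(gene_id)
        s = self.contigs[f.contig_id][f.start - 1 : f.end]
        return s if f.strand == "+" else reverse_complement(s)

    def translate_cds(self, gene_id: str) -> str:
        """Translate a CDS (bacterial table), dropping the terminal stop."""
        nt = self.cds_nucleotides(gene_id)
        aa = str(Seq(nt).translate(table=BACTERIAL_TABLE))
        return aa[:-1] if aa.endswith("*") else aa

    def protein_of(self, gene_id: str) -> str | None:
        """Annotated translation if present, else computed; None if untranslatable."""
        f = self.get_cds(gene_id)
        if f.protein:
            return f.protein
        if f.length % 3 != 0:
            return None
        return self.translate_cds(gene_id)


def read_genome(
    path: str | Path,
    format: str = "genbank",
    gff3: str | Path | None = None,
) -> AnnotatedGenome:
    """Read an annotated genome from GenBank or a FASTA + GFF3 pair."""
    if format == "genbank":
        return read_genbank(path)
    if format in ("fasta+gff3", "gff3"):
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires the gff3= path")
        return read_fasta_gff3(path, gff3)
    raise ValueError(f"unknown genome format {format!r}")


def read_genbank(path: str | Path) -> AnnotatedGenome:
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises bare ValueError on bad records
        raise GenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"no GenBank records in {path}")
    contigs: dict[str, str] = {}
    features: list[CDSFeature] = []
    for rec in records:
        contigs[rec.id] = str(rec.seq).upper()
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            gene_id = _first(
                feat.qualifiers, "locus_tag", "gene", "protein_id"
            ) or f"cds_{len(features) + 1}"
            protein = _first(feat.qualifiers, "translation")
            features.append(
                CDSFeature(
                    gene_id=gene_id,
                    contig_id=rec.id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    protein=protein,
                )
            )
    genome = AnnotatedGenome(path.stem, contigs, features)
    return _fill_translations(genome)


def read_fasta_gff3(fasta_path: str | Path, gff3_path: str | Path) -> AnnotatedGenome:
    import gffutils

    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not contigs:
        raise GenomeParseError(f"no FASTA records in {fasta_path}")
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise GenomeParseError(f"cannot parse GFF3 file {gff3_path}: {exc}") from exc
    features: list[CDSFeature] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = (
            _first(feat.attributes, "locus_tag", "ID", "Name")
            or f"cds_{len(features) + 1}"
        )
        features.append(
            CDSFeature(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand="-" if feat.strand == "-" else "+",
            )
        )
    genome = AnnotatedGenome(fasta_path.stem, contigs, features)
    return _fill_translations(genome)


def _first(mapping, *keys) -> str | None:
    for k in keys:
        v = mapping.get(k)
        if v:
            return v[0] if isinstance(v, (list, tuple)) else str(v)
    return None


def _fill_translations(genome: AnnotatedGenome) -> AnnotatedGenome:
    filled = []
    for f in genome.cds_features:
        if f.protein is None and f.length % 3 == 0:
            f = replace(f, protein=genome.translate_cds(f.gene_id))
        filled.append(f)
    genome.cds_features = filled
    return genome


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    records = []
    for contig_id, seq in genome.contigs.items():
        rec = SeqRecord(Seq(seq), id=contig_id, name=contig_id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        for f in genome.cds_features:
            if f.contig_id != contig_id:
                continue
            quals = {"locus_tag": [f.gene_id]}
            if f.protein:
                quals["translation"] = [f.protein]
            rec.features.append(
                SeqFeature(
                    FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1),
                    type="CDS",
                    qualifiers=quals,
                )
            )
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, seq in genome.contigs.items():
            fh.write(f"##sequence-region {contig_id} 1 {len(seq)}\n")
        for f in genome.cds_features:
            attrs = f"ID={f.gene_id};locus_tag={f.gene_id}"
            fh.write(
                f"{f.contig_id}\tt3mine\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
            )


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_protein_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    write_fasta(
        ((f.gene_id, p) for f in genome.cds_features if (p := genome.protein_of(f.gene_id))),
        path,
    )


def extract_upstream(
    genome: AnnotatedGenome,
    gene_id: str,
    window: int,
    truncate_at_cds: bool = False,
) -> UpstreamRegion:
    """Extract up to ``window`` nt upstream of a gene, on its coding strand.

    Truncates at the contig edge.  By default neighboring CDS do NOT truncate
    the window (a plain fixed-window screen); ``truncate_at_cds=True`` clips
    the region at the nearest same-contig CDS boundary.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    f = genome.get_cds(gene_id)  # raises KeyError for unknown genes
    contig = genome.contigs[f.contig_id]
    if f.strand == "+":
        lo = max(1, f.start - window)
        if truncate_at_cds:
            for other in genome.cds_features:
                if other.contig_id == f.contig_id and other.end < f.start:
                    lo = max(lo, other.end + 1)
        seq = contig[lo - 1 : f.start - 1]
    else:
        hi = min(len(contig), f.end + window)
        if truncate_at_cds:
            for other in genome.cds_features:
                if other.contig_id == f.contig_id and other.start > f.end:
                    hi = min(hi, other.start - 1)
        seq = reverse_complement(contig[f.end : hi])
    return UpstreamRegion(gene_id=gene_id, sequence=seq)
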