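"""Sequence and annotation I/O plus strand-aware upstream-window extraction.

Coordinate conventions
----------------------
External coordinates are 1-based inclusive on the forward genomic strand
(GFF3 convention) and converted once at this module's boundary.  Offsets
relative to a start codon use the "-1 convention": the base immediately 5'
of the start codon's first base has offset -1, so a 30-nt upstream window
spans offsets -30..-1 on the mRNA sense strand.  For minus-strand genes the
window is reverse-complemented so it always reads 5'->3' on the mRNA.

Windows are *not* clipped at the transcription start site by default: the
scan covers a fixed 30 nt upstream of every start codon, extending past the
TSS into upstream DNA for leaderless genes.  Pass ``respect_tss=True``
together with the gene's transcription unit to clip for sensitivity
analyses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import normalize_seq, revcomp
from .errors import InputError, ValidationError

DEFAULT_WINDOW_WIDTH = 30
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")


@dataclass(frozen=True)
class GenomeRecord:
    """A contig: id plus normalized A/C/G/T/N sequence."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValidationError("contig id must be non-empty")
        seq = normalize_seq(self.sequence, context=f"contig {self.contig_id}")
        if not seq:
            raise ValidationError(f"contig {self.contig_id!r} has empty sequence")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A CDS with 1-based inclusive genomic coordinates.

    ``cds_start``/``cds_end`` are forward-strand coordinates with
    ``cds_start <= cds_end`` regardless of strand; the first base of the
    start codon sits at ``cds_start`` on '+' genes and at ``cds_end`` on
    '-' genes.  ``start_codon`` (mRNA sense) is optional and may be filled
    from the genome with :func:`start_codon_from_genome`.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_start: int
    cds_end: int
    start_codon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (1 <= self.cds_start <= self.cds_end):
            raise ValidationError(
                f"gene {self.gene_id!r}: need 1 <= cds_start <= cds_end, "
                f"got {self.cds_start}..{self.cds_end}"
            )
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id!r}: CDS length not divisible by 3"
            )
        if self.start_codon is not None:
            codon = normalize_seq(self.start_codon, context=f"start codon of {self.gene_id}")
            if len(codon) != 3:
                raise ValidationError(f"gene {self.gene_id!r}: start codon must be a 3-mer")
            object.__setattr__(self, "start_codon", codon)

    @property
    def start_codon_position(self) -> int:
        """Genomic coordinate of the start codon's first base (mRNA sense)."""
        return self.cds_start if self.strand == "+" else self.cds_end


@dataclass(frozen=True)
class TranscriptionUnit:
    """An operon: TSS plus an ordered cistron list (first = proximal)."""

    tu_id: str
    contig_id: str
    strand: str
    tss: int
    cistrons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"TU {self.tu_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 1:
            raise ValidationError(f"TU {self.tu_id!r}: TSS must be >= 1")
        if not self.cistrons:
            raise ValidationError(f"TU {self.tu_id!r}: needs at least one cistron")
        object.__setattr__(self, "cistrons", tuple(self.cistrons))

    @property
    def proximal(self) -> str:
        return self.cistrons[0]

    @property
    def distal(self) -> tuple[str, ...]:
        return self.cistrons[1:]


@dataclass(frozen=True)
class UpstreamWindow:
    """mRNA-sense sequence immediately 5' of a start codon.

    ``offset_of_first_base`` is the offset of ``seq[0]`` relative to the
    start codon (-1 = base immediately preceding it); offsets run
    consecutively up to -1.  ``truncated`` marks clipping at a contig edge
    (or at the TSS when requested).
    """

    gene_id: str
    seq: str
    offset_of_first_base: int
    truncated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_seq(self.seq, context=f"window of {self.gene_id}"))
        if len(self.seq) != -self.offset_of_first_base:
            raise ValidationError(
                f"window of {self.gene_id!r}: offset_of_first_base "
                f"{self.offset_of_first_base} inconsistent with length {len(self.seq)}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, str(rec.seq)))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.contig_id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene tables

_GENE_COLUMNS = ("gene_id", "contig", "strand", "cds_start", "cds_end")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """TSV gene models: gene_id, contig, strand, cds_start, cds_end
    [, start_codon]."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene table not found: {path}")
    genes: list[GeneModel] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_GENE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"gene table {path}: missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                genes.append(
                    GeneModel(
                        gene_id=row["gene_id"],
                        contig_id=row["contig"],
                        strand=row["strand"],
                        cds_start=int(row["cds_start"]),
                        cds_end=int(row["cds_end"]),
                        start_codon=row.get("start_codon") or None,
                    )
                )
            except (KeyError, TypeError) as exc:
                raise ValidationError(f"gene table {path} line {i}: {exc}") from exc
            except ValueError as exc:
                raise ValidationError(
                    f"gene table {path} line {i}: non-integer coordinate ({exc})"
                ) from exc
    if not genes:
        raise InputError(f"gene table {path} has no rows")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"gene table {path}: duplicate gene ids")
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_GENE_COLUMNS + ("start_codon",))
        for g in genes:
            w.writerow(
                [g.gene_id, g.contig_id, g.strand, g.cds_start, g.cds_end, g.start_codon or ""]
            )


def read_gff3_genes(path: str | Path, feature_type: str = "CDS") -> list[GeneModel]:
    """Gene models from GFF3 (feature type CDS, attribute ID)."""
    import gffutils

    path = Path(path)
    if not path.exists():
        raise InputError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                contig_id=feat.seqid,
                strand=feat.strand,
                cds_start=feat.start,
                cds_end=feat.end,
            )
        )
    if not genes:
        raise InputError(f"no {feature_type} features in {path}")
    return genes


def start_codon_from_genome(gene: GeneModel, genome: GenomeRecord) -> str:
    """The 3-mer at the CDS 5' end, on mRNA sense."""
    if gene.contig_id != genome.contig_id:
        raise ValidationError(
            f"gene {gene.gene_id!r} is on contig {gene.contig_id!r}, "
            f"not {genome.contig_id!r}"
        )
    if gene.cds_end > genome.length:
        raise ValidationError(f"gene {gene.gene_id!r} extends past contig end")
    if gene.strand == "+":
        return genome.sequence[gene.cds_start - 1 : gene.cds_start + 2]
    return revcomp(genome.sequence[gene.cds_end - 3 : gene.cds_end])


# ---------------------------------------------------------------------------
# Transcription-unit tables

_TU_COLUMNS = ("tu_id", "contig", "strand", "tss", "cistrons")


def read_tu_table(
    path: str | Path, genes: Mapping[str, GeneModel] | None = None
) -> list[TranscriptionUnit]:
    """TSV transcription units: tu_id, contig, strand, tss,
    comma-separated ordered gene list.  With ``genes`` given, cross-validates
    cistron existence, strand/contig agreement, 5'->3' ordering and that the
    proximal start codon is not upstream of the TSS.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"TU table not found: {path}")
    tus: list[TranscriptionUnit] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TU_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"TU table {path}: missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                tss = int(row["tss"])
            except ValueError as exc:
                raise ValidationError(f"TU table {path} line {i}: non-integer TSS") from exc
            cistrons = tuple(c for c in row["cistrons"].split(",") if c)
            tus.append(
                TranscriptionUnit(
                    tu_id=row["tu_id"], contig_id=row["contig"],
                    strand=row["strand"], tss=tss, cistrons=cistrons,
                )
            )
    if not tus:
        raise InputError(f"TU table {path} has no rows")
    if genes is not None:
        for tu in tus:
            validate_tu(tu, genes)
    return tus


def validate_tu(tu: TranscriptionUnit, genes: Mapping[str, GeneModel]) -> None:
    sign = 1 if tu.strand == "+" else -1
    prev_pos: int | None = None
    for gid in tu.cistrons:
        gene = genes.get(gid)
        if gene is None:
            raise ValidationError(f"TU {tu.tu_id!r}: gene {gid!r} not in gene table")
        if gene.strand != tu.strand:
            raise ValidationError(
                f"TU {tu.tu_id!r}: gene {gid!r} strand {gene.strand!r} != TU strand"
            )
        if gene.contig_id != tu.contig_id:
            raise ValidationError(
                f"TU {tu.tu_id!r}: gene {gid!r} on contig {gene.contig_id!r}, "
                f"TU on {tu.contig_id!r}"
            )
        pos = sign * gene.start_codon_position
        if prev_pos is not None and pos <= prev_pos:
            raise ValidationError(f"TU {tu.tu_id!r}: cistrons not ordered 5'->3'")
        prev_pos = pos
    proximal = genes[tu.proximal]
    if sign * proximal.start_codon_position < sign * tu.tss:
        raise ValidationError(
            f"TU {tu.tu_id!r}: TSS {tu.tss} lies downstream of the proximal "
            f"start codon of {tu.proximal!r}"
        )


def write_tu_table(tus: Iterable[TranscriptionUnit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TU_COLUMNS)
        for tu in tus:
            w.writerow([tu.tu_id, tu.contig_id, tu.strand, tu.tss, ",".join(tu.cistrons)])


# ---------------------------------------------------------------------------
# Upstream windows


def extract_upstream_window(
    genome: GenomeRecord,
    gene: GeneModel,
    width: int = DEFAULT_WINDOW_WIDTH,
    clip_at_tss: TranscriptionUnit | None = None,
    respect_tss: bool = False,
) -> UpstreamWindow:
    """The ``width`` bases immediately 5' of the start codon, mRNA sense.

    On '-' genes the genomic segment 3' of ``cds_end`` is
    reverse-complemented.  The window is clipped (``truncated=True``) at the
    contig edge; clipping at the TSS happens only when both ``clip_at_tss``
    and ``respect_tss`` are given.
    """
    if width <= 0:
        raise ValidationError(f"window width must be positive, got {width}")
    if gene.contig_id != genome.contig_id:
        raise ValidationError(
            f"gene {gene.gene_id!r} contig {gene.contig_id!r} != genome contig "
            f"{genome.contig_id!r}"
        )
    if gene.cds_end > genome.length:
        raise ValidationError(f"gene {gene.gene_id!r} extends past contig end")

    truncated = False
    if gene.strand == "+":
        hi = gene.cds_start - 1          # last window base, genomic
        lo = gene.cds_start - width
        if lo < 1:
            lo, truncated = 1, True
        if respect_tss and clip_at_tss is not None and clip_at_tss.tss > lo:
            lo, truncated = clip_at_tss.tss, True
        seq = genome.sequence[lo - 1 : hi]
    else:
        lo = gene.cds_end + 1
        hi = gene.cds_end + width
        if hi > genome.length:
            hi, truncated = genome.length, True
        if respect_tss and clip_at_tss is not None and clip_at_tss.tss < hi:
            hi, truncated = clip_at_tss.tss, True
        seq = revcomp(genome.sequence[lo - 1 : hi]) if hi >= lo else ""
    return UpstreamWindow(
        gene_id=gene.gene_id, seq=seq, offset_of_first_base=-len(seq), truncated=truncated
    )


def window_offset_to_genomic(gene: GeneModel, offset: int) -> int:
    """Map a start-codon-relative offset back to a genomic coordinate."""
    if gene.strand == "+":
        return gene.cds_start + offset
    return gene.cds_end - offset


def windows_to_tsv(windows: Iterable[UpstreamWindow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "seq", "offset_of_first_base", "truncated"])
        for win in windows:
            w.writerow([win.gene_id, win.seq, win.offset_of_first_base, int(win.truncated)])


def windows_to_fasta(windows: Iterable[UpstreamWindow], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(w.seq), id=w.gene_id,
                  description=f"offset={w.offset_of_first_base} truncated={int(w.truncated)}")
        for w in windows if w.seq
    ]
    SeqIO.write(recs, str(path), "fasta")
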