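"""Positional Shine-Dalgarno signal calling and anti-SD duplex scoring.

The scan reports every exact (possibly overlapping) occurrence of each
motif in the 30-nt upstream window of a start codon.  An occurrence counts
as an SD *signal* when the motif's 5' base lies between offsets -18 and -9
(inclusive) of the annotated start codon or of another in-frame start
codon (AUG/GUG/UUG by default) found within a configurable span around the
annotated start.  A gene carries a signal for a motif iff at least one
occurrence passes for at least one reference start; it is counted once per
motif regardless of the number of passing hits.

Summaries are stratified the way genome-wide counts are reported: the
proximal stratum is restricted to *leadered* proximal cistrons (mRNAs with
a 5'UTR of at least 11 nt), while the distal stratum covers all distal
cistrons.

The default motif set {GGAGG, TGAGG} matches the anti-SD 3' tail of the
processed 16S rRNA (5'-CCUCC-3'); the preset {GGAGG, GGTGG} is available
for purine-rich variants.  ``longest_antiparallel_duplex`` scores the
complementarity between an SD candidate and an anti-SD tail as the longest
contiguous antiparallel Watson-Crick (optionally +G:U wobble) duplex over
all relative alignments.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import normalize_seq, round_half_up
from .errors import ValidationError
from .io_annotation import (
    DEFAULT_START_CODONS,
    DEFAULT_WINDOW_WIDTH,
    GeneModel,
    GenomeRecord,
    TranscriptionUnit,
    UpstreamWindow,
    extract_upstream_window,
    window_offset_to_genomic,
)
from .leader_classify import DISTAL, LEADERED, PROXIMAL, LeaderAnnotation

RULE_WINDOW = (-18, -9)          # inclusive offsets of the motif's 5' base
DEFAULT_ALT_START_SPAN = (-30, 30)

ANNOTATED = "annotated"
ALTERNATIVE = "alternative"

STRATUM_LEADERED_PROXIMAL = "leadered_proximal"
STRATUM_DISTAL = "distal"
STRATA = (STRATUM_LEADERED_PROXIMAL, STRATUM_DISTAL)


@dataclass(frozen=True)
class MotifSet:
    """Exact motifs searched in upstream windows (DNA alphabet)."""

    motifs: tuple[str, ...] = ("GGAGG", "TGAGG")

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValidationError("motif set must be non-empty")
        norm = []
        for m in self.motifs:
            s = normalize_seq(m, context=f"motif {m!r}")
            if len(s) < 3 or "N" in s:
                raise ValidationError(f"motif {m!r}: need length >= 3 over A/C/G/T")
            norm.append(s)
        object.__setattr__(self, "motifs", tuple(norm))

    @classmethod
    def results_preset(cls) -> "MotifSet":
        return cls(("GGAGG", "TGAGG"))

    @classmethod
    def purine_rich_preset(cls) -> "MotifSet":
        return cls(("GGAGG", "GGTGG"))


@dataclass(frozen=True)
class ReferenceStart:
    """A start codon the positional rule may anchor on."""

    kind: str      # annotated | alternative
    offset: int    # nt offset of its first base from the annotated start; 0 for annotated
    codon: str

    def __post_init__(self) -> None:
        if self.kind == ANNOTATED and self.offset != 0:
            raise ValidationError("annotated reference start must have offset 0")
        if self.offset % 3 != 0:
            raise ValidationError(
                f"alternative start offset {self.offset} is not a multiple of 3"
            )


@dataclass(frozen=True)
class SDHit:
    gene_id: str
    motif: str
    offset_5prime: int           # of the motif's 5' base, relative to reference_start
    reference_start: str         # annotated | alternative
    reference_start_offset: int  # 0 for annotated
    passes_rule: bool


@dataclass(frozen=True)
class SDSummaryRow:
    motif: str
    stratum: str
    n_total: int
    n_with_signal: int
    percent: float | None        # one decimal; None (NA) when n_total == 0


@dataclass(frozen=True)
class DuplexResult:
    max_contiguous_bp: int
    # (index in seq_a of the duplex's 5'-most base, index in seq_b of its
    # partner, i.e. the 3'-most paired base of seq_b); (-1, -1) if no pair
    pairing_start_offsets: tuple[int, int]
    allow_wobble: bool


# ---------------------------------------------------------------------------
# Scanning


def find_motif_occurrences(
    window: UpstreamWindow, motifs: MotifSet | Sequence[str] = MotifSet()
) -> list[tuple[str, int]]:
    """Every exact occurrence of every motif; offsets of the 5' base in the
    window's -1 convention.  Overlapping occurrences are all reported; N
    never matches."""
    if isinstance(motifs, MotifSet):
        motif_list = motifs.motifs
    else:
        motif_list = MotifSet(tuple(motifs)).motifs
    hits: list[tuple[str, int]] = []
    seq = window.seq
    for motif in motif_list:
        i = seq.find(motif)
        while i != -1:
            hits.append((motif, window.offset_of_first_base + i))
            i = seq.find(motif, i + 1)
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def _codon_at(genome: GenomeRecord, gene: GeneModel, offset: int) -> str | None:
    """mRNA-sense 3-mer whose first base sits ``offset`` nt from the
    annotated start; None if it runs off the contig."""
    from ._util import revcomp

    if gene.strand == "+":
        lo = gene.cds_start + offset
        if lo < 1 or lo + 2 > genome.length:
            return None
        return genome.sequence[lo - 1 : lo + 2]
    hi = gene.cds_end - offset
    if hi > genome.length or hi - 2 < 1:
        return None
    return revcomp(genome.sequence[hi - 3 : hi])


def enumerate_reference_starts(
    gene: GeneModel,
    genome: GenomeRecord,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    span: tuple[int, int] = DEFAULT_ALT_START_SPAN,
) -> list[ReferenceStart]:
    """The annotated start (offset 0) plus every in-frame occurrence of a
    configured start codon whose first base lies within ``span`` nt of the
    annotated start (multiples of 3 only)."""
    lo, hi = span
    if lo % 3 != 0 or hi % 3 != 0:
        raise ValidationError(f"alternative-start span {span} must be multiples of 3")
    codon_set = {normalize_seq(c, context="start codon") for c in start_codons}
    annotated = _codon_at(genome, gene, 0)
    if annotated is None:
        raise ValidationError(f"gene {gene.gene_id!r}: start codon outside contig")
    starts = [ReferenceStart(ANNOTATED, 0, annotated)]
    for d in range(lo, hi + 1, 3):
        if d == 0:
            continue
        codon = _codon_at(genome, gene, d)
        if codon is not None and codon in codon_set:
            starts.append(ReferenceStart(ALTERNATIVE, d, codon))
    starts.sort(key=lambda s: s.offset)
    return starts


def call_sd_signals(
    window: UpstreamWindow,
    hits: Sequence[tuple[str, int]],
    reference_starts: Sequence[ReferenceStart],
    rule: tuple[int, int] = RULE_WINDOW,
) -> list[SDHit]:
    """Re-express each occurrence relative to each reference start and
    apply the positional rule (5' base within ``rule``, inclusive)."""
    lo, hi = rule
    calls: list[SDHit] = []
    for motif, offset in hits:
        for ref in reference_starts:
            rel = offset - ref.offset
            calls.append(
                SDHit(
                    gene_id=window.gene_id,
                    motif=motif,
                    offset_5prime=rel,
                    reference_start=ref.kind,
                    reference_start_offset=ref.offset,
                    passes_rule=lo <= rel <= hi,
                )
            )
    return calls


def gene_signal_motifs(hits: Iterable[SDHit]) -> set[str]:
    """Motifs for which at least one hit passes the positional rule."""
    return {h.motif for h in hits if h.passes_rule}


def scan_gene(
    genome: GenomeRecord,
    gene: GeneModel,
    motifs: MotifSet = MotifSet(),
    width: int = DEFAULT_WINDOW_WIDTH,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    span: tuple[int, int] = DEFAULT_ALT_START_SPAN,
    rule: tuple[int, int] = RULE_WINDOW,
    clip_at_tss: TranscriptionUnit | None = None,
    respect_tss: bool = False,
) -> list[SDHit]:
    """Window extraction + motif scan + positional-rule calls for one gene."""
    window = extract_upstream_window(
        genome, gene, width=width, clip_at_tss=clip_at_tss, respect_tss=respect_tss
    )
    occurrences = find_motif_occurrences(window, motifs)
    if not occurrences:
        return []
    refs = enumerate_reference_starts(gene, genome, start_codons=start_codons, span=span)
    return call_sd_signals(window, occurrences, refs, rule=rule)


def scan_genes(
    genome: GenomeRecord,
    genes: Sequence[GeneModel],
    motifs: MotifSet = MotifSet(),
    **kwargs,
) -> dict[str, list[SDHit]]:
    return {g.gene_id: scan_gene(genome, g, motifs=motifs, **kwargs) for g in genes}


# ---------------------------------------------------------------------------
# Summaries


def summarize_sd(
    calls: Mapping[str, Sequence[SDHit]],
    leader_annotations: Sequence[LeaderAnnotation],
    motifs: MotifSet = MotifSet(),
) -> list[SDSummaryRow]:
    """Stratified counts of genes with a passing signal per motif.

    Proximal stratum = leadered proximal cistrons only; distal stratum =
    all distal cistrons.  Percent is NA (None) for an empty stratum, never
    0.
    """
    strata: dict[str, list[str]] = {s: [] for s in STRATA}
    for ann in leader_annotations:
        if ann.role == PROXIMAL and ann.leader_class == LEADERED:
            strata[STRATUM_LEADERED_PROXIMAL].append(ann.gene_id)
        elif ann.role == DISTAL:
            strata[STRATUM_DISTAL].append(ann.gene_id)
    rows: list[SDSummaryRow] = []
    for motif in motifs.motifs:
        for stratum, gene_ids in strata.items():
            n_total = len(gene_ids)
            n_sig = sum(
                1 for gid in gene_ids if motif in gene_signal_motifs(calls.get(gid, ()))
            )
            percent = round_half_up(100.0 * n_sig / n_total, 1) if n_total else None
            rows.append(SDSummaryRow(motif, stratum, n_total, n_sig, percent))
    return rows


def summary_percent(rows: Sequence[SDSummaryRow], motif: str, stratum: str) -> float | None:
    for row in rows:
        if row.motif == motif and row.stratum == stratum:
            return row.percent
    raise KeyError(f"no summary row for motif {motif!r} stratum {stratum!r}")


# ---------------------------------------------------------------------------
# Anti-SD duplex


def _pairs(a: str, b: str, allow_wobble: bool) -> bool:
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    if (a, b) in wc:
        return True
    return allow_wobble and (a, b) in {("G", "T"), ("T", "G")}


def longest_antiparallel_duplex(
    seq_a: str, seq_b: str, allow_wobble: bool = False
) -> DuplexResult:
    """Longest contiguous antiparallel duplex over all relative alignments.

    Both inputs are 5'->3'; seq_b is read 3'->5' against seq_a.  RNA input
    is accepted (U == T).
    """
    a = normalize_seq(seq_a, context="seq_a")
    b = normalize_seq(seq_b, context="seq_b")
    if not a or not b:
        raise ValidationError("duplex sequences must be non-empty")
    rb = b[::-1]
    best_len = 0
    best_start = (-1, -1)
    for shift in range(-(len(rb) - 1), len(a)):
        run = 0
        run_start_i = 0
        for j in range(len(rb)):
            i = shift + j
            if 0 <= i < len(a) and _pairs(a[i], rb[j], allow_wobble):
                if run == 0:
                    run_start_i, run_start_j = i, j
                run += 1
                if run > best_len:
                    best_len = run
                    # partner of a's 5'-most paired base, in b's own 5'->3'
                    best_start = (run_start_i, len(b) - 1 - run_start_j)
            else:
                run = 0
    return DuplexResult(best_len, best_start, allow_wobble)


# ---------------------------------------------------------------------------
# Export


def hits_to_tsv(calls: Mapping[str, Sequence[SDHit]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene_id", "motif", "offset_5prime", "reference_start",
             "reference_start_offset", "passes_rule"]
        )
        for gid in sorted(calls):
            for h in calls[gid]:
                w.writerow(
                    [h.gene_id, h.motif, h.offset_5prime, h.reference_start,
                     h.reference_start_offset, int(h.passes_rule)]
                )


def hits_to_gff3(
    calls: Mapping[str, Sequence[SDHit]],
    genes: Mapping[str, GeneModel],
    path: str | Path,
) -> None:
    """SD hits as GFF3 ``SD_signal`` features; score = -offset of the 5'
    base relative to the annotated start."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(calls):
            gene = genes[gid]
            n = 0
            for h in calls[gid]:
                if h.reference_start != ANNOTATED:
                    continue  # one feature per occurrence, anchored on the annotated start
                n += 1
                abs_off = h.offset_5prime
                g1 = window_offset_to_genomic(gene, abs_off)
                g2 = window_offset_to_genomic(gene, abs_off + len(h.motif) - 1)
                start, end = min(g1, g2), max(g1, g2)
                attrs = (
                    f"ID=sd_{gid}_{n};gene={gid};motif={h.motif};"
                    f"passes_rule={int(h.passes_rule)}"
                )
                fh.write(
                    "\t".join(
                        [gene.contig_id, "tirscan", "SD_signal", str(start), str(end),
                         str(-abs_off), gene.strand, ".", attrs]
                    )
                    + "\n"
                )


def summary_to_tsv(rows: Sequence[SDSummaryRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["motif", "stratum", "n_total", "n_with_signal", "percent"])
        for r in rows:
            w.writerow(
                [r.motif, r.stratum, r.n_total, r.n_with_signal,
                 "NA" if r.percent is None else r.percent]
            )


def summary_to_json(rows: Sequence[SDSummaryRow], path: str | Path) -> None:
    payload = [
        {"motif": r.motif, "stratum": r.stratum, "n_total": r.n_total,
         "n_with_signal": r.n_with_signal, "percent": r.percent}
        for r in rows
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
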