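"""5'UTR length computation and three-way leader classification.

An mRNA (proximal cistron) is *leaderless* when its 5'UTR is at most 5 nt,
a *short-leader* mRNA at 6-10 nt, and *leadered* at 11 nt or more.  The
three classes tile the non-negative integers; the boundaries are 5/6 and
10/11.  Distal cistrons have no 5'UTR of their own and receive class NA.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import round_half_up
from .errors import ValidationError
from .io_annotation import GeneModel, TranscriptionUnit

LEADERLESS = "leaderless"
SHORT_LEADER = "short_leader"
LEADERED = "leadered"
NA = "NA"
LEADER_CLASSES = (LEADERLESS, SHORT_LEADER, LEADERED)

PROXIMAL = "proximal"
DISTAL = "distal"

LEADERLESS_MAX = 5   # 5'UTR <= 5 nt
SHORT_LEADER_MAX = 10  # 6..10 nt; >= 11 is leadered


@dataclass(frozen=True)
class LeaderAnnotation:
    gene_id: str
    role: str                     # proximal | distal
    leader_length: int | None     # None (NA) for distal cistrons
    leader_class: str


def leader_length(tu: TranscriptionUnit, gene: GeneModel) -> int:
    """Transcribed nucleotides strictly 5' of the start codon's first base.

    Zero when the TSS coincides with the start codon's first base.
    """
    if gene.gene_id != tu.proximal:
        raise ValidationError(
            f"gene {gene.gene_id!r} is not the proximal cistron of TU {tu.tu_id!r}"
        )
    if gene.strand != tu.strand:
        raise ValidationError(
            f"gene {gene.gene_id!r} strand differs from TU {tu.tu_id!r}"
        )
    if tu.strand == "+":
        length = gene.start_codon_position - tu.tss
    else:
        length = tu.tss - gene.start_codon_position
    if length < 0:
        raise ValidationError(
            f"TU {tu.tu_id!r}: TSS downstream of start codon of {gene.gene_id!r}"
        )
    return length


def classify_leader(length: int) -> str:
    if length < 0:
        raise ValidationError(f"leader length must be non-negative, got {length}")
    if length <= LEADERLESS_MAX:
        return LEADERLESS
    if length <= SHORT_LEADER_MAX:
        return SHORT_LEADER
    return LEADERED


def annotate_leaders(
    tus: Sequence[TranscriptionUnit], genes: Mapping[str, GeneModel]
) -> list[LeaderAnnotation]:
    """Per-cistron annotations: proximal cistrons get a length and class,
    distal cistrons get NA."""
    out: list[LeaderAnnotation] = []
    for tu in tus:
        prox = genes[tu.proximal]
        length = leader_length(tu, prox)
        out.append(LeaderAnnotation(prox.gene_id, PROXIMAL, length, classify_leader(length)))
        for gid in tu.distal:
            out.append(LeaderAnnotation(gid, DISTAL, None, NA))
    return out


def summarize_leader_classes(
    annotations: Iterable[LeaderAnnotation],
) -> dict[str, float]:
    """Percentages (one decimal, half-up) of each class over proximal
    cistrons only."""
    counts = dict.fromkeys(LEADER_CLASSES, 0)
    n = 0
    for ann in annotations:
        if ann.role != PROXIMAL:
            continue
        n += 1
        counts[ann.leader_class] += 1
    if n == 0:
        raise ValidationError("no proximal annotations to summarize")
    return {cls: round_half_up(100.0 * counts[cls] / n, 1) for cls in LEADER_CLASSES}


def annotations_to_tsv(annotations: Iterable[LeaderAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "role", "leader_length", "leader_class"])
        for a in annotations:
            w.writerow(
                [a.gene_id, a.role, "NA" if a.leader_length is None else a.leader_length,
                 a.leader_class]
            )
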