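"""3'-end variant calling from circularized-16S-rRNA junction reads.

A circular-ligation read crosses the 5'/3' junction of the ligated rRNA:
the bases immediately 5' of the junction are the molecule's 3' end, the
bases from the junction on are its 5' start.  The junction is located by
anchoring on the rRNA's known 5'-start motif (AAUCC); when the anchor
occurs more than once, the occurrence agreeing best with the downstream
5'-region reference wins (ties -> leftmost).  The read suffix ending at
the junction is then matched against a catalog of 3'-end variants
(CCUCC, CCUCA, CCUC, CCU by default); the longest exactly-matching entry
wins, and no match yields ``other``.

Matching is done after U->T normalization; variant labels are reported in
the RNA alphabet.  No sequencing-error tolerance is applied by default
(Sanger-clone inputs); an optional mismatch allowance exists for the
anchor only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._util import normalize_seq, to_rna
from .errors import AnchorNotFoundError, InputError, ValidationError

DEFAULT_ANCHOR = "AAUCC"
DEFAULT_CATALOG = ("CCUCC", "CCUCA", "CCUC", "CCU")
OTHER = "other"


@dataclass(frozen=True)
class JunctionRead:
    read_id: str
    seq: str  # normalized to DNA alphabet

    def __post_init__(self) -> None:
        s = normalize_seq(self.seq, context=f"read {self.read_id}")
        if not s:
            raise ValidationError(f"read {self.read_id!r} is empty")
        object.__setattr__(self, "seq", s)


@dataclass(frozen=True)
class EndVariantCall:
    read_id: str
    variant: str            # RNA-alphabet catalog entry or 'other'
    junction_index: int     # index of the first 5'-start base; junction sits 5' of it
    matched_suffix: str     # RNA alphabet; '' for 'other'


def read_junction_fasta(path: str | Path) -> list[JunctionRead]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"junction-read FASTA not found: {path}")
    reads = [JunctionRead(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not reads:
        raise InputError(f"no reads in {path}")
    return reads


def _hamming_leq(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def locate_junction(
    read: JunctionRead,
    five_prime_anchor: str = DEFAULT_ANCHOR,
    reference_5prime: str | None = None,
    max_anchor_mismatches: int = 0,
) -> int:
    """Index of the 5'-start anchor occurrence that maximizes downstream
    agreement with ``reference_5prime`` (ties -> leftmost).

    ``reference_5prime`` defaults to the anchor itself.  Agreement is the
    number of position-wise matches between the read from the candidate
    index and the reference.  Raises :class:`AnchorNotFoundError` when the
    anchor is absent — a different failure from an ``other`` variant call.
    """
    anchor = normalize_seq(five_prime_anchor, context="anchor")
    if len(anchor) < 5:
        raise ValidationError(f"anchor must be at least 5 nt, got {len(anchor)}")
    ref = anchor if reference_5prime is None else normalize_seq(
        reference_5prime, context="5' reference"
    )
    seq = read.seq
    candidates = [
        i
        for i in range(len(seq) - len(anchor) + 1)
        if _hamming_leq(seq[i : i + len(anchor)], anchor, max_anchor_mismatches)
    ]
    if not candidates:
        raise AnchorNotFoundError(
            f"anchor {to_rna(anchor)!r} not found in read {read.read_id!r}"
        )
    best, best_score = candidates[0], -1
    for i in candidates:
        score = sum(1 for x, y in zip(seq[i:], ref) if x == y)
        if score > best_score:  # strict: ties keep the leftmost
            best, best_score = i, score
    return best


def classify_end_variant(
    read: JunctionRead,
    junction_index: int,
    variant_catalog: Sequence[str] = DEFAULT_CATALOG,
) -> EndVariantCall:
    """Longest catalog entry exactly matching the read suffix that ends at
    the junction; no match -> ``other``."""
    if not (0 <= junction_index <= len(read.seq)):
        raise ValidationError(
            f"junction index {junction_index} outside read {read.read_id!r}"
        )
    catalog_dna = [(v, normalize_seq(v, context=f"catalog entry {v!r}")) for v in variant_catalog]
    catalog_dna.sort(key=lambda kv: len(kv[1]), reverse=True)
    prefix = read.seq[:junction_index]
    for label, dna in catalog_dna:
        if prefix.endswith(dna):
            return EndVariantCall(read.read_id, to_rna(label.upper()), junction_index, to_rna(dna))
    return EndVariantCall(read.read_id, OTHER, junction_index, "")


def classify_reads(
    reads: Sequence[JunctionRead],
    five_prime_anchor: str = DEFAULT_ANCHOR,
    reference_5prime: str | None = None,
    variant_catalog: Sequence[str] = DEFAULT_CATALOG,
    max_anchor_mismatches: int = 0,
) -> list[EndVariantCall]:
    return [
        classify_end_variant(
            r,
            locate_junction(
                r, five_prime_anchor, reference_5prime, max_anchor_mismatches
            ),
            variant_catalog,
        )
        for r in reads
    ]


def tally_variants(
    calls: Sequence[EndVariantCall],
    variant_catalog: Sequence[str] = DEFAULT_CATALOG,
) -> dict[str, int]:
    """Counts per variant in catalog order, plus 'other' and 'total'."""
    if not calls:
        raise ValidationError("cannot tally an empty call list")
    labels = [to_rna(normalize_seq(v, context="catalog")) for v in variant_catalog]
    counts = {v: 0 for v in labels}
    counts[OTHER] = 0
    for c in calls:
        counts[c.variant if c.variant in counts else OTHER] += 1
    counts["total"] = len(calls)
    return counts


def calls_to_tsv(calls: Iterable[EndVariantCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "variant", "junction_index", "matched_suffix"])
        for c in calls:
            w.writerow([c.read_id, c.variant, c.junction_index, c.matched_suffix])


def tally_to_json(tally: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(tally, indent=2) + "\n")
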