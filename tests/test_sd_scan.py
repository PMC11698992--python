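"""Motif scanning, the positional rule, stratified summaries and the
anti-SD duplex search — each checked against an independent brute-force
oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tirscan.errors import ValidationError
from tirscan.io_annotation import GeneModel, GenomeRecord, UpstreamWindow
from tirscan.leader_classify import LeaderAnnotation
from tirscan.sd_scan import (
    ANNOTATED,
    ALTERNATIVE,
    STRATUM_DISTAL,
    STRATUM_LEADERED_PROXIMAL,
    MotifSet,
    ReferenceStart,
    call_sd_signals,
    enumerate_reference_starts,
    find_motif_occurrences,
    gene_signal_motifs,
    longest_antiparallel_duplex,
    summarize_sd,
    summary_percent,
)

# ---------------------------------------------------------------------------
# Independent oracles


def naive_motif_scan(seq: str, motifs) -> list:
    """O(n*m) sliding-window oracle, offsets in the -1 convention."""
    hits = []
    for m in motifs:
        for i in range(len(seq) - len(m) + 1):
            if seq[i : i + len(m)] == m:
                hits.append((m, i - len(seq)))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def _pairs(x, y, wobble):
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    return (x, y) in wc or (wobble and (x, y) in gu)


def duplex_oracle(a: str, b: str, wobble=False) -> int:
    """Extend a duplex from every (i, j) anchor pair; a[i+k] pairs b[j-k]."""
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j - k >= 0 and _pairs(a[i + k], b[j - k], wobble):
                k += 1
            best = max(best, k)
    return best


def _window(seq: str) -> UpstreamWindow:
    return UpstreamWindow("g", seq, -len(seq))


# ---------------------------------------------------------------------------


class TestFindMotifOccurrences:
    def test_no_match_in_homopolymer(self):
        assert find_motif_occurrences(_window("C" * 30)) == []

    def test_planted_motif_offset(self):
        seq = "C" * 13 + "GGAGG" + "C" * 12  # 5' G at offset -17
        assert find_motif_occurrences(_window(seq), MotifSet(("GGAGG",))) == [
            ("GGAGG", -17)
        ]

    def test_overlapping_occurrences(self):
        hits = find_motif_occurrences(_window("GGAGGAGG"), MotifSet(("GGAGG",)))
        assert hits == [("GGAGG", -8), ("GGAGG", -5)]

    def test_rna_motif_input_normalized(self):
        seq = "C" * 10 + "TGAGG" + "C" * 15
        assert find_motif_occurrences(_window(seq), MotifSet(("UGAGG",))) == [
            ("TGAGG", -20)
        ]

    def test_n_never_matches(self):
        seq = "C" * 13 + "GGANG" + "C" * 12
        assert find_motif_occurrences(_window(seq)) == []

    def test_oracle_equivalence_on_random_windows(self):
        rng = np.random.default_rng(1234)
        motifs = MotifSet(("GGAGG", "TGAGG"))
        for _ in range(1000):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            assert find_motif_occurrences(_window(seq), motifs) == naive_motif_scan(
                seq, motifs.motifs
            )


class TestEnumerateReferenceStarts:
    def _gene_and_genome(self, upstream: str, cds: str):
        pad = "C" * 10
        genome = GenomeRecord("c1", pad + upstream + cds + "C" * 10)
        start = len(pad) + len(upstream) + 1
        gene = GeneModel("g1", "c1", "+", start, start + len(cds) - 1)
        return gene, genome

    def test_annotated_only(self):
        cds = "ATG" + "CCC" * 12 + "TAA"
        gene, genome = self._gene_and_genome("C" * 30, cds)
        starts = enumerate_reference_starts(gene, genome)
        assert [(s.kind, s.offset) for s in starts] == [(ANNOTATED, 0)]

    def test_downstream_in_frame_gtg(self):
        cds = "ATG" + "CCC" + "GTG" + "CCC" * 10 + "TAA"  # GTG at +6
        gene, genome = self._gene_and_genome("C" * 30, cds)
        starts = enumerate_reference_starts(gene, genome)
        assert (ALTERNATIVE, 6) in [(s.kind, s.offset) for s in starts]

    def test_upstream_in_frame_atg(self):
        upstream = "C" * 21 + "ATG" + "C" * 6  # ATG at -9
        cds = "ATG" + "CCC" * 12 + "TAA"
        gene, genome = self._gene_and_genome(upstream, cds)
        starts = enumerate_reference_starts(gene, genome)
        assert (ALTERNATIVE, -9) in [(s.kind, s.offset) for s in starts]

    def test_span_must_be_multiple_of_three(self):
        gene, genome = self._gene_and_genome("C" * 30, "ATG" + "CCC" * 12 + "TAA")
        with pytest.raises(ValidationError):
            enumerate_reference_starts(gene, genome, span=(-29, 30))

    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_codon_walk(self, seed):
        """Enumeration matches a direct codon walk over the mRNA-sense
        sequence, on both strands."""
        rng = np.random.default_rng(seed)
        mrna = "".join("ACGT"[i] for i in rng.integers(0, 4, 130))
        # annotated CDS begins at mRNA position 50 (0-based), force ATG
        mrna = mrna[:50] + "ATG" + mrna[53:]
        strand = "+" if seed % 2 == 0 else "-"
        if strand == "+":
            genome = GenomeRecord("c1", mrna)
            gene = GeneModel("g1", "c1", "+", 51, 51 + 59)
        else:
            from tirscan._util import revcomp

            genome = GenomeRecord("c1", revcomp(mrna))
            gene = GeneModel("g1", "c1", "-", 130 - 110 + 1, 130 - 51 + 1)
        got = {
            (s.kind, s.offset)
            for s in enumerate_reference_starts(gene, genome, span=(-30, 30))
        }
        expected = {(ANNOTATED, 0)}
        for d in range(-30, 31, 3):
            if d == 0:
                continue
            codon = mrna[50 + d : 53 + d]
            if codon in ("ATG", "GTG", "TTG"):
                expected.add((ALTERNATIVE, d))
        assert got == expected


class TestCallSdSignals:
    def _call(self, offset, refs=None):
        refs = refs or [ReferenceStart(ANNOTATED, 0, "ATG")]
        win = _window("C" * 30)
        (hit,) = [
            h
            for h in call_sd_signals(win, [("GGAGG", offset)], refs)
            if h.reference_start_offset == refs[-1].offset
        ]
        return hit

    def test_boundary_minus9_passes(self):
        assert self._call(-9).passes_rule

    def test_boundary_minus18_passes(self):
        assert self._call(-18).passes_rule

    @pytest.mark.parametrize("offset", [-8, -19])
    def test_just_outside_bounds_fails(self, offset):
        assert not self._call(offset).passes_rule

    def test_passes_via_alternative_start(self):
        # 5' G at -21 of the annotated start = -12 of an in-frame start at -9
        refs = [
            ReferenceStart(ANNOTATED, 0, "ATG"),
            ReferenceStart(ALTERNATIVE, -9, "ATG"),
        ]
        win = _window("C" * 30)
        hits = call_sd_signals(win, [("GGAGG", -21)], refs)
        by_ref = {h.reference_start_offset: h.passes_rule for h in hits}
        assert by_ref == {0: False, -9: True}
        assert gene_signal_motifs(hits) == {"GGAGG"}


class TestSummarizeSd:
    def _annotations(self, n_leadered, n_distal):
        anns = [
            LeaderAnnotation(f"p{i}", "proximal", 20, "leadered")
            for i in range(n_leadered)
        ]
        anns += [LeaderAnnotation(f"d{i}", "distal", None, "NA") for i in range(n_distal)]
        return anns

    def _calls(self, gene_ids, motif="GGAGG"):
        win_hits = {}
        for gid in gene_ids:
            win = UpstreamWindow(gid, "C" * 30, -30)
            win_hits[gid] = call_sd_signals(
                win, [(motif, -12)], [ReferenceStart(ANNOTATED, 0, "ATG")]
            )
        return win_hits

    def test_proximal_percentages(self):
        anns = self._annotations(169, 0)
        calls = self._calls([f"p{i}" for i in range(9)])
        rows = summarize_sd(calls, anns, MotifSet(("GGAGG",)))
        assert summary_percent(rows, "GGAGG", STRATUM_LEADERED_PROXIMAL) == 5.3

    def test_distal_percentages(self):
        anns = self._annotations(0, 879)
        calls = self._calls([f"d{i}" for i in range(72)])
        rows = summarize_sd(calls, anns, MotifSet(("GGAGG",)))
        assert summary_percent(rows, "GGAGG", STRATUM_DISTAL) == 8.2

    def test_zero_hits_gives_zero_percent(self):
        anns = self._annotations(10, 0)
        rows = summarize_sd({}, anns, MotifSet(("GGAGG",)))
        assert summary_percent(rows, "GGAGG", STRATUM_LEADERED_PROXIMAL) == 0.0

    def test_empty_stratum_is_na_not_zero(self):
        anns = self._annotations(5, 0)
        rows = summarize_sd({}, anns, MotifSet(("GGAGG",)))
        assert summary_percent(rows, "GGAGG", STRATUM_DISTAL) is None

    def test_gene_counts_once_despite_multiple_passing_hits(self):
        anns = self._annotations(4, 0)
        win = UpstreamWindow("p0", "C" * 30, -30)
        calls = {
            "p0": call_sd_signals(
                win,
                [("GGAGG", -12), ("GGAGG", -15)],
                [ReferenceStart(ANNOTATED, 0, "ATG")],
            )
        }
        rows = summarize_sd(calls, anns, MotifSet(("GGAGG",)))
        (row,) = [r for r in rows if r.stratum == STRATUM_LEADERED_PROXIMAL]
        assert row.n_with_signal == 1 and row.percent == 25.0

    def test_percent_recomputation_invariant(self):
        from tirscan._util import round_half_up

        anns = self._annotations(37, 113)
        calls = self._calls([f"p{i}" for i in range(5)] + [f"d{i}" for i in range(11)])
        for row in summarize_sd(calls, anns, MotifSet(("GGAGG", "TGAGG"))):
            if row.n_total:
                assert row.percent == round_half_up(
                    100.0 * row.n_with_signal / row.n_total, 1
                )


class TestDuplex:
    def test_full_complementarity(self):
        assert longest_antiparallel_duplex("GGAGG", "CCUCC").max_contiguous_bp == 5

    def test_genomic_end_pairs_one_fewer(self):
        assert longest_antiparallel_duplex("GGAGG", "CCUCA").max_contiguous_bp == 4

    def test_exact_reverse_complement_pairs_full_length(self):
        from tirscan._util import revcomp

        seq = "GATTACAGGAGG"
        res = longest_antiparallel_duplex(seq, revcomp(seq))
        assert res.max_contiguous_bp == len(seq)

    def test_wobble_extends_pairing(self):
        # G:U pair only counts with wobble enabled
        assert longest_antiparallel_duplex("GGG", "TCC").max_contiguous_bp == 2
        assert (
            longest_antiparallel_duplex("GGG", "TCC", allow_wobble=True).max_contiguous_bp
            == 3
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            longest_antiparallel_duplex("", "ACGT")

    @given(
        st.text(alphabet="ACGU", min_size=1, max_size=12),
        st.text(alphabet="ACGU", min_size=1, max_size=12),
        st.booleans(),
    )
    def test_brute_force_equivalence_symmetry_and_wobble_monotonicity(self, a, b, wobble):
        res = longest_antiparallel_duplex(a, b, allow_wobble=wobble)
        assert res.max_contiguous_bp == duplex_oracle(a, b, wobble)
        assert (
            res.max_contiguous_bp
            == longest_antiparallel_duplex(b, a, allow_wobble=wobble).max_contiguous_bp
        )
        assert (
            longest_antiparallel_duplex(a, b, allow_wobble=True).max_contiguous_bp
            >= longest_antiparallel_duplex(a, b).max_contiguous_bp
        )
        assert res.max_contiguous_bp <= min(len(a), len(b))
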