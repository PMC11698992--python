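"""Synthetic genomes, transcription units, junction reads and toeprint
tables with known ground truth.

The generator emulates the statistical structure the analysis assumes:
operonic transcription units whose proximal cistrons carry 5'UTRs drawn
from a controllable leader-class partition (73/11/16% leaderless /
short-leader / leadered by default), upstream windows that are motif-free
background except for planted SD motifs — rule-passing plantings in a
chosen fraction of genes and *positional decoys* (motif present but 5'
base outside [-18,-9] relative to every enumerated start codon) in
another — circularized-rRNA junction reads with a stated 3'-end variant
mixture, and toeprint lanes with stated T/RT means plus truncated
Gaussian noise.

Ground truth is returned alongside every output so each pipeline stage
can be checked for exact planted-truth recovery.  A single root seed is
split into per-component substreams, so adding one generator does not
perturb the others, and a fixed seed reproduces every output
byte-identically.

Background control is enforced by rejection sampling: a gene's upstream
window is redrawn until it contains exactly the planted motif occurrences
and no in-frame start codon other than the annotated (and any planted
alternative) one within the enumeration span.  An iteration cap guards
against infeasible configurations.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import normalize_seq, revcomp, round_half_up, to_rna
from .errors import InfeasibleConfigError, ValidationError
from .io_annotation import (
    DEFAULT_WINDOW_WIDTH,
    GeneModel,
    GenomeRecord,
    TranscriptionUnit,
    write_fasta,
    write_gene_table,
    write_tu_table,
)
from .leader_classify import (
    DISTAL,
    LEADERED,
    LEADERLESS,
    PROXIMAL,
    SHORT_LEADER,
    LEADERLESS_MAX,
    SHORT_LEADER_MAX,
)
from .rrna_end_junction import JunctionRead
from .sd_scan import RULE_WINDOW, STRATUM_DISTAL, STRATUM_LEADERED_PROXIMAL

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = {"ATG", "GTG", "TTG"}
_ALL_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_SAFE_CODONS = sorted(set(_ALL_CODONS) - _STOPS - _STARTS)
_BODY_CODONS = sorted(set(_ALL_CODONS) - _STOPS)

DEFAULT_LEADER_PROPORTIONS = (0.73, 0.11, 0.16)
DEFAULT_SD_RATES: dict[str, dict[str, float]] = {
    "GGAGG": {STRATUM_LEADERED_PROXIMAL: 0.053, STRATUM_DISTAL: 0.082},
    "TGAGG": {STRATUM_LEADERED_PROXIMAL: 0.041, STRATUM_DISTAL: 0.053},
}
DEFAULT_JUNCTION_MIXTURE: dict[str, float] = {
    "CCUCC": 27, "CCUCA": 1, "CCUC": 3, "CCU": 1,
}
DEFAULT_TOEPRINT_MEANS: dict[str, tuple[float, float]] = {
    "triphosphate": (60.0, 40.0),
    "monophosphate": (40.0, 60.0),
    "hydroxyl": (20.0, 80.0),
}
# Synthetic stand-in for the rRNA 5'-start region; begins with the AAUCC anchor.
DEFAULT_REFERENCE_5PRIME = "AAUCCGGUUGAUCCUGCCAG"
# Synthetic bases immediately 5' of the variable rRNA 3' end.
DEFAULT_THREE_PRIME_CONTEXT = "GGAUCACUAG"


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _choice(rng: np.random.Generator, items: Sequence, p: Sequence[float] | None = None):
    return items[int(rng.choice(len(items), p=p))]


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Integer allocation of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValidationError("weights must be non-negative and sum > 0")
    quota = w / w.sum() * total
    counts = np.floor(quota).astype(int)
    order = np.argsort(-(quota - counts), kind="stable")
    for i in order[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


# ---------------------------------------------------------------------------
# Configs


@dataclass
class GenomeSimConfig:
    n_tus: int = 200
    operon_size_probs: dict[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})
    leader_class_proportions: tuple[float, float, float] = DEFAULT_LEADER_PROPORTIONS
    motifs: tuple[str, ...] = ("GGAGG", "TGAGG")
    sd_positive_rate: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_SD_RATES.items()}
    )
    decoy_rate: float = 0.25
    alt_start_prob: float = 0.2
    exact_counts: bool = True
    window_width: int = DEFAULT_WINDOW_WIDTH
    rule: tuple[int, int] = RULE_WINDOW
    alt_start_span: tuple[int, int] = (-30, 30)
    leader_max: int = 50
    cds_codons: tuple[int, int] = (20, 60)
    max_resample: int = 500

    def __post_init__(self) -> None:
        if self.n_tus < 1:
            raise ValidationError("n_tus must be >= 1")
        props = tuple(self.leader_class_proportions)
        if len(props) != 3 or any(p < 0 for p in props) or abs(sum(props) - 1) > 1e-9:
            raise ValidationError(
                "leader_class_proportions must be 3 non-negative values summing to 1"
            )
        if not (0 <= self.decoy_rate <= 1) or not (0 <= self.alt_start_prob <= 1):
            raise ValidationError("rates must lie in [0, 1]")
        for m, by_stratum in self.sd_positive_rate.items():
            for s, r in by_stratum.items():
                if not (0 <= r <= 1):
                    raise ValidationError(f"sd_positive_rate[{m}][{s}] must lie in [0, 1]")
        self.motifs = tuple(normalize_seq(m, context=f"motif {m}") for m in self.motifs)
        for m in self.motifs:
            if self.window_width < len(m) or -self.rule[0] > self.window_width:
                raise InfeasibleConfigError(
                    f"window width {self.window_width} too small to plant motif {m!r} "
                    f"under rule {self.rule}"
                )
        if self.cds_codons[0] < 13:
            raise ValidationError("cds_codons minimum must be >= 13 (start + 10 controlled + body + stop)")


@dataclass
class JunctionSimConfig:
    n_reads: int = 32
    variant_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_JUNCTION_MIXTURE)
    )
    exact_counts: bool = True
    anchor: str = "AAUCC"
    reference_5prime: str = DEFAULT_REFERENCE_5PRIME
    three_prime_context: str = DEFAULT_THREE_PRIME_CONTEXT
    flank: int = 6
    decoy_anchor_rate: float = 0.0
    max_resample: int = 200

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValidationError("n_reads must be >= 1")
        if not self.variant_mixture:
            raise ValidationError("variant mixture must be non-empty")
        if any(w < 0 for w in self.variant_mixture.values()):
            raise ValidationError("mixture weights must be non-negative")
        ref = normalize_seq(self.reference_5prime, context="reference_5prime")
        anc = normalize_seq(self.anchor, context="anchor")
        if not ref.startswith(anc):
            raise ValidationError("reference_5prime must begin with the anchor")


@dataclass
class ToeprintSimConfig:
    condition_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TOEPRINT_MEANS)
    )
    n_replicates: int | dict[str, int] = 3
    noise_sd: float = 5.0
    mrnas: tuple[str, ...] = ("lmRNA-1",)

    def __post_init__(self) -> None:
        for cond, (t, rt) in self.condition_means.items():
            if t < 0 or rt < 0 or t + rt <= 0:
                raise ValidationError(
                    f"condition {cond!r}: means must be non-negative with T+RT > 0"
                )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def replicates_for(self, condition: str) -> int:
        if isinstance(self.n_replicates, int):
            return self.n_replicates
        return int(self.n_replicates.get(condition, 0))


@dataclass
class SimulationConfig:
    """Root config: one seed streams into per-component substreams."""

    seed: int = 0
    genome: GenomeSimConfig = field(default_factory=GenomeSimConfig)
    junctions: JunctionSimConfig = field(default_factory=JunctionSimConfig)
    toeprint: ToeprintSimConfig = field(default_factory=ToeprintSimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        for key, sub_cls in (("genome", GenomeSimConfig),
                             ("junctions", JunctionSimConfig),
                             ("toeprint", ToeprintSimConfig)):
            if key in raw:
                sub = dict(raw[key])
                for tup_key in ("leader_class_proportions", "motifs", "rule",
                                "alt_start_span", "cds_codons", "mrnas"):
                    if tup_key in sub and isinstance(sub[tup_key], list):
                        sub[tup_key] = tuple(sub[tup_key])
                if "operon_size_probs" in sub:
                    sub["operon_size_probs"] = {int(k): float(v)
                                                for k, v in sub["operon_size_probs"].items()}
                if "condition_means" in sub:
                    sub["condition_means"] = {k: tuple(v)
                                              for k, v in sub["condition_means"].items()}
                kwargs[key] = sub_cls(**sub)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# Genome + TU generation


@dataclass
class _GenePlan:
    gene_id: str
    tu_id: str
    role: str
    leader_class: str            # NA for distal
    leader_length: int | None
    stratum: str | None          # scan stratum or None
    positive_motif: str | None = None
    decoy_motif: str | None = None
    use_alt_start: bool = False


@dataclass
class SyntheticGenomeData:
    genome: GenomeRecord
    genes: list[GeneModel]
    tus: list[TranscriptionUnit]
    truth: pd.DataFrame

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


def _naive_occurrences(window: str, motifs: Sequence[str]) -> set[tuple[str, int]]:
    """Brute-force sliding-window scan, offsets in the -1 convention."""
    out = set()
    w = len(window)
    for m in motifs:
        for i in range(w - len(m) + 1):
            if window[i : i + len(m)] == m:
                out.add((m, i - w))
    return out


def _inframe_alt_starts(
    window: str, cds: str, span: tuple[int, int], start_codons: set[str]
) -> set[int]:
    """Offsets (multiples of 3, != 0) of start codons around the annotated
    start, read off the composed window+CDS string."""
    w = len(window)
    found = set()
    for d in range(span[0], span[1] + 1, 3):
        if d == 0:
            continue
        if d < 0:
            if w + d < 0 or d + 3 > 0:
                continue
            codon = window[w + d : w + d + 3]
        else:
            if d + 3 > len(cds):
                continue
            codon = cds[d : d + 3]
        if codon in start_codons:
            found.add(d)
    return found


def _compose_gene(
    rng: np.random.Generator, cfg: GenomeSimConfig, plan: _GenePlan
) -> tuple[str, str, int | None]:
    """Window + CDS for one gene, rejection-sampled until the composed
    sequences realize exactly the planted truth."""
    width = cfg.window_width
    rule_lo, rule_hi = cfg.rule
    n_codons = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
    for _ in range(cfg.max_resample):
        window = list(_rand_seq(rng, width))
        start = _choice(rng, ("ATG", "GTG"), p=(0.8, 0.2))
        head = [_choice(rng, _SAFE_CODONS) for _ in range(10)]
        body = [_choice(rng, _BODY_CODONS) for _ in range(n_codons - 12)]
        stop = _choice(rng, sorted(_STOPS))
        cds = list(start + "".join(head) + "".join(body) + stop)

        alt_d: int | None = None
        expected_occ: set[tuple[str, int]] = set()
        if plan.positive_motif:
            m = plan.positive_motif
            if plan.use_alt_start:
                alt_d = int(_choice(rng, (-9, -6, -3, 3, 6, 9)))
                lo = max(rule_lo, -width - alt_d)
                hi = min(rule_hi, -len(m) - alt_d)
                if lo > hi:
                    continue
                rel = int(rng.integers(lo, hi + 1))
                abs_off = alt_d + rel
                alt_codon = _choice(rng, ("ATG", "GTG", "TTG"))
                if alt_d < 0:
                    window[width + alt_d : width + alt_d + 3] = alt_codon
                else:
                    cds[alt_d : alt_d + 3] = alt_codon
            else:
                abs_off = int(rng.integers(max(rule_lo, -width), min(rule_hi, -len(m)) + 1))
            window[width + abs_off : width + abs_off + len(m)] = m
            expected_occ = {(m, abs_off)}
        elif plan.decoy_motif:
            m = plan.decoy_motif
            pool = [o for o in range(-width, -len(m) + 1) if not (rule_lo <= o <= rule_hi)]
            if not pool:
                raise InfeasibleConfigError(
                    f"no decoy offsets available for motif {m!r} in a "
                    f"{width}-nt window under rule {cfg.rule}"
                )
            abs_off = int(_choice(rng, pool))
            window[width + abs_off : width + abs_off + len(m)] = m
            expected_occ = {(m, abs_off)}

        win_s, cds_s = "".join(window), "".join(cds)
        if _naive_occurrences(win_s, cfg.motifs) != expected_occ:
            continue
        expected_alt = {alt_d} if alt_d is not None else set()
        if _inframe_alt_starts(win_s, cds_s, cfg.alt_start_span, _STARTS) != expected_alt:
            continue
        return win_s, cds_s, alt_d
    raise InfeasibleConfigError(
        f"could not compose gene {plan.gene_id!r} within "
        f"{cfg.max_resample} resampling attempts"
    )


def _allocate_plans(rng: np.random.Generator, cfg: GenomeSimConfig) -> list[list[_GenePlan]]:
    """Per-TU gene plans: roles, leader classes/lengths and SD assignments."""
    sizes_items = sorted(cfg.operon_size_probs.items())
    sizes = [s for s, _ in sizes_items]
    probs = np.array([p for _, p in sizes_items], dtype=float)
    probs = probs / probs.sum()
    tu_sizes = [int(_choice(rng, sizes, p=probs)) for _ in range(cfg.n_tus)]

    plans: list[list[_GenePlan]] = []
    gid = 0
    for t, size in enumerate(tu_sizes):
        tu_id = f"tu{t:05d}"
        tu_plans = []
        for j in range(size):
            tu_plans.append(
                _GenePlan(
                    gene_id=f"g{gid:05d}", tu_id=tu_id,
                    role=PROXIMAL if j == 0 else DISTAL,
                    leader_class="NA", leader_length=None, stratum=None,
                )
            )
            gid += 1
        plans.append(tu_plans)

    proximal = [p[0] for p in plans]
    classes = (LEADERLESS, SHORT_LEADER, LEADERED)
    if cfg.exact_counts:
        counts = _largest_remainder(cfg.leader_class_proportions, len(proximal))
        labels = [c for c, n in zip(classes, counts) for _ in range(n)]
        labels = [labels[i] for i in rng.permutation(len(labels))]
    else:
        labels = [
            _choice(rng, classes, p=cfg.leader_class_proportions) for _ in proximal
        ]
    ranges = {
        LEADERLESS: (0, LEADERLESS_MAX),
        SHORT_LEADER: (LEADERLESS_MAX + 1, SHORT_LEADER_MAX),
        LEADERED: (SHORT_LEADER_MAX + 1, cfg.leader_max),
    }
    for plan, cls in zip(proximal, labels):
        plan.leader_class = cls
        lo, hi = ranges[cls]
        plan.leader_length = int(rng.integers(lo, hi + 1))
        if cls == LEADERED:
            plan.stratum = STRATUM_LEADERED_PROXIMAL
    distal = [g for p in plans for g in p[1:]]
    for plan in distal:
        plan.stratum = STRATUM_DISTAL

    for stratum, members in (
        (STRATUM_LEADERED_PROXIMAL, [p for p in proximal if p.stratum]),
        (STRATUM_DISTAL, distal),
    ):
        if not members:
            continue
        pool = [members[i] for i in rng.permutation(len(members))]
        n = len(members)
        for motif in cfg.motifs:
            rate = cfg.sd_positive_rate.get(motif, {}).get(stratum, 0.0)
            n_pos = int(round_half_up(rate * n, 0)) if cfg.exact_counts else int(
                rng.binomial(n, rate)
            )
            if n_pos > len(pool):
                raise InfeasibleConfigError(
                    f"stratum {stratum!r}: not enough genes to plant {n_pos} "
                    f"{motif} positives"
                )
            for plan in pool[:n_pos]:
                plan.positive_motif = motif
                plan.use_alt_start = bool(rng.random() < cfg.alt_start_prob)
            pool = pool[n_pos:]
        for motif in cfg.motifs:
            n_dec = int(round_half_up(cfg.decoy_rate * n, 0)) if cfg.exact_counts else int(
                rng.binomial(n, cfg.decoy_rate)
            )
            n_dec = min(n_dec, len(pool))
            for plan in pool[:n_dec]:
                plan.decoy_motif = motif
            pool = pool[n_dec:]
    return plans


def generate_genome_and_tus(
    cfg: GenomeSimConfig, seed: int | np.random.Generator = 0
) -> SyntheticGenomeData:
    """Random-background genome with planted leader classes and SD motifs.

    Returns the contig, gene models, transcription units and a
    ground-truth table (one row per gene: role, leader length/class,
    per-motif signal and decoy flags, alternative-start offset).
    """
    rng = _rng(seed)
    plans = _allocate_plans(rng, cfg)

    genome_parts: list[str] = []
    pos = 0
    genes: list[GeneModel] = []
    tus: list[TranscriptionUnit] = []
    truth_rows: list[dict] = []
    contig = "synthetic_chr"

    for tu_plans in plans:
        strand = "+" if rng.random() < 0.5 else "-"
        block_parts: list[str] = []
        local_pos = 0
        gene_locals: list[tuple[_GenePlan, int, int, str, int | None]] = []
        for j, plan in enumerate(tu_plans):
            window, cds, alt_d = _compose_gene(rng, cfg, plan)
            if j == 0:
                pad_len = 10 + max(0, (plan.leader_length or 0) - cfg.window_width)
            else:
                pad_len = 10
            pad = _rand_seq(rng, pad_len)
            block_parts += [pad, window, cds]
            cds_local_start = local_pos + pad_len + cfg.window_width + 1  # 1-based
            cds_local_end = cds_local_start + len(cds) - 1
            gene_locals.append((plan, cds_local_start, cds_local_end, cds[:3], alt_d))
            local_pos = cds_local_end

        block = "".join(block_parts)
        L = len(block)
        genome_parts.append(_rand_seq(rng, 20))
        pos += 20
        genome_parts.append(block if strand == "+" else revcomp(block))
        block_off = pos
        pos += L

        cistron_ids = []
        for plan, s_l, e_l, start_codon, alt_d in gene_locals:
            if strand == "+":
                cds_start, cds_end = block_off + s_l, block_off + e_l
            else:
                cds_start = block_off + L - e_l + 1
                cds_end = block_off + L - s_l + 1
            genes.append(
                GeneModel(plan.gene_id, contig, strand, cds_start, cds_end, start_codon)
            )
            cistron_ids.append(plan.gene_id)
            row = {
                "gene_id": plan.gene_id, "tu_id": plan.tu_id, "role": plan.role,
                "strand": strand,
                "leader_length": plan.leader_length,
                "leader_class": plan.leader_class,
                "alt_start_offset": alt_d,
            }
            for m in cfg.motifs:
                row[f"sd_{m}"] = plan.positive_motif == m
                row[f"decoy_{m}"] = plan.decoy_motif == m
            truth_rows.append(row)

        prox_plan, s_l, _, _, _ = gene_locals[0]
        tss_local = s_l - (prox_plan.leader_length or 0)
        tss = block_off + tss_local if strand == "+" else block_off + L - tss_local + 1
        tus.append(TranscriptionUnit(prox_plan.tu_id, contig, strand, tss, tuple(cistron_ids)))

    genome = GenomeRecord(contig, "".join(genome_parts))
    truth = pd.DataFrame(truth_rows)
    truth["leader_length"] = truth["leader_length"].astype("Int64")
    truth["alt_start_offset"] = truth["alt_start_offset"].astype("Int64")
    return SyntheticGenomeData(genome, genes, tus, truth)


# ---------------------------------------------------------------------------
# Junction reads


def _mixture_counts(cfg: JunctionSimConfig, rng: np.random.Generator) -> list[str]:
    labels = [to_rna(normalize_seq(v, context="variant")) for v in cfg.variant_mixture]
    weights = list(cfg.variant_mixture.values())
    if cfg.exact_counts:
        if all(float(w).is_integer() for w in weights) and int(sum(weights)) == cfg.n_reads:
            counts = [int(w) for w in weights]
        else:
            counts = _largest_remainder(weights, cfg.n_reads)
        variants = [v for v, n in zip(labels, counts) for _ in range(n)]
    else:
        p = np.array(weights, dtype=float)
        p = p / p.sum()
        variants = [_choice(rng, labels, p=p) for _ in range(cfg.n_reads)]
    return [variants[i] for i in rng.permutation(len(variants))]


def generate_junction_reads(
    cfg: JunctionSimConfig, seed: int | np.random.Generator = 0
) -> tuple[list[JunctionRead], pd.DataFrame]:
    """Circular-ligation reads: [flank][3'-context][variant | anchor +
    5'-reference][flank], with exact variant counts when requested."""
    rng = _rng(seed)
    anchor = normalize_seq(cfg.anchor, context="anchor")
    ref = normalize_seq(cfg.reference_5prime, context="reference")
    ctx = normalize_seq(cfg.three_prime_context, context="3' context")
    variants = _mixture_counts(cfg, rng)

    reads: list[JunctionRead] = []
    rows: list[dict] = []
    for k, variant in enumerate(variants):
        variant_dna = normalize_seq(variant, context="variant")
        want_decoy = bool(rng.random() < cfg.decoy_anchor_rate)
        for _ in range(cfg.max_resample):
            flank5 = _rand_seq(rng, cfg.flank)
            if want_decoy:
                bad_base = _choice(rng, [b for b in _BASES if b != ref[len(anchor)]])
                flank5 = flank5 + anchor + bad_base
            flank3 = _rand_seq(rng, cfg.flank)
            seq = flank5 + ctx + variant_dna + ref + flank3
            junction = len(flank5) + len(ctx) + len(variant_dna)
            anchor_positions = [
                i for i in range(len(seq) - len(anchor) + 1)
                if seq[i : i + len(anchor)] == anchor
            ]
            expected = {junction} | ({len(flank5) - len(anchor) - 1} if want_decoy else set())
            if set(anchor_positions) != expected:
                continue
            if want_decoy:
                # the true junction must win the downstream-agreement tie-break
                def _score(i: int) -> int:
                    return sum(1 for x, y in zip(seq[i:], ref) if x == y)
                decoy_pos = len(flank5) - len(anchor) - 1
                if _score(decoy_pos) >= _score(junction):
                    continue
            break
        else:
            raise InfeasibleConfigError(
                f"could not compose junction read {k} within {cfg.max_resample} attempts"
            )
        read_id = f"clone{k:03d}"
        reads.append(JunctionRead(read_id, seq))
        rows.append({"read_id": read_id, "true_variant": variant, "junction_index": junction})
    return reads, pd.DataFrame(rows)


def junction_reads_to_fasta(reads: Sequence[JunctionRead], path: str | Path) -> None:
    records = [GenomeRecord(r.read_id, r.seq) for r in reads]
    write_fasta(records, path)


# ---------------------------------------------------------------------------
# Toeprint tables


def generate_toeprint_table(
    cfg: ToeprintSimConfig, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lane table (lane_id, condition, mrna, T, RT) with truncated
    Gaussian noise around the condition means; ``noise_sd=0`` reproduces
    the means exactly.  Conditions with zero replicates are omitted."""
    rng = _rng(seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    for mrna in cfg.mrnas:
        for cond, (t_mean, rt_mean) in cfg.condition_means.items():
            n = cfg.replicates_for(cond)
            for k in range(n):
                if cfg.noise_sd > 0:
                    t = max(0.0, float(rng.normal(t_mean, cfg.noise_sd)))
                    rt = max(0.0, float(rng.normal(rt_mean, cfg.noise_sd)))
                else:
                    t, rt = float(t_mean), float(rt_mean)
                lane_id = f"{mrna}_{cond}_{k + 1}"
                rows.append(
                    {"lane_id": lane_id, "condition": cond, "mrna": mrna, "T": t, "RT": rt}
                )
                truth_rows.append(
                    {"lane_id": lane_id, "true_T_mean": t_mean, "true_RT_mean": rt_mean}
                )
    if not rows:
        raise ValidationError("toeprint config produced no lanes")
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Full dataset


@dataclass
class SyntheticDataset:
    genome_data: SyntheticGenomeData
    junction_reads: list[JunctionRead]
    junction_truth: pd.DataFrame
    toeprint_table: pd.DataFrame
    toeprint_truth: pd.DataFrame


def generate_all(cfg: SimulationConfig) -> SyntheticDataset:
    """All three generators from one root seed via independent substreams."""
    g_ss, j_ss, t_ss = np.random.SeedSequence(cfg.seed).spawn(3)
    genome_data = generate_genome_and_tus(cfg.genome, np.random.default_rng(g_ss))
    reads, j_truth = generate_junction_reads(cfg.junctions, np.random.default_rng(j_ss))
    table, t_truth = generate_toeprint_table(cfg.toeprint, np.random.default_rng(t_ss))
    return SyntheticDataset(genome_data, reads, j_truth, table, t_truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic output as plain text; byte-identical under a
    fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.tsv",
        "tus": outdir / "tus.tsv",
        "gene_truth": outdir / "truth_genes.tsv",
        "junction_reads": outdir / "junction_reads.fa",
        "junction_truth": outdir / "truth_junctions.tsv",
        "toeprint": outdir / "toeprint_lanes.tsv",
        "toeprint_truth": outdir / "truth_toeprint.tsv",
    }
    write_fasta([ds.genome_data.genome], paths["genome"])
    write_gene_table(ds.genome_data.genes, paths["genes"])
    write_tu_table(ds.genome_data.tus, paths["tus"])
    ds.genome_data.truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    junction_reads_to_fasta(ds.junction_reads, paths["junction_reads"])
    ds.junction_truth.to_csv(paths["junction_truth"], sep="\t", index=False)
    ds.toeprint_table.to_csv(paths["toeprint"], sep="\t", index=False)
    ds.toeprint_truth.to_csv(paths["toeprint_truth"], sep="\t", index=False)
    return paths
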