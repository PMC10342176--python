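"""Bulk variant filtering and candidate scoring.

The pipeline: hard-filter each bulk's calls, keep consequence classes that can
break a protein, subtract calls shared between mutant and wildtype bulks, then
score the surviving mutant-specific candidates against the read fractions a
recessive segregating allele must show in both bulks. A candidate is "present"
in a bulk when it survives that bulk's filtered call set; read-level evidence
is consulted only at the scoring stage, mirroring a call-level subtraction
followed by read inspection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from . import mendel
from .formats_io import AnnotatedVariant, normalize_effect
from .mendel import BulkDesign, binomial_consistency, expected_alt_fraction

log = logging.getLogger(__name__)

DEFAULT_CLASSES = frozenset({"missense", "frameshift"})

#: Severity order used for tie-breaking: a frameshift is the most disruptive,
#: then a gained stop, then a missense change; anything else ranks last.
EFFECT_SEVERITY = {"frameshift": 0, "stop_gain": 1, "missense": 2}

VariantKey = tuple[str, int, str, str]
#: (ad_ref, ad_alt) read support at a site in one bulk.
Evidence = tuple[int, int]


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds applied to each bulk's calls.

    ``min_ab`` applies to heterozygous calls only: a het call passes when its
    major-allele balance max(ad_ref, ad_alt)/(ad_ref + ad_alt) is at least
    ``min_ab``. With the 0.8 default this removes balanced heterozygous calls
    and keeps strongly skewed ones — which is what makes a causal allele seen
    in only a minority of wildtype-bulk reads drop out of the wildtype call
    set and therefore survive bulk subtraction. Homozygous-support calls
    (either depth zero) pass the balance check trivially.
    """

    min_ab: float = 0.8
    min_dp: int = 6
    min_gq: int = 0
    min_qd: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_ab <= 1:
            raise ValueError("min_ab must be in [0, 1]")
        if self.min_dp < 0 or self.min_gq < 0 or self.min_qd < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class CandidateScore:
    """Segregation-consistency score of one mutant-specific candidate."""

    variant: AnnotatedVariant
    p_mutant_bulk: float | None = None
    p_wt_bulk: float | None = None
    combined: float | None = None
    effect_rank: int = len(EFFECT_SEVERITY)
    status: str = "ok"  # ok | incompatible | no-evidence
    rank: int | None = None

    @property
    def key(self) -> VariantKey:
        return self.variant.key


@dataclass(frozen=True)
class SnpIndexPoint:
    """Per-site alternate-allele read fraction (the SNP-index)."""

    chrom: str
    pos: int
    snp_index: float


@dataclass(frozen=True)
class IndexWindow:
    """Sliding-window mean of per-site SNP-indices (0-based half-open)."""

    chrom: str
    start0: int
    end0: int
    n_sites: int
    window_mean: float


def hard_filter(
    variants: list[AnnotatedVariant], thresholds: FilterThresholds
) -> list[AnnotatedVariant]:
    """Apply depth / quality / allele-balance hard filters.

    A variant is retained iff dp >= min_dp, gq >= min_gq, qd >= min_qd and its
    allele balance passes (see :class:`FilterThresholds`). Absent GQ or QD
    fields pass their threshold (permissive, logged); absent depth fails
    ``min_dp`` > 0. Stricter thresholds always retain a subset.
    """
    retained = []
    for v in variants:
        reason = _filter_reason(v, thresholds)
        if reason is None:
            retained.append(v)
        else:
            log.debug("dropped %s:%d %s>%s: %s", v.chrom, v.pos, v.ref, v.alt, reason)
    return retained


def _filter_reason(v: AnnotatedVariant, t: FilterThresholds) -> str | None:
    dp = v.dp
    if dp is None and v.ad_ref is not None and v.ad_alt is not None:
        dp = v.ad_ref + v.ad_alt
    if dp is None:
        if t.min_dp > 0:
            return "depth absent"
    elif dp < t.min_dp:
        return f"dp {dp} < {t.min_dp}"
    if v.gq is None:
        if t.min_gq > 0:
            log.debug("%s:%d GQ absent, treated as passing", v.chrom, v.pos)
    elif v.gq < t.min_gq:
        return f"gq {v.gq} < {t.min_gq}"
    if v.qd is None:
        if t.min_qd > 0:
            log.debug("%s:%d QD absent, treated as passing", v.chrom, v.pos)
    elif v.qd < t.min_qd:
        return f"qd {v.qd} < {t.min_qd}"
    ab = v.allele_balance
    if ab is not None and ab < t.min_ab:
        return f"allele balance {ab:.3f} < {t.min_ab}"
    return None


def consequence_filter(
    variants: list[AnnotatedVariant],
    classes: frozenset[str] = DEFAULT_CLASSES,
) -> list[AnnotatedVariant]:
    """Keep variants carrying at least one effect of the requested classes.

    Class matching is case-insensitive and accepts both annotation dialects
    ("missense_variant" and "missense variation").
    """
    wanted = {normalize_effect(c) for c in classes}
    return [
        v
        for v in variants
        if any(normalize_effect(eff) in wanted for eff, _, _ in v.effects)
    ]


def locus_gene_counts(variants: list[AnnotatedVariant]) -> tuple[int, int]:
    """(distinct loci, distinct annotated genes) for a variant set."""
    loci = {v.key for v in variants}
    genes = {g for v in variants for _, g, _ in v.effects if g}
    return len(loci), len(genes)


def bulk_subtract(
    bulk_a: list[AnnotatedVariant], bulk_b: list[AnnotatedVariant]
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Partition two bulks' calls by the identity key (chrom, pos, ref, alt).

    Returns ``(a_specific, b_specific, common)`` where ``common`` holds bulk
    A's records for the shared keys. Duplicate keys within one bulk are an
    error (the caller should have decomposed multi-allelics already).
    """
    a_by_key = _index_unique(bulk_a, "bulk A")
    b_by_key = _index_unique(bulk_b, "bulk B")
    a_specific = [v for k, v in a_by_key.items() if k not in b_by_key]
    b_specific = [v for k, v in b_by_key.items() if k not in a_by_key]
    common = [v for k, v in a_by_key.items() if k in b_by_key]
    return a_specific, b_specific, common


def _index_unique(
    variants: list[AnnotatedVariant], label: str
) -> dict[VariantKey, AnnotatedVariant]:
    index: dict[VariantKey, AnnotatedVariant] = {}
    for v in variants:
        if v.key in index:
            raise ValueError(f"duplicate variant key {v.key} in {label}")
        index[v.key] = v
    return index


def effect_rank(variant: AnnotatedVariant) -> int:
    """Most-severe effect ordinal of a variant (lower = more severe)."""
    ranks = [
        EFFECT_SEVERITY.get(normalize_effect(eff), len(EFFECT_SEVERITY))
        for eff, _, _ in variant.effects
    ]
    return min(ranks, default=len(EFFECT_SEVERITY))


def score_candidates(
    candidates: list[AnnotatedVariant],
    mutant_design: BulkDesign,
    wt_design: BulkDesign,
    mutant_evidence: dict[VariantKey, Evidence],
    wt_evidence: dict[VariantKey, Evidence],
    error_rate: float = mendel.DEFAULT_ERROR_RATE,
    incompatible_floor: float = 0.9,
) -> list[CandidateScore]:
    """Score and rank mutant-specific candidates by segregation consistency.

    For each candidate the mutant-bulk reads are tested against an expected
    alt fraction of 1 and the wildtype-bulk reads against the fraction the
    bulk design predicts (e.g. 0.25 for 3 heterozygotes among 6 plants); the
    two exact binomial p-values are Fisher-combined,
    ``combined = -2 (ln p_mut + ln p_wt)``, so smaller means more consistent.
    Candidates whose mutant-bulk alt fraction falls below ``incompatible_floor``
    cannot be a homozygous causal allele and are flagged ``incompatible``;
    candidates lacking read evidence in either bulk get status ``no-evidence``
    and no rank. Ranking: unflagged before flagged, ascending combined, ties
    broken by effect severity then genomic order.
    """
    f_wt = expected_alt_fraction(wt_design)
    f_mut = expected_alt_fraction(mutant_design)
    scores: list[CandidateScore] = []
    for v in candidates:
        score = CandidateScore(variant=v, effect_rank=effect_rank(v))
        mut_ev = mutant_evidence.get(v.key)
        wt_ev = wt_evidence.get(v.key)
        if mut_ev is None or wt_ev is None or sum(mut_ev) == 0 or sum(wt_ev) == 0:
            score.status = "no-evidence"
            scores.append(score)
            continue
        mut_ref, mut_alt = mut_ev
        wt_ref, wt_alt = wt_ev
        score.p_mutant_bulk = binomial_consistency(
            mut_alt, mut_ref + mut_alt, f_mut, error_rate
        )
        score.p_wt_bulk = binomial_consistency(
            wt_alt, wt_ref + wt_alt, f_wt, error_rate
        )
        score.combined = -2.0 * (
            math.log(score.p_mutant_bulk) + math.log(score.p_wt_bulk)
        )
        if mut_alt / (mut_ref + mut_alt) < incompatible_floor:
            score.status = "incompatible"
        scores.append(score)

    rankable = [s for s in scores if s.status != "no-evidence"]
    rankable.sort(
        key=lambda s: (
            s.status == "incompatible",
            s.combined,
            s.effect_rank,
            s.variant.chrom,
            s.variant.pos,
            s.variant.ref,
            s.variant.alt,
        )
    )
    for i, s in enumerate(rankable, start=1):
        s.rank = i
    unranked = [s for s in scores if s.status == "no-evidence"]
    unranked.sort(key=lambda s: (s.variant.chrom, s.variant.pos))
    return rankable + unranked


def evidence_from_variants(
    variants: list[AnnotatedVariant],
) -> dict[VariantKey, Evidence]:
    """Build a site-evidence table from (unfiltered) VCF records."""
    ev: dict[VariantKey, Evidence] = {}
    for v in variants:
        if v.ad_ref is not None and v.ad_alt is not None:
            ev[v.key] = (v.ad_ref, v.ad_alt)
    return ev


def snp_index(
    variants: list[AnnotatedVariant],
    window_size: int = 1_000_000,
    step: int = 100_000,
) -> tuple[list[SnpIndexPoint], list[IndexWindow]]:
    """Per-site SNP-index and its sliding-window mean.

    The SNP-index of a site is ad_alt / (ad_ref + ad_alt); zero-depth or
    depth-less sites are skipped with a log entry. Windows of ``window_size``
    advance by ``step`` from position 0 of each chromosome; empty windows are
    omitted. Near a causal recessive locus the mutant bulk's index approaches
    1.
    """
    points: list[SnpIndexPoint] = []
    for v in variants:
        f = v.alt_fraction
        if f is None:
            log.debug("snp_index: no depth at %s:%d, skipped", v.chrom, v.pos)
            continue
        points.append(SnpIndexPoint(v.chrom, v.pos, f))
    points.sort(key=lambda p: (p.chrom, p.pos))

    windows: list[IndexWindow] = []
    by_chrom: dict[str, list[SnpIndexPoint]] = {}
    for p in points:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, pts in by_chrom.items():
        max_pos = pts[-1].pos
        start = 0
        while start <= max_pos:
            end = start + window_size
            inside = [p.snp_index for p in pts if start < p.pos <= end]
            if inside:
                windows.append(
                    IndexWindow(chrom, start, end, len(inside),
                                sum(inside) / len(inside))
                )
            start += step
    return points, windows


def write_igv_batch(
    candidates: list[AnnotatedVariant],
    genome_id: str,
    snapshot_dir: str,
    flank_bp: int = 500,
) -> str:
    """Emit an IGV batch script imaging each candidate locus.

    One ``goto``/``snapshot`` pair per candidate with ``flank_bp`` padding on
    each side, in genomic order, after the standard ``new``/``genome``/
    ``snapshotDirectory`` preamble. Feed to IGV's "run batch script".
    """
    lines = ["new", f"genome {genome_id}", f"snapshotDirectory {snapshot_dir}"]
    for v in sorted(candidates, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        start = max(1, v.pos - flank_bp)
        end = v.pos + flank_bp
        lines.append(f"goto {v.chrom}:{start}-{end}")
        lines.append(f"snapshot {v.chrom}_{v.pos}_{v.ref}_{v.alt}.png")
    return "\n".join(lines) + "\n"
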