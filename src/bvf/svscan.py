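"""Large-deletion detection from zero-coverage or zero-expression runs.

A homozygous multi-gene deletion in a bulk leaves a contiguous stretch of the
genome with essentially no aligned reads (DNA evidence) and no transcripts for
the genes inside it (RNA evidence). Both signals are scanned for maximal
sub-threshold runs, and the affected gene models are enumerated. Boundaries
are reported at the resolution of the input windows; no split-read
refinement is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .formats_io import CoverageTrack, GeneModel

log = logging.getLogger(__name__)

#: "No signal" defaults: at most 2 stray reads per window for coverage, at
#: most 0.1 expression units for RNA quantification noise.
DEFAULT_ZERO_COVERAGE = 2.0
DEFAULT_ZERO_EXPRESSION = 0.1
DEFAULT_MIN_LENGTH = 50_000  # suppress single-window dropouts
DEFAULT_MAX_GAP = 2_000  # bridge isolated mis-mapping windows
DEFAULT_MIN_RUN = 3  # consecutive silent genes

_SPLICE_SUFFIX = re.compile(r"\.\d+$")


@dataclass
class DeletionCall:
    """A zero-signal interval (0-based half-open) and the genes it covers."""

    chrom: str
    start0: int
    end0: int
    evidence: str  # "coverage" | "expression"
    mean_signal_inside: float
    mean_signal_flank: float | None = None
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end0 - self.start0


def detect_deletions(
    track: CoverageTrack,
    zero_threshold: float = DEFAULT_ZERO_COVERAGE,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_gap: int = DEFAULT_MAX_GAP,
    genes: list[GeneModel] | None = None,
) -> list[DeletionCall]:
    """Call deletions as maximal runs of sub-threshold coverage windows.

    Runs separated by at most ``max_gap`` bases are merged; merged runs
    shorter than ``min_length`` are discarded. The flank signal is the
    length-weighted mean depth over up to ``min_length`` bases on each side,
    where track windows exist. Gene lists are attached when ``genes`` is
    given.
    """
    if min_length <= 0:
        raise ValueError("min_length must be positive")
    low = [(s, e, d) for s, e, d in track.windows if d <= zero_threshold]
    if not low:
        return []

    groups: list[list[tuple[int, int, float]]] = [[low[0]]]
    for w in low[1:]:
        if w[0] - groups[-1][-1][1] <= max_gap:
            groups[-1].append(w)
        else:
            groups.append([w])

    calls: list[DeletionCall] = []
    for grp in groups:
        start0, end0 = grp[0][0], grp[-1][1]
        if end0 - start0 < min_length:
            continue
        total_len = sum(e - s for s, e, _ in grp)
        inside = sum((e - s) * d for s, e, d in grp) / total_len
        flank = _flank_mean(track, start0, end0, min_length)
        call = DeletionCall(
            chrom=track.chrom,
            start0=start0,
            end0=end0,
            evidence="coverage",
            mean_signal_inside=inside,
            mean_signal_flank=flank,
        )
        if genes is not None:
            call.genes = genes_in_interval(genes, track.chrom, start0, end0)
        calls.append(call)
    return calls


def _flank_mean(
    track: CoverageTrack, start0: int, end0: int, flank_len: int
) -> float | None:
    lo, hi = start0 - flank_len, end0 + flank_len
    num = den = 0.0
    for s, e, d in track.windows:
        for fs, fe in ((lo, start0), (end0, hi)):
            ov = min(e, fe) - max(s, fs)
            if ov > 0:
                num += ov * d
                den += ov
    return num / den if den > 0 else None


def deleted_genes_from_expression(
    expr: dict[str, float],
    genes: list[GeneModel],
    zero_threshold: float = DEFAULT_ZERO_EXPRESSION,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[DeletionCall]:
    """Call deletions as runs of consecutive genes with no expression.

    Genes are walked in genomic order per chromosome; maximal runs of at
    least ``min_run`` consecutive genes whose expression is at or below
    ``zero_threshold`` become calls spanning the first gene's start to the
    last gene's end. A gene missing from the expression table carries no
    evidence and breaks the run. Expression entries for genes absent from
    the annotation are logged and ignored.
    """
    known = {g.gene_id for g in genes}
    for gid in expr:
        if gid not in known:
            log.warning("expression entry %s not in annotation; ignored", gid)

    calls: list[DeletionCall] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, chrom_genes in by_chrom.items():
        run: list[GeneModel] = []
        for g in chrom_genes + [None]:  # type: ignore[list-item]
            silent = (
                g is not None
                and g.gene_id in expr
                and expr[g.gene_id] <= zero_threshold
            )
            if silent:
                run.append(g)
                continue
            if len(run) >= min_run:
                vals = [expr[r.gene_id] for r in run]
                calls.append(
                    DeletionCall(
                        chrom=chrom,
                        start0=run[0].start - 1,
                        end0=run[-1].end,
                        evidence="expression",
                        mean_signal_inside=sum(vals) / len(vals),
                        genes=[r.gene_id for r in run],
                    )
                )
            run = []
    return calls


def genes_in_interval(
    genes: list[GeneModel], chrom: str, start0: int, end0: int
) -> list[str]:
    """Primary gene loci overlapping a half-open interval, sorted by start.

    Splice-variant suffixes (a trailing ``.N``) are collapsed so each primary
    locus is counted once. An unknown chromosome yields an empty list with a
    warning.
    """
    if not any(g.chrom == chrom for g in genes):
        log.warning("no genes annotated on %s", chrom)
        return []
    hits: dict[str, int] = {}
    for g in sorted(genes, key=lambda g: g.start):
        if g.chrom != chrom:
            continue
        # half-open overlap test against the 1-based inclusive gene span
        if g.start - 1 < end0 and g.end > start0:
            primary = _SPLICE_SUFFIX.sub("", g.gene_id)
            hits.setdefault(primary, g.start)
    return sorted(hits, key=lambda gid: hits[gid])


def count_locus_id_range(first_id: str, last_id: str, stride: int = 100) -> int:
    """Count loci in an identifier range with numeric suffixes at a stride.

    Locus identifiers like ``Glyma.11G023700`` end in a zero-padded ordinal
    assigned every ``stride`` units along the chromosome, so the count between
    two loci is ``(suffix_last - suffix_first) / stride + 1``. Both ids must
    share the non-numeric stem (same annotation prefix and chromosome) and the
    suffix difference must align to the stride.
    """
    m1 = re.fullmatch(r"(.*?)(\d+)", first_id)
    m2 = re.fullmatch(r"(.*?)(\d+)", last_id)
    if not m1 or not m2:
        raise ValueError("locus ids must end in a numeric suffix")
    if m1.group(1) != m2.group(1):
        raise ValueError(
            f"locus ids {first_id!r} and {last_id!r} differ outside the "
            f"numeric suffix (different prefix or chromosome)"
        )
    diff = int(m2.group(2)) - int(m1.group(2))
    if diff < 0:
        raise ValueError("last_id precedes first_id")
    if diff % stride != 0:
        raise ValueError(f"suffix difference {diff} not aligned to stride {stride}")
    return diff // stride + 1
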