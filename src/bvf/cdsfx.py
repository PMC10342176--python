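"""Coding-consequence prediction: frameshifts, premature stops, truncations.

Given a gene model, its CDS sequence and a variant, the variant is mapped
from genomic to CDS coordinates (reverse-complemented on the minus strand),
applied, and both sequences translated with the standard nuclear code.
Protein length counts residues before the first in-frame stop, excluding the
stop itself (a 1734 bp CDS encodes 1734/3 - 1 = 577 residues). Only the
primary transcript per gene is considered; variants outside the CDS report
"non-coding" rather than guessing at splice or regulatory effects.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .formats_io import AnnotatedVariant, GeneModel

_VALID = set("ACGT")


class CdsSequenceError(ValueError):
    """Non-ACGT base or reference mismatch inside a CDS."""


@dataclass(frozen=True)
class CodingEffect:
    """Predicted protein-level consequence of a variant on one gene."""

    gene_id: str
    effect_class: str  # synonymous | missense | frameshift | stop_gain | stop_loss
    wt_protein_len: int
    mut_protein_len: int
    stop_codon_position: int | None  # 0-based codon index of first mutant stop
    no_stop: bool = False  # mutant CDS ran off the end without a stop

    @property
    def truncation(self) -> int:
        """Residues lost (negative = extension, only sensible for stop_loss)."""
        return self.wt_protein_len - self.mut_protein_len


def apply_variant_to_cds(
    cds_sequence: str, variant: AnnotatedVariant, gene: GeneModel
) -> tuple[str | None, str]:
    """Apply a variant to a transcript-orientation CDS sequence.

    Returns ``(mutant_cds, status)`` where status is ``"coding"`` or
    ``"non-coding"`` (variant outside every CDS segment; no edit performed).
    An edit whose reference span crosses a CDS/intron boundary is rejected
    with a ValueError, as its transcript consequence is undefined without a
    splicing model.
    """
    segs = sorted(gene.cds_segments)
    if len(cds_sequence) != sum(e - s + 1 for s, e in segs):
        raise ValueError(
            f"CDS sequence length {len(cds_sequence)} does not match gene "
            f"model {gene.gene_id} ({sum(e - s + 1 for s, e in segs)} bp)"
        )
    # work in genomic orientation; flip back at the end for minus strand
    genomic_cds = (
        str(Seq(cds_sequence).reverse_complement())
        if gene.strand == "-"
        else cds_sequence
    )

    span_start, span_end = variant.pos, variant.pos + len(variant.ref) - 1
    offset = None
    cum = 0
    for s, e in segs:
        if s <= span_start <= e:
            if span_end > e:
                raise ValueError(
                    f"variant {variant.chrom}:{variant.pos} {variant.ref}>"
                    f"{variant.alt} spans a CDS/intron boundary of {gene.gene_id}"
                )
            offset = cum + (span_start - s)
            break
        if span_start < s and span_end >= s:
            raise ValueError(
                f"variant {variant.chrom}:{variant.pos} {variant.ref}>"
                f"{variant.alt} spans a CDS/intron boundary of {gene.gene_id}"
            )
        cum += e - s + 1
    if offset is None:
        return None, "non-coding"

    ref = variant.ref.upper()
    observed = genomic_cds[offset : offset + len(ref)].upper()
    if observed != ref:
        raise CdsSequenceError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: CDS has "
            f"{observed!r}, variant claims {ref!r}"
        )
    mutant_genomic = (
        genomic_cds[:offset] + variant.alt.upper() + genomic_cds[offset + len(ref):]
    )
    mutant = (
        str(Seq(mutant_genomic).reverse_complement())
        if gene.strand == "-"
        else mutant_genomic
    )
    return mutant, "coding"


def _check_bases(cds: str, label: str) -> None:
    for i, base in enumerate(cds.upper()):
        if base not in _VALID:
            raise CdsSequenceError(f"{label}: non-ACGT base {base!r} at position {i + 1}")


def _translate_to_stop(cds: str) -> tuple[int, bool]:
    """(residues before first in-frame stop, ran_off_end_without_stop)."""
    aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = aa.find("*")
    if stop == -1:
        return len(aa), True
    return stop, False


def translate_and_classify(
    wt_cds: str, mut_cds: str, gene_id: str = ""
) -> CodingEffect:
    """Translate wildtype and mutant CDS and classify the consequence.

    Frameshift when the length difference is not a multiple of 3; otherwise
    the stop structure decides: an earlier mutant stop is a stop gain, a lost
    terminal stop is a stop loss, an altered protein of equal stop behaviour
    is missense, an identical protein synonymous.
    """
    wt_cds, mut_cds = wt_cds.upper(), mut_cds.upper()
    _check_bases(wt_cds, "wildtype CDS")
    _check_bases(mut_cds, "mutant CDS")
    wt_len, wt_no_stop = _translate_to_stop(wt_cds)
    if wt_no_stop:
        raise ValueError("wildtype CDS has no in-frame stop codon")
    mut_len, no_stop = _translate_to_stop(mut_cds)

    indel = len(wt_cds) - len(mut_cds)
    if indel % 3 != 0:
        effect = "frameshift"
    elif wt_cds == mut_cds:
        effect = "synonymous"
    elif no_stop or mut_len > wt_len - indel // 3:
        # the in-frame length change cannot explain a longer protein: the
        # original stop was destroyed
        effect = "stop_loss"
    elif mut_len < wt_len - indel // 3:
        # stop appears earlier than the in-frame length change explains
        effect = "stop_gain"
    else:
        wt_aa = str(Seq(wt_cds).translate())[:wt_len]
        mut_aa = str(Seq(mut_cds).translate())[:mut_len]
        effect = "synonymous" if wt_aa == mut_aa else "missense"
    return CodingEffect(
        gene_id=gene_id,
        effect_class=effect,
        wt_protein_len=wt_len,
        mut_protein_len=mut_len,
        stop_codon_position=None if no_stop else mut_len,
        no_stop=no_stop,
    )


def truncation_report(wt_len: int, mut_len: int) -> int:
    """Residues lost to truncation; negative values flag an extension."""
    if wt_len < 0 or mut_len < 0:
        raise ValueError("protein lengths must be >= 0")
    return wt_len - mut_len


def extract_cds(genome: dict[str, str] | object, gene: GeneModel) -> str:
    """Extract a gene's transcript-orientation CDS from a genome sequence.

    ``genome`` maps chromosome name to sequence (a pyfaidx.Fasta works).
    """
    chrom_seq = genome[gene.chrom]
    parts = [str(chrom_seq[s - 1 : e]) for s, e in sorted(gene.cds_segments)]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds.upper()


def predict_effect(
    genome: dict[str, str] | object,
    gene: GeneModel,
    variant: AnnotatedVariant,
) -> CodingEffect | None:
    """End-to-end effect prediction for one variant on one gene.

    Returns None for non-coding placement.
    """
    wt = extract_cds(genome, gene)
    mut, status = apply_variant_to_cds(wt, variant, gene)
    if status != "coding" or mut is None:
        return None
    return translate_and_classify(wt, mut, gene_id=gene.gene_id)
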