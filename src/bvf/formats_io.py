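"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: VCF and GFF3 are 1-based inclusive on disk; bedGraph
is 0-based half-open. All internal interval arithmetic uses 0-based half-open
coordinates, converted at this I/O boundary.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import cyvcf2
import gffutils

log = logging.getLogger(__name__)

# SnpEff emits machine-readable effect terms ("missense_variant") while report
# text often uses the human-readable dialect ("missense variation"); both are
# normalized to a bare class word for matching in normalize_effect().


class VcfParseError(ValueError):
    """Malformed VCF content."""


class BedGraphError(ValueError):
    """Malformed or unsorted bedGraph content."""


def normalize_effect(effect: str) -> str:
    """Collapse an annotation effect term to a bare lower-case class word.

    ``"missense_variant"``, ``"Missense variation"`` -> ``"missense"``;
    ``"stop_gained"``/``"stop gain"`` -> ``"stop"`` is avoided by special-casing
    the stop classes (``stop_gained`` -> ``stop_gain``, ``stop_lost`` ->
    ``stop_loss``). Compound terms joined by ``&`` must be split by the caller.
    """
    e = effect.strip().lower().replace(" ", "_")
    if e in ("stop_gained", "stop_gain"):
        return "stop_gain"
    if e in ("stop_lost", "stop_loss"):
        return "stop_loss"
    for suffix in ("_variant", "_variation"):
        if e.endswith(suffix):
            e = e[: -len(suffix)]
    return e


@dataclass(frozen=True)
class AnnotatedVariant:
    """One biallelic variant with per-bulk allele depths and annotations.

    ``ad_ref``/``ad_alt`` are ``None`` when the source record carried no AD
    field; such records are retained but flagged downstream. ``effects`` holds
    ``(effect_class, gene_id, transcript_id)`` triples parsed from the ANN
    annotation, with the effect class kept verbatim (normalize on use).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qd: float | None = None
    gq: int | None = None
    dp: int | None = None
    ad_ref: int | None = None
    ad_alt: int | None = None
    effects: tuple[tuple[str, str, str], ...] = ()

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vclass(self) -> str:
        if len(self.ref) < len(self.alt):
            return "insertion"
        if len(self.ref) > len(self.alt):
            return "deletion"
        return "snp"

    @property
    def allele_balance(self) -> float | None:
        """Major-allele read fraction, or None without usable depths."""
        if self.ad_ref is None or self.ad_alt is None:
            return None
        total = self.ad_ref + self.ad_alt
        if total == 0:
            return None
        return max(self.ad_ref, self.ad_alt) / total

    @property
    def alt_fraction(self) -> float | None:
        if self.ad_ref is None or self.ad_alt is None:
            return None
        total = self.ad_ref + self.ad_alt
        if total == 0:
            return None
        return self.ad_alt / total


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with its CDS segments in transcription (5'->3') order."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    cds_segments: tuple[tuple[int, int], ...] = ()  # 1-based inclusive, 5'->3'

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass
class CoverageTrack:
    """Windowed read-depth signal for one chromosome (0-based half-open)."""

    chrom: str
    windows: list[tuple[int, int, float]] = field(default_factory=list)


def _parse_ann(ann_value: str, alt: str) -> tuple[tuple[str, str, str], ...]:
    """Parse SnpEff-style ANN entries matching one alternate allele."""
    effects: list[tuple[str, str, str]] = []
    for entry in ann_value.split(","):
        sub = entry.split("|")
        if not sub or sub[0] != alt:
            continue
        raw_effect = sub[1] if len(sub) > 1 else ""
        gene_id = sub[4] if len(sub) > 4 else ""
        transcript_id = sub[6] if len(sub) > 6 else ""
        for eff in raw_effect.split("&"):
            if eff:
                effects.append((eff, gene_id, transcript_id))
    return tuple(effects)


def _validate_vcf_header(path: str) -> None:
    opener = open
    if str(path).endswith(".gz"):
        import gzip

        opener = gzip.open  # type: ignore[assignment]
    with opener(path, "rt") as fh:  # type: ignore[arg-type]
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise VcfParseError(
                f"{path}: line 1: missing ##fileformat=VCF header line"
            )
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                return
            raise VcfParseError(
                f"{path}: line {lineno}: expected #CHROM column header, "
                f"got {line[:40]!r}"
            )
    raise VcfParseError(f"{path}: no #CHROM column header found")


def read_vcf(path: str, sample: str | None = None) -> list[AnnotatedVariant]:
    """Read a VCF into AnnotatedVariant records for one sample.

    Multi-allelic records are decomposed into one record per alternate allele
    (sharing the site-level DP/GQ/QD). ``sample`` names the column to read;
    a single-sample file needs no selector. Records without an AD field are
    retained with allele depths absent.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_vcf_header(path)
    vcf = cyvcf2.VCF(path)
    samples = list(vcf.samples)
    if sample is None:
        if len(samples) > 1:
            raise ValueError(
                f"{path} has {len(samples)} samples {samples}; pass sample="
            )
        sidx = 0 if samples else None
    else:
        if sample not in samples:
            raise ValueError(f"sample {sample!r} not in {path} ({samples})")
        sidx = samples.index(sample)

    out: list[AnnotatedVariant] = []
    for rec in vcf:
        qd = rec.INFO.get("QD")
        # htslib stores INFO floats in single precision; round away the
        # float32 noise so values round-trip through write_vcf
        qd = round(float(qd), 4) if qd is not None else None
        ann = rec.INFO.get("ANN")

        gq = dp = None
        ad = None
        if sidx is not None:
            try:
                gqs = rec.format("GQ")
                if gqs is not None and gqs[sidx][0] >= 0:
                    gq = int(gqs[sidx][0])
            except KeyError:
                pass
            try:
                dps = rec.format("DP")
                if dps is not None and dps[sidx][0] >= 0:
                    dp = int(dps[sidx][0])
            except KeyError:
                pass
            try:
                ads = rec.format("AD")
                if ads is not None and int(ads[sidx][0]) >= 0:
                    ad = [int(x) for x in ads[sidx]]
            except KeyError:
                pass
        if dp is None:
            info_dp = rec.INFO.get("DP")
            dp = int(info_dp) if info_dp is not None else None

        for i, alt in enumerate(rec.ALT):
            ad_ref = ad_alt = None
            if ad is not None:
                ad_ref = ad[0]
                ad_alt = ad[i + 1] if len(ad) > i + 1 else 0
            effects = _parse_ann(str(ann), alt) if ann is not None else ()
            out.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    qd=qd,
                    gq=gq,
                    dp=dp,
                    ad_ref=ad_ref,
                    ad_alt=ad_alt,
                    effects=effects,
                )
            )
    vcf.close()
    return out


def write_vcf(
    variants: list[AnnotatedVariant],
    path: str,
    sample: str = "SAMPLE",
    extra_header_lines: list[str] | None = None,
) -> None:
    """Write biallelic AnnotatedVariant records to a single-sample VCF 4.2.

    Genotype is inferred from allele depths (0/0, 0/1 or 1/1) since the domain
    type does not carry a call; records re-read with :func:`read_vcf` compare
    equal to the input.
    """
    chroms = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            info_parts = []
            if v.qd is not None:
                info_parts.append(f"QD={v.qd:g}")
            if v.effects:
                ann = ",".join(
                    f"{v.alt}|{eff}|MODIFIER|{gene}|{gene}|transcript|{tx}|"
                    for eff, gene, tx in v.effects
                )
                info_parts.append(f"ANN={ann}")
            info = ";".join(info_parts) if info_parts else "."
            if v.ad_ref is None or v.ad_alt is None:
                gt, ad_str = "./.", "."
            else:
                if v.ad_alt == 0:
                    gt = "0/0"
                elif v.ad_ref == 0:
                    gt = "1/1"
                else:
                    gt = "0/1"
                ad_str = f"{v.ad_ref},{v.ad_alt}"
            dp_str = str(v.dp) if v.dp is not None else "."
            gq_str = str(v.gq) if v.gq is not None else "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t"
                f"GT:AD:DP:GQ\t{gt}:{ad_str}:{dp_str}:{gq_str}\n"
            )


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    One GeneModel per ``gene`` feature; CDS segments are collected through the
    first mRNA child (or directly-parented CDS) and ordered 5'->3' in the
    transcript orientation. CDS features whose Parent resolves to no gene are
    skipped with a warning.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    known_parents: set[str] = set()
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        known_parents.add(gene.id)
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if mrnas:
            parent = mrnas[0]
            known_parents.update(m.id for m in mrnas)
        else:
            parent = gene
        segs = [
            (c.start, c.end)
            for c in db.children(parent, featuretype="CDS", order_by="start")
        ]
        if gene.strand == "-":
            segs = segs[::-1]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds_segments=tuple(segs),
            )
        )
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or all(p not in known_parents for p in parents):
            log.warning("CDS at %s:%d-%d has no parent gene; skipped",
                        cds.seqid, cds.start, cds.end)
    return genes


def read_coverage(path: str) -> dict[str, CoverageTrack]:
    """Read a bedGraph into per-chromosome CoverageTracks.

    Windows must be sorted and non-overlapping within each chromosome;
    overlapping or unsorted input is rejected with a hint to sort.
    """
    tracks: dict[str, CoverageTrack] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise BedGraphError(f"{path}: line {lineno}: expected 4 columns")
            chrom, s, e, d = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if e <= s:
                raise BedGraphError(f"{path}: line {lineno}: end <= start")
            if d < 0:
                raise BedGraphError(f"{path}: line {lineno}: negative depth")
            track = tracks.setdefault(chrom, CoverageTrack(chrom=chrom))
            if track.windows and s < track.windows[-1][1]:
                raise BedGraphError(
                    f"{path}: line {lineno}: unsorted or overlapping interval; "
                    f"sort with `sort -k1,1 -k2,2n`"
                )
            track.windows.append((s, e, d))
    return tracks


def write_bedgraph(tracks: dict[str, CoverageTrack], path: str,
                   header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for chrom in sorted(tracks):
            for s, e, d in tracks[chrom].windows:
                fh.write(f"{chrom}\t{s}\t{e}\t{d:g}\n")


def read_expression(path: str) -> dict[str, float]:
    """Read a two-column gene-id/value TSV into a dict (empty file -> {})."""
    expr: dict[str, float] = {}
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"\t|,", line)
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if first_data_line:
                first_data_line = False
                if parts[0].lower() in ("gene", "gene_id", "id"):
                    continue
            expr[parts[0]] = float(parts[1])
    return expr


def write_expression(expr: dict[str, float], path: str,
                     header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene_id\tvalue\n")
        for gene_id in expr:
            fh.write(f"{gene_id}\t{expr[gene_id]:g}\n")
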