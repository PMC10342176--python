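"""Synthetic mutagenized-family bulk-sequencing experiments.

The generator emulates the data a mapping-by-sequencing study produces
without touching real reads: a selfed heterozygous parent yields progeny
segregating 3:1 for a recessive causal allele; mutant-phenotype and
wildtype-phenotype plants are pooled into bulks; each variant site receives
Poisson read depth and binomial alternate-read counts with sequencing error;
background induced variants (shared and bulk-specific, homozygous and
segregating-heterozygous) provide the nuisance load that defeats naive
allele-frequency peak methods. An optional large deletion zeroes coverage
and expression over a gene block for the structural-variant scanner.

All outputs are written in the pipeline's input formats (FASTA, GFF3, VCF,
bedGraph, expression TSV), so a simulated scenario exercises the pipeline
end to end. Identical seed and scenario give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .formats_io import (
    AnnotatedVariant,
    CoverageTrack,
    GeneModel,
    write_bedgraph,
    write_expression,
    write_vcf,
)

CHROM = "Chr01"
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)

#: Annotation-class mix for background variants. The heavy synonymous and
#: intergenic load provides the decoys the consequence filter must remove.
EFFECT_MIX = (
    ("synonymous_variant", 0.40),
    ("missense_variant", 0.30),
    ("intergenic_region", 0.20),
    ("frameshift_variant", 0.05),
    ("stop_gained", 0.05),
)


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one synthetic family / bulk-sequencing experiment.

    Defaults describe a compact but complete experiment: a 2 Mb genome with
    200 genes, 1,000 background induced variants of which half are shared
    between bulks, 30x pooled depth with 1% sequencing error, and bulks of
    4 mutant plants and 6 wildtype-phenotype plants of which 3 are known
    heterozygotes (so the causal allele is expected in a quarter of
    wildtype-bulk reads).
    """

    seed: int = 0
    genome_length: int = 2_000_000
    n_genes: int = 200
    n_background_variants: int = 1_000
    shared_fraction: float = 0.5
    causal_gene_index: int = 100
    causal_effect: str = "frameshift"  # or "missense"
    causal_indel_length: int = 4
    bulk_mutant_n: int = 4
    bulk_wt_n: int = 6
    wt_het_count: int | str = 3  # or "random"
    mean_depth: float = 30.0
    error_rate: float = 0.01
    het_background_fraction: float = 0.5
    artifact_fraction: float = 0.05  # low-quality junk calls
    deletion: tuple[int, int] | None = None  # 0-based half-open
    coverage_window: int = 1_000

    def __post_init__(self) -> None:
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction in [0,1]")
        if not 0 <= self.causal_gene_index < self.n_genes:
            raise ValueError("causal gene outside gene count")
        if min(self.genome_length, self.n_genes, self.bulk_mutant_n,
               self.bulk_wt_n, self.n_background_variants) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment, for recovery tests."""

    causal_key: tuple[str, int, str, str] | None
    causal_gene_id: str | None
    mutant_bulk_genotypes: list[str]
    wt_bulk_genotypes: list[str]
    wt_het_count: int
    true_wt_alt_fraction: float
    deletion: tuple[int, int] | None = None
    deleted_gene_ids: list[str] = field(default_factory=list)


@dataclass
class SimResult:
    """In-memory simulated experiment plus its ground truth."""

    scenario: SimScenario
    truth: SimTruth
    genome: dict[str, str]
    genes: list[GeneModel]
    mutant_variants: list[AnnotatedVariant]  # the mutant bulk's "VCF"
    wt_variants: list[AnnotatedVariant]
    mutant_evidence: dict[tuple[str, int, str, str], tuple[int, int]]
    wt_evidence: dict[tuple[str, int, str, str], tuple[int, int]]
    mutant_coverage: dict[str, CoverageTrack]
    wt_coverage: dict[str, CoverageTrack]
    expression: dict[str, float]  # mutant-bulk RNA signal


def draw_progeny(n: int, rng: np.random.Generator) -> list[str]:
    """Draw selfed-heterozygote progeny genotypes (1 MM : 2 Mm : 1 mm)."""
    codes = rng.choice(["MM", "Mm", "mm"], size=n, p=[0.25, 0.5, 0.25])
    return list(codes)


def simulate_family(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> SimTruth:
    """Assemble phenotype bulks from a segregating selfed family.

    Progeny are drawn from Mendelian proportions until both bulks are filled
    (mutant phenotype iff mm). With ``wt_het_count`` fixed, the wildtype
    bulk's composition is forced to that many heterozygotes; with
    ``"random"`` it is drawn conditional on the wildtype phenotype (2/3
    carriers).
    """
    if rng is None:
        rng = np.random.default_rng([scenario.seed, 0])
    need_mut, need_wt = scenario.bulk_mutant_n, scenario.bulk_wt_n
    mutant_bulk: list[str] = []
    wt_bulk: list[str] = []
    max_draws = 1000 * (need_mut + need_wt)
    drawn = 0
    while len(mutant_bulk) < need_mut or len(wt_bulk) < need_wt:
        if drawn >= max_draws:
            raise RuntimeError("bulk sizes unattainable within draw budget")
        g = draw_progeny(1, rng)[0]
        drawn += 1
        if g == "mm" and len(mutant_bulk) < need_mut:
            mutant_bulk.append(g)
        elif g != "mm" and len(wt_bulk) < need_wt:
            wt_bulk.append(g)
    if scenario.wt_het_count != "random":
        h = int(scenario.wt_het_count)
        if not 0 <= h <= need_wt:
            raise ValueError("wt_het_count outside bulk size")
        wt_bulk = ["Mm"] * h + ["MM"] * (need_wt - h)
    het = sum(1 for g in wt_bulk if g == "Mm")
    return SimTruth(
        causal_key=None,
        causal_gene_id=None,
        mutant_bulk_genotypes=mutant_bulk,
        wt_bulk_genotypes=wt_bulk,
        wt_het_count=het,
        true_wt_alt_fraction=het / (2 * need_wt),
        deletion=scenario.deletion,
    )


def _random_genome(length: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, 4, size=length)
    return np.frombuffer(b"ACGT", dtype="S1")[idx].tobytes().decode()


def _make_orf(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + TAA; length 3*n_codons."""
    middle = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    return "ATG" + "".join(middle) + "TAA"


# Gene layout constants: three 300 bp CDS exons separated by 200 bp introns.
_EXON_OFFSETS = ((0, 300), (500, 800), (1000, 1300))
_GENE_SPAN = 1300
_GENE_MARGIN = 2000


def _build_genome_and_genes(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel]]:
    seq = list(_random_genome(scenario.genome_length, rng))
    spacing = scenario.genome_length // scenario.n_genes
    if spacing < _GENE_SPAN + _GENE_MARGIN + 100:
        raise ValueError("genome too short for the requested gene count")
    genes: list[GeneModel] = []
    for i in range(scenario.n_genes):
        start = i * spacing + _GENE_MARGIN + 1  # 1-based
        segs = tuple(
            (start + s, start + e - 1) for s, e in _EXON_OFFSETS
        )
        strand = "+" if i % 2 == 0 else "-"
        orf = _make_orf(300, rng)
        genomic_cds = orf if strand == "+" else str(Seq(orf).reverse_complement())
        k = 0
        for s, e in segs:
            seg_len = e - s + 1
            seq[s - 1 : e] = genomic_cds[k : k + seg_len]
            k += seg_len
        gene_segs = segs if strand == "+" else segs[::-1]
        genes.append(
            GeneModel(
                gene_id=f"Syn.01G{(i + 1) * 100:06d}",
                chrom=CHROM,
                start=start,
                end=start + _GENE_SPAN - 1,
                strand=strand,
                cds_segments=gene_segs,
            )
        )
    return {CHROM: "".join(seq)}, genes


def _draw_effect_classes(n: int, rng: np.random.Generator) -> list[str]:
    labels = [e for e, _ in EFFECT_MIX]
    probs = [p for _, p in EFFECT_MIX]
    return list(rng.choice(labels, size=n, p=probs))


@dataclass
class _SiteSpec:
    pos: int
    ref: str
    alt: str
    effect: str
    gene_id: str
    in_mutant: bool
    in_wt: bool
    f_mutant: float
    f_wt: float
    artifact: bool
    is_causal: bool = False


def _plan_sites(
    truth: SimTruth,
    scenario: SimScenario,
    genome: str,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> list[_SiteSpec]:
    spacing = scenario.genome_length // scenario.n_genes

    # causal site: an indel (or SNP) inside the third exon of the causal gene
    causal_gene = genes[scenario.causal_gene_index]
    seg = causal_gene.cds_segments[2]
    lo, hi = min(seg), max(seg)
    if scenario.causal_effect == "frameshift":
        L = scenario.causal_indel_length
        pos = int(rng.integers(lo + 5, hi - L - 5))
        ref = genome[pos - 1 : pos + L]
        alt = ref[0]
        causal_class = "frameshift_variant"
    else:
        pos = int(rng.integers(lo + 5, hi - 5))
        ref = genome[pos - 1]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        causal_class = "missense_variant"
    sites = [
        _SiteSpec(
            pos=pos,
            ref=ref,
            alt=alt,
            effect=causal_class,
            gene_id=causal_gene.gene_id,
            in_mutant=True,
            in_wt=True,
            f_mutant=1.0,
            f_wt=truth.true_wt_alt_fraction,
            artifact=False,
            is_causal=True,
        )
    ]
    causal_span = set(range(pos, pos + len(ref)))

    n = scenario.n_background_variants
    positions = rng.choice(
        np.arange(10, scenario.genome_length - 10), size=3 * n, replace=False
    )
    positions = [int(p) for p in positions if p not in causal_span][:n]
    classes = _draw_effect_classes(n, rng)
    membership = rng.random(n)
    zygosity = rng.random(n)
    carrier = rng.uniform(0.2, 1.0, size=n)
    artifact = rng.random(n) < scenario.artifact_fraction
    for j, p in enumerate(positions):
        ref = genome[p - 1]
        if classes[j] == "frameshift_variant":
            dl = int(rng.integers(1, 3))  # 1 or 2 bp deletion decoy
            ref = genome[p - 1 : p + dl]
            alt = ref[0]
        else:
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        gene_id = genes[min((p - 1) // spacing, len(genes) - 1)].gene_id
        shared = membership[j] < scenario.shared_fraction
        in_mut = shared or membership[j] < (1 + scenario.shared_fraction) / 2
        in_wt = shared or not in_mut
        if artifact[j]:
            f = float(rng.uniform(0.05, 0.3))
            in_mut, in_wt = (True, False) if rng.random() < 0.5 else (False, True)
            f_mut = f if in_mut else 0.0
            f_wt = f if in_wt else 0.0
        elif zygosity[j] < scenario.het_background_fraction:
            f = 0.5 * carrier[j]
            f_mut = f if in_mut else 0.0
            f_wt = f if in_wt else 0.0
        else:
            f_mut = 1.0 if in_mut else 0.0
            f_wt = 1.0 if in_wt else 0.0
        sites.append(
            _SiteSpec(
                pos=p,
                ref=ref,
                alt=alt,
                effect=classes[j],
                gene_id=gene_id,
                in_mutant=in_mut,
                in_wt=in_wt,
                f_mutant=f_mut,
                f_wt=f_wt,
                artifact=bool(artifact[j]),
            )
        )
    sites.sort(key=lambda s: s.pos)
    return sites


#: A bulk "calls" a site when at least this many alt reads at this fraction
#: support it (a rough model of a caller's heterozygous sensitivity).
CALL_MIN_ALT = 2
CALL_MIN_FRACTION = 0.2


def simulate_reads(
    truth: SimTruth,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Generate the read-level evidence and all derived inputs of a scenario.

    At every variant site, each bulk draws depth ~ Poisson(mean_depth) and
    alternate reads ~ Binomial(depth, f') with f' the true pool fraction
    shifted by the sequencing error rate. A site enters a bulk's VCF when it
    would plausibly be called (>= 2 alt reads at >= 20% fraction); full read
    evidence at every site is kept separately, standing in for read-level
    inspection of candidate loci. The optional deletion zeroes the mutant
    bulk's coverage and expression over its interval.
    """
    if rng is None:
        rng = np.random.default_rng([scenario.seed, 1])
    genome_map, genes = _build_genome_and_genes(scenario, rng)
    genome = genome_map[CHROM]
    sites = _plan_sites(truth, scenario, genome, genes, rng)
    err = scenario.error_rate

    mutant_variants: list[AnnotatedVariant] = []
    wt_variants: list[AnnotatedVariant] = []
    mutant_evidence: dict = {}
    wt_evidence: dict = {}
    for s in sites:
        key = (CHROM, s.pos, s.ref, s.alt)
        if s.is_causal:
            truth.causal_key = key
            truth.causal_gene_id = s.gene_id
        for bulk, f, present in (
            ("mutant", s.f_mutant, s.in_mutant),
            ("wt", s.f_wt, s.in_wt),
        ):
            depth = int(rng.poisson(scenario.mean_depth))
            # a read error loses an alt-supporting read with probability err,
            # but converts a ref read into this specific alt base only a
            # third of the time (three possible wrong bases)
            f_obs = f * (1 - err) + (1 - f) * err / 3.0
            alt = int(rng.binomial(depth, f_obs)) if depth > 0 else 0
            ev = (depth - alt, alt)
            called = alt >= CALL_MIN_ALT and depth > 0 and alt / depth >= CALL_MIN_FRACTION
            if s.artifact:
                qd = float(rng.uniform(0.2, 1.9))
                gq = int(rng.integers(5, 40))
            else:
                qd = float(rng.uniform(15.0, 35.0))
                gq = 99
            if bulk == "mutant":
                mutant_evidence[key] = ev
            else:
                wt_evidence[key] = ev
            if called:
                v = AnnotatedVariant(
                    chrom=CHROM,
                    pos=s.pos,
                    ref=s.ref,
                    alt=s.alt,
                    qd=round(qd, 2),
                    gq=gq,
                    dp=depth,
                    ad_ref=depth - alt,
                    ad_alt=alt,
                    effects=((s.effect, s.gene_id, s.gene_id + ".1"),),
                )
                (mutant_variants if bulk == "mutant" else wt_variants).append(v)

    mutant_coverage = {
        CHROM: _coverage_track(scenario, rng, deletion=scenario.deletion)
    }
    wt_coverage = {CHROM: _coverage_track(scenario, rng, deletion=None)}

    expression: dict[str, float] = {}
    deleted: list[str] = []
    for g in genes:
        in_del = scenario.deletion is not None and (
            g.start - 1 < scenario.deletion[1] and g.end > scenario.deletion[0]
        )
        if in_del:
            expression[g.gene_id] = 0.0
            deleted.append(g.gene_id)
        else:
            expression[g.gene_id] = float(np.round(rng.lognormal(3.0, 1.0), 3))
    truth.deleted_gene_ids = deleted
    truth.deletion = scenario.deletion

    return SimResult(
        scenario=scenario,
        truth=truth,
        genome=genome_map,
        genes=genes,
        mutant_variants=mutant_variants,
        wt_variants=wt_variants,
        mutant_evidence=mutant_evidence,
        wt_evidence=wt_evidence,
        mutant_coverage=mutant_coverage,
        wt_coverage=wt_coverage,
        expression=expression,
    )


def _coverage_track(
    scenario: SimScenario,
    rng: np.random.Generator,
    deletion: tuple[int, int] | None,
) -> CoverageTrack:
    w = scenario.coverage_window
    starts = np.arange(0, scenario.genome_length, w)
    track = CoverageTrack(chrom=CHROM)
    for s0 in starts:
        e0 = min(s0 + w, scenario.genome_length)
        frac_outside = 1.0
        if deletion is not None:
            ov = min(e0, deletion[1]) - max(s0, deletion[0])
            if ov > 0:
                frac_outside = 1.0 - ov / (e0 - s0)
        lam = scenario.mean_depth * frac_outside + 0.05
        track.windows.append((int(s0), int(e0), float(rng.poisson(lam))))
    return track


def simulate(scenario: SimScenario) -> SimResult:
    """Run the full generator: family, then reads and derived files."""
    truth = simulate_family(scenario)
    return simulate_reads(truth, scenario)


def large_deletion_scenario(seed: int = 0, **overrides) -> SimScenario:
    """Default large-deletion scenario: a 300 kb block spanning the causal
    gene is absent from the mutant genome (zero DNA coverage, zero RNA)."""
    params = dict(seed=seed, deletion=(850_000, 1_150_000))
    params.update(overrides)
    return SimScenario(**params)


# ---------------------------------------------------------------------------
# serialization

def write_gff3(genes: list[GeneModel], path: str, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if comment:
            fh.write(f"# {comment}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            # exon lengths are multiples of 3 here, so every phase is 0
            for i, (s, e) in enumerate(sorted(g.cds_segments)):
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_site_evidence(
    evidence: dict[tuple[str, int, str, str], tuple[int, int]],
    path: str,
    comment: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("chrom\tpos\tref\talt\tad_ref\tad_alt\n")
        for (chrom, pos, ref, alt), (ad_ref, ad_alt) in sorted(evidence.items()):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{ad_ref}\t{ad_alt}\n")


def read_site_evidence(
    path: str,
) -> dict[tuple[str, int, str, str], tuple[int, int]]:
    ev: dict[tuple[str, int, str, str], tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, ref, alt, ad_ref, ad_alt = line.split("\t")
            ev[(chrom, int(pos), ref, alt)] = (int(ad_ref), int(ad_alt))
    return ev


def write_truth_json(truth: SimTruth, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)
        fh.write("\n")


def write_scenario_dir(
    result: SimResult,
    outdir: str,
    include: tuple[str, ...] = (
        "vcf", "evidence", "fasta", "gff", "coverage", "expression", "truth",
    ),
) -> dict[str, str]:
    """Serialize a SimResult into a directory of pipeline input files."""
    os.makedirs(outdir, exist_ok=True)
    tag = f"simbulk seed={result.scenario.seed}"
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    if "vcf" in include:
        write_vcf(result.mutant_variants, p("mutant.vcf"), sample="mutant_bulk",
                  extra_header_lines=[f"##source={tag}"])
        write_vcf(result.wt_variants, p("wildtype.vcf"), sample="wt_bulk",
                  extra_header_lines=[f"##source={tag}"])
    if "evidence" in include:
        write_site_evidence(result.mutant_evidence, p("mutant_evidence.tsv"), tag)
        write_site_evidence(result.wt_evidence, p("wildtype_evidence.tsv"), tag)
    if "fasta" in include:
        write_fasta(result.genome, p("genome.fa"))
    if "gff" in include:
        write_gff3(result.genes, p("genes.gff3"), tag)
    if "coverage" in include:
        write_bedgraph(result.mutant_coverage, p("mutant_coverage.bedgraph"), tag)
        write_bedgraph(result.wt_coverage, p("wildtype_coverage.bedgraph"), tag)
    if "expression" in include:
        write_expression(result.expression, p("expression.tsv"), tag)
    if "truth" in include:
        write_truth_json(result.truth, p("truth.json"))
    return paths


# ---------------------------------------------------------------------------
# synthetic worked example for truncation arithmetic

def synthetic_truncation_cds() -> tuple[str, int, int]:
    """A synthetic 1734 bp ORF on which a 4 bp deletion truncates 577 -> 380 aa.

    Returns ``(wt_cds, deletion_start, deletion_length)`` with the deletion
    start 1-based in CDS coordinates. The sequence is engineered (not a real
    gene): 578 codons of benign filler with a TGA planted in the shifted
    reading frame so the first post-deletion stop falls at codon 381, giving
    a 380-residue product — the structural shape of a frameshift that removes
    a third of a protein.
    """
    n_codons, del_start, del_len = 578, 1090, 4
    codons = ["GAA"] * n_codons
    codons[0] = "ATG"
    codons[-1] = "TAA"
    codons[381] = "ATG"  # wt codon 382: supplies T,G of the shifted-frame TGA
    codons[382] = "AAA"  # wt codon 383: supplies the A
    wt = "".join(codons)
    assert len(wt) == 1734
    mut = wt[: del_start - 1] + wt[del_start - 1 + del_len :]
    # sanity: construction yields the intended lengths
    from .cdsfx import translate_and_classify

    eff = translate_and_classify(wt, mut)
    assert eff.effect_class == "frameshift"
    assert (eff.wt_protein_len, eff.mut_protein_len) == (577, 380), eff
    return wt, del_start, del_len
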