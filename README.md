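# bvf — bulk variant filtering for mapping-by-sequencing

`bvf` identifies the causal mutation behind a recessive phenotype from
bulked-segregant sequencing of a selfed mutant family. Given per-bulk VCFs
(with allele depths and SnpEff-style annotations) from a mutant-phenotype
pool and a wildtype-phenotype pool, it hard-filters calls, keeps
protein-breaking consequences (missense / frameshift), subtracts calls
shared between the bulks, and ranks the mutant-specific survivors by how
well their read fractions match Mendelian expectation. It also detects
large multi-gene deletions from zero-coverage or zero-expression runs, and
predicts CDS-level consequences (frameshifts, premature stops, truncated
protein lengths).

It is written for geneticists mapping induced mutations in selfing crops
(or any organism where a heterozygous parent is selfed and progeny bulks
are sequenced), as an automated, testable alternative to spreadsheet
filtering and manual genome-browser triage.

## The statistic at the core

Under monogenic recessive inheritance from a selfed heterozygote, the
mutant bulk is fixed for the causal allele (expected alternate-read
fraction f = 1), while a wildtype bulk of *n* plants containing *h* known
heterozygous carriers shows

    f_wt = h / (2n)            (known composition)
    f_wt = (2/3)(1/2) = 1/3    (composition unknown, 3:1 family)

For each candidate, `bvf` computes exact two-sided binomial p-values of the
observed allele depths against f = 1 (mutant bulk) and f_wt (wildtype
bulk), and combines them with Fisher's method:

    combined = -2 (ln p_mut + ln p_wt)

Smaller is more consistent with causality. Candidates whose mutant-bulk
alternate fraction falls below 0.9 cannot be homozygous in the mutant bulk
and are flagged `incompatible`. Phenotype segregation itself is tested with
a Pearson chi-square against 3:1 (df = 1).

## Worked example

Simulate a complete experiment (2 Mb genome, 200 genes, a planted 4 bp
frameshift deletion, 1,000 background variants, 30× bulks of 4 mutant / 6
wildtype plants with 3 heterozygotes), then run the pipeline:

```sh
bvf simulate --seed 4 --out demo
bvf run --mutant-vcf demo/mutant.vcf --wt-vcf demo/wildtype.vcf \
        --mutant-evidence demo/mutant_evidence.tsv \
        --wt-evidence demo/wildtype_evidence.tsv \
        --design mutant:n=4 --design wildtype:n=6,het=3 \
        --out demo/report
```

which prints

```
top candidate: Chr01:1003222 TCGTT>T combined=1.63
report in demo/report
```

and `demo/report/candidates.tsv` begins

```
rank  chrom  pos      ref    alt  vclass    effects             genes          p_mutant_bulk  p_wt_bulk  combined  status
1     Chr01  1003222  TCGTT  T    deletion  frameshift_variant  Syn.01G010100  1              0.4433     1.627     ok
2     Chr01  574934   G      A    snp       missense_variant    Syn.01G005800  1              0.007113   9.892     ok
```

The rank-1 candidate is the planted causal frameshift (`demo/truth.json`
confirms the key `Chr01:1003222 TCGTT>T`): all 27 mutant-bulk reads carry
the deletion (p_mut = 1 against f = 1) and the wildtype bulk carries it in
roughly a quarter of reads (p_wt = 0.44 against f = 0.25). The runner-up is
a mutant-specific background variant: perfectly homozygous in the mutant
bulk, but with essentially no wildtype-bulk support (p_wt = 0.007) — absent
where a causal recessive allele must be present. `stage_counts.tsv` records
the funnel (here 610 raw mutant-bulk calls → 44 mutant-specific candidates
in 40 genes), and `igv_batch.txt` is ready for IGV's *run batch script* to
snapshot every ranked locus.

The segregation test on pooled phenotype counts (39 mutants among 227
plants):

```
$ bvf segtest --mutant 39 --wildtype 188
chi2    df      p
7.4023  1       0.006514
```

Other subcommands: `filter`, `subtract`, `score`, `snp-index`, `svscan`
(deletion detection from bedGraph coverage or an expression table),
`consequence` (protein-level effect prediction from FASTA + GFF3 + VCF) and
`igv-batch`. Every command is a thin wrapper over the library modules
(`bvf.prioritize`, `bvf.mendel`, `bvf.svscan`, `bvf.cdsfx`,
`bvf.simbulk`), which can be used directly from Python.

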