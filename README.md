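# snvmart

A desk-scale SNV allele-frequency **data mart** for population genetics.
`snvmart` pre-processes a multi-population VCF into a compact indexed store of
per-population allele and genotype counts, then serves batch queries — by
rs-number list, nucleotide range or gene-symbol list — over any combination of
populations or continental groups, reporting for every site the statistics a
population geneticist reads off first:

| column | meaning |
|---|---|
| MA / MAF | minor allele and its frequency |
| H_OBS | observed heterozygosity (fraction of heterozygous individuals) |
| H_EXP | expected heterozygosity (gene diversity), `1 − Σ pⱼ²` |
| F_IS | within-population inbreeding, `1 − H_OBS/H_EXP` |
| F_ST | between-group differentiation, `(H_T − H_S)/H_T` with copy-count-weighted H_S |
| class | F_ST colour step: `<0.05` low, `<0.15` moderate, `<0.25` high, `≥0.25` very high |
| I_n | Rosenberg informativeness for assignment, `Σⱼ[−p̄ⱼ ln p̄ⱼ + Σᵢ (pᵢⱼ/K) ln pᵢⱼ]` |
| call rate | typed samples over samples selected |

Threshold filters (MAF, F_ST) refine any query; a genome-wide F_ST scan
computes per-site values across a chosen grouping with 1-Mb window means, an
upper-2.5%-tail flag and a top-hit table (F_ST > 0.9); and individual
genotypes for any query can be exported in Structure format. Because the mart
stores integer counts, merging populations is exact — pooled statistics equal
statistics of the concatenated raw genotypes. A Balding–Nichols simulator
generates VCF + panel + BED fixtures with tunable differentiation F, so the
whole pipeline is testable without any external download.

It is aimed at population-genetics and forensic-genetics researchers who want
batched, scriptable variant summaries (ancestry-informative marker screens,
selection-signal scans, frequency lookups by gene) rather than one-SNP-at-a-time
browsing.

## Worked example

Build a mart from the bundled deterministic example dataset (a
lactase-persistence-style marker, rs4988235 in MCM6, typed in four continental
groups) and query it:

```sh
python -c "import snvmart; snvmart.make_figure1_fixture('example')"
snvmart build --vcf example/figure1.vcf --panel example/figure1.panel \
        --genes example/figure1_genes.bed --ancestral example/figure1_ancestral.txt \
        --out example/figure1.mart
snvmart query example/figure1.mart --pops AFR,EUR,EAS,AME --genes MCM6
```

The query prints a TSV whose rs4988235 row reads (columns abridged):

```
variant_id  chrom  pos        genes  ref  anc  N    minor  maf    h_obs  h_exp    f_is      f_st      f_st_class  i_n       call_rate
rs4988235   2      136608646  MCM6   G    G    100  A      0.285  0.25   0.40755  0.386578  0.327199  very_high   0.168925  1
```

Read: across 100 individuals the derived allele A has pooled frequency 0.285,
but its frequency differs sharply between the groups (0.70 in EUR vs 0.04 in
AFR), so the between-group F_ST of 0.327 lands in the `very_high` colour class
— the hallmark of a locus under strong local positive selection. The same mart
answers region queries (`--region 2:136500000-136650000`), rs-lists
(`--rs-file ids.txt`), merged-pool queries (`--merge`), threshold filters
(`--min-maf 0.05 --min-fst 0.25`), genome scans (`snvmart scan`) and Structure
export (`snvmart export`). Simulated datasets of any size come from
`snvmart simulate --pops 4 --samples 50 --sites 20000 --fst 0.1 --seed 42
--out DIR`.

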