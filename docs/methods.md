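# Methods

## What the tool computes

`snvmart` summarizes diploid SNV genotypes from a multi-population VCF into a
pre-computed store — one record of allele copy counts, heterozygote count,
typed-sample count and haploid-call count per (population, variant) — and then
answers batch queries (rs-number lists, nucleotide ranges, gene-symbol lists)
over arbitrary combinations of populations or continental groups. Because the
store keeps **integer counts** rather than frequencies, merging populations is
exact: pooling any subset and recomputing a frequency gives precisely the
frequency of the concatenated raw genotypes. Frequencies, being ratios of the
stored integers, are always derivable; the reverse is not true. This is the one
deliberate strengthening over a frequency-per-grouping store, and it is why
population combinations can be formed at query time instead of being
pre-enumerated.

## Statistics

Let site j have allele frequencies `p_j` within a selection and let K units
(populations or pooled continental groups) be compared.

- **MAF / minor allele** — the second-ranked allele by frequency, ties broken
  alphabetically after the descending-frequency sort. Monomorphic sites report
  MAF 0 and minor allele `NA` (not the reference allele at frequency 1).
- **H_OBS** — heterozygous individuals over diploid typed individuals. Haploid
  calls contribute one allele copy to the frequencies but are excluded from
  both numerator and denominator of H_OBS, since a single-allele call carries
  no heterozygosity information.
- **H_EXP** — gene diversity `1 − Σ p_j²`, *uncorrected*. The `2n/(2n−1)`
  small-sample correction is intentionally omitted: the uncorrected form is a
  function of pooled counts alone, so merging populations and computing H_EXP
  commutes with pooling. The cost is a downward bias of order `1/(2n)` at
  small n.
- **F_IS** — `1 − H_OBS/H_EXP`; `NA` when H_EXP = 0.
- **F_ST** — the heterozygosity-partition (Nei G_ST-style) estimator
  `(H_T − H_S)/H_T`, where H_S is the within-unit gene diversity averaged with
  allele-copy-count weights and H_T is the gene diversity of the pooled
  counts. This estimator was chosen because it is computable from the
  summarized per-population counts alone — the defining constraint of the
  architecture. Weir–Cockerham θ needs genotype-level variance components the
  store does not keep and is out of scope. Consequences to keep in mind:
  G_ST is biased upward relative to the generative model's F at finite sample
  size (visible as ≈ +0.007 at 2N = 100 in the recovery runs) and compresses
  toward 0 for highly diverse markers. Negative values (possible under
  sampling noise) are clamped to 0; a pooled-monomorphic site reports `NA`,
  never 0 — absence of variation is not absence of differentiation.
- **F_ST colour class** — `[0, 0.05)` low, `[0.05, 0.15)` moderate,
  `[0.15, 0.25)` high, `[0.25, 1]` very high. The boundaries are half-open on
  the left value; the labels drive downstream display and the `>= 0.25` filter
  convention.
- **I_n** — Rosenberg's informativeness for assignment,
  `Σ_j [ −p̄_j ln p̄_j + Σ_i (p_ij/K) ln p_ij ]` with natural logs, the
  *unweighted* mean frequency `p̄_j` across the K units, and `0·ln 0 := 0`.
  Bounded by `ln K`; 0 iff all unit spectra are identical.
- **call rate** — typed individuals over samples in the selection.

Between-unit statistics (F_ST, I_n) are reported only when at least two units
are compared side by side (`merge=False` with ≥ 2 selection codes); a merged
or single-unit selection shows within-pool statistics and `NA` for both. Units
that carry zero allele copies at a site (all calls missing) are dropped from
the between-unit comparison; if fewer than two remain, both statistics are
`NA`.

## Genome-wide F_ST scan

Per-site F_ST is computed across an explicit grouping for every stored site.
Sites with undefined F_ST are excluded from the empirical distribution, the
windows and the flags. Window means use non-overlapping fixed-width windows
aligned to position 1 (`[1, w], [w+1, 2w], …`; default w = 1 Mb). The "upper
2.5%" flag is made precise as: with n defined values and quantile q (default
0.975), `k = ceil((1 − q)·n)` sites form the nominal tail, the threshold is
the k-th largest value, and every site **≥** the threshold is flagged — so
ties at the threshold are all flagged and at least one site is always
flagged. A separate absolute-threshold table (default F_ST > 0.9) lists top
hits with gene annotation and rs-number.

## Input conventions and degenerate cases

- Only SNVs are retained (single-base REF and every ALT); indels and SVs are
  skipped and counted. Multi-allelic SNVs (up to 3 ALTs) are kept.
- Variant identity: a VCF ID beginning `rs` is used verbatim; otherwise a
  `chrom:pos:ref:alt` key is synthesized. Duplicate ids keep the first record.
- Phased (`|`) and unphased (`/`) separators are equivalent; `.` alleles are
  missing. A haploid GT contributes one copy.
- Chromosome names are taken verbatim (no `chr` normalization); region queries
  must match the VCF's dialect. Regions and gene intervals are 1-based fully
  closed internally; BED input is converted on read (`start+1`, `end`).
- Ancestral alleles come from an optional two-column lookup table (variant id,
  allele); ids absent from the table render `NA`.
- Structure export recodes A=1, C=2, G=3, T=4, missing −9; two rows per
  individual, haploid calls leave −9 in the second row; numeric population
  codes are assigned by sorted population name and written to a `.legend`
  sidecar. Genotype export always re-reads the raw VCF — the mart holds only
  summaries.

## Synthetic data generator

The generator emulates unlinked biallelic SNVs in K demes under the
Balding–Nichols model: per site an ancestral frequency `p ~ U(0.05, 0.95)`,
then each population's frequency from `Beta(p(1−F)/F, (1−p)(1−F)/F)` — mean
p, variance `p(1−p)F` — followed by Hardy–Weinberg genotype draws within each
population and i.i.d. missingness. Defaults are the package's standard
recovery conditions: 4 populations × 50 diploid samples × 20,000 sites,
F = 0.10, 2% missing calls, seed 42 (the seed is recorded in the VCF header).
What it deliberately does **not** model: linkage and haplotype structure,
demography beyond the single F parameter, selective sweeps, and
sequencing/genotyping error — so passing recovery tests demonstrates correct
arithmetic and calibrated differentiation under an idealized frequency model,
not robustness to low-coverage calling artifacts in real resequencing data.
Because the G_ST estimator is biased relative to the model's F, recovery is
asserted against an independent frequency-level oracle evaluated on the same
simulated frequencies (tolerance ±0.03 on the mean over 20,000 sites), plus
monotonicity of the mean estimate in F over {0.02, 0.1, 0.3} — not against
the analytic F itself.

A second, fully deterministic fixture hand-codes a worked example: a marker
labelled rs4988235 inside a gene labelled MCM6 with four continental groups
(derived-allele copy counts 35/2/5/15 out of 50, giving F_ST ≈ 0.327, the
very-high colour class — the classic lactase-persistence differentiation
signal), alongside a fixed-difference site (F_ST = 1), a monomorphic site, a
triallelic site, missing and haploid calls, and one indel that the SNV filter
must skip. Rebuilding it is byte-identical.

## Numerical and design choices

- Undefined statistics are `None` in memory and `NA` in TSV/JSON output.
- Floats are rendered with `%.6g`, making repeated identical queries
  byte-identical.
- Tiny negative values of I_n from floating-point cancellation are floored at
  0 (the literal sum can land at −1e−17 for identical spectra).
- The store is SQLite (read-only connections at query time); the contract is
  indexed lookup on variant id, (chrom, pos) and gene symbol, not the engine.
- Gene overlap uses an interval tree built once per build pass.
- Problem sizes in the test-suite fixtures (120-site simulated dataset,
  8-site worked example, 20,000-site recovery runs) were chosen so every
  oracle comparison is exhaustive at desk scale.

## Known limitations

- Biallelic-only simulator (the query path itself handles triallelic sites).
- No Weir–Cockerham θ, no haplotype/LD statistics, no HWE tests, no
  significance assessment of F_ST outliers.
- H_EXP and G_ST carry the small-sample biases discussed above; compare
  values across selections of similar size.
- The scan treats chromosomes independently and reports tables, not plots.
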