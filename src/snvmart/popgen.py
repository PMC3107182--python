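"""Per-site population-genetics statistics from summarized allele counts.

Every statistic displayed for a variant site is computable from the
per-population summaries alone: allele copy counts, the heterozygote count,
the number of typed individuals and the number of haploid calls. This is
what makes a pre-summarized data mart sufficient — no raw genotypes are
needed at query time.

Conventions
-----------
* ``None`` is the undefined marker (rendered ``NA`` downstream): H_OBS with
  no diploid individuals, F_IS with H_EXP = 0, F_ST at a pooled-monomorphic
  site.
* H_EXP is the uncorrected gene diversity ``1 - sum(p_j**2)`` — no
  ``2n/(2n-1)`` small-sample correction, so pooling populations and then
  computing equals computing on the pooled counts.
* F_ST is the heterozygosity-partition (Nei G_ST-style) estimator
  ``(H_T - H_S) / H_T`` with H_S weighted by allele-copy totals; it needs
  only the mart's counts. Negative sampling-noise values are clamped to 0.
* I_n is Rosenberg's informativeness for assignment with natural logs and
  the unweighted across-population mean frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import SelectionError

ALLELES = ("A", "C", "G", "T")

#: Colour-step boundaries for the F_ST class labels.
FST_CLASS_BOUNDS = (0.05, 0.15, 0.25)
FST_CLASSES = ("low", "moderate", "high", "very_high")

# FrequencySpectrum is a plain mapping allele -> frequency in [0, 1].
FrequencySpectrum = Dict[str, float]


@dataclass(frozen=True)
class AlleleCounts:
    """Summarized genotype information for one (population, site) pair.

    Parameters
    ----------
    counts
        Allele symbol -> copy count. Diploid typed individuals contribute
        two copies, haploid calls one.
    het_count
        Individuals carrying two distinct alleles.
    n_typed
        Individuals with a non-missing genotype (diploid or haploid).
    n_haploid
        Typed individuals with a single-allele call.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    het_count: int = 0
    n_typed: int = 0
    n_haploid: int = 0

    @property
    def total_copies(self) -> int:
        return sum(self.counts.values())

    @property
    def n_diploid(self) -> int:
        return self.n_typed - self.n_haploid

    def validate(self) -> None:
        """Check the bookkeeping invariants; raise ``ValueError`` on breach."""
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative allele copy count")
        if min(self.het_count, self.n_typed, self.n_haploid, 0) < 0:
            raise ValueError("negative count field")
        if self.total_copies != 2 * self.n_diploid + self.n_haploid:
            raise ValueError(
                f"copy total {self.total_copies} inconsistent with "
                f"{self.n_typed} typed / {self.n_haploid} haploid individuals"
            )
        if self.het_count > self.n_diploid:
            raise ValueError("more heterozygotes than diploid individuals")


def allele_frequencies(c: AlleleCounts) -> FrequencySpectrum:
    """Relative frequency of each allele; empty spectrum when no copies."""
    total = c.total_copies
    if total == 0:
        return {}
    return {a: n / total for a, n in c.counts.items() if n > 0}


def minor_allele(freqs: FrequencySpectrum) -> Tuple[Optional[str], float]:
    """Second-most-frequent allele and its frequency (the MA and MAF).

    Ties are broken alphabetically after sorting by descending frequency,
    so ``{A: 0.5, G: 0.5}`` has major allele A and minor allele G.
    Monomorphic or empty spectra return ``(None, 0.0)``.
    """
    ranked = sorted(
        ((a, f) for a, f in freqs.items() if f > 0.0),
        key=lambda item: (-item[1], item[0]),
    )
    if len(ranked) < 2:
        return None, 0.0
    allele, freq = ranked[1]
    return allele, freq


def observed_heterozygosity(c: AlleleCounts) -> Optional[float]:
    """Proportion of diploid typed individuals that are heterozygous.

    Haploid calls carry no heterozygosity information and are excluded
    from both numerator and denominator. ``None`` when no diploid
    individuals were typed.
    """
    if c.n_diploid == 0:
        return None
    return c.het_count / c.n_diploid


def expected_heterozygosity(freqs: FrequencySpectrum) -> float:
    """Gene diversity ``1 - sum(p_j**2)``, uncorrected."""
    return 1.0 - sum(f * f for f in freqs.values())


def inbreeding_fis(h_obs: Optional[float], h_exp: float) -> Optional[float]:
    """Within-population inbreeding coefficient ``1 - H_OBS / H_EXP``.

    Undefined (``None``) when the site is monomorphic (H_EXP = 0) or when
    H_OBS itself is undefined.
    """
    if h_obs is None or h_exp == 0.0:
        return None
    return 1.0 - h_obs / h_exp


def pool_counts(groups: Sequence[AlleleCounts]) -> AlleleCounts:
    """Field-wise integer sum of count records — exact population merging."""
    if not groups:
        raise SelectionError("cannot pool an empty selection of populations")
    counts: Dict[str, int] = {}
    het = typed = haploid = 0
    for g in groups:
        for a, n in g.counts.items():
            counts[a] = counts.get(a, 0) + n
        het += g.het_count
        typed += g.n_typed
        haploid += g.n_haploid
    return AlleleCounts(counts=counts, het_count=het, n_typed=typed, n_haploid=haploid)


def fst_among(groups: Sequence[AlleleCounts]) -> Optional[float]:
    """Among-group differentiation ``(H_T - H_S) / H_T``.

    H_S is the allele-copy-weighted mean within-group gene diversity and
    H_T the gene diversity of the pooled counts. Returns ``None`` when the
    pooled site is monomorphic (H_T = 0); small negative sampling-noise
    values are clamped to 0.
    """
    if len(groups) < 2:
        raise SelectionError("F_ST requires at least two groups")
    totals = [g.total_copies for g in groups]
    if any(t == 0 for t in totals):
        raise SelectionError("F_ST requires at least one allele copy per group")
    grand = sum(totals)
    h_s = sum(
        (t / grand) * expected_heterozygosity(allele_frequencies(g))
        for g, t in zip(groups, totals)
    )
    h_t = expected_heterozygosity(allele_frequencies(pool_counts(groups)))
    if h_t == 0.0:
        return None
    return max(0.0, (h_t - h_s) / h_t)


def informativeness_in(groups: Sequence[FrequencySpectrum]) -> float:
    """Rosenberg informativeness for assignment, I_n.

    ``I_n = sum_j [ -pbar_j ln pbar_j + sum_i (p_ij / K) ln p_ij ]`` where
    ``pbar_j`` is the unweighted mean frequency of allele j over the K
    groups and ``0 ln 0 := 0``. Bounded by ``ln K``; zero iff all spectra
    are identical.
    """
    k = len(groups)
    if k < 2:
        raise SelectionError("I_n requires at least two groups")
    alleles = sorted({a for g in groups for a in g})

    def xlogx(x: float) -> float:
        return 0.0 if x <= 0.0 else x * math.log(x)

    total = 0.0
    for a in alleles:
        p = [g.get(a, 0.0) for g in groups]
        pbar = sum(p) / k
        total += -xlogx(pbar) + sum(xlogx(pi) for pi in p) / k
    # exact-arithmetic floor: tiny negatives from float cancellation
    return max(0.0, total)


def fst_class(f_st: float) -> str:
    """Colour-step label for an F_ST value.

    Half-open bins on the left boundary: ``[0, 0.05)`` low, ``[0.05, 0.15)``
    moderate, ``[0.15, 0.25)`` high, ``[0.25, 1]`` very_high.
    """
    if not 0.0 <= f_st <= 1.0:
        raise ValueError(f"F_ST must lie in [0, 1], got {f_st!r}")
    for bound, label in zip(FST_CLASS_BOUNDS, FST_CLASSES):
        if f_st < bound:
            return label
    return FST_CLASSES[-1]


def call_rate(c: AlleleCounts, n_samples_in_selection: int) -> float:
    """Fraction of selected samples with a non-missing genotype."""
    if n_samples_in_selection <= 0:
        raise ValueError("selection contains no samples")
    if c.n_typed > n_samples_in_selection:
        raise ValueError("more typed individuals than samples in selection")
    return c.n_typed / n_samples_in_selection


@dataclass(frozen=True)
class SiteStatistics:
    """The statistics-tab values for one site over one selection."""

    maf: float
    minor_allele: Optional[str]
    h_obs: Optional[float]
    h_exp: float
    f_is: Optional[float]
    f_st: Optional[float]
    f_st_class: Optional[str]
    i_n: Optional[float]
    call_rate: float


def site_statistics(
    units: Sequence[AlleleCounts],
    n_samples_in_selection: int,
    between: bool = True,
) -> SiteStatistics:
    """Compute every per-site statistic for a selection of count units.

    Within-selection statistics (MAF, H_OBS, H_EXP, F_IS, call rate) are
    computed on the pooled counts. Between-unit statistics (F_ST, I_n) are
    computed across the units when ``between`` is true and at least two
    units carry allele copies; otherwise they are undefined.
    """
    pooled = pool_counts(units)
    freqs = allele_frequencies(pooled)
    ma, maf = minor_allele(freqs)
    h_obs = observed_heterozygosity(pooled)
    h_exp = expected_heterozygosity(freqs)
    f_is = inbreeding_fis(h_obs, h_exp)
    f_st = i_n = cls = None
    if between:
        informative = [u for u in units if u.total_copies > 0]
        if len(informative) >= 2:
            f_st = fst_among(informative)
            i_n = informativeness_in([allele_frequencies(u) for u in informative])
            cls = fst_class(f_st) if f_st is not None else None
    rate = call_rate(pooled, n_samples_in_selection)
    return SiteStatistics(
        maf=maf,
        minor_allele=ma,
        h_obs=h_obs,
        h_exp=h_exp,
        f_is=f_is,
        f_st=f_st,
        f_st_class=cls,
        i_n=i_n,
        call_rate=rate,
    )
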