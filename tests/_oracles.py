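"""Independent brute-force oracles, evaluated literally from raw genotypes.

Everything here works on a "raw genotype matrix": one list per group, each
individual a tuple of allele letters (length 2 diploid, length 1 haploid)
or None when missing. Nothing imports the package's statistics code — the
formulas are spelled out directly so the oracles stay an independent check
on the implementation.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, List, Optional, Sequence, Tuple

Genotype = Optional[Tuple[str, ...]]
Group = Sequence[Genotype]


def copy_counter(group: Group) -> Counter:
    c: Counter = Counter()
    for gt in group:
        if gt is not None:
            c.update(gt)
    return c


def freqs(group: Group) -> Dict[str, float]:
    c = copy_counter(group)
    total = sum(c.values())
    return {a: n / total for a, n in c.items()} if total else {}


def minor_allele(group: Group) -> Tuple[Optional[str], float]:
    f = freqs(group)
    ranked = sorted(f.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = [(a, x) for a, x in ranked if x > 0]
    return ranked[1] if len(ranked) >= 2 else (None, 0.0)


def h_obs(group: Group) -> Optional[float]:
    diploid = [gt for gt in group if gt is not None and len(gt) == 2]
    if not diploid:
        return None
    return sum(1 for gt in diploid if gt[0] != gt[1]) / len(diploid)


def h_exp(group: Group) -> float:
    return 1.0 - sum(p * p for p in freqs(group).values())


def f_is(group: Group) -> Optional[float]:
    ho, he = h_obs(group), h_exp(group)
    if ho is None or he == 0.0:
        return None
    return 1.0 - ho / he


def call_rate(group: Group) -> float:
    return sum(1 for gt in group if gt is not None) / len(group)


def pooled(groups: Sequence[Group]) -> List[Genotype]:
    out: List[Genotype] = []
    for g in groups:
        out.extend(g)
    return out


def f_st(groups: Sequence[Group]) -> Optional[float]:
    """(H_T - H_S) / H_T with allele-copy-count weights, clamped at 0."""
    totals = [sum(copy_counter(g).values()) for g in groups]
    grand = sum(totals)
    h_s = sum((t / grand) * h_exp(g) for g, t in zip(groups, totals))
    h_t = h_exp(pooled(groups))
    if h_t == 0.0:
        return None
    return max(0.0, (h_t - h_s) / h_t)


def informativeness(groups: Sequence[Group]) -> float:
    """Rosenberg I_n with natural logs and unweighted mean frequencies."""
    spectra = [freqs(g) for g in groups]
    k = len(spectra)
    alleles = sorted({a for s in spectra for a in s})
    total = 0.0
    for a in alleles:
        p = [s.get(a, 0.0) for s in spectra]
        pbar = sum(p) / k
        term = -(pbar * math.log(pbar)) if pbar > 0 else 0.0
        for pi in p:
            if pi > 0:
                term += (pi * math.log(pi)) / k
        total += term
    return total


def gst_from_freqs(q, weights=None):
    """Vectorized biallelic G_ST directly from a (sites, pops) frequency array.

    Unweighted mean over populations (equal weights) unless ``weights``
    (per-population allele-copy totals, same shape) is given.
    """
    import numpy as np

    q = np.asarray(q, dtype=float)
    if weights is None:
        h_s = (2.0 * q * (1.0 - q)).mean(axis=1)
        qbar = q.mean(axis=1)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum(axis=1, keepdims=True)
        h_s = (w * 2.0 * q * (1.0 - q)).sum(axis=1)
        qbar = (w * q).sum(axis=1)
    h_t = 2.0 * qbar * (1.0 - qbar)
    with __import__("numpy").errstate(invalid="ignore", divide="ignore"):
        g = (h_t - h_s) / h_t
    return g


def upper_tail_flags(values, quantile):
    """Tie-inclusive upper-tail flags: k = ceil((1-q) n), threshold = k-th largest."""
    import numpy as np

    v = np.asarray(values, dtype=float)
    n = len(v)
    k = max(1, math.ceil((1.0 - quantile) * n))
    thr = np.sort(v)[::-1][k - 1]
    return v >= thr, float(thr)


def random_genotype_matrix(rng, max_groups=4, max_individuals=30, max_alleles=3):
    """A random raw genotype matrix for oracle-equivalence sweeps.

    Ensures every group carries at least one allele copy so every
    statistic is defined at the group level.
    """
    alleles = list("AGT")[: rng.integers(2, max_alleles + 1)]
    k = rng.integers(2, max_groups + 1)
    groups = []
    for _ in range(k):
        n = int(rng.integers(2, max_individuals + 1))
        probs = rng.dirichlet([1.0] * len(alleles))
        group: List[Genotype] = []
        for _ in range(n):
            r = rng.random()
            if r < 0.05:
                group.append(None)
            elif r < 0.10:
                group.append((str(rng.choice(alleles, p=probs)),))
            else:
                a = str(rng.choice(alleles, p=probs))
                b = str(rng.choice(alleles, p=probs))
                group.append((a, b))
        if not any(gt for gt in group):
            group[0] = (alleles[0], alleles[0])
        groups.append(group)
    return groups


def to_allele_counts(group: Group):
    """Package AlleleCounts built by plain tallying of a raw group."""
    from snvmart.popgen import AlleleCounts

    c = copy_counter(group)
    typed = [gt for gt in group if gt is not None]
    return AlleleCounts(
        counts=dict(c),
        het_count=sum(1 for gt in typed if len(gt) == 2 and gt[0] != gt[1]),
        n_typed=len(typed),
        n_haploid=sum(1 for gt in typed if len(gt) == 1),
    )
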