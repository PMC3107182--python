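"""Turn mart lookups into the per-site statistics table, filters and scans.

The statistics table has a fixed column set mirroring what a population
geneticist wants per site: identity and location, gene context, reference
and ancestral alleles, the alleles actually observed in the selection,
sample count, MAF and minor allele, observed/expected heterozygosity,
F_IS, F_ST with its colour class, I_n and the call rate.

Between-group statistics (F_ST, I_n) are only defined when at least two
selection units are compared side by side (``merge=False``); a merged or
single-unit selection reports within-pool statistics and NA for both.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import popgen
from .errors import QueryError, SelectionError
from .io import PanelMap, read_vcf, write_structure
from .mart import Mart, MartRecord, select_counts
from .popgen import AlleleCounts, allele_frequencies, pool_counts, site_statistics

NA = "NA"

#: Fixed output column order of the statistics table.
SITE_SUMMARY_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "genes",
    "ref_allele",
    "ancestral_allele",
    "observed_alleles",
    "populations",
    "n_samples",
    "minor_allele",
    "maf",
    "h_obs",
    "h_exp",
    "f_is",
    "f_st",
    "f_st_class",
    "i_n",
    "call_rate",
)

QUERY_MODES = ("rs_list", "region", "gene_list")


@dataclass(frozen=True)
class Filters:
    """Inclusive per-site threshold filters on MAF and F_ST."""

    maf_min: Optional[float] = None
    maf_max: Optional[float] = None
    fst_min: Optional[float] = None
    fst_max: Optional[float] = None

    def validate(self) -> None:
        for name in ("maf", "fst"):
            lo = getattr(self, f"{name}_min")
            hi = getattr(self, f"{name}_max")
            for v in (lo, hi):
                if v is not None and not 0.0 <= v <= 1.0:
                    raise QueryError(f"{name} filter bound {v} outside [0, 1]")
            if lo is not None and hi is not None and lo > hi:
                raise QueryError(f"{name} filter has min {lo} > max {hi}")

    @property
    def fst_active(self) -> bool:
        return self.fst_min is not None or self.fst_max is not None

    @property
    def empty(self) -> bool:
        return all(getattr(self, f.name) is None for f in fields(self))


@dataclass(frozen=True)
class QuerySpec:
    """A batch query: mode + payload, population selection, filters.

    ``mode`` is one of ``rs_list`` (payload: list of ids), ``region``
    (payload: ``(chrom, start, end)`` 1-based inclusive) or ``gene_list``
    (payload: list of symbols). ``selection`` holds population and/or
    continental-group codes; ``merge=True`` pools them into one unit.
    """

    mode: str
    payload: object
    selection: Tuple[str, ...]
    merge: bool = False
    filters: Filters = field(default_factory=Filters)

    def validate(self) -> None:
        if self.mode not in QUERY_MODES:
            raise QueryError(f"unknown query mode {self.mode!r}")
        if not self.selection:
            raise SelectionError("empty population selection")
        self.filters.validate()
        if self.mode == "region":
            chrom, start, end = self.payload  # type: ignore[misc]
            if start > end or start < 1:
                raise QueryError(f"invalid region {chrom}:{start}-{end}")


@dataclass(frozen=True)
class SiteSummary:
    """One row of the statistics table."""

    variant_id: str
    chrom: str
    pos: int
    genes: Tuple[str, ...]
    ref_allele: str
    ancestral_allele: Optional[str]
    observed_alleles: Tuple[str, ...]
    populations: Tuple[str, ...]
    n_samples: int
    minor_allele: Optional[str]
    maf: float
    h_obs: Optional[float]
    h_exp: float
    f_is: Optional[float]
    f_st: Optional[float]
    f_st_class: Optional[str]
    i_n: Optional[float]
    call_rate: float


def _dispatch_lookup(mart: Mart, spec: QuerySpec) -> Tuple[List[MartRecord], List[str]]:
    if spec.mode == "rs_list":
        return mart.lookup_by_rs(list(spec.payload))
    if spec.mode == "region":
        chrom, start, end = spec.payload
        return mart.lookup_by_region(chrom, start, end), []
    return mart.lookup_by_gene(list(spec.payload))


def summarize_site(
    rec: MartRecord,
    selection: Sequence[str],
    panel: PanelMap,
    sample_counts: Dict[str, int],
    merge: bool,
) -> SiteSummary:
    """Build one statistics-table row for one variant and one selection."""
    units = select_counts([rec], selection, panel, merge=False)[0]
    unit_counts = [c for _, c in units]
    selected_pops = sorted({p for code in selection for p in panel.expand(code)})
    n_samples = sum(sample_counts[p] for p in selected_pops)
    stats = site_statistics(
        unit_counts, n_samples, between=(not merge and len(units) >= 2)
    )
    pooled = pool_counts(unit_counts)
    observed = tuple(sorted(a for a, n in pooled.counts.items() if n > 0))
    ann = rec.annotation
    return SiteSummary(
        variant_id=ann.variant_id,
        chrom=ann.chrom,
        pos=ann.pos,
        genes=ann.genes,
        ref_allele=ann.ref_allele,
        ancestral_allele=ann.ancestral_allele,
        observed_alleles=observed,
        populations=tuple(selection),
        n_samples=n_samples,
        minor_allele=stats.minor_allele,
        maf=stats.maf,
        h_obs=stats.h_obs,
        h_exp=stats.h_exp,
        f_is=stats.f_is,
        f_st=stats.f_st,
        f_st_class=stats.f_st_class,
        i_n=stats.i_n,
        call_rate=stats.call_rate,
    )


def run_query(mart: Mart, spec: QuerySpec) -> List[SiteSummary]:
    """Execute a QuerySpec: lookup, per-site statistics, then filters.

    Rows come back in lookup order (input order for rs-lists, position
    order for regions and genes). Filters that eliminate everything yield
    an empty list, not an error.
    """
    spec.validate()
    records, _missing = _dispatch_lookup(mart, spec)
    panel = mart.panel_view()
    sample_counts = mart.sample_counts
    rows = [
        summarize_site(rec, spec.selection, panel, sample_counts, spec.merge)
        for rec in records
    ]
    return apply_filters(rows, spec.filters)


def apply_filters(rows: Sequence[SiteSummary], filters: Filters) -> List[SiteSummary]:
    """Keep rows inside the inclusive MAF/F_ST bounds.

    Rows with NA F_ST are dropped whenever an F_ST bound is active —
    a threshold on an undefined value cannot be satisfied.
    """
    filters.validate()
    if filters.empty:
        return list(rows)
    out = []
    for r in rows:
        if filters.maf_min is not None and r.maf < filters.maf_min:
            continue
        if filters.maf_max is not None and r.maf > filters.maf_max:
            continue
        if filters.fst_active:
            if r.f_st is None:
                continue
            if filters.fst_min is not None and r.f_st < filters.fst_min:
                continue
            if filters.fst_max is not None and r.f_st > filters.fst_max:
                continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# genome-wide F_ST scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanResult:
    """Genome-wide F_ST scan output.

    ``sites`` lists every variant with a defined F_ST under the grouping
    (chrom, pos, variant_id, f_st, flagged). ``windows`` carries the mean
    F_ST of non-overlapping fixed-width windows aligned to position 1.
    ``top_hits`` lists sites above the absolute threshold with gene
    annotation. ``quantile_threshold`` is the smallest F_ST value flagged.
    """

    sites: pd.DataFrame
    windows: pd.DataFrame
    top_hits: pd.DataFrame
    quantile_threshold: float
    window_bp: int
    quantile: float
    abs_threshold: float


def quantile_flags(values: np.ndarray, quantile: float) -> Tuple[np.ndarray, float]:
    """Flag the upper tail of an empirical distribution, ties included.

    With n defined values, ``k = ceil((1 - quantile) * n)`` sites form the
    nominal upper tail; the threshold is the k-th largest value and every
    site with a value >= the threshold is flagged (so ties at the
    threshold are all flagged).
    """
    n = len(values)
    if n == 0:
        return np.zeros(0, dtype=bool), math.nan
    k = max(1, math.ceil((1.0 - quantile) * n))
    threshold = float(np.sort(values)[n - k])
    return values >= threshold, threshold


def fst_genome_scan(
    mart: Mart,
    grouping: Sequence[str],
    window_bp: int = 1_000_000,
    quantile: float = 0.975,
    abs_threshold: float = 0.9,
) -> ScanResult:
    """Per-site F_ST across a grouping for every mart site, plus windows.

    Sites where F_ST is undefined under the grouping (pooled-monomorphic,
    or fewer than two groups carrying allele copies) are excluded from the
    empirical distribution, the windows and the flags. Window means are
    taken over non-overlapping ``window_bp``-wide windows
    ``[1, w], [w+1, 2w], ...`` per chromosome.
    """
    if len(grouping) < 2:
        raise SelectionError("genome scan needs at least two groups")
    if window_bp < 1:
        raise QueryError("window width must be >= 1 bp")
    panel = mart.panel_view()
    unit_pops = [(code, panel.expand(code)) for code in grouping]
    rows = []
    for rec in mart.iter_all():
        units = [
            pool_counts([rec.counts.get(p, AlleleCounts()) for p in pops])
            for _, pops in unit_pops
        ]
        informative = [u for u in units if u.total_copies > 0]
        if len(informative) < 2:
            continue
        f = popgen.fst_among(informative)
        if f is None:
            continue
        ann = rec.annotation
        rows.append((ann.chrom, ann.pos, ann.variant_id, f, ";".join(ann.genes)))
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "variant_id", "f_st", "genes"]
    )
    if len(sites):
        flags, threshold = quantile_flags(sites["f_st"].to_numpy(), quantile)
    else:
        flags, threshold = np.zeros(0, dtype=bool), math.nan
    sites["flagged"] = flags
    sites["window_start"] = (sites["pos"] - 1) // window_bp * window_bp + 1
    windows = (
        sites.groupby(["chrom", "window_start"], as_index=False)
        .agg(mean_f_st=("f_st", "mean"), n_sites=("f_st", "size"))
        .sort_values(["chrom", "window_start"], ignore_index=True)
    )
    top_hits = (
        sites.loc[sites["f_st"] > abs_threshold,
                  ["chrom", "pos", "variant_id", "f_st", "genes"]]
        .sort_values("f_st", ascending=False, kind="mergesort", ignore_index=True)
    )
    site_cols = sites[["chrom", "pos", "variant_id", "f_st", "flagged"]]
    return ScanResult(
        sites=site_cols,
        windows=windows,
        top_hits=top_hits,
        quantile_threshold=threshold,
        window_bp=window_bp,
        quantile=quantile,
        abs_threshold=abs_threshold,
    )


# ---------------------------------------------------------------------------
# genotype export
# ---------------------------------------------------------------------------

def export_genotypes(
    vcf_path: str | Path,
    rows: Sequence[SiteSummary],
    panel: PanelMap,
    selection: Sequence[str],
    out_path: str | Path,
) -> Path:
    """Re-read the queried sites from the raw VCF and write Structure format.

    The mart stores only summaries, so individual genotypes must come from
    the original source; a missing VCF is reported as exactly that.
    """
    if not rows:
        raise QueryError("nothing to export: the query returned no rows")
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise QueryError(
            f"genotype export requires the raw VCF source; not found: {vcf_path}"
        )
    wanted = {(r.chrom, r.pos, r.variant_id) for r in rows}
    reader = read_vcf(vcf_path, panel)
    records = [
        rec
        for rec in reader
        if (rec.chrom, rec.pos, rec.variant_id) in wanted
    ]
    if not records:
        raise QueryError("none of the queried sites are present in the VCF")
    return write_structure(records, reader.samples, panel, selection, out_path)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _cell(value) -> str:
    if value is None:
        return NA
    if isinstance(value, float):
        return format(value, ".6g")
    if isinstance(value, tuple):
        return ";".join(value) if value else NA
    return str(value)


def summaries_to_dataframe(rows: Sequence[SiteSummary]) -> pd.DataFrame:
    """Statistics table as a DataFrame in the fixed column order."""
    data = {
        col: [getattr(r, col) for r in rows] for col in SITE_SUMMARY_COLUMNS
    }
    return pd.DataFrame(data, columns=list(SITE_SUMMARY_COLUMNS))


def write_summaries(rows: Sequence[SiteSummary], path: str | Path, fmt: str = "tsv") -> Path:
    """Write the statistics table as TSV (default) or JSON; NA for undefined."""
    path = Path(path)
    if fmt == "tsv":
        lines = ["\t".join(SITE_SUMMARY_COLUMNS)]
        for r in rows:
            lines.append(
                "\t".join(_cell(getattr(r, col)) for col in SITE_SUMMARY_COLUMNS)
            )
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = [
            {col: getattr(r, col) for col in SITE_SUMMARY_COLUMNS} for r in rows
        ]
        path.write_text(json.dumps(payload, indent=1, default=list) + "\n")
    else:
        raise QueryError(f"unknown output format {fmt!r}")
    return path
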