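"""The summarized data mart: build, persist and query per-population counts.

The mart is a single SQLite file holding, for every retained SNV, one
annotation row and one count row per population — allele copy counts, the
heterozygote count, typed-sample and haploid-call counts. Storing integer
counts rather than frequencies makes population merging exact: pooling any
subset of populations and recomputing frequencies gives precisely the
frequencies of the concatenated raw genotypes.

Indexes cover variant id, (chrom, pos) and upper-cased gene symbol, so the
three query modes (rs-list, region, gene-list) are all indexed lookups.
A mart is self-describing: dataset name, per-population sample counts, the
population->group mapping, build timestamp and builder version live in a
metadata table, so queries need no access to the original VCF or panel.
"""

from __future__ import annotations

import json
import sqlite3
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from intervaltree import IntervalTree

from . import __version__
from .errors import InputFormatError, QueryError, SelectionError
from .io import GeneModel, PanelMap, VcfReader, read_vcf
from .popgen import AlleleCounts, pool_counts

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE variants (
    variant_id TEXT PRIMARY KEY,
    chrom TEXT NOT NULL,
    pos INTEGER NOT NULL CHECK (pos >= 1),
    ref TEXT NOT NULL,
    alts TEXT NOT NULL,
    ancestral TEXT,
    genes TEXT NOT NULL DEFAULT '[]'
);
CREATE INDEX idx_variants_pos ON variants (chrom, pos);
CREATE TABLE gene_map (
    symbol TEXT NOT NULL,
    variant_id TEXT NOT NULL,
    PRIMARY KEY (symbol, variant_id)
);
CREATE TABLE pop_counts (
    variant_id TEXT NOT NULL,
    pop TEXT NOT NULL,
    a INTEGER NOT NULL, c INTEGER NOT NULL,
    g INTEGER NOT NULL, t INTEGER NOT NULL,
    het INTEGER NOT NULL,
    n_typed INTEGER NOT NULL,
    n_haploid INTEGER NOT NULL,
    PRIMARY KEY (variant_id, pop)
);
"""


@dataclass(frozen=True)
class VariantAnnotation:
    """Static per-variant columns of the statistics table."""

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: Tuple[str, ...]
    ancestral_allele: Optional[str]
    genes: Tuple[str, ...]


@dataclass(frozen=True)
class MartRecord:
    """One variant with its per-population summarized counts."""

    annotation: VariantAnnotation
    counts: Dict[str, AlleleCounts]


def _counts_to_row(c: AlleleCounts) -> Tuple[int, int, int, int, int, int, int]:
    return (
        c.counts.get("A", 0),
        c.counts.get("C", 0),
        c.counts.get("G", 0),
        c.counts.get("T", 0),
        c.het_count,
        c.n_typed,
        c.n_haploid,
    )


def _row_to_counts(a: int, c: int, g: int, t: int, het: int, n_typed: int, n_hap: int) -> AlleleCounts:
    counts = {k: v for k, v in zip("ACGT", (a, c, g, t)) if v > 0}
    return AlleleCounts(counts=counts, het_count=het, n_typed=n_typed, n_haploid=n_hap)


def summarize_record(calls, alleles: Sequence[str], sample_pops: Sequence[str]) -> Dict[str, AlleleCounts]:
    """Collapse per-sample calls into per-population AlleleCounts."""
    acc: Dict[str, Dict[str, int]] = {}
    for call, pop in zip(calls, sample_pops):
        slot = acc.setdefault(pop, {"het": 0, "n_typed": 0, "n_haploid": 0})
        if call is None:
            continue
        slot["n_typed"] += 1
        if len(call) == 1:
            slot["n_haploid"] += 1
        elif call[0] != call[1]:
            slot["het"] += 1
        for idx in call:
            base = alleles[idx]
            slot[base] = slot.get(base, 0) + 1
    return {
        pop: AlleleCounts(
            counts={b: n for b, n in slot.items() if b in "ACGT"},
            het_count=slot["het"],
            n_typed=slot["n_typed"],
            n_haploid=slot["n_haploid"],
        )
        for pop, slot in acc.items()
    }


def build_datamart(
    vcf_path: str | Path,
    panel: PanelMap,
    genes: Sequence[GeneModel] = (),
    ancestral: Optional[Dict[str, str]] = None,
    out_path: str | Path = "mart.sqlite",
    dataset_name: Optional[str] = None,
) -> "Mart":
    """Single-pass summarization of a VCF into a mart file.

    For every retained SNV and every panel population an
    :class:`~snvmart.popgen.AlleleCounts` record is stored, together with a
    :class:`VariantAnnotation` carrying the overlapping gene symbols
    (1-based closed-interval containment) and the ancestral allele when the
    lookup table knows it. Rebuilding from identical inputs yields
    identical query results.
    """
    ancestral = ancestral or {}
    out_path = Path(out_path)
    reader = read_vcf(vcf_path, panel)
    sample_pops = [panel.sample_to_pop[s] for s in reader.samples]
    pops_present = sorted(set(sample_pops))

    trees: Dict[str, IntervalTree] = {}
    for gm in genes:
        # half-open internal tree; +1 so the closed end is included
        trees.setdefault(gm.chrom, IntervalTree()).addi(gm.start, gm.end + 1, gm.symbol)

    if out_path.exists():
        out_path.unlink()
    con = sqlite3.connect(out_path)
    try:
        con.executescript(_SCHEMA)
        n_sites = 0
        duplicate_ids = 0
        for rec in reader:
            if rec.variant_id is None:
                continue
            genes_here = sorted(
                {iv.data for iv in trees.get(rec.chrom, IntervalTree())[rec.pos]}
            )
            cur = con.execute(
                "INSERT OR IGNORE INTO variants VALUES (?,?,?,?,?,?,?)",
                (
                    rec.variant_id,
                    rec.chrom,
                    rec.pos,
                    rec.ref_allele,
                    ",".join(rec.alt_alleles),
                    ancestral.get(rec.variant_id),
                    json.dumps(genes_here),
                ),
            )
            if cur.rowcount == 0:
                duplicate_ids += 1
                continue
            for symbol in genes_here:
                con.execute(
                    "INSERT OR IGNORE INTO gene_map VALUES (?,?)",
                    (symbol.upper(), rec.variant_id),
                )
            per_pop = summarize_record(rec.calls, rec.alleles, sample_pops)
            for pop in pops_present:
                c = per_pop.get(pop, AlleleCounts())
                con.execute(
                    "INSERT INTO pop_counts VALUES (?,?,?,?,?,?,?,?,?)",
                    (rec.variant_id, pop) + _counts_to_row(c),
                )
            n_sites += 1
        if n_sites == 0:
            con.close()
            out_path.unlink(missing_ok=True)
            raise InputFormatError(f"no SNVs retained from {vcf_path}")
        sample_counts = {
            p: sum(1 for sp in sample_pops if sp == p) for p in pops_present
        }
        meta = {
            "dataset": dataset_name or Path(vcf_path).stem,
            "populations": pops_present,
            "sample_counts": sample_counts,
            "pop_to_group": {p: panel.pop_to_group[p] for p in pops_present},
            "n_sites": n_sites,
            "skipped_non_snv": reader.skipped_non_snv,
            "duplicate_ids_dropped": duplicate_ids,
            "build_timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
            "builder_version": __version__,
        }
        con.executemany(
            "INSERT INTO meta VALUES (?,?)",
            [(k, json.dumps(v)) for k, v in meta.items()],
        )
        con.commit()
    finally:
        con.close()
    return Mart(out_path)


class Mart:
    """Handle to an open mart file; context-manager aware."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.exists():
            raise QueryError(f"mart file not found: {self.path}")
        try:
            self._con = sqlite3.connect(f"file:{self.path}?mode=ro", uri=True)
            self._meta = {
                k: json.loads(v)
                for k, v in self._con.execute("SELECT key, value FROM meta")
            }
        except sqlite3.DatabaseError as exc:
            raise QueryError(f"not a mart file: {self.path} ({exc})") from exc

    # -- metadata ---------------------------------------------------------
    @property
    def populations(self) -> List[str]:
        return list(self._meta["populations"])

    @property
    def sample_counts(self) -> Dict[str, int]:
        return dict(self._meta["sample_counts"])

    @property
    def pop_to_group(self) -> Dict[str, str]:
        return dict(self._meta["pop_to_group"])

    def panel_view(self) -> PanelMap:
        """A PanelMap carrying the mart's population/group structure.

        Sample identities are not stored in the mart (only counts), so the
        sample map is empty; the view supports group expansion only.
        """
        return PanelMap(sample_to_pop={}, pop_to_group=self.pop_to_group)

    def info(self) -> Dict:
        return dict(self._meta)

    def close(self) -> None:
        self._con.close()

    def __enter__(self) -> "Mart":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- lookups ----------------------------------------------------------
    def _fetch_records(self, rows: List[Tuple]) -> List[MartRecord]:
        out = []
        for vid, chrom, pos, ref, alts, anc, genes in rows:
            counts = {
                pop: _row_to_counts(a, c, g, t, het, nt, nh)
                for pop, a, c, g, t, het, nt, nh in self._con.execute(
                    "SELECT pop,a,c,g,t,het,n_typed,n_haploid FROM pop_counts "
                    "WHERE variant_id = ?",
                    (vid,),
                )
            }
            ann = VariantAnnotation(
                variant_id=vid,
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_alleles=tuple(alts.split(",")) if alts else (),
                ancestral_allele=anc,
                genes=tuple(json.loads(genes)),
            )
            out.append(MartRecord(annotation=ann, counts=counts))
        return out

    def lookup_by_rs(self, ids: Sequence[str]) -> Tuple[List[MartRecord], List[str]]:
        """Fetch variants by id, input order preserved, first occurrence kept.

        Returns ``(records, missing_ids)``; unknown ids are reported, not
        raised.
        """
        seen: Set[str] = set()
        ordered = [i for i in ids if not (i in seen or seen.add(i))]
        rows, missing = [], []
        for vid in ordered:
            row = self._con.execute(
                "SELECT variant_id,chrom,pos,ref,alts,ancestral,genes "
                "FROM variants WHERE variant_id = ?",
                (vid,),
            ).fetchone()
            if row is None:
                missing.append(vid)
            else:
                rows.append(row)
        return self._fetch_records(rows), missing

    def lookup_by_region(self, chrom: str, start: int, end: int) -> List[MartRecord]:
        """All variants with ``start <= pos <= end``, position-sorted."""
        if start > end:
            raise QueryError(f"invalid region: start {start} > end {end}")
        rows = self._con.execute(
            "SELECT variant_id,chrom,pos,ref,alts,ancestral,genes FROM variants "
            "WHERE chrom = ? AND pos BETWEEN ? AND ? ORDER BY pos",
            (chrom, start, end),
        ).fetchall()
        return self._fetch_records(rows)

    def lookup_by_gene(self, symbols: Sequence[str]) -> Tuple[List[MartRecord], List[str]]:
        """Union of variants annotated to any symbol (case-insensitive).

        Position-sorted; symbols matching nothing are returned separately.
        """
        vids: Set[str] = set()
        missing = []
        for sym in symbols:
            hits = [
                r[0]
                for r in self._con.execute(
                    "SELECT variant_id FROM gene_map WHERE symbol = ?",
                    (sym.upper(),),
                )
            ]
            if hits:
                vids.update(hits)
            else:
                missing.append(sym)
        if not vids:
            return [], missing
        placeholders = ",".join("?" * len(vids))
        rows = self._con.execute(
            f"SELECT variant_id,chrom,pos,ref,alts,ancestral,genes FROM variants "
            f"WHERE variant_id IN ({placeholders}) ORDER BY chrom, pos",
            sorted(vids),
        ).fetchall()
        return self._fetch_records(rows), missing

    def iter_all(self) -> Iterable[MartRecord]:
        """Every variant in (chrom, pos) order — the genome-scan feed."""
        rows = self._con.execute(
            "SELECT variant_id,chrom,pos,ref,alts,ancestral,genes FROM variants "
            "ORDER BY chrom, pos"
        ).fetchall()
        for row in rows:
            yield self._fetch_records([row])[0]


def open_mart(path: str | Path) -> Mart:
    return Mart(path)


def select_counts(
    records: Sequence[MartRecord],
    selection: Sequence[str],
    panel: PanelMap,
    merge: bool,
) -> List[Union[AlleleCounts, List[Tuple[str, AlleleCounts]]]]:
    """Resolve a population/group selection against each record's counts.

    Each selection code expands to its member populations through the
    panel; the member counts are pooled into one unit per code. With
    ``merge=True`` the units are pooled further into a single
    :class:`AlleleCounts` per record; with ``merge=False`` a
    ``[(code, AlleleCounts), ...]`` list is returned per record, ready for
    between-group statistics.
    """
    if not selection:
        raise SelectionError("empty population selection")
    unit_pops = [(code, panel.expand(code)) for code in selection]
    out: List[Union[AlleleCounts, List[Tuple[str, AlleleCounts]]]] = []
    for rec in records:
        units = []
        for code, pops in unit_pops:
            members = [rec.counts.get(p, AlleleCounts()) for p in pops]
            units.append((code, pool_counts(members)))
        if merge:
            out.append(pool_counts([u for _, u in units]))
        else:
            out.append(units)
    return out
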