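"""Readers and writers for the formats the tool touches.

VCF genotypes (via cyvcf2/htslib), sample->population panel files, BED4
gene models, rs-number lists, the optional ancestral-allele table, and the
two-row-per-individual Structure genotype export.

Only the GT subfield of the VCF is consumed; phased and unphased
separators are equivalent. Sites are restricted to SNVs (single-base REF
and ALTs); everything else is skipped and counted. Chromosome names are
taken verbatim from the VCF — queries must use the same dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

from cyvcf2 import VCF

from .errors import InputFormatError, SelectionError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Structure-format allele recoding; missing alleles are written as -9.
STRUCTURE_CODES = {"A": 1, "C": 2, "G": 3, "T": 4}
STRUCTURE_MISSING = -9

# A per-sample call is a tuple of allele indices: (i, j) diploid, (i,)
# haploid, or None when missing.
Call = Optional[Tuple[int, ...]]


@dataclass(frozen=True)
class GenotypeRecord:
    """One SNV site with per-sample diploid (or haploid) calls."""

    chrom: str
    pos: int
    variant_id: str
    ref_allele: str
    alt_alleles: Tuple[str, ...]
    calls: Tuple[Call, ...]
    ancestral_allele: Optional[str] = None

    @property
    def alleles(self) -> Tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles


@dataclass(frozen=True)
class PanelMap:
    """Sample -> population and population -> continental-group assignments."""

    sample_to_pop: Dict[str, str]
    pop_to_group: Dict[str, str]

    @property
    def populations(self) -> List[str]:
        return sorted(set(self.sample_to_pop.values()) | set(self.pop_to_group))

    @property
    def groups(self) -> List[str]:
        return sorted(set(self.pop_to_group.values()))

    def samples_in(self, pops: Iterable[str]) -> List[str]:
        wanted = set(pops)
        return [s for s, p in self.sample_to_pop.items() if p in wanted]

    def expand(self, code: str) -> List[str]:
        """Resolve a population or group code to its member populations.

        ``ALL`` selects every population. Population codes win over group
        codes on a clash. Unknown codes raise :class:`SelectionError`.
        """
        if code == "ALL":
            return self.populations
        if code in self.pop_to_group:
            return [code]
        members = sorted(p for p, g in self.pop_to_group.items() if g == code)
        if not members:
            valid = sorted(set(self.pop_to_group) | set(self.pop_to_group.values()))
            raise SelectionError(
                f"unknown population or group code {code!r}; valid codes: "
                + ", ".join(valid)
            )
        return members


@dataclass(frozen=True)
class GeneModel:
    """A named interval, 1-based fully-closed coordinates."""

    symbol: str
    chrom: str
    start: int
    end: int


def variant_identity(chrom: str, pos: int, ref: str, alts: Sequence[str], vcf_id) -> str:
    """rs-number from the VCF ID column when present, else a positional key.

    The offline reduction of "dbSNP used for mapping purposes": an ID
    beginning with ``rs`` is trusted, anything else is replaced by
    ``chrom:pos:ref:alt``.
    """
    if vcf_id and str(vcf_id).startswith("rs"):
        return str(vcf_id)
    return f"{chrom}:{pos}:{ref}:{','.join(alts)}"


class VcfReader:
    """Streaming SNV reader over a VCF restricted to panel samples.

    Iterating yields :class:`GenotypeRecord` objects whose ``calls`` align
    with :attr:`samples` (the VCF sample order restricted to samples known
    to the panel). Non-SNV records are skipped and counted in
    :attr:`skipped_non_snv`.
    """

    def __init__(self, path: str | Path, panel: PanelMap):
        path = Path(path)
        if not path.exists():
            raise InputFormatError(f"VCF not found: {path}")
        try:
            self._vcf = VCF(str(path))
            vcf_samples = list(self._vcf.samples)
        except Exception as exc:  # htslib raises bare Exceptions
            raise InputFormatError(f"cannot read VCF {path}: {exc}") from exc
        self._keep = [i for i, s in enumerate(vcf_samples) if s in panel.sample_to_pop]
        dropped = [s for s in vcf_samples if s not in panel.sample_to_pop]
        if dropped:
            logger.warning(
                "%d VCF sample(s) absent from the panel are skipped: %s",
                len(dropped),
                ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
            )
        if not self._keep:
            raise InputFormatError(
                "no overlap between VCF samples and the panel file"
            )
        self.samples: List[str] = [vcf_samples[i] for i in self._keep]
        self.path = path
        self.skipped_non_snv = 0
        self.retained = 0

    def __iter__(self) -> Iterator[GenotypeRecord]:
        for rec in self._vcf:
            ref = rec.REF.upper()
            alts = tuple(a.upper() for a in rec.ALT)
            if (
                len(ref) != 1
                or ref not in VALID_BASES
                or not alts
                or any(len(a) != 1 or a not in VALID_BASES for a in alts)
            ):
                self.skipped_non_snv += 1
                continue
            calls: List[Call] = []
            genotypes = rec.genotypes
            for i in self._keep:
                g = genotypes[i]
                idx = tuple(int(a) for a in g[:-1] if int(a) >= 0)
                calls.append(idx if idx else None)
            self.retained += 1
            yield GenotypeRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                variant_id=variant_identity(rec.CHROM, rec.POS, ref, alts, rec.ID),
                ref_allele=ref,
                alt_alleles=alts,
                calls=tuple(calls),
            )


def read_vcf(path: str | Path, panel: PanelMap) -> VcfReader:
    """Open a VCF as a stream of SNV :class:`GenotypeRecord` objects."""
    return VcfReader(path, panel)


def read_panel(path: str | Path) -> PanelMap:
    """Parse a whitespace-delimited ``sample population [group]`` file.

    When the group column is absent each population is its own group.
    Duplicate sample lines are idempotent; a conflicting duplicate is an
    error.
    """
    sample_to_pop: Dict[str, str] = {}
    pop_to_group: Dict[str, str] = {}
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"panel file not found: {path}")
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise InputFormatError(
                f"{path}:{lineno}: expected 'sample population [group]', got {raw!r}"
            )
        sample, pop = fields[0], fields[1]
        group = fields[2] if len(fields) >= 3 else pop
        if sample in sample_to_pop and sample_to_pop[sample] != pop:
            raise InputFormatError(
                f"{path}:{lineno}: sample {sample} assigned to both "
                f"{sample_to_pop[sample]} and {pop}"
            )
        if pop in pop_to_group and pop_to_group[pop] != group:
            raise InputFormatError(
                f"{path}:{lineno}: population {pop} assigned to both "
                f"group {pop_to_group[pop]} and {group}"
            )
        sample_to_pop[sample] = pop
        pop_to_group[pop] = group
    return PanelMap(sample_to_pop=sample_to_pop, pop_to_group=pop_to_group)


def read_gene_bed(path: str | Path) -> List[GeneModel]:
    """Read BED4 gene models, converting to 1-based inclusive coordinates."""
    genes: List[GeneModel] = []
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"BED file not found: {path}")
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise InputFormatError(
                f"{path}:{lineno}: BED4 needs chrom, start, end, name"
            )
        chrom, start_s, end_s, symbol = fields[:4]
        try:
            bed_start, bed_end = int(start_s), int(end_s)
        except ValueError as exc:
            raise InputFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if bed_start >= bed_end:
            raise InputFormatError(
                f"{path}:{lineno}: empty or inverted interval [{bed_start}, {bed_end})"
            )
        genes.append(GeneModel(symbol=symbol, chrom=chrom, start=bed_start + 1, end=bed_end))
    return genes


def read_rs_list(path: str | Path) -> List[str]:
    """One variant id per line, ``#`` comments allowed, deduplicated in order."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"rs-list file not found: {path}")
    seen: Set[str] = set()
    out: List[str] = []
    for raw in path.read_text().splitlines():
        token = raw.split("#", 1)[0].strip()
        if token and token not in seen:
            seen.add(token)
            out.append(token)
    return out


def read_ancestral_table(path: str | Path) -> Dict[str, str]:
    """Two-column ``variant_id allele`` lookup; alleles normalized to upper case."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"ancestral-allele table not found: {path}")
    table: Dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise InputFormatError(f"{path}:{lineno}: expected 'variant_id allele'")
        vid, allele = fields[0], fields[1].upper()
        if allele not in VALID_BASES:
            raise InputFormatError(
                f"{path}:{lineno}: ancestral allele must be one of A/C/G/T, got {fields[1]!r}"
            )
        table[vid] = allele
    return table


def write_structure(
    records: Sequence[GenotypeRecord],
    samples: Sequence[str],
    panel: PanelMap,
    selection: Iterable[str],
    path: str | Path,
) -> Path:
    """Write genotypes in raw Structure format (two rows per individual).

    ``samples`` names the individuals, in the order the ``calls`` tuples of
    every record follow. Only samples belonging to the selected populations
    (or groups, expanded through the panel) are exported. Each data row
    carries the sample label, a numeric population code (assigned by sorted
    population-name order, recorded in a ``.legend`` sidecar) and one
    column per site with alleles recoded A=1, C=2, G=3, T=4; missing
    alleles are -9. A haploid call fills the first of an individual's two
    rows and leaves -9 in the second.
    """
    if not records:
        raise SelectionError("nothing to export: empty record list")
    pops: Set[str] = set()
    for code in selection:
        pops.update(panel.expand(code))
    keep = [
        (i, s) for i, s in enumerate(samples) if panel.sample_to_pop.get(s) in pops
    ]
    if not keep:
        raise SelectionError(
            "selection matches no samples: " + ", ".join(sorted(pops))
        )
    pop_codes = {p: i + 1 for i, p in enumerate(sorted(pops))}
    path = Path(path)
    with path.open("w") as fh:
        for i, sample in keep:
            rows: Tuple[List[int], List[int]] = ([], [])
            for rec in records:
                call = rec.calls[i]
                alleles = rec.alleles
                codes = (
                    [STRUCTURE_CODES[alleles[j]] for j in call] if call else []
                )
                rows[0].append(codes[0] if len(codes) >= 1 else STRUCTURE_MISSING)
                rows[1].append(codes[1] if len(codes) >= 2 else STRUCTURE_MISSING)
            code = pop_codes[panel.sample_to_pop[sample]]
            for row in rows:
                fh.write(
                    "\t".join([sample, str(code)] + [str(v) for v in row]) + "\n"
                )
    legend = path.with_name(path.name + ".legend")
    with legend.open("w") as fh:
        for p, c in sorted(pop_codes.items()):
            fh.write(f"{p}\t{c}\n")
    return path
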