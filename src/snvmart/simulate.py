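"""Synthetic genotype data with controlled population structure.

The generator draws per-population allele frequencies from the
Balding–Nichols model: for each site an ancestral frequency ``p`` is drawn
uniformly on [0.05, 0.95], then every population's frequency comes from a
Beta distribution with mean ``p`` and variance ``p (1 - p) F`` — shape
parameters ``p (1 - F) / F`` and ``(1 - p) (1 - F) / F`` — so the single
parameter ``F`` tunes the expected differentiation between populations.
Genotypes within a population follow Hardy–Weinberg proportions; calls go
missing i.i.d. at a configurable rate.

Output is a plain-text VCF, a panel file, a small BED of fixture genes and
a JSON bookkeeping file with the true per-site, per-population counts, so
every downstream module can be tested against exact expectations without
any external download.

A separate deterministic fixture, :func:`make_figure1_fixture`, hand-codes
a lactase-persistence-style worked example: a site labelled rs4988235
inside a gene labelled MCM6, with four continental groups whose allele
frequencies put the between-group F_ST in the very-high colour class, plus
a fixed-difference site, a monomorphic site, a triallelic site, missing
and haploid calls, and one indel record that the SNV filter must skip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults are the package's standard recovery conditions: 4 populations
    of 50 diploid samples at 20,000 sites with F = 0.10 and 2% missing
    calls.
    """

    n_pops: int = 4
    samples_per_pop: int = 50
    n_sites: int = 20_000
    fst: float = 0.10
    missing_rate: float = 0.02
    seed: int = 42
    chrom: str = "1"
    chrom_length: int = 249_250_621
    pop_names: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if not 0.0 < self.fst < 1.0:
            raise ValueError("differentiation F must lie in the open interval (0, 1)")
        if min(self.n_pops, self.samples_per_pop, self.n_sites) < 1:
            raise ValueError("population, sample and site counts must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def populations(self) -> Tuple[str, ...]:
        if self.pop_names is not None:
            if len(self.pop_names) != self.n_pops:
                raise ValueError("pop_names length must equal n_pops")
            return self.pop_names
        return tuple(f"POP{i + 1}" for i in range(self.n_pops))


def simulate_frequencies(cfg: SimulationConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ancestral and per-population derived-allele frequencies.

    Returns ``(ancestral, freqs)`` with shapes ``(n_sites,)`` and
    ``(n_sites, n_pops)``. Reproducible under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(0.05, 0.95, size=cfg.n_sites)
    f = cfg.fst
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    freqs = rng.beta(a[:, None], b[:, None], size=(cfg.n_sites, cfg.n_pops))
    return p, freqs


def simulate_genotype_counts(
    freqs: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-site, per-population genotype category counts under HWE.

    Returns an integer array of shape ``(n_sites, n_pops, 4)`` holding
    counts of (hom-derived, het, hom-ancestral, missing) among the
    ``samples_per_pop`` individuals; missingness is i.i.d. at
    ``missing_rate`` independent of genotype.
    """
    q = np.asarray(freqs, dtype=float)
    m = cfg.missing_rate
    probs = np.stack(
        [
            (1.0 - m) * q * q,
            (1.0 - m) * 2.0 * q * (1.0 - q),
            (1.0 - m) * (1.0 - q) * (1.0 - q),
            np.full_like(q, m),
        ],
        axis=-1,
    )
    flat = probs.reshape(-1, 4)
    counts = rng.multinomial(cfg.samples_per_pop, flat)
    return counts.reshape(q.shape[0], q.shape[1], 4)


def _site_positions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing positions spread over the chromosome."""
    spacing = max(2, cfg.chrom_length // (cfg.n_sites + 1))
    jitter = rng.integers(0, max(1, spacing - 1), size=cfg.n_sites)
    return (np.arange(1, cfg.n_sites + 1) * spacing + jitter).astype(np.int64)


def simulate_genotypes(
    freqs: np.ndarray, cfg: SimulationConfig, out_dir: str | Path
) -> Dict[str, Path]:
    """Materialize a simulated dataset as VCF + panel + BED + bookkeeping.

    Individual genotypes are assigned by shuffling each population's
    genotype multiset per site, so sample columns carry no artificial
    structure. The bookkeeping file records the exact per-site,
    per-population counts the VCF encodes, for round-trip tests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 1])
    pops = cfg.populations
    n = cfg.samples_per_pop
    samples = [f"{p}_{i + 1:03d}" for p in pops for i in range(n)]
    counts = simulate_genotype_counts(freqs, cfg, rng)
    positions = _site_positions(cfg, rng)
    ref_idx = rng.integers(0, 4, size=cfg.n_sites)
    alt_shift = rng.integers(1, 4, size=cfg.n_sites)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]

    gt_strings = np.array(["1/1", "0/1", "0/0", "./."])
    truth: List[dict] = []
    vcf_path = out_dir / "sim.vcf"
    with vcf_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cfg.chrom},length={cfg.chrom_length}>\n")
        fh.write(f"##source=snvmart-simulate seed={cfg.seed} F={cfg.fst}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for s in range(cfg.n_sites):
            vid = f"rs{9_000_000 + s}"
            cells: List[str] = []
            site_truth: Dict[str, List[int]] = {}
            for k, pop in enumerate(pops):
                n_dd, n_het, n_aa, n_miss = counts[s, k]
                gts = np.repeat(gt_strings, [n_dd, n_het, n_aa, n_miss])
                rng.shuffle(gts)
                cells.extend(gts.tolist())
                n_typed = int(n - n_miss)
                derived = int(2 * n_dd + n_het)
                site_truth[pop] = [
                    2 * n_typed - derived,  # ref copies
                    derived,  # alt copies
                    int(n_het),
                    n_typed,
                ]
            fh.write(
                f"{cfg.chrom}\t{positions[s]}\t{vid}\t{refs[s]}\t{alts[s]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n"
            )
            truth.append(
                {
                    "variant_id": vid,
                    "pos": int(positions[s]),
                    "ref": str(refs[s]),
                    "alt": str(alts[s]),
                    "pops": site_truth,
                }
            )

    panel_path = out_dir / "sim.panel"
    with panel_path.open("w") as fh:
        for sample in samples:
            pop = sample.rsplit("_", 1)[0]
            fh.write(f"{sample}\t{pop}\t{pop}\n")

    bed_path = out_dir / "sim_genes.bed"
    with bed_path.open("w") as fh:
        # a few fixture genes, each spanning a run of simulated sites
        n_genes = min(3, cfg.n_sites)
        chunk = max(1, cfg.n_sites // 4)
        for gi in range(n_genes):
            lo = positions[min(gi * chunk, cfg.n_sites - 1)]
            hi = positions[min(gi * chunk + chunk - 1, cfg.n_sites - 1)]
            fh.write(f"{cfg.chrom}\t{lo - 1}\t{hi}\tSIMG{gi + 1}\n")

    truth_path = out_dir / "sim_truth.json"
    truth_path.write_text(json.dumps({"config_seed": cfg.seed, "sites": truth}))
    return {"vcf": vcf_path, "panel": panel_path, "bed": bed_path, "truth": truth_path}


def simulate_dataset(cfg: SimulationConfig, out_dir: str | Path) -> Dict[str, Path]:
    """Frequencies + genotypes in one call (the CLI entry point)."""
    _, freqs = simulate_frequencies(cfg)
    return simulate_genotypes(freqs, cfg, out_dir)


def counts_to_allele_counts(site_counts: np.ndarray, n: int) -> List:
    """Genotype category counts for one site -> per-population AlleleCounts.

    ``site_counts`` has shape ``(n_pops, 4)`` with (hom-derived, het,
    hom-ancestral, missing) counts; the reference/ancestral allele is coded
    A and the derived allele G (the statistics are label-invariant).
    """
    from .popgen import AlleleCounts

    out = []
    for n_dd, n_het, n_aa, n_miss in site_counts:
        n_typed = int(n - n_miss)
        derived = int(2 * n_dd + n_het)
        counts = {}
        if 2 * n_typed - derived:
            counts["A"] = 2 * n_typed - derived
        if derived:
            counts["G"] = derived
        out.append(
            AlleleCounts(counts=counts, het_count=int(n_het), n_typed=n_typed)
        )
    return out


def recovered_mean_fst(cfg: SimulationConfig) -> Tuple[float, np.ndarray, np.ndarray]:
    """Simulate genotypes under ``cfg`` and average the per-site F_ST estimate.

    Returns ``(mean_fst, per_site_fst, true_freqs)``; sites where the
    estimator is undefined (pooled-monomorphic in the sample) carry NaN in
    ``per_site_fst`` and are excluded from the mean. This is the
    parameter-recovery pathway: the estimate is computed from sampled
    genotypes through the same counts-based estimator the query engine
    uses.
    """
    from .popgen import fst_among

    _, freqs = simulate_frequencies(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    counts = simulate_genotype_counts(freqs, cfg, rng)
    per_site = np.full(cfg.n_sites, np.nan)
    for s in range(cfg.n_sites):
        units = counts_to_allele_counts(counts[s], cfg.samples_per_pop)
        informative = [u for u in units if u.total_copies > 0]
        if len(informative) < 2:
            continue
        f = fst_among(informative)
        if f is not None:
            per_site[s] = f
    mean = float(np.nanmean(per_site))
    return mean, per_site, freqs


# ---------------------------------------------------------------------------
# deterministic worked-example fixture
# ---------------------------------------------------------------------------

# Four continental groups, one population each, 25 diploid samples per
# population. Sites live on chromosome 2 around the LCT/MCM6 region
# (GRCh37-style coordinates), entirely synthetic genotypes.
_FIG_POPS = (("YRI", "AFR"), ("CEU", "EUR"), ("CHB", "EAS"), ("MXL", "AME"))
_FIG_N = 25


def _gts(*blocks: Tuple[str, int]) -> List[str]:
    out: List[str] = []
    for gt, n in blocks:
        out.extend([gt] * n)
    return out


def _figure1_sites() -> List[Tuple[int, str, str, str, Dict[str, List[str]]]]:
    """(pos, id, ref, alt, per-pop genotype lists) for the fixture."""
    sites = []
    # neutral biallelic site, similar frequencies everywhere -> low F_ST
    sites.append(
        (
            135_300_000,
            "rs5551001",
            "A",
            "G",
            {
                "YRI": _gts(("0/0", 9), ("0/1", 12), ("1/1", 4)),
                "CEU": _gts(("0/0", 10), ("0/1", 11), ("1/1", 4)),
                "CHB": _gts(("0/0", 8), ("0/1", 13), ("1/1", 4)),
                "MXL": _gts(("0/0", 9), ("0/1", 11), ("1/1", 5)),
            },
        )
    )
    # fixed difference between AFR and everyone else -> F_ST = 1
    sites.append(
        (
            135_400_100,
            "rs5551002",
            "G",
            "A",
            {
                "YRI": _gts(("1/1", 25)),
                "CEU": _gts(("0/0", 25)),
                "CHB": _gts(("0/0", 25)),
                "MXL": _gts(("0/0", 25)),
            },
        )
    )
    # monomorphic site (alt never observed) -> MAF 0, F_ST undefined
    sites.append(
        (
            135_500_500,
            "rs5551003",
            "C",
            "T",
            {p: _gts(("0/0", 25)) for p, _ in _FIG_POPS},
        )
    )
    # triallelic SNV
    sites.append(
        (
            135_600_000,
            "rs5551004",
            "C",
            "G,T",
            {
                "YRI": _gts(("0/0", 10), ("0/1", 8), ("1/1", 3), ("0/2", 3), ("1/2", 1)),
                "CEU": _gts(("0/0", 15), ("0/1", 6), ("0/2", 4)),
                "CHB": _gts(("0/0", 18), ("0/1", 5), ("2/2", 2)),
                "MXL": _gts(("0/0", 12), ("0/1", 9), ("1/1", 2), ("0/2", 2)),
            },
        )
    )
    # incomplete genotyping: missing and one haploid call
    sites.append(
        (
            135_700_000,
            "rs5551005",
            "T",
            "C",
            {
                "YRI": _gts(("0/0", 10), ("0/1", 9), ("./.", 6)),
                "CEU": _gts(("0/0", 12), ("0/1", 8), ("1/1", 2), ("./.", 3)),
                "CHB": _gts(("0", 1), ("0/0", 14), ("0/1", 8), ("./.", 2)),
                "MXL": _gts(("0/0", 13), ("0/1", 10), ("1/1", 2)),
            },
        )
    )
    # LCT intron site, moderate differentiation
    sites.append(
        (
            136_560_000,
            "rs5551006",
            "A",
            "C",
            {
                "YRI": _gts(("0/0", 14), ("0/1", 9), ("1/1", 2)),
                "CEU": _gts(("0/0", 6), ("0/1", 12), ("1/1", 7)),
                "CHB": _gts(("0/0", 12), ("0/1", 10), ("1/1", 3)),
                "MXL": _gts(("0/0", 10), ("0/1", 11), ("1/1", 4)),
            },
        )
    )
    # the worked example: lactase-persistence marker in MCM6; derived (A)
    # copy counts out of 50 are CEU 35, YRI 2, CHB 5, MXL 15, giving a
    # heterozygosity-partition F_ST of ~0.327 (very_high colour class)
    sites.append(
        (
            136_608_646,
            "rs4988235",
            "G",
            "A",
            {
                "YRI": _gts(("0/1", 2), ("0/0", 23)),
                "CEU": _gts(("1/1", 12), ("0/1", 11), ("0/0", 2)),
                "CHB": _gts(("0/1", 5), ("0/0", 20)),
                "MXL": _gts(("1/1", 4), ("0/1", 7), ("0/0", 14)),
            },
        )
    )
    # second MCM6 site, mild differentiation
    sites.append(
        (
            136_620_000,
            "rs5551008",
            "G",
            "T",
            {
                "YRI": _gts(("0/0", 16), ("0/1", 8), ("1/1", 1)),
                "CEU": _gts(("0/0", 13), ("0/1", 10), ("1/1", 2)),
                "CHB": _gts(("0/0", 17), ("0/1", 7), ("1/1", 1)),
                "MXL": _gts(("0/0", 15), ("0/1", 9), ("1/1", 1)),
            },
        )
    )
    return sites


def make_figure1_fixture(out_dir: str | Path) -> Dict[str, Path]:
    """Write the deterministic worked-example dataset; byte-stable.

    Contains 8 SNVs (one of them triallelic, one monomorphic, one with a
    fixed AFR-vs-rest difference) plus one indel record that VCF reading
    must skip, a 100-sample four-group panel, BED models for LCT and MCM6
    and an ancestral-allele table covering two sites.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = [f"{p}{i + 1:02d}" for p, _ in _FIG_POPS for i in range(_FIG_N)]

    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=2,length=243199373>",
        "##source=snvmart-fixture worked-example",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    rows = []
    for pos, vid, ref, alt, per_pop in _figure1_sites():
        cells = []
        for p, _ in _FIG_POPS:
            gts = per_pop[p]
            assert len(gts) == _FIG_N
            cells.extend(gts)
        rows.append((pos, f"2\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(cells)))
    # an indel the SNV filter must skip
    indel_cells = "\t".join(["0/0"] * (_FIG_N * len(_FIG_POPS)))
    rows.append((135_800_000, "2\t135800000\trs5551100\tAT\tA\t.\tPASS\t.\tGT\t" + indel_cells))
    rows.sort(key=lambda r: r[0])
    lines.extend(line for _, line in rows)
    vcf_path = out_dir / "figure1.vcf"
    vcf_path.write_text("\n".join(lines) + "\n")

    panel_path = out_dir / "figure1.panel"
    panel_path.write_text(
        "".join(
            f"{p}{i + 1:02d}\t{p}\t{g}\n"
            for p, g in _FIG_POPS
            for i in range(_FIG_N)
        )
    )

    bed_path = out_dir / "figure1_genes.bed"
    bed_path.write_text(
        "2\t136545414\t136594750\tLCT\n2\t136594751\t136631628\tMCM6\n"
    )

    anc_path = out_dir / "figure1_ancestral.txt"
    anc_path.write_text("rs4988235\tG\nrs5551002\tG\n")

    rs_path = out_dir / "figure1_rs.txt"
    rs_path.write_text("# worked example\nrs4988235\n")

    return {
        "vcf": vcf_path,
        "panel": panel_path,
        "bed": bed_path,
        "ancestral": anc_path,
        "rs_list": rs_path,
    }
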