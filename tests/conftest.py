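import json
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

import snvmart as sm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig_paths(tmp_path_factory):
    """Deterministic worked-example fixture files (VCF, panel, BED, ...)."""
    return sm.make_figure1_fixture(tmp_path_factory.mktemp("fig"))


@pytest.fixture(scope="session")
def fig_panel(fig_paths):
    return sm.read_panel(fig_paths["panel"])


@pytest.fixture(scope="session")
def fig_mart(fig_paths, fig_panel, tmp_path_factory):
    genes = sm.read_gene_bed(fig_paths["bed"])
    ancestral = sm.read_ancestral_table(fig_paths["ancestral"])
    out = tmp_path_factory.mktemp("figmart") / "figure1.mart"
    mart = sm.build_datamart(fig_paths["vcf"], fig_panel, genes, ancestral, out)
    yield mart
    mart.close()


SIM_CFG = sm.SimulationConfig(
    n_pops=3, samples_per_pop=20, n_sites=120, fst=0.15, missing_rate=0.05, seed=7
)


@pytest.fixture(scope="session")
def sim_paths(tmp_path_factory):
    """A small seeded Balding-Nichols dataset with truth bookkeeping."""
    return sm.simulate_dataset(SIM_CFG, tmp_path_factory.mktemp("sim"))


@pytest.fixture(scope="session")
def sim_cfg():
    return SIM_CFG


@pytest.fixture(scope="session")
def sim_truth(sim_paths):
    return json.loads(Path(sim_paths["truth"]).read_text())["sites"]


@pytest.fixture(scope="session")
def sim_panel(sim_paths):
    return sm.read_panel(sim_paths["panel"])


@pytest.fixture(scope="session")
def sim_mart(sim_paths, sim_panel, tmp_path_factory):
    genes = sm.read_gene_bed(sim_paths["bed"])
    out = tmp_path_factory.mktemp("simmart") / "sim.mart"
    mart = sm.build_datamart(sim_paths["vcf"], sim_panel, genes, {}, out)
    yield mart
    mart.close()


def raw_groups_from_vcf(vcf_path, panel, pops=None):
    """Parse a VCF into raw per-population genotype-letter matrices.

    Returns ``{variant_id: {pop: [genotype-letter-tuples or None]}}`` —
    the naive re-scan representation the oracle functions consume.
    """
    reader = sm.read_vcf(vcf_path, panel)
    sample_pops = [panel.sample_to_pop[s] for s in reader.samples]
    wanted = set(pops) if pops is not None else set(sample_pops)
    out = {}
    for rec in reader:
        per_pop = {p: [] for p in wanted}
        for call, pop in zip(rec.calls, sample_pops):
            if pop not in wanted:
                continue
            letters = tuple(rec.alleles[i] for i in call) if call else None
            per_pop[pop].append(letters)
        out[rec.variant_id] = per_pop
    return out
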