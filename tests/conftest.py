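import pytest
from hypothesis import HealthCheck, settings

from sigrev import SimulationConfig, simulate_bundle
from sigrev.signatures import (DEFAULT_GRID, adaptive_lfc_cutoff, build_signature,
                               filter_de, map_orthologs)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: fast, fully featured miniature study used by most integration-style tests
SMALL_CONFIG = SimulationConfig(
    seed=11,
    n_genes_mouse=400,
    n_genes_human=380,
    program_sizes={"precystic_up": 40, "precystic_down": 40,
                   "cystic_up": 40, "cystic_down": 40,
                   "aki_up": 30, "aki_down": 20},
    n_compounds=60,
    n_planted_reversers=3,
    n_planted_mimics=2,
    n_forced_approved_reversers=2,
    n_gene_sets=12,
    gene_set_size_range=(8, 30),
)

#: dense universe for concordance power: enough null AKI-consensus genes reach
#: BH significance in the pre-cystic table to estimate its chance-level fraction
DENSE_CONCORDANCE_CONFIG = SimulationConfig(
    seed=0,
    n_genes_mouse=1250,
    n_genes_human=1300,
    program_sizes={"precystic_up": 330, "precystic_down": 330,
                   "cystic_up": 100, "cystic_down": 100,
                   "aki_up": 157, "aki_down": 88},
    n_compounds=20,
    n_planted_reversers=2,
    n_planted_mimics=1,
    n_forced_approved_reversers=2,
    n_gene_sets=10,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_bundle(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_bundle():
    return simulate_bundle(SimulationConfig(seed=7))


def build_precystic_signature(bundle, n_per_side=100, padj=0.05):
    """The pipeline's standard signature-construction steps on a bundle."""
    table = bundle.de_tables["precystic"]
    cutoff, _ = adaptive_lfc_cutoff(table, padj, grid=DEFAULT_GRID)
    mapped = map_orthologs(filter_de(table, cutoff, padj), bundle.orthology,
                           bundle.reference.universe)
    return build_signature(mapped, n_per_side, dataset_id="precystic",
                           lfc_cutoff=cutoff, padj_cutoff=padj)


def pipeline_up_gene_sets(bundle, padj=0.05, cut_precystic=1.1, cut_cystic=2.0):
    """Per-dataset upregulated human gene sets as the cascade consumes them."""
    out = {}
    for ds, table in bundle.de_tables.items():
        cut = cut_precystic if ds == "precystic" else cut_cystic
        de = filter_de(table, cut, padj)
        de = de[de["lfc"] > 0]
        out[ds] = set(map_orthologs(de, bundle.orthology,
                                    bundle.reference.universe)["gene_id"])
    return out
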