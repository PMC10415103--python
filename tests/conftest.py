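import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cernet.differential import (
    DEFAULT_THRESHOLDS,
    compute_fpkm,
    compute_tpm,
    de_analysis,
)
from cernet.synthetic_data import COMPARISONS, PlantConfig, generate, paper_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gen_bundle():
    """The standard planted bundle (strong effects, dispersion 0.05)."""
    return generate(PlantConfig(seed=42))


@pytest.fixture(scope="session")
def fixture_bundle():
    """The calibrated bundle realizing the published summary counts."""
    return paper_fixture(42)


def normalize_layers(bundle):
    out = {}
    for layer in ("lncRNA", "mRNA", "miRNA"):
        counts = bundle.counts[layer]
        lengths = bundle.lengths(layer)
        out[layer] = (
            compute_tpm(counts, lengths) if layer == "miRNA" else compute_fpkm(counts, lengths)
        )
    return out


def de_calls(norm, layer):
    """Per-comparison (up, down) feature-id sets after the full DE chain."""
    calls = {}
    for comp in COMPARISONS:
        _, results = de_analysis(norm[layer], comp, DEFAULT_THRESHOLDS[layer])
        calls[comp.name] = (
            {r.feature_id for r in results if r.direction == "up"},
            {r.feature_id for r in results if r.direction == "down"},
        )
    return calls


@pytest.fixture(scope="session")
def gen_norm(gen_bundle):
    return normalize_layers(gen_bundle)


@pytest.fixture(scope="session")
def gen_de_sets(gen_bundle, gen_norm):
    sets = {}
    for layer in ("lncRNA", "mRNA", "miRNA"):
        sets[layer] = set()
        for up, down in de_calls(gen_norm, layer).values():
            sets[layer] |= up | down
    return sets


@pytest.fixture(scope="session")
def gen_mre_hits(gen_bundle, gen_de_sets):
    from cernet.cerna_network import predict_mre

    hits = []
    for mid, mseq in gen_bundle.mirna_seqs.items():
        if mid not in gen_de_sets["miRNA"]:
            continue
        for layer in ("lncRNA", "mRNA"):
            for host in sorted(gen_de_sets[layer]):
                if host in gen_bundle.transcript_seqs:
                    hits.extend(
                        predict_mre(mseq, gen_bundle.transcript_seqs[host], mid, host, layer)
                    )
    return hits


@pytest.fixture
def rng():
    return np.random.default_rng(0)
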