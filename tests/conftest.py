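import numpy as np
import pytest
from hypothesis import settings

import tadscan as ts

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same deterministic stream
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-chromosome world, no expression planted yet."""
    cfg = ts.SimulationConfig(
        chromosome_lengths=(8_000_000, 8_000_000),
        n_genes=60, n_markers=200, n_peaks=300,
    )
    return ts.generate_genome(cfg, seed=101)


@pytest.fixture(scope="session")
def null_world():
    """All-null truth: expression is intercept + noise for every gene."""
    cfg = ts.SimulationConfig(n_genes=150, n_markers=400, n_peaks=600)
    ds = ts.generate_genome(cfg, seed=11)
    ds, _ = ts.plant_models(ds, ts.TruthSpec(class_proportions={"null": 1.0}), seed=12)
    return ds


@pytest.fixture(scope="session")
def null_scan(null_world):
    """100k random intrachromosomal trios fit on the all-null world."""
    return ts.run_scan(null_world, ts.ScanPlan(n_models=100_000, seed=13))


def dense_interacting_config():
    """Dense marker/peak placement so intra-TAD causality can be forced."""
    return ts.SimulationConfig(
        chromosome_lengths=(8_000_000, 8_000_000),
        n_genes=200, n_markers=350, n_peaks=350,
        tad_min_bp=500_000, gap_prob=0.0, tile_to_end=True,
    )


@pytest.fixture(scope="session")
def interacting_world():
    """Every gene planted interacting, causal elements intra-TAD, |b3|>=0.5."""
    ds = ts.generate_genome(dense_interacting_config(), seed=21)
    spec = ts.TruthSpec(
        class_proportions={"interacting": 1.0},
        beta3_range=(0.5, 1.0),
        intra_tad_prob=1.0,
        sigma=0.3,
    )
    ds, records = ts.plant_models(ds, spec, seed=22)
    return ds, records


@pytest.fixture(scope="session")
def interacting_scan(interacting_world):
    ds, _ = interacting_world
    return ts.run_scan(ds, ts.ScanPlan(mode="tad_constrained", alpha=1e-7))


@pytest.fixture(scope="session")
def mixed_world():
    """Planted class mixture with 80% intra-TAD causal placement."""
    ds = ts.generate_genome(dense_interacting_config(), seed=31)
    spec = ts.TruthSpec(
        class_proportions={
            "null": 0.1, "genotype_only": 0.2, "atac_only": 0.1,
            "additive": 0.2, "interacting": 0.4,
        },
        beta3_range=(0.5, 1.0),
        intra_tad_prob=0.8,
        sigma=0.3,
    )
    ds, records = ts.plant_models(ds, spec, seed=32)
    return ds, records


@pytest.fixture(scope="session")
def mixed_scan(mixed_world):
    ds, _ = mixed_world
    return ts.run_scan(ds, ts.ScanPlan(mode="tad_constrained", alpha=1e-7))


@pytest.fixture(scope="session")
def ctcf_pwm():
    """A length-8 informative motif with soft probabilities (no exact zeros)."""
    rows = []
    consensus = [2, 2, 1, 1, 0, 3, 2, 0]  # GGCCATGA-like
    for c in consensus:
        row = np.full(4, 0.06)
        row[c] = 0.82
        rows.append(row)
    return ts.PWM(np.array(rows), name="ctcf_synthetic")
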