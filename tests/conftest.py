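import numpy as np
import pytest

from poca import PocaConfig, SimConfig, generate, match_labels
from poca.pipeline import analyze_recording


def labeled_simulation(seed: int, config: PocaConfig | None = None, **sim_kwargs):
    """Generate, analyze and ground-truth-label one synthetic recording."""
    sim = generate(SimConfig(seed=seed, **sim_kwargs))
    res = analyze_recording(sim.recording, config)
    tol = 0.25 / sim.config.locomotor_freq
    table, coverage = match_labels(sim.labels, res.table, tol)
    return sim, res, table, coverage


@pytest.fixture(scope="session")
def cfg() -> PocaConfig:
    return PocaConfig()


@pytest.fixture(scope="session")
def benchmark():
    """Ten default-condition synthetic recordings (seeds 1-10), labeled."""
    out = {}
    for seed in range(1, 11):
        sim, res, table, coverage = labeled_simulation(seed)
        out[f"sim{seed:02d}"] = {
            "sim": sim,
            "result": res,
            "table": table,
            "coverage": coverage,
        }
    return out


@pytest.fixture(scope="session")
def benchmark_tables(benchmark):
    """Recording id -> labeled peak table, for harness-level tests."""
    return {rid: item["table"] for rid, item in benchmark.items()}


@pytest.fixture(scope="session")
def noiseless():
    """A noise-free synthetic recording for exact-recovery checks."""
    return labeled_simulation(99, noise_sd=0.0)
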