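import numpy as np
import pytest

from strdnm.simulate import SimConfig, generate_catalog, inject_errors, simulate_pedigrees
from strdnm.phasing import phase_calls
from strdnm.trio import call_mdnms

ZERO_ERROR = {i: 0.0 for i in range(1, 7)}


def zero_noise_config(**overrides) -> SimConfig:
    """Noise-free study conditions: every marker-trio testable, no errors."""
    base = dict(
        n_markers=400,
        n_trios=80,
        n_threegen_families=15,
        genotyping_error_rate=dict(ZERO_ERROR),
        dropout_rate=0.0,
        availability_mean=1.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Simulated cohort with no genotyping noise, fully called and phased."""
    cfg = zero_noise_config()
    rng = np.random.default_rng(123)
    cat = generate_catalog(cfg, rng)
    sim = simulate_pedigrees(cat, cfg, rng)
    observed = inject_errors(sim, cfg, rng)
    result = call_mdnms(observed, sim.pedigree, cat)
    phased, concordance = phase_calls(
        result["calls"], sim.read_evidence, sim.threegen_evidence
    )
    return {
        "config": cfg,
        "catalog": cat,
        "sim": sim,
        "observed": observed,
        "result": result,
        "phased": phased,
        "concordance": concordance,
    }


@pytest.fixture(scope="session")
def noisy_cohort():
    """Simulated cohort at default noise levels."""
    cfg = SimConfig(n_markers=400, n_trios=100, n_threegen_families=15)
    rng = np.random.default_rng(7)
    cat = generate_catalog(cfg, rng)
    sim = simulate_pedigrees(cat, cfg, rng)
    observed = inject_errors(sim, cfg, rng)
    result = call_mdnms(observed, sim.pedigree, cat)
    return {"config": cfg, "catalog": cat, "sim": sim, "observed": observed, "result": result}
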