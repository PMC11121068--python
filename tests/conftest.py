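import numpy as np
import pytest

from popexclusive import (
    GenotypeMatrix,
    PopulationSpec,
    QualityConfig,
    SimConfig,
    SpikeConfig,
    VariantKey,
    simulate_study,
)


def make_matrix(doses, samples=None, variants=None, dp=None, gq=None):
    """Build a GenotypeMatrix from a nested list (samples x variants)."""
    dose = np.asarray(doses, dtype=np.int8)
    ns, nv = dose.shape
    if samples is None:
        samples = [f"S{i}" for i in range(ns)]
    if variants is None:
        variants = [VariantKey("1", 1000 + 10 * j, "A", "G") for j in range(nv)]
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dose=dose,
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
    )


def small_sim_config(seed=0, **overrides):
    """A scaled-down study configuration for fast unit tests."""
    defaults = dict(
        n_sites=400,
        seed=seed,
        populations=(
            PopulationSpec("NAVARRE", 0.0005, 80),
            PopulationSpec("IBS", 0.0005, 60),
            PopulationSpec("MGP", 0.001, 80),
            PopulationSpec("gnomAD", 0.01, 1000),
            PopulationSpec("EUR", 0.004, 60),
            PopulationSpec("EAS", 0.03, 60),
            PopulationSpec("AFR", 0.045, 60),
        ),
        kgp_labels=("EUR", "EAS", "AFR"),
        n_validation=60,
        spike=SpikeConfig(n_exclusive=20),
        quality=QualityConfig(),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_sim_config(seed=11))
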