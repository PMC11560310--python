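import numpy as np
import pytest

from prolens.ensembles import GeneratorConfig, sample_ensemble


@pytest.fixture(scope="session")
def small_ensemble():
    """200-frame default-peptide ensemble, uniform weights."""
    return sample_ensemble(GeneratorConfig(n_conformers=200, seed=11))


@pytest.fixture(scope="session")
def ensemble_5000():
    """5000-frame ensemble at the reference cis fraction (p = 0.10)."""
    return sample_ensemble(GeneratorConfig(n_conformers=5000, seed=42))


@pytest.fixture(scope="session")
def cis_compact_ensemble():
    """Ensemble whose cis subensemble is generated more compact than the
    trans one (compaction applied to the cis stratum only), by merging two
    separately generated strata with matching topology."""
    from prolens.ensembles import Ensemble

    n_cis, n_trans = 300, 1700
    cis = sample_ensemble(GeneratorConfig(
        n_conformers=n_cis, cis_fraction=1.0, compaction=4.0, seed=5))
    trans = sample_ensemble(GeneratorConfig(
        n_conformers=n_trans, cis_fraction=0.0, compaction=0.0, seed=6))
    coords = np.concatenate([cis.coords, trans.coords])
    n = n_cis + n_trans
    return Ensemble(cis.topology, coords, np.full(n, 1.0 / n),
                    {"seed": (5, 6)})
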