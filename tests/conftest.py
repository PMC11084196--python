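import numpy as np
import pytest

from hsascreen import GeneratorConfig, KineticParams, LigandRecord

#: Averaged baseline rates of the solvent-matched (DMSO) HSA-Abeta40
#: interaction, used as the generating truth in round-trip studies.
BASELINE_DMSO = dict(ka1=2.7e2, kd1=0.216e-4, ka2=8.9e2, kd2=26e-4)

#: Five-point HSA titration of the SPR assay, M.
ASSAY_CONCS = (2.5e-6, 5e-6, 10e-6, 20e-6, 40e-6)


@pytest.fixture
def baseline_params() -> KineticParams:
    return KineticParams(**BASELINE_DMSO)


@pytest.fixture
def passing_record():
    """A record that clears every filter stage."""

    def make(**overrides):
        base = dict(
            id="L1",
            name="ligand",
            mass=300.0,
            solubility=100.0,
            bbb_penetration=80.0,
            plasma_conc=10.0,
            ad_refs=5,
            is_fatty_acid=False,
        )
        base.update(overrides)
        return LigandRecord(**base)

    return make


@pytest.fixture
def planted_sites():
    """Well-separated 5-cluster synthetic sites (separation >> jitter)."""
    from hsascreen import gen_binding_sites

    cfg = GeneratorConfig(seed=11, n_clusters=5, sites_per_cluster=8, site_jitter=1)
    return gen_binding_sites(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
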