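import numpy as np
import pytest

from hipquant import (AMIDATION, HEAVY_LEU, HipMHCSpec, PSMRecord,
                      SimulationConfig, generate_replicate_experiment)

CHANNELS = ["TMT126", "TMT127", "TMT128", "TMT129", "TMT130", "TMT131"]
LOSS = {"TMT126": 1.0, "TMT127": 0.8, "TMT128": 1.3,
        "TMT129": 0.5, "TMT130": 1.0, "TMT131": 2.0}


def tmt_psm(sequence="SIINFEKLM", reporter=None, mods=None, **kw):
    """A TMT PSM that passes the default filters unless overridden."""
    defaults = dict(
        sequence=sequence, modifications=mods or [], charge=2,
        ion_score=50.0, percolator_q=0.01, isolation_interference_pct=5.0,
        search_rank=1, sample_id="plex1", fraction_id="f1", rt_sec=1000.0,
        scan=1,
        reporter=reporter or {c: 100.0 for c in CHANNELS})
    defaults.update(kw)
    return PSMRecord(**defaults)


def lf_psm(sequence="SIINFEKLM", auc=1000.0, sample_id="s1", **kw):
    defaults = dict(
        sequence=sequence, modifications=[], charge=2, ion_score=50.0,
        search_rank=1, sample_id=sample_id, fraction_id="f1",
        rt_sec=1000.0, scan=1, auc=auc)
    defaults.update(kw)
    return PSMRecord(**defaults)


@pytest.fixture
def correction_spec():
    return HipMHCSpec("ALNEQIARL", [9], "correction",
                      {c: 30.0 for c in CHANNELS})


@pytest.fixture
def titration_spec():
    amounts = dict(zip(CHANNELS, [30.0, 60.0, 100.0, 150.0, 200.0, 300.0]))
    return HipMHCSpec("SVVESVKFL", [8], "titration", amounts)


@pytest.fixture(scope="session")
def noisefree_experiment():
    """6-plex with known loss factors, no noise: correction is exact."""
    cfg = SimulationConfig(seed=11, n_peptides=150, sigma_log2=0.0,
                           loss_factors=dict(LOSS), psm_rate=2.0)
    return generate_replicate_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_experiment():
    cfg = SimulationConfig(seed=7, n_peptides=300, sigma_log2=0.2,
                           loss_factors=dict(LOSS))
    return generate_replicate_experiment(cfg)


def default_norm(experiment):
    """Run the normalization stage on a generated experiment tuple."""
    from hipquant import default_standards, normalize_experiment
    records, _, layout = experiment
    return normalize_experiment(records, default_standards(CHANNELS), layout)


def heavy_mods(position=9, amidated=True):
    mods = [(HEAVY_LEU, position)]
    if amidated:
        mods.append((AMIDATION, 0))
    return mods


def rng(seed=0):
    return np.random.default_rng(seed)
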