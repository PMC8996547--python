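import numpy as np
import pytest

from xspecies.intervals import GenomicInterval, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_peak(chrom="chr1", start=100, end=600, summit=None, species="mouse",
              tissue="brain", name="p1", dataset_id="ds1"):
    if summit is None:
        summit = (start + end) // 2
    return Peak(
        interval=GenomicInterval(species, chrom, start, end),
        summit=summit, tissue=tissue, dataset_id=dataset_id, name=name,
    )


@pytest.fixture
def tiny_cohort():
    """Small but fully featured cohort shared across tests (session cache)."""
    return _tiny_cohort_cached()


_CACHE = {}


def _tiny_cohort_cached():
    if "tiny" not in _CACHE:
        from xspecies.simulate import SimConfig, simulate_cohort

        _CACHE["tiny"] = simulate_cohort(
            SimConfig(n_regions=240, n_clade_loss=30, seed=7)
        )
    return _CACHE["tiny"]


@pytest.fixture
def noiseless_cohort():
    """Dropout-free cohort: ortholog map total, constructors vs truth exact."""
    if "noiseless" not in _CACHE:
        from xspecies.simulate import SimConfig, simulate_cohort

        _CACHE["noiseless"] = simulate_cohort(
            SimConfig(n_regions=240, n_clade_loss=30, dropout_rate_per_my=0.0, seed=9)
        )
    return _CACHE["noiseless"]
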