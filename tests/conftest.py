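import numpy as np
import pytest

from photocap import season


@pytest.fixture(scope="session")
def design():
    return season.build_default_design()


@pytest.fixture()
def default_cfg():
    return season.TraitTrajectoryConfig(rng_seed=0)


@pytest.fixture()
def noiseless_cfg():
    cfg = season.TraitTrajectoryConfig(rng_seed=0)
    cfg.anchors = {
        k: season.TraitAnchors(a.baseline, a.peak, a.end, 0.0)
        for k, a in cfg.anchors.items()
    }
    cfg.sla_cv = 0.0
    return cfg


def make_truth(vcmax25=100.0, jmax25=160.0, rd25=1.5, **kw):
    """A single plausible leaf with the given capacities."""
    defaults = dict(
        leaf_id="L1",
        doy=126,
        stage="Flowering",
        n_area=200.0,
        chl_area=72.0,
        car_area=12.0,
        sla=200.0,
    )
    defaults.update(kw)
    return season.SyntheticLeafTruth(
        vcmax25=vcmax25, jmax25=jmax25, rd25=rd25, **defaults
    )


@pytest.fixture()
def leaf_truth():
    return make_truth()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
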