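import numpy as np
import pytest

from morphotraj import synthetic as syn
from morphotraj import pipeline


@pytest.fixture(scope="session")
def base_skull():
    return syn.make_base_skull()


@pytest.fixture(scope="session")
def fixture_tree():
    return syn.fixture_tree()


@pytest.fixture(scope="session")
def fixture_study():
    """One simulated 12-taxon study with its full analysis (no
    permutation tests, for speed); shared across tests."""
    configs, tree, truth, info = pipeline.simulate_fixture_study(seed=11)
    result = pipeline.analyze_fixture_study(configs, tree, n_perm_regression=0,
                                            n_perm_signal=0, seed=11)
    return {"configs": configs, "tree": tree, "truth": truth, "info": info,
            "result": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def to_aligned_frame(vector, truth, sample):
    """Rotate a generator-frame shape vector into the canonical frame of
    an aligned sample (the GPA orients shapes by consensus principal
    axes, so truth directions must be rotated before comparison)."""
    from morphotraj.superimposition import optimal_rotation
    base = truth.base_shape.reshape(-1, 2)
    cons = sample.consensus.reshape(-1, 2)
    r = optimal_rotation(base, cons)
    w = (np.asarray(vector).reshape(-1, 2) @ r).reshape(-1)
    if sample.tangent_projected:
        c = sample.consensus
        w = w - (w @ c) * c  # directions live in the tangent plane at c
    return w


def random_configs(n, k, rng, spread=0.05):
    """Plain random landmark configurations around the schematic skull."""
    from morphotraj.io import LandmarkConfiguration
    base = syn.make_base_skull(k) if k >= 10 else None
    out = []
    for i in range(n):
        if base is not None:
            xy = base.coords + rng.normal(0, spread * 3, size=(k, 2))
        else:
            xy = rng.normal(0, 1, size=(k, 2))
        out.append(LandmarkConfiguration(specimen_id=f"sp{i}", taxon=f"t{i}",
                                         stage="adult", coords=xy))
    return out
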