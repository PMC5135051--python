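import numpy as np
import pytest

from antweb.network_model import InteractionEvent, LayerMatrix


def make_layer(A, resource="EFN") -> LayerMatrix:
    """Wrap a plain array (no zero rows/cols) as a LayerMatrix with P*/A* labels."""
    A = np.asarray(A)
    plants = [f"P{i + 1}" for i in range(A.shape[0])]
    ants = [f"A{j + 1}" for j in range(A.shape[1])]
    return LayerMatrix(resource, plants, ants, A)


def make_event(plant="P1", ant="A1", resource="EFN", site="S1", **kw) -> InteractionEvent:
    defaults = dict(site_id=site, plot_id="p1", season="Jan", workers=1)
    defaults.update(kw)
    return InteractionEvent(plant_sp=plant, ant_sp=ant, resource=resource, **defaults)


@pytest.fixture
def tiny_layer() -> LayerMatrix:
    """The 2x2 event-count example [[2,0],[0,1]]."""
    return make_layer([[2, 0], [0, 1]])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
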