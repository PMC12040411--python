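import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecodist as ed
from ecodist import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_collection():
    """A small but structurally complete collection (no climate)."""
    cfg = ed.SyntheticConfig(
        n_ecoregions=8,
        plots_per_ecoregion=30,
        pixels_per_ecoregion=3,
        include_climate=False,
        seed=42,
    )
    return ed.generate_collection(cfg)


@pytest.fixture(scope="session")
def small_pairwise(small_collection):
    """Pairwise separation table for the small collection."""
    c = small_collection
    scaled = ed.scale_amplitudes(ed.descriptor_sets(c.series))
    centroids = ed.indicator_centroids(c.plots, c.indicator_names, min_plots=30)
    geo = (
        c.plots.groupby("ecoregion_id")[["lat", "lon"]].mean().reset_index()
    )
    return ed.pairwise_table(centroids, scaled, geo)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def predictor_cols(small_collection):
    return syn.predictor_columns(small_collection.plots)
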