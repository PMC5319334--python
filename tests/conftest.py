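import numpy as np
import pytest

from bowercourt import CourtGeometry, CourtModel, CourtObject, generate_court


@pytest.fixture
def geom():
    """Default viewing frame: entrance 20 cm ahead, 80 x 100 cm court."""
    return CourtGeometry()


@pytest.fixture
def flat_geom():
    """Eye in the ground plane: depth angles vanish."""
    return CourtGeometry(eye_height=0.0)


def make_court(n, seed, *, slope=0.02, noise=0.3, geom=None):
    model = CourtModel(
        n_objects=n,
        slope_width=slope,
        slope_depth=slope,
        noise_sd=noise,
        geometry=geom or CourtGeometry(),
        seed=seed,
    )
    return generate_court(model)


@pytest.fixture
def small_court(geom):
    """Five objects with a clear positive size-distance gradient."""
    return make_court(5, seed=11, geom=geom)


@pytest.fixture
def court20(geom):
    return make_court(20, seed=42, geom=geom)


def on_axis_objects(xs, widths, depths=None):
    """Objects straight down the avenue axis at the given x positions."""
    depths = depths if depths is not None else widths
    return [
        CourtObject(id=f"o{i}", x=float(x), y=0.0,
                    visible_width=float(w), visible_depth=float(d))
        for i, (x, w, d) in enumerate(zip(xs, widths, depths))
    ]
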