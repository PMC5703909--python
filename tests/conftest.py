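import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rodquant as rq

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_config(seed=0, n_cells=20, field=(800, 800), channels=(), **kw):
    return rq.SimConfig(
        n_cells=n_cells, field_shape=field, seed=seed, channels=list(channels), **kw
    )


@pytest.fixture(scope="session")
def wt_like_field():
    """Small wild-type-like field: symmetric ParB focus pairs at SNR ~10,
    a centered half-length nucleoid, and bipolar subpolar patches."""
    cfg = make_config(
        seed=11,
        n_cells=15,
        channels=[
            dict(
                name="parb",
                kind="foci",
                rule="symmetric_pair",
                count_probs={2: 1.0},
                amplitude=rq.focus_amplitude_for_snr(10, 100.0, 1.3),
            ),
            dict(name="dapi", kind="nucleoid", amplitude=rq.extended_amplitude_for_snr(10, 100.0)),
            dict(name="bacp", kind="patch", polarity="bipolar", amplitude=300.0),
        ],
    )
    truths, channels, labels = rq.simulate_field(cfg)
    return cfg, truths, channels, labels


@pytest.fixture(scope="session")
def wt_geometries(wt_like_field):
    cfg, truths, channels, labels = wt_like_field
    return rq.extract_geometry(labels, cfg.pixel_size)


def synth_geom(length_um, cell_id=1, pixel_size=0.1):
    """Directly constructed horizontal straight-axis frame (no mask)."""
    n = length_um / pixel_size
    return rq.CellGeometry(
        cell_id=cell_id,
        pixel_size=pixel_size,
        pole_a=np.array([0.0, 0.0]),
        pole_b=np.array([0.0, n]),
        centroid=np.array([0.0, n / 2]),
        axis=np.array([0.0, 1.0]),
        length_um=length_um,
        area_px=int(10 * n),
    )


def straight_cell_mask(shape=(60, 200), row0=20, row1=40, col0=30, col1=170, label=1):
    """Axis-aligned rectangular 'cell' label mask for exact geometry checks."""
    m = np.zeros(shape, dtype=np.uint16)
    m[row0:row1, col0:col1] = label
    return m
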