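"""Shared fixtures: small synthetic scenes and label-map builders."""

from __future__ import annotations

import numpy as np
import pytest

from trisyn.scenes import MarkerParams, SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def puncta_config(**overrides) -> SceneConfig:
    """A small, fast single-marker scene used across tests."""
    defaults = dict(
        field_size_px=(256, 256),
        markers={"vacht": MarkerParams(1500.0, 3.0, 0.15, 120.0, 15.0)},
        presyn_roles=("vacht",),
        soma_count=0,
        nucleus_count=0,
        psd_apposition_prob=0.0,
        tripartite_prob=0.0,
        ptdp43_clusters_per_bouton_rate=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


def noise_free(**overrides) -> dict:
    """Config overrides disabling every noise source."""
    base = dict(shot_noise_scale=0.0, read_noise_sd=0.0, background_level=0.0)
    base.update(overrides)
    return base


def random_label_map(rng: np.random.Generator, shape=(64, 64), n_seeds=12) -> np.ndarray:
    """Random blobby label map: labelled discs stamped at random positions."""
    labels = np.zeros(shape, dtype=np.int32)
    h, w = shape
    lab = 0
    for _ in range(n_seeds):
        lab += 1
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = rng.integers(2, 7)
        yy, xx = np.mgrid[0:h, 0:w]
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = lab
    # relabel contiguous since stamps may overwrite whole blobs
    out = np.zeros_like(labels)
    for i, l in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == l] = i
    return out


def disc_mask(shape, cy, cx, r) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
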