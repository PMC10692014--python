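"""Shared fixtures: seeded phantom clips and corpora, generated at test time."""

import numpy as np
import pytest
from scipy import ndimage

from ivcflow import phantom, retrieval, segmentation


@pytest.fixture(scope="session")
def ivc_clip():
    """A mid-size good-quality IVC phantom with 50% true collapsibility."""
    params = phantom.PhantomParams(
        d_max_mm=15.0, d_min_mm=7.5, mm_per_px=0.3, image_size=(160, 240),
        frame_rate_hz=10.0, resp_period_s=4.0, n_cycles=2, seed=42,
    )
    clip, masks, truth, labels = phantom.make_clip(params)
    return params, clip, masks, truth, labels


@pytest.fixture(scope="session")
def small_corpus():
    """Labelled corpus with a withheld (never-trained) Doppler-like view."""
    spec = phantom.CorpusSpec(
        counts={"ivc": 10, "plax_like": 7, "a4c_like": 7, "doppler_like": 6},
        n_frames=8, image_size=(96, 128),
    )
    return phantom.make_corpus(spec, seed=11)


@pytest.fixture(scope="session")
def trained_two_head(small_corpus):
    model = retrieval.train_two_head(small_corpus, seed=5)
    frames, views, _ = small_corpus.subset("train").frames_and_labels()
    calibration = retrieval.calibrate_openmax(model, frames, views)
    return model, calibration


def random_blob_mask(seed: int, size: int = 64, clean: bool = False) -> np.ndarray:
    """Random single-8-connected-component mask from thresholded smooth noise."""
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.normal(size=(size, size)), rng.uniform(1.0, 4.0))
    mask = img > np.quantile(img, rng.uniform(0.55, 0.9))
    if clean:
        return segmentation.clean_mask(mask)
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        return np.zeros((size, size), bool)
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return lab == 1 + int(np.argmax(sizes))
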