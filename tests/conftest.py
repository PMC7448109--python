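from dataclasses import replace

import numpy as np
import pytest

from prostadx import pipeline, synth
from prostadx.config import RunConfig


def convex_mask(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """Random rasterized convex shape (rotated filled ellipse) in a
    size x size raster; regenerates until nonempty."""
    while True:
        a = rng.uniform(1.5, size / 3.5)
        b = rng.uniform(1.5, size / 3.5)
        theta = rng.uniform(0, np.pi)
        cy, cx = rng.uniform(size / 3, 2 * size / 3, size=2)
        rr, cc = np.mgrid[0:size, 0:size]
        x = (cc - cx) * np.cos(theta) + (rr - cy) * np.sin(theta)
        y = -(cc - cx) * np.sin(theta) + (rr - cy) * np.cos(theta)
        mask = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        if mask.any():
            return mask


def hysteresis_bfs_oracle(mag: np.ndarray, t_low: float, t_high: float) -> np.ndarray:
    """Breadth-first connectivity oracle for double thresholding."""
    from collections import deque

    h, w = mag.shape
    strong = mag >= t_high
    weak = mag >= t_low
    out = np.zeros_like(strong)
    queue = deque(zip(*np.nonzero(strong)))
    for r, c in queue:
        out[r, c] = True
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and weak[rr, cc] and not out[rr, cc]:
                    out[rr, cc] = True
                    queue.append((rr, cc))
    return out.astype(np.uint8)


def finite_diff_gradients(net, x, desired, h=1e-6):
    """Central-difference gradient oracle for the squared-error loss."""
    from prostadx import mlp

    def loss_at(n):
        out, _ = mlp.forward(n, x)
        return 0.5 * (desired - out) ** 2

    gw = [np.zeros_like(w) for w in net.weights]
    gb = [np.zeros_like(b) for b in net.biases]
    for m, w in enumerate(net.weights):
        for idx in np.ndindex(w.shape):
            n2 = net.copy()
            n2.weights[m][idx] += h
            up = loss_at(n2)
            n2.weights[m][idx] -= 2 * h
            down = loss_at(n2)
            gw[m][idx] = (up - down) / (2 * h)
    for m, b in enumerate(net.biases):
        for idx in np.ndindex(b.shape):
            n2 = net.copy()
            n2.biases[m][idx] += h
            up = loss_at(n2)
            n2.biases[m][idx] -= 2 * h
            down = loss_at(n2)
            gb[m][idx] = (up - down) / (2 * h)
    return gw, gb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_config() -> RunConfig:
    """Default config with a reduced epoch budget for test-suite speed."""
    base = RunConfig()
    return RunConfig(
        marker_net=replace(base.marker_net, max_epochs=2000),
        image_net=replace(base.image_net, max_epochs=2000),
    )


@pytest.fixture(scope="session")
def small_cohort():
    spec = synth.CohortSpec(n=120, seed=3)
    patients = synth.generate_cohort(spec)
    return patients, synth.cohort_frame(patients)


@pytest.fixture(scope="session")
def trained_nets(small_cohort, fast_config):
    _, df = small_cohort
    marker_net, image_net, _, _ = pipeline.train_channels(df.iloc[:100], fast_config)
    return marker_net, image_net
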