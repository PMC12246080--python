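"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: smoothing is
verified against a directly sampled kernel and dense convolution, DBSCAN
against a from-the-definition O(n^2) reference on a full distance matrix,
and nearest-neighbour distances against a full pairwise scan.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitofish import (MinfluxSceneParams, PixelImage, StedSceneParams,
                      generate_minflux_scene, generate_sted_scene)
from mitofish.sted import FWHM_SIGMA


# ---------------------------------------------------------------------------
# oracles

def dense_gaussian_kernel(fwhm_nm: float, pitch: float, radius: int) -> np.ndarray:
    """Directly sampled, normalized isotropic Gaussian kernel."""
    sigma = fwhm_nm / FWHM_SIGMA / pitch
    ax = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma ** 2))
    return g / g.sum()


def brute_force_nn(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each row of a, min Euclidean distance to rows of b (full scan)."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN from the definition on a full O(n^2) distance matrix."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    neighborhoods = [np.nonzero(d[i] <= eps)[0].tolist() for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighborhoods]
    labels = np.full(n, -1, dtype=int)
    visited = [False] * n
    cluster = 0
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        stack = [i]
        visited[i] = True
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in neighborhoods[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                if not visited[k] and core[k]:
                    visited[k] = True
                    stack.append(k)
        cluster += 1
    return labels


def gaussian_spot_image(fwhm_nm: float, pitch: float = 20.0, size: int = 64,
                        amplitude: float = 100.0, center_px=None,
                        offset: float = 0.0) -> PixelImage:
    """Noiseless isotropic Gaussian spot sampled at pixel centers."""
    if center_px is None:
        center_px = (size // 2, size // 2)
    sigma = fwhm_nm / FWHM_SIGMA
    centers = (np.arange(size) + 0.5) * pitch
    x0 = (center_px[1] + 0.5) * pitch
    y0 = (center_px[0] + 0.5) * pitch
    gx = np.exp(-((centers - x0) ** 2) / (2 * sigma ** 2))
    gy = np.exp(-((centers - y0) ** 2) / (2 * sigma ** 2))
    return PixelImage(grid=amplitude * np.outer(gy, gx) + offset, pitch=pitch)


def match_spots(detected: np.ndarray, truth: np.ndarray, tol_nm: float = 100.0):
    """Greedy one-to-one matching of detected vs true positions."""
    tp, used = 0, set()
    for t in truth:
        if len(detected) == 0:
            continue
        dd = np.linalg.norm(detected - t, axis=1)
        order = np.argsort(dd)
        for j in order:
            if dd[j] > tol_nm:
                break
            if j not in used:
                used.add(int(j))
                tp += 1
                break
    fn = len(truth) - tp
    fp = len(detected) - len(used)
    return tp, fp, fn


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def sted_scene():
    params = StedSceneParams(image_size=192, seed=11, density=1.5,
                             min_separation=200.0)
    images, truth = generate_sted_scene(params)
    return params, images, truth


@pytest.fixture(scope="session")
def minflux_scene():
    params = MinfluxSceneParams(seed=11)
    raw, beads, truth = generate_minflux_scene(params)
    return params, raw, beads, truth
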