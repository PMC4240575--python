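"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (pure-python flood fill, per-voxel
eigendecomposition, permutation sampling): they re-derive the quantities
the package computes through an unrelated code path, at small problem
sizes, so the two can be compared.
"""

from __future__ import annotations

import numpy as np
import pytest

import angiomorph as am


@pytest.fixture(scope="session")
def tumor_phantom():
    """One seeded tumor-preset phantom shared across tests (~10 cm^3)."""
    spec = am.tumor_preset(seed=1)
    image, voi, tree, truth = am.generate_phantom(spec)
    return spec, image, voi, tree, truth


@pytest.fixture(scope="session")
def control_phantom():
    spec = am.control_preset(seed=2)
    image, voi, tree, truth = am.generate_phantom(spec)
    return spec, image, voi, tree, truth


@pytest.fixture(scope="session")
def phantom_config():
    return am.experiments.phantom_pipeline_config()


# ---------------------------------------------------------------- oracles

_NEIGHBORS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}
_NEIGHBORS[18] = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if 0 < abs(dx) + abs(dy) + abs(dz) <= 2
]
_NEIGHBORS[26] = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill_partition(mask: np.ndarray, connectivity: int) -> set[frozenset]:
    """Connected components by explicit BFS; returns a set of voxel sets."""
    offsets = _NEIGHBORS[connectivity]
    remaining = {tuple(c) for c in np.argwhere(mask)}
    parts = set()
    while remaining:
        seed = next(iter(remaining))
        remaining.discard(seed)
        comp = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for off in offsets:
                n = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if n in remaining:
                    remaining.discard(n)
                    comp.add(n)
                    frontier.append(n)
        parts.add(frozenset(comp))
    return parts


def labels_to_partition(labels: np.ndarray) -> set[frozenset]:
    parts = {}
    for c in np.argwhere(labels > 0):
        parts.setdefault(int(labels[tuple(c)]), set()).add(tuple(c))
    return {frozenset(v) for v in parts.values()}


def brute_force_multiscale_vesselness(vol, params) -> np.ndarray:
    """Literal per-voxel reimplementation: build each 3x3 Hessian, take
    eigenvalues, apply the closed-form score, maximize over scales."""
    best = np.zeros(vol.shape)
    for sigma in params.scales_mm:
        h = am.hessian_at_scale(vol, sigma, gamma=params.gamma_normalization)
        mats = h.as_matrix_field()
        if params.c is not None:
            c = params.c
        else:
            fro = 0.0
            for idx in np.ndindex(vol.shape):
                fro = max(fro, float(np.sqrt((mats[idx] ** 2).sum())))
            c = fro / 2.0 if fro > 0 else 1.0
        out = np.zeros(vol.shape)
        for idx in np.ndindex(vol.shape):
            w = np.linalg.eigvalsh(mats[idx])
            l1, l2, l3 = sorted(w, key=abs)
            if l2 > 0 or l3 > 0 or abs(l3) == 0:
                v = 0.0
            else:
                ra = abs(l2) / abs(l3)
                rb = abs(l1) / np.sqrt(abs(l2) * abs(l3))
                s = np.sqrt(l1**2 + l2**2 + l3**2)
                v = (
                    (1 - np.exp(-(ra**2) / (2 * params.alpha**2)))
                    * np.exp(-(rb**2) / (2 * params.beta**2))
                    * (1 - np.exp(-(s**2) / (2 * c**2)))
                )
            out[idx] = v
        best = np.maximum(best, out)
    return best


def permutation_wilcoxon_p(diffs: np.ndarray, n_draws: int, rng) -> float:
    """Monte-Carlo estimate of the two-sided (doubled min-tail) p-value by
    random sign assignment on the observed ranks."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    signs = rng.random((n_draws, len(d))) < 0.5
    w_star = (signs * ranks).sum(axis=1)
    p_le = (w_star <= w_obs + 1e-12).mean()
    p_ge = (w_star >= w_obs - 1e-12).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def make_cylinder_mask(shape, spacing, p0, p1, radius) -> np.ndarray:
    """Brute-force voxel-center distance test against one segment (mm)."""
    spacing = np.asarray(spacing, dtype=float)
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    centers = (idx + 0.5) * spacing
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    ab = p1 - p0
    t = np.clip(((centers - p0) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = p0 + t[..., None] * ab
    d = np.linalg.norm(centers - proj, axis=-1)
    return d <= radius
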