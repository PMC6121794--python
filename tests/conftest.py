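"""Shared fixtures and independent-oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import craterlakes as cl
from craterlakes.morphometrics import centroid_size


# ---------------------------------------------------------------------------
# helpers (importable as `from conftest import ...`)
# ---------------------------------------------------------------------------

def make_shape_data(offsets: dict, n=30, noise=0.1, seed=0, p=24) -> cl.ShapeData:
    """Gaussian groups around given flat mean vectors (corrected-space toy)."""
    rng = np.random.default_rng(seed)
    coords, groups = [], []
    for name, off in offsets.items():
        off = np.zeros(p) if off is None else np.asarray(off, dtype=float)
        coords.append(off + rng.normal(0.0, noise, size=(n, p)))
        groups += [name] * n
    return cl.ShapeData(
        np.vstack(coords), np.array(groups, dtype=object), state="allometry_corrected"
    )


def zero_sum_orthogonal_vectors(p=24):
    """Two zero-mean, mutually orthogonal sign patterns (Pearson corr 0)."""
    v1 = np.tile([1.0, -1.0], p // 2)
    v2 = np.tile([1.0, 1.0, -1.0, -1.0], p // 4)
    assert abs(v1.sum()) < 1e-12 and abs(v2.sum()) < 1e-12 and abs(v1 @ v2) < 1e-12
    return v1, v2


def brute_force_two_shape_procrustes(s1: np.ndarray, s2: np.ndarray, step=1e-4):
    """Grid-search ordinary Procrustes fit of two shapes.

    Both inputs are centred and scaled to unit centroid size here; the
    rotation angle of s2 onto s1 is found by exhaustive search.  Returns
    (min distance, consensus of the midpoint, rotated s2).
    """
    def norm(s):
        s = s - s.mean(axis=0)
        return s / np.sqrt((s**2).sum())

    s1, s2 = norm(s1), norm(s2)
    angles = np.arange(0.0, 2 * np.pi, step)
    cos, sin = np.cos(angles), np.sin(angles)
    # distance^2(theta) = 2 - 2*(A cos + B sin) with A = <s1, s2>, B = <s1, rot90(s2)>
    a = float((s1 * s2).sum())
    b = float((s1[:, 0] * -s2[:, 1] + s1[:, 1] * s2[:, 0]).sum())
    d2 = 2.0 - 2.0 * (a * cos + b * sin)
    i = int(np.argmin(d2))
    rot = np.array([[cos[i], sin[i]], [-sin[i], cos[i]]])
    s2r = s2 @ rot
    mid = norm((s1 + s2r) / 2.0)
    return float(np.sqrt(max(d2[i], 0.0))), mid, s2r


def rotate_flat_into_base(flat_vec: np.ndarray, consensus: np.ndarray,
                          base: np.ndarray) -> np.ndarray:
    """Re-express a flat (2k,) vector from the GPA frame in the base frame.

    GPA fixes orientation only up to the initial reference, so planted
    effects come back globally rotated; this applies the optimal rotation
    of the consensus onto the (centred) base to undo that.
    """
    from craterlakes.morphometrics import optimal_rotation

    centred = base - base.mean(axis=0)
    rot = optimal_rotation(consensus, centred / np.sqrt((centred**2).sum()))
    return (flat_vec.reshape(-1, 2) @ rot).ravel()


def brute_force_mahalanobis(xa: np.ndarray, xb: np.ndarray, rank: int) -> float:
    """Explicit-eigendecomposition Mahalanobis distance between two groups."""
    pooled = np.zeros((xa.shape[1], xa.shape[1]))
    dof = 0
    for x in (xa, xb):
        xc = x - x.mean(axis=0)
        for row in xc:
            pooled += np.outer(row, row)
        dof += x.shape[0] - 1
    pooled /= dof
    evals, evecs = np.linalg.eigh(pooled)
    order = np.argsort(evals)[::-1][:rank]
    delta = xa.mean(axis=0) - xb.mean(axis=0)
    total = 0.0
    for idx in order:
        if evals[idx] > 1e-10 * evals.max():
            total += (evecs[:, idx] @ delta) ** 2 / evals[idx]
    return float(np.sqrt(total))


def brute_force_jackknife_se(num: np.ndarray, den: np.ndarray, n_blocks: int) -> float:
    """Ordinary delete-one block jackknife SE for equal-sized blocks."""
    m = num.size // n_blocks
    loo = []
    for j in range(n_blocks):
        keep = np.ones(num.size, dtype=bool)
        keep[j * m:(j + 1) * m] = False
        loo.append(num[keep].sum() / den[keep].sum())
    loo = np.asarray(loo)
    return float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def unit_base():
    """The 12-landmark fish base shape at unit centroid size."""
    base = cl.BASE_FISH_SHAPE
    return base / centroid_size(base)


@pytest.fixture(scope="session")
def two_group_landmarks(unit_base):
    """Raw landmark data with a planted +/-d elongation contrast.

    Offsets are pure shape changes (orthogonal to the similarity
    directions), so the group mean difference survives superimposition.
    """
    d = cl.elongation_offset(0.02, unit_base)
    spec = cl.SyntheticLandmarkSpec(
        base_shape=unit_base,
        groups=[
            cl.GroupSpec("crater", 30, mean_offset=d),
            cl.GroupSpec("source", 30, mean_offset=-d),
        ],
        landmark_noise_sd=0.01,
    )
    return cl.generate_landmark_dataset(spec, seed=7), d


@pytest.fixture(scope="session")
def null_genotypes():
    """Four-population genotypes with no admixture."""
    return cl.generate_genotype_dataset(
        cl.SyntheticGenotypeSpec(n_snps=2000), seed=11
    )
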