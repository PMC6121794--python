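"""Group-level shape statistics: distances, within-lake variation, PCA.

Distances are computed between group mean shapes on a single global
superimposition (after allometry correction); within-lake shape variance
uses a separate, lake-specific superimposition so it does not depend on
the other lakes' data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import LandmarkDataset, ShapeData
from .morphometrics import AllometryRegression, gpa

__all__ = [
    "procrustes_distance",
    "mahalanobis_distance",
    "shape_variance",
    "elongation_cv",
    "pca",
    "between_group_pca",
    "OrdinationResult",
    "pooled_within_group_cov",
    "DEFAULT_SL_PAIR",
    "DEFAULT_BH_PAIR",
]

# Inter-landmark pairs used for the elongation index on the 12-landmark
# fish scheme of the synthetic generator: snout tip to mid caudal peduncle
# (standard length) and dorsal to ventral extreme (body height).
DEFAULT_SL_PAIR = (0, 6)
DEFAULT_BH_PAIR = (3, 9)


def _group_mean(shape: ShapeData, label: str) -> np.ndarray:
    return shape.group_matrix(label).mean(axis=0)


def procrustes_distance(shape: ShapeData, group_a: str, group_b: str) -> float:
    """Euclidean norm of the difference between two group mean shapes."""
    return float(np.linalg.norm(_group_mean(shape, group_a) - _group_mean(shape, group_b)))


def pooled_within_group_cov(shape: ShapeData) -> np.ndarray:
    """Pooled within-group covariance of the shape coordinates (all groups)."""
    p = shape.coords.shape[1]
    s = np.zeros((p, p))
    dof = 0
    for g in shape.group_labels():
        x = shape.group_matrix(g)
        if x.shape[0] < 2:
            continue
        xc = x - x.mean(axis=0)
        s += xc.T @ xc
        dof += x.shape[0] - 1
    if dof == 0:
        raise ValueError("no within-group degrees of freedom")
    return s / dof


def mahalanobis_distance(
    shape: ShapeData,
    group_a: str,
    group_b: str,
    rank: int | None = None,
    eig_tol: float = 1e-10,
) -> float:
    """Mahalanobis distance between two group means.

    The pooled within-group covariance of superimposed 2D coordinates is
    rank deficient (4 dimensions are lost to the superimposition), so the
    inverse is a pseudo-inverse restricted to the top
    ``r = min(n - g, rank)`` eigen-dimensions whose eigenvalues exceed
    ``eig_tol`` times the largest (the tolerance removes the
    superimposition's null directions).
    """
    w = pooled_within_group_cov(shape)
    delta = _group_mean(shape, group_a) - _group_mean(shape, group_b)
    n = shape.n_specimens
    g = len(shape.group_labels())
    r = min(shape.coords.shape[1], n - g)
    if rank is not None:
        r = min(r, rank)
    if r < 1:
        raise ValueError("covariance rank budget < 1; too few specimens")
    evals, evecs = np.linalg.eigh(w)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eig_tol * evals[0]
    keep[r:] = False
    if not keep.any():
        raise ValueError("pooled covariance has no usable eigen-dimensions")
    proj = evecs[:, keep].T @ delta
    return float(np.sqrt(np.sum(proj**2 / evals[keep])))


def shape_variance(
    raw_dataset: LandmarkDataset,
    lake: str,
    correct_allometry: bool = True,
) -> float:
    """Within-lake shape variance from a lake-specific superimposition.

    Runs GPA (and, by default, a within-lake allometry correction) on that
    lake's specimens alone, then returns the mean squared Euclidean
    distance of each specimen's coordinate vector to the lake consensus.
    """
    sub = raw_dataset.subset_lake(lake)
    if len(sub) < 3:
        raise ValueError(f"lake {lake!r} has fewer than 3 specimens")
    aligned = gpa(sub)
    if correct_allometry:
        res = AllometryRegression(
            aligned, grouping=np.array(["all"] * len(sub), dtype=object)
        ).fit()
        coords = res.corrected_coords
    else:
        coords = aligned.flat
    consensus = coords.mean(axis=0)
    return float(((coords - consensus) ** 2).sum(axis=1).mean())


def elongation_cv(
    raw_dataset: LandmarkDataset,
    lake: str,
    sl_pair: tuple[int, int] = DEFAULT_SL_PAIR,
    bh_pair: tuple[int, int] = DEFAULT_BH_PAIR,
) -> float:
    """Coefficient of variation (%) of the elongation index within a lake.

    The elongation index of a specimen is the ratio of two inter-landmark
    distances corresponding to standard length and body height; being a
    ratio it is invariant to per-photograph scale.
    """
    sub = raw_dataset.subset_lake(lake)
    k = sub.n_landmarks
    for pair in (sl_pair, bh_pair):
        if not (0 <= pair[0] < k and 0 <= pair[1] < k) or pair[0] == pair[1]:
            raise ValueError(f"invalid landmark pair {pair}")
    eis = []
    for c in sub.configurations:
        sl = np.linalg.norm(c.coords[sl_pair[0]] - c.coords[sl_pair[1]])
        bh = np.linalg.norm(c.coords[bh_pair[0]] - c.coords[bh_pair[1]])
        if bh == 0:
            raise ValueError(f"zero body-height distance for specimen {c.specimen_id!r}")
        eis.append(sl / bh)
    eis = np.asarray(eis)
    return float(100.0 * eis.std(ddof=1) / eis.mean())


@dataclass
class OrdinationResult:
    """PCA/bgPCA axes, explained-variance fractions and projections."""

    axes: np.ndarray  # (p, n_axes), columns orthonormal
    variance_explained: np.ndarray
    scores: np.ndarray  # (n, n_axes)
    mean: np.ndarray
    group_mean_scores: pd.DataFrame | None = None

    def reconstruct(self) -> np.ndarray:
        return self.mean + self.scores @ self.axes.T


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Flip each axis so its largest-magnitude loading is positive."""
    flips = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(axes.shape[1])])
    flips[flips == 0] = 1.0
    return axes * flips


def pca(shape: ShapeData) -> OrdinationResult:
    """Ordinary PCA of the coordinate covariance."""
    x = shape.coords
    if x.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    total = evals.sum()
    ve = evals / total if total > 0 else evals
    return OrdinationResult(
        axes=evecs, variance_explained=ve, scores=xc @ evecs, mean=mean
    )


def between_group_pca(shape: ShapeData, groups: list[str] | None = None) -> OrdinationResult:
    """PCA of the (equally weighted) group mean shapes, with individuals
    projected onto the group-mean axes."""
    labels = groups if groups is not None else shape.group_labels()
    if len(labels) < 3:
        raise ValueError("between-group PCA needs at least 3 groups")
    means = np.stack([_group_mean(shape, g) for g in labels])
    grand = means.mean(axis=0)
    mc = means - grand
    cov = mc.T @ mc / (means.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    n_axes = min(len(labels) - 1, shape.coords.shape[1])
    evecs = _fix_signs(evecs[:, order][:, :n_axes])
    evals = evals[:n_axes]
    total = evals.sum()
    ve = evals / total if total > 0 else evals
    scores = (shape.coords - grand) @ evecs
    gms = pd.DataFrame(mc @ evecs, index=labels,
                       columns=[f"bgPC{i+1}" for i in range(n_axes)])
    return OrdinationResult(
        axes=evecs,
        variance_explained=ve,
        scores=scores,
        mean=grand,
        group_mean_scores=gms,
    )


def distance_matrices(shape: ShapeData) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Procrustes and Mahalanobis distance matrices over groups."""
    labels = shape.group_labels()
    n = len(labels)
    pd_mat = np.zeros((n, n))
    md_mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pd_mat[i, j] = pd_mat[j, i] = procrustes_distance(shape, labels[i], labels[j])
            md_mat[i, j] = md_mat[j, i] = mahalanobis_distance(shape, labels[i], labels[j])
    return (
        pd.DataFrame(pd_mat, index=labels, columns=labels),
        pd.DataFrame(md_mat, index=labels, columns=labels),
    )
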