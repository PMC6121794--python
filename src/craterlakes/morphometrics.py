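"""Generalized Procrustes superimposition and allometry correction.

The superimposition is the partial-Procrustes variant standard in
geometric morphometrics: every configuration is centred, scaled to unit
centroid size, and rotated (reflections disallowed) to the iteratively
re-estimated consensus.  Allometric size effects are then removed by a
multivariate pooled within-group regression of the aligned coordinates on
log10 centroid size; the corrected coordinates are the residuals plus each
specimen's grand-mean allometric expectation, so group mean differences
are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import LandmarkDataset, ShapeData

__all__ = [
    "centroid_size",
    "gpa",
    "AlignedDataset",
    "AllometryRegression",
    "AllometryResults",
    "optimal_rotation",
]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances to their centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 landmarks")
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise ValueError("all landmarks coincident: centroid size undefined")
    return cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix (no reflection) minimising ||source @ R - target||."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return u @ s @ vt


@dataclass
class AlignedDataset:
    """Procrustes-superimposed coordinates with sizes and the consensus."""

    coords: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, 2)
    groups: np.ndarray
    lakes: np.ndarray
    specimen_ids: list[str]
    n_iterations: int = 0
    residual_ss_path: list[float] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def flat(self) -> np.ndarray:
        n = self.coords.shape[0]
        return self.coords.reshape(n, -1)

    def as_shape_data(self) -> ShapeData:
        return ShapeData(
            coords=self.flat,
            groups=self.groups,
            lakes=self.lakes,
            specimen_ids=self.specimen_ids,
            state="aligned",
        )


def gpa(
    dataset: LandmarkDataset,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedDataset:
    """Generalized Procrustes analysis of a raw landmark dataset.

    Iterates rotate-to-consensus / re-estimate-consensus until the
    consensus moves by less than ``tol`` (root summed squared change).
    The consensus is kept centred and at unit centroid size.  The summed
    squared residual around the consensus is non-increasing across
    iterations.
    """
    if dataset.state != "raw":
        raise ValueError(f"gpa expects a raw dataset, got state {dataset.state!r}")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 configurations")
    coords = dataset.coords_array().astype(float)
    if coords.shape[1] < 3:
        raise ValueError("need at least 3 landmarks")

    sizes = np.array([centroid_size(c) for c in coords])
    centred = coords - coords.mean(axis=1, keepdims=True)
    scaled = centred / sizes[:, None, None]

    consensus = scaled[0].copy()
    consensus /= np.sqrt((consensus**2).sum())
    ss_path: list[float] = []
    aligned = scaled.copy()
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = scaled[i] @ optimal_rotation(scaled[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.sqrt((new_consensus**2).sum())
        if norm == 0:
            raise ValueError("degenerate consensus (all shapes cancel)")
        new_consensus /= norm
        ss_path.append(float(((aligned - new_consensus) ** 2).sum()))
        delta = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if delta < tol:
            # final rotation pass against the converged consensus
            for i in range(n):
                aligned[i] = scaled[i] @ optimal_rotation(scaled[i], consensus)
            return AlignedDataset(
                coords=aligned,
                centroid_sizes=sizes,
                consensus=consensus,
                groups=dataset.groups,
                lakes=dataset.lakes,
                specimen_ids=dataset.specimen_ids,
                n_iterations=it,
                residual_ss_path=ss_path,
            )
    raise RuntimeError(
        f"GPA did not converge in {max_iter} iterations "
        f"(last residual SS {ss_path[-1]:.3e})"
    )


@dataclass
class AllometryResults:
    """Fitted pooled within-group allometry regression.

    ``corrected`` holds the size-free coordinates: observed minus
    ``slope * (log CS - grand mean log CS)``.
    """

    slope: np.ndarray  # (2k,)
    group_means: dict
    corrected_coords: np.ndarray  # (n, 2k)
    log_sizes: np.ndarray
    grand_mean_log_size: float
    groups: np.ndarray
    lakes: np.ndarray
    specimen_ids: list[str]
    percent_predicted: float = float("nan")

    def as_shape_data(self) -> ShapeData:
        return ShapeData(
            coords=self.corrected_coords,
            groups=self.groups,
            lakes=self.lakes,
            specimen_ids=self.specimen_ids,
            state="allometry_corrected",
        )

    def summary(self) -> str:
        lines = [
            "Pooled within-group allometry regression",
            f"  specimens: {len(self.log_sizes)}",
            f"  groups:    {len(self.group_means)}",
            f"  size predictor: log10 centroid size "
            f"(grand mean {self.grand_mean_log_size:.4f})",
            f"  |slope|: {np.linalg.norm(self.slope):.6f}",
            f"  % shape variance predicted by size: {self.percent_predicted:.2f}",
        ]
        return "\n".join(lines)


class AllometryRegression:
    """Model: aligned shape coordinates regressed on log centroid size,
    with group-specific intercepts and one pooled slope vector.

    Parameters
    ----------
    aligned : AlignedDataset
        Output of :func:`gpa`.
    grouping : array-like, optional
        Labels defining the pooling groups; defaults to the dataset's
        group labels.
    size_log : bool
        Use log10 centroid size (default) rather than raw centroid size.
    """

    def __init__(self, aligned: AlignedDataset, grouping=None, size_log: bool = True):
        self.aligned = aligned
        self.grouping = (
            np.asarray(grouping, dtype=object)
            if grouping is not None
            else aligned.groups
        )
        if self.grouping.shape[0] != aligned.n_specimens:
            raise ValueError("grouping length mismatch")
        for g, cnt in zip(*np.unique(self.grouping.astype(str), return_counts=True)):
            if cnt < 3:
                raise ValueError(f"group {g!r} has fewer than 3 specimens")
        self.size_log = size_log

    def fit(self) -> AllometryResults:
        y = self.aligned.flat
        x = (
            np.log10(self.aligned.centroid_sizes)
            if self.size_log
            else self.aligned.centroid_sizes.astype(float)
        )
        labels = self.grouping
        xc = x.copy()
        yc = y.copy()
        for g in np.unique(labels.astype(str)):
            mask = labels.astype(str) == g
            xc[mask] = x[mask] - x[mask].mean()
            yc[mask] = y[mask] - y[mask].mean(axis=0)
        sxx = float(xc @ xc)
        # tolerance: identical sizes leave only rounding residue after centering
        if sxx <= len(x) * (1e-12 * max(1.0, float(np.abs(x).max()))) ** 2:
            warnings.warn(
                "no within-group size variation: slope inestimable, "
                "correction is the identity",
                stacklevel=2,
            )
            slope = np.zeros(y.shape[1])
        else:
            slope = (xc @ yc) / sxx
        grand = float(x.mean())
        corrected = y - np.outer(x - grand, slope)
        predicted_ss = sxx * float(slope @ slope)
        total_ss = float((yc**2).sum())
        pct = 100.0 * predicted_ss / total_ss if total_ss > 0 else float("nan")
        group_means = {
            g: corrected[labels.astype(str) == g].mean(axis=0)
            for g in np.unique(labels.astype(str))
        }
        return AllometryResults(
            slope=slope,
            group_means=group_means,
            corrected_coords=corrected,
            log_sizes=x,
            grand_mean_log_size=grand,
            groups=self.aligned.groups,
            lakes=self.aligned.lakes,
            specimen_ids=self.aligned.specimen_ids,
            percent_predicted=pct,
        )
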