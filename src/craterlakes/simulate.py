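"""Synthetic landmark, genotype and lake-table generators.

These emulate the statistical structure the downstream analyses assume:

* landmark data — a common base shape, per-group mean offsets (typically
  along the body-elongation axis), a shared allometric component
  proportional to log centroid size, isotropic per-landmark Gaussian
  noise, and nuisance rotation/translation plus a per-photograph image
  scale factor;
* genotype data — four populations on the fixed topology (((W, X), Y), Z)
  with truncated-Gaussian allele-frequency drift per branch and a
  controllable admixture fraction of Y ancestry into W;
* lake tables — predictors drawn log-uniformly over realistic crater-lake
  ranges with one planted predictor-response relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeDataset,
    LakeTable,
    LandmarkConfiguration,
    LandmarkDataset,
)

__all__ = [
    "BASE_FISH_SHAPE",
    "GroupSpec",
    "SyntheticLandmarkSpec",
    "SyntheticGenotypeSpec",
    "generate_landmark_dataset",
    "generate_genotype_dataset",
    "generate_lake_table",
    "elongation_offset",
    "shape_space_offset",
    "similarity_tangent_basis",
]

# 12-landmark lateral fish outline (x: snout -> tail, y: dorsal/ventral).
# Landmark 0 is the snout tip, 6 the mid caudal peduncle, 3 the dorsal and
# 9 the ventral extreme, matching the elongation-index defaults.
BASE_FISH_SHAPE = np.array(
    [
        [0.00, 0.00],   # 0 snout tip
        [0.25, 0.28],   # 1 nape
        [0.55, 0.38],   # 2 anterior dorsal fin
        [0.95, 0.42],   # 3 dorsal extreme
        [1.40, 0.30],   # 4 posterior dorsal fin
        [1.75, 0.12],   # 5 dorsal caudal peduncle
        [1.85, 0.00],   # 6 mid caudal peduncle
        [1.75, -0.12],  # 7 ventral caudal peduncle
        [1.35, -0.25],  # 8 anal fin
        [0.90, -0.38],  # 9 ventral extreme
        [0.50, -0.35],  # 10 pelvic fin
        [0.20, -0.22],  # 11 lower jaw
    ]
)


def similarity_tangent_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4 x 2k) of the similarity directions at ``base``:
    x/y translation, infinitesimal rotation and uniform scaling.

    Offsets orthogonal to this space are pure shape changes that a
    Procrustes superimposition passes through (to first order), which makes
    planted effects recoverable downstream.
    """
    base = np.asarray(base, dtype=float)
    k = base.shape[0]
    centred = base - base.mean(axis=0)
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    scale = centred.ravel()
    rot = np.column_stack([-centred[:, 1], centred[:, 0]]).ravel()
    basis = np.stack([tx, ty, scale, rot])
    # Gram-Schmidt (translations are already orthogonal to the centred dirs)
    q, _ = np.linalg.qr(basis.T)
    return q.T


def shape_space_offset(vec: np.ndarray, base: np.ndarray = BASE_FISH_SHAPE) -> np.ndarray:
    """Project a flat offset vector off the similarity directions of ``base``."""
    vec = np.asarray(vec, dtype=float).ravel()
    basis = similarity_tangent_basis(base)
    return vec - basis.T @ (basis @ vec)


def elongation_offset(magnitude: float, base: np.ndarray = BASE_FISH_SHAPE) -> np.ndarray:
    """A flat offset vector stretching the body axis and flattening depth.

    Positive ``magnitude`` makes the shape more slender (the limnetic
    direction); landmarks are pushed outward along x and inward along y in
    proportion to their distance from the shape centroid.  The vector is
    orthogonalised against translation/rotation/scaling so it is a pure
    shape change of unit norm times ``magnitude``.
    """
    centred = base - base.mean(axis=0)
    off = np.empty_like(centred)
    off[:, 0] = centred[:, 0]
    off[:, 1] = -centred[:, 1]
    off = shape_space_offset(off.ravel(), base)
    off = off / np.linalg.norm(off)
    return magnitude * off


@dataclass
class GroupSpec:
    label: str
    n_specimens: int
    mean_offset: np.ndarray  # flat (2k,)
    allometry_slope: np.ndarray | None = None
    lake: str | None = None

    def __post_init__(self) -> None:
        if self.n_specimens < 3:
            raise ValueError("each group needs at least 3 specimens")
        self.mean_offset = np.asarray(self.mean_offset, dtype=float)
        if self.allometry_slope is not None:
            self.allometry_slope = np.asarray(self.allometry_slope, dtype=float)


@dataclass
class SyntheticLandmarkSpec:
    """Study-like defaults: ~30 specimens per group, landmark noise of
    0.02 shape units on a base shape of centroid size ~1.5, centroid sizes
    log-normal around 10 (roughly cm-scale fish), and full nuisance
    rotation/translation."""

    groups: list[GroupSpec]
    base_shape: np.ndarray = field(default_factory=lambda: BASE_FISH_SHAPE.copy())
    landmark_noise_sd: float = 0.02
    size_log_mean: float = np.log(10.0)
    size_log_sd: float = 0.25
    rotation_range: tuple[float, float] = (-np.pi, np.pi)
    translation_range: tuple[float, float] = (-5.0, 5.0)
    image_scale_range: tuple[float, float] | None = (0.5, 2.0)

    def __post_init__(self) -> None:
        self.base_shape = np.asarray(self.base_shape, dtype=float)
        if self.landmark_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if np.allclose(self.base_shape, self.base_shape[0]):
            raise ValueError("degenerate base shape: all landmarks identical")


def generate_landmark_dataset(
    spec: SyntheticLandmarkSpec, seed: int | None = None
) -> LandmarkDataset:
    """Draw a raw landmark dataset.

    Per specimen the flat shape is
    ``base + group offset + slope * (log10 CS - mean log10 CS) + noise``,
    scaled so its centroid size equals the drawn CS, then rotated and
    translated at random.  The nuisance image-scale factor is stored in
    the configuration's ``scale`` field (the coordinates themselves are in
    shape units), mirroring how a per-photograph SCALE factor enters a TPS
    file.
    """
    rng = np.random.default_rng(seed)
    k = spec.base_shape.shape[0]
    base_flat = spec.base_shape.ravel()
    configs: list[LandmarkConfiguration] = []
    mean_log10_cs = spec.size_log_mean / np.log(10.0)
    counter = 0
    for grp in spec.groups:
        if grp.mean_offset.shape[0] != 2 * k:
            raise ValueError(f"group {grp.label!r}: offset must have {2 * k} values")
        slope = (
            grp.allometry_slope
            if grp.allometry_slope is not None
            else np.zeros(2 * k)
        )
        for _ in range(grp.n_specimens):
            counter += 1
            log_cs = rng.normal(spec.size_log_mean, spec.size_log_sd)
            cs = float(np.exp(log_cs))
            flat = (
                base_flat
                + grp.mean_offset
                + slope * (log_cs / np.log(10.0) - mean_log10_cs)
                + rng.normal(0.0, spec.landmark_noise_sd, size=2 * k)
            )
            coords = flat.reshape(k, 2)
            centred = coords - coords.mean(axis=0)
            cs0 = np.sqrt((centred**2).sum())
            if cs0 == 0:
                raise ValueError("degenerate specimen shape")
            coords = centred * (cs / cs0)
            theta = rng.uniform(*spec.rotation_range)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            coords = coords @ rot.T + rng.uniform(*spec.translation_range, size=2)
            image_scale = (
                float(rng.uniform(*spec.image_scale_range))
                if spec.image_scale_range is not None
                else None
            )
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{grp.label}_{counter:04d}",
                    coords=coords,
                    lake=grp.lake or grp.label,
                    group=grp.label,
                    scale=image_scale,
                )
            )
    return LandmarkDataset(configs, state="raw")


@dataclass
class SyntheticGenotypeSpec:
    """Four-population genotype simulation on (((W, X), Y), Z).

    ``drift`` gives the per-branch standard deviation of truncated-Gaussian
    allele-frequency change; ``admix_f`` replaces that fraction of W's
    ancestry with Y's post-drift frequencies.  Defaults emulate a recently
    founded crater-lake pair (W, X) against a diverged lake (Y) and a
    distant outgroup (Z).
    """

    n_snps: int = 2000
    sample_sizes: dict = field(
        default_factory=lambda: {"W": 10, "X": 10, "Y": 10, "Z": 5}
    )
    drift: dict = field(
        default_factory=lambda: {
            "internal": 0.05,
            "wx": 0.05,
            "w": 0.05,
            "x": 0.05,
            "y": 0.10,
            "z": 0.20,
        }
    )
    admix_f: float = 0.0
    beta_params: tuple[float, float] = (0.8, 0.8)
    snps_per_locus: int = 1
    missing_rate: float = 0.0
    pop_names: tuple[str, str, str, str] = ("W", "X", "Y", "Z")

    def __post_init__(self) -> None:
        if not 0.0 <= self.admix_f <= 1.0:
            raise ValueError("admix_f must lie in [0, 1]")
        for pop, n in self.sample_sizes.items():
            if n < 2:
                raise ValueError(f"population {pop!r} needs at least 2 samples")


def _drift(p: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return p.copy()
    return np.clip(p + rng.normal(0.0, sd, size=p.shape), 0.0, 1.0)


def generate_genotype_dataset(
    spec: SyntheticGenotypeSpec, seed: int | None = None
) -> GenotypeDataset:
    rng = np.random.default_rng(seed)
    a, b = spec.beta_params
    p0 = rng.beta(a, b, size=spec.n_snps)
    p_z = _drift(p0, spec.drift.get("z", 0.0), rng)
    p_n1 = _drift(p0, spec.drift.get("internal", 0.0), rng)
    p_y = _drift(p_n1, spec.drift.get("y", 0.0), rng)
    p_wx = _drift(p_n1, spec.drift.get("wx", 0.0), rng)
    p_w = _drift(p_wx, spec.drift.get("w", 0.0), rng)
    p_x = _drift(p_wx, spec.drift.get("x", 0.0), rng)
    if spec.admix_f > 0:
        p_w = (1.0 - spec.admix_f) * p_w + spec.admix_f * p_y
    name_w, name_x, name_y, name_z = spec.pop_names
    freq_by_pop = {name_w: p_w, name_x: p_x, name_y: p_y, name_z: p_z}
    samples: list[str] = []
    pops: list[str] = []
    rows: list[np.ndarray] = []
    for pop in spec.pop_names:
        n = spec.sample_sizes[pop]
        geno = rng.binomial(2, freq_by_pop[pop], size=(n, spec.n_snps))
        rows.append(geno)
        samples.extend(f"{pop}_{i + 1:03d}" for i in range(n))
        pops.extend([pop] * n)
    geno = np.vstack(rows).astype(np.int8)
    if spec.missing_rate > 0:
        miss = rng.random(geno.shape) < spec.missing_rate
        geno[miss] = -1
    locus_ids = np.array(
        [f"loc{j // spec.snps_per_locus:06d}" for j in range(spec.n_snps)],
        dtype=object,
    )
    return GenotypeDataset(
        genotypes=geno,
        samples=samples,
        pops=np.array(pops, dtype=object),
        locus_ids=locus_ids,
        chrom=np.array(["chr1"] * spec.n_snps, dtype=object),
        pos=(np.arange(spec.n_snps) + 1) * 1000,
        outgroup=name_z,
    )


# Table-1-like log-uniform predictor ranges for synthetic crater lakes.
_PREDICTOR_RANGES = {
    "n_founder": (30.0, 9000.0),
    "t_col": (500.0, 1700.0),
    "admix": (0.04, 0.33),
    "ne_longterm": (1000.0, 9000.0),
    "mean_depth": (17.0, 142.0),
    "littoral_area": (0.1, 10.0),
}


def generate_lake_table(
    n_lakes: int,
    response: str = "shape_variance",
    predictor: str = "mean_depth",
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    log_predictor: bool = False,
    seed: int | None = None,
) -> LakeTable:
    """Synthetic per-lake table with one planted predictor-response relation.

    Predictors are drawn log-uniformly over crater-lake-like ranges; the
    chosen response is ``slope * x + intercept + noise`` with ``x``
    optionally log10-transformed.
    """
    if n_lakes < 3:
        raise ValueError("need at least 3 lakes")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {
        "lake": np.array([f"lake_{i + 1}" for i in range(n_lakes)], dtype=object)
    }
    for col, (lo, hi) in _PREDICTOR_RANGES.items():
        data[col] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_lakes))
    x = data[predictor]
    if log_predictor:
        x = np.log10(x)
    data[response] = slope * x + intercept + rng.normal(0.0, noise_sd, size=n_lakes)
    return LakeTable(pd.DataFrame(data))
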