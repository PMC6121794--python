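"""Core in-memory containers shared across the pipeline.

Landmark data move through three states: ``raw`` (digitised coordinates),
``aligned`` (after generalized Procrustes superimposition) and
``allometry_corrected`` (after pooled within-group size regression).
Genotype data are held as a dense specimens x SNPs dosage matrix with a
population map, mirroring what a biallelic-SNP VCF plus a two-column
population file encode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "ShapeData",
    "GenotypeDataset",
    "LakeTable",
    "MISSING",
]

#: sentinel for a missing diploid genotype in the dosage matrix
MISSING: int = -1

STATES = ("raw", "aligned", "allometry_corrected")


@dataclass
class LandmarkConfiguration:
    """One specimen's digitised landmarks.

    ``coords`` is a ``(k, 2)`` array in shape units (any image scale factor
    already applied).  ``scale`` records the original pixels-per-unit factor
    so the configuration can be written back to image units.
    """

    specimen_id: str
    coords: np.ndarray
    lake: str = ""
    group: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coords must be (k, 2), "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """A set of landmark configurations sharing one landmark scheme."""

    configurations: list[LandmarkConfiguration]
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.configurations:
            k = self.configurations[0].n_landmarks
            for c in self.configurations:
                if c.n_landmarks != k:
                    raise ValueError(
                        f"specimen {c.specimen_id!r} has {c.n_landmarks} "
                        f"landmarks, expected {k}"
                    )

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def n_landmarks(self) -> int:
        if not self.configurations:
            raise ValueError("empty dataset has no landmark count")
        return self.configurations[0].n_landmarks

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an ``(n, k, 2)`` array."""
        return np.stack([c.coords for c in self.configurations])

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def lakes(self) -> np.ndarray:
        return np.array([c.lake for c in self.configurations], dtype=object)

    @property
    def groups(self) -> np.ndarray:
        return np.array([c.group for c in self.configurations], dtype=object)

    def subset(self, mask: np.ndarray) -> "LandmarkDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return LandmarkDataset(
            [replace(self.configurations[i]) for i in idx], state=self.state
        )

    def subset_lake(self, lake: str) -> "LandmarkDataset":
        mask = self.lakes == lake
        if not mask.any():
            raise KeyError(f"unknown lake {lake!r}")
        return self.subset(mask)

    def attach_metadata(self, meta: pd.DataFrame) -> None:
        """Fill lake/group labels from a specimen metadata table.

        ``meta`` needs columns ``specimen_id``, ``lake`` and optionally
        ``group`` (defaults to the lake label).
        """
        meta = meta.set_index("specimen_id")
        missing = [s for s in self.specimen_ids if s not in meta.index]
        if missing:
            raise KeyError(f"specimens absent from metadata: {missing}")
        has_group = "group" in meta.columns
        for c in self.configurations:
            row = meta.loc[c.specimen_id]
            c.lake = str(row["lake"])
            c.group = str(row["group"]) if has_group else c.lake


@dataclass
class ShapeData:
    """Flat shape coordinates plus labels, the input to all group-level
    statistics (distances, trajectories, ordinations)."""

    coords: np.ndarray  # (n, 2k)
    groups: np.ndarray
    lakes: np.ndarray | None = None
    specimen_ids: Sequence[str] | None = None
    state: str = "allometry_corrected"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.coords.shape[0] != self.groups.shape[0]:
            raise ValueError("coords and groups disagree on specimen count")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    def group_matrix(self, label: str) -> np.ndarray:
        mask = self.groups == label
        if not mask.any():
            raise KeyError(f"unknown group {label!r}")
        return self.coords[mask]

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)


@dataclass
class GenotypeDataset:
    """Biallelic SNP dosages (0/1/2, -1 missing) with a population map.

    ``locus_ids`` carries the RAD-tag locus identifier of each SNP so that
    a one-SNP-per-locus filter can be applied; several SNPs may share one
    locus id.
    """

    genotypes: np.ndarray  # (n_samples, n_snps), int8
    samples: list[str]
    pops: np.ndarray  # per-sample population label
    locus_ids: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    outgroup: str | None = None
    filter_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pops = np.asarray(self.pops, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        n, m = self.genotypes.shape
        if len(self.samples) != n or self.pops.shape[0] != n:
            raise ValueError("sample annotations disagree with matrix rows")
        if self.locus_ids.shape[0] != m:
            raise ValueError("locus_ids disagree with matrix columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def pop_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def pop_matrix(self, pop: str) -> np.ndarray:
        mask = self.pops == pop
        if not mask.any():
            raise KeyError(f"unknown population {pop!r}")
        return self.genotypes[mask]

    def allele_freqs(self, pop: str) -> np.ndarray:
        """Per-SNP alternate-allele frequency; NaN where no genotype called."""
        g = self.pop_matrix(pop).astype(float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def select_snps(self, idx: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            genotypes=self.genotypes[:, idx],
            samples=list(self.samples),
            pops=self.pops.copy(),
            locus_ids=self.locus_ids[idx],
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx],
            outgroup=self.outgroup,
            filter_counts=dict(self.filter_counts),
        )


PREDICTOR_COLUMNS = (
    "n_founder",
    "t_col",
    "admix",
    "ne_longterm",
    "mean_depth",
    "littoral_area",
)
RESPONSE_COLUMNS = (
    "procrustes_dist",
    "mahalanobis_dist",
    "shape_variance",
    "cv_ei",
    "rate",
)


@dataclass
class LakeTable:
    """Per-crater-lake predictors and morphological responses.

    Predictors: founder population size (individuals), colonization time
    (generations), admixture proportion, long-term effective population
    size, mean lake depth (m) and littoral-zone area (km^2).  Responses are
    filled by the morphometric stages.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "lake" not in df.columns:
            raise ValueError("LakeTable requires a 'lake' column")
        for col in PREDICTOR_COLUMNS + RESPONSE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        admix = df["admix"].dropna()
        if ((admix < 0) | (admix > 1)).any():
            raise ValueError("admix must lie in [0, 1]")
        if (df["t_col"].dropna() <= 0).any():
            raise ValueError("t_col must be positive")
        if (df["n_founder"].dropna() <= 0).any():
            raise ValueError("n_founder must be positive")

    @property
    def lakes(self) -> list[str]:
        return list(self.frame["lake"])

    def set_response(self, lake: str, column: str, value: float) -> None:
        if column not in RESPONSE_COLUMNS:
            raise KeyError(f"unknown response column {column!r}")
        mask = self.frame["lake"] == lake
        if not mask.any():
            raise KeyError(f"unknown lake {lake!r}")
        self.frame.loc[mask, column] = value
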