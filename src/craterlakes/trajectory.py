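"""Pairwise phenotypic divergence-vector statistics (dL and theta).

Each derived population is contrasted with its source population through a
vector of 24 two-sample t-statistics, one per x/y landmark coordinate of
the allometry-corrected shape.  For two such vectors, dL is the absolute
difference of their signed sums (in standard-error units) and theta the
arccosine of their Pearson correlation.  Significance comes from
label-switch permutations that reshuffle derived/source labels within each
pair; a bootstrap over specimens tests whether the angle is distinguishable
from orthogonality (90 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ShapeData

__all__ = [
    "TrajectoryVector",
    "VectorComparison",
    "t_vector",
    "compare_vectors",
    "permutation_test",
    "orthogonality_bootstrap",
    "TrajectoryDivergence",
    "TrajectoryResults",
]


@dataclass
class TrajectoryVector:
    crater_group: str
    source_group: str
    t_stats: np.ndarray  # one per shape coordinate
    vector_length: float  # signed sum of the t-statistics

    def __post_init__(self) -> None:
        self.t_stats = np.asarray(self.t_stats, dtype=float)
        if not np.all(np.isfinite(self.t_stats)):
            raise ValueError("non-finite t-statistics")


@dataclass
class VectorComparison:
    pair_a: tuple[str, str]
    pair_b: tuple[str, str]
    dL: float
    theta_deg: float
    p_dL: float | None = None
    p_theta: float | None = None
    p_orth: float | None = None
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None


def _t_stats(x: np.ndarray, y: np.ndarray, welch: bool = False) -> np.ndarray:
    """Two-sample t-statistics per column; pooled variance by default."""
    n1, n2 = x.shape[0], y.shape[0]
    mdiff = x.mean(axis=0) - y.mean(axis=0)
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)
    if welch:
        se = np.sqrt(v1 / n1 + v2 / n2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mdiff / se
    return t, se


def t_vector(
    shape: ShapeData,
    crater_group: str,
    source_group: str,
    welch: bool = False,
) -> TrajectoryVector:
    """Divergence vector of a derived group against its source.

    Sign convention: positive where the derived (crater) mean exceeds the
    source mean.
    """
    x = shape.group_matrix(crater_group)
    y = shape.group_matrix(source_group)
    if x.shape[0] < 3 or y.shape[0] < 3:
        raise ValueError("both groups need at least 3 specimens")
    t, se = _t_stats(x, y, welch=welch)
    bad = np.flatnonzero(se == 0)
    if bad.size:
        raise ValueError(f"zero pooled variance in coordinate(s) {bad.tolist()}")
    return TrajectoryVector(
        crater_group=crater_group,
        source_group=source_group,
        t_stats=t,
        vector_length=float(t.sum()),
    )


def compare_vectors(va: TrajectoryVector, vb: TrajectoryVector) -> tuple[float, float]:
    """(dL, theta in degrees) for two divergence vectors."""
    if va.t_stats.shape != vb.t_stats.shape:
        raise ValueError("t-vectors must have equal length")
    dl = abs(va.vector_length - vb.vector_length)
    sa = va.t_stats.std()
    sb = vb.t_stats.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance t-vector: correlation undefined")
    r = float(np.corrcoef(va.t_stats, vb.t_stats)[0, 1])
    theta = float(np.degrees(np.arccos(np.clip(r, -1.0, 1.0))))
    return dl, theta


def _pair_arrays(shape: ShapeData, pair: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    crater, source = pair
    if crater == source:
        raise ValueError("crater and source labels must differ")
    return shape.group_matrix(crater), shape.group_matrix(source)


def _null_stats(xc, xs, welch=False):
    t, se = _t_stats(xc, xs, welch=welch)
    t = np.where(se == 0, 0.0, t)
    return t


def permutation_test(
    shape: ShapeData,
    pair_a: tuple[str, str],
    pair_b: tuple[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    welch: bool = False,
) -> VectorComparison:
    """Label-switch permutation test for dL and theta between two pairs.

    The null hypothesis is that the two pairs share one common divergence
    trajectory.  Each permutation reshuffles pair labels within role:
    derived (crater) specimens are exchanged between the two pairs, and
    source specimens likewise, with sample sizes preserved; both t-vectors
    are recomputed and |dL| and theta recorded.  When the two pairs share
    the same source population its specimens enter the source pool once
    per pair (duplicated), giving the paired design.  p-values use the
    (count+1)/(n_perm+1) convention; both statistics are tested one-tailed
    on null >= observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    xa_c, xa_s = _pair_arrays(shape, pair_a)
    xb_c, xb_s = _pair_arrays(shape, pair_b)

    va = t_vector(shape, *pair_a, welch=welch)
    vb = t_vector(shape, *pair_b, welch=welch)
    obs_dl, obs_theta = compare_vectors(va, vb)

    pool_crater = np.vstack([xa_c, xb_c])
    pool_source = np.vstack([xa_s, xb_s])
    na_c, na_s = xa_c.shape[0], xa_s.shape[0]

    count_dl = 0
    count_theta = 0
    for _ in range(n_perm):
        perm_c = rng.permutation(pool_crater.shape[0])
        perm_s = rng.permutation(pool_source.shape[0])
        ta = _null_stats(
            pool_crater[perm_c[:na_c]], pool_source[perm_s[:na_s]], welch
        )
        tb = _null_stats(
            pool_crater[perm_c[na_c:]], pool_source[perm_s[na_s:]], welch
        )
        dl_null = abs(ta.sum() - tb.sum())
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(ta, tb)[0, 1]
        theta_null = np.degrees(np.arccos(np.clip(r, -1.0, 1.0)))
        if dl_null >= obs_dl:
            count_dl += 1
        if np.isnan(theta_null) or theta_null >= obs_theta:
            count_theta += 1
    return VectorComparison(
        pair_a=pair_a,
        pair_b=pair_b,
        dL=obs_dl,
        theta_deg=obs_theta,
        p_dL=(count_dl + 1) / (n_perm + 1),
        p_theta=(count_theta + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )


def orthogonality_bootstrap(
    shape: ShapeData,
    pair_a: tuple[str, str],
    pair_b: tuple[str, str],
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    welch: bool = False,
) -> float:
    """Two-tailed bootstrap proportion of theta replicates spanning 90 deg.

    Specimens are resampled with replacement within each of the four
    groups; returns ``2 * min(frac(theta* >= 90), frac(theta* < 90))``.  A
    value <= 0.05 flags the vector pair as significantly more parallel (or
    more anti-parallel) than orthogonal.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    arrays = [*_pair_arrays(shape, pair_a), *_pair_arrays(shape, pair_b)]
    above = 0
    for _ in range(n_boot):
        res = [a[rng.integers(0, a.shape[0], size=a.shape[0])] for a in arrays]
        ta = _null_stats(res[0], res[1], welch)
        tb = _null_stats(res[2], res[3], welch)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(ta, tb)[0, 1]
        theta = np.degrees(np.arccos(np.clip(r, -1.0, 1.0)))
        if not np.isnan(theta) and theta >= 90.0:
            above += 1
    frac_above = above / n_boot
    return 2.0 * min(frac_above, 1.0 - frac_above)


@dataclass
class TrajectoryResults:
    """Pairwise divergence-vector table: statistics below the diagonal,
    permutation p-values above, mirroring the conventional layout."""

    names: list[str]
    vectors: dict
    comparisons: list[VectorComparison]
    dL_table: pd.DataFrame
    theta_table: pd.DataFrame
    n_perm: int
    n_boot: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append(
                {
                    "pair_a": "/".join(c.pair_a),
                    "pair_b": "/".join(c.pair_b),
                    "dL": c.dL,
                    "theta_deg": c.theta_deg,
                    "p_dL": c.p_dL,
                    "p_theta": c.p_theta,
                    "p_orth": c.p_orth,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        n_sig = int((df["p_theta"] < 0.05).sum())
        lines = [
            "Pairwise phenotypic divergence vector analyses",
            f"  trajectories: {len(self.names)}  comparisons: {len(df)}",
            f"  permutations: {self.n_perm}  bootstrap: {self.n_boot}",
            f"  theta significant at 0.05: {n_sig}/{len(df)}",
            df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


class TrajectoryDivergence:
    """Model: divergence vectors for a set of (derived, source) pairs and
    all pairwise dL/theta comparisons with permutation and bootstrap
    inference.

    ``pairs`` maps a display name to a ``(crater_group, source_group)``
    tuple.  Pairs may share a source population (its specimens are used in
    each pair's paired design independently).
    """

    def __init__(
        self,
        shape: ShapeData,
        pairs: dict[str, tuple[str, str]],
        n_perm: int = 1000,
        n_boot: int = 1000,
        seed: int | None = None,
        welch: bool = False,
    ):
        if len(pairs) < 2:
            raise ValueError("need at least 2 pairs")
        if len(set(pairs.values())) != len(pairs):
            raise ValueError("duplicate (crater, source) pairs")
        self.shape = shape
        self.pairs = dict(pairs)
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.seed = seed
        self.welch = welch

    def fit(self) -> TrajectoryResults:
        names = list(self.pairs)
        rng = np.random.default_rng(self.seed)
        vectors = {
            name: t_vector(self.shape, *pair, welch=self.welch)
            for name, pair in self.pairs.items()
        }
        n = len(names)
        dl = np.full((n, n), np.nan)
        th = np.full((n, n), np.nan)
        comparisons: list[VectorComparison] = []
        for i in range(n):
            for j in range(i + 1, n):
                comp = permutation_test(
                    self.shape,
                    self.pairs[names[i]],
                    self.pairs[names[j]],
                    n_perm=self.n_perm,
                    rng=rng,
                    welch=self.welch,
                )
                if self.n_boot:
                    comp.p_orth = orthogonality_bootstrap(
                        self.shape,
                        self.pairs[names[i]],
                        self.pairs[names[j]],
                        n_boot=self.n_boot,
                        rng=rng,
                        welch=self.welch,
                    )
                    comp.n_boot = self.n_boot
                comp.seed = self.seed
                comparisons.append(comp)
                # statistic below the diagonal, p-value above
                dl[j, i] = comp.dL
                dl[i, j] = comp.p_dL
                th[j, i] = comp.theta_deg
                th[i, j] = comp.p_theta
        return TrajectoryResults(
            names=names,
            vectors=vectors,
            comparisons=comparisons,
            dL_table=pd.DataFrame(dl, index=names, columns=names),
            theta_table=pd.DataFrame(th, index=names, columns=names),
            n_perm=self.n_perm,
            n_boot=self.n_boot,
            seed=self.seed,
        )
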