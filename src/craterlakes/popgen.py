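"""Population-genetic statistics: SNP filtering, Patterson's D with a
weighted block jackknife, and the Weir-Cockerham F_ST estimator with a
permutation test.

Patterson's D tests treeness of a quartet (((W, X), Y), Z): with sample
allele frequencies p_W..p_Z per SNP,

    D = sum (p_W - p_X)(p_Y - p_Z) / sum (p_W + p_X - 2 p_W p_X)(p_Y + p_Z - 2 p_Y p_Z)

and an excess of ABBA over BABA patterns (D < 0 for this orientation, or
the reverse) signals gene flow violating the tree.  Standard errors come
from a delete-one block jackknife over contiguous SNP blocks, weighted by
block size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeDataset

log = logging.getLogger(__name__)

__all__ = [
    "filter_snps",
    "d_statistic",
    "DStatResult",
    "PattersonD",
    "weir_cockerham_fst",
    "fst_permutation_test",
    "FstResult",
    "WeirCockerhamFst",
]


def filter_snps(
    geno: GenotypeDataset,
    min_per_pop: int = 6,
    min_outgroup: int = 3,
    one_per_locus: bool = True,
) -> GenotypeDataset:
    """Apply the study's SNP retention rules.

    Keeps SNPs with at least ``min_per_pop`` called genotypes in every
    population (``min_outgroup`` for the population flagged as outgroup),
    then at most one SNP per RAD-tag locus (the first in input order).
    The filter is idempotent.
    """
    called = geno.genotypes != MISSING
    keep = np.ones(geno.n_snps, dtype=bool)
    for pop in geno.pop_labels():
        threshold = min_outgroup if pop == geno.outgroup else min_per_pop
        counts = called[geno.pops == pop].sum(axis=0)
        keep &= counts >= threshold
    n_after_calls = int(keep.sum())
    dropped_calls = geno.n_snps - n_after_calls
    if one_per_locus:
        seen: set = set()
        for j in np.flatnonzero(keep):
            lid = geno.locus_ids[j]
            if lid in seen:
                keep[j] = False
            else:
                seen.add(lid)
    dropped_locus = n_after_calls - int(keep.sum())
    if not keep.any():
        raise ValueError("no SNPs survive filtering")
    log.info(
        "filter_snps: dropped %d for call counts, %d duplicate-locus; kept %d",
        dropped_calls, dropped_locus, int(keep.sum()),
    )
    out = geno.select_snps(np.flatnonzero(keep))
    out.filter_counts.update(
        {"dropped_call_threshold": dropped_calls, "dropped_duplicate_locus": dropped_locus}
    )
    return out


@dataclass
class DStatResult:
    quartet: tuple[str, str, str, str]
    D: float
    abba: float
    baba: float
    Z: float
    p: float
    se: float
    n_blocks: int
    n_snps_used: int
    block_size: int

    def summary(self) -> str:
        w, x, y, z = self.quartet
        return (
            f"Patterson's D for ((({w}, {x}), {y}), {z})\n"
            f"  D = {self.D:.4f}  (BABA {self.baba:.2f}, ABBA {self.abba:.2f})\n"
            f"  block jackknife SE = {self.se:.4f} over {self.n_blocks} blocks "
            f"of <= {self.block_size} SNPs ({self.n_snps_used} SNPs)\n"
            f"  Z = {self.Z:.3f}, two-tailed p = {self.p:.3g}"
        )


def _jackknife(num: np.ndarray, den: np.ndarray, blocks: np.ndarray) -> tuple[float, float, int]:
    """Weighted delete-one block jackknife for a ratio-of-sums statistic.

    ``blocks`` assigns each SNP to a block id.  Block weights are SNP
    counts; with equal blocks this reduces to the ordinary delete-one
    jackknife.  Returns (estimate, SE, n_blocks).
    """
    tot_num, tot_den = num.sum(), den.sum()
    theta = tot_num / tot_den
    ids = np.unique(blocks)
    g = ids.size
    if g < 2:
        raise ValueError("need at least 2 jackknife blocks")
    n = float(num.size)
    m = np.array([(blocks == b).sum() for b in ids], dtype=float)
    loo = np.array(
        [
            (tot_num - num[blocks == b].sum()) / (tot_den - den[blocks == b].sum())
            for b in ids
        ]
    )
    h = n / m
    theta_j = g * theta - float(((1.0 - m / n) * loo).sum())
    tau = h * theta - (h - 1.0) * loo
    var = float((((tau - theta_j) ** 2) / (h - 1.0)).sum()) / g
    return theta, float(np.sqrt(var)), g


def d_statistic(
    geno: GenotypeDataset,
    quartet: tuple[str, str, str, str],
    block_size_snps: int = 500,
) -> DStatResult:
    """Patterson's D with block-jackknife Z for a (((W, X), Y), Z) quartet.

    SNPs with any of the four populations entirely missing are skipped.
    Blocks are contiguous runs of the used SNPs in input order (which is
    genome order for data read from a sorted VCF).
    """
    freqs = np.stack([geno.allele_freqs(p) for p in quartet])
    usable = ~np.isnan(freqs).any(axis=0)
    pw, px, py, pz = freqs[:, usable]
    num = (pw - px) * (py - pz)
    den = (pw + px - 2 * pw * px) * (py + pz - 2 * py * pz)
    if den.sum() == 0:
        raise ValueError("no informative sites: denominator is zero")
    abba = float(((1 - pw) * px * py * (1 - pz) + pw * (1 - px) * (1 - py) * pz).sum())
    baba = float((pw * (1 - px) * py * (1 - pz) + (1 - pw) * px * (1 - py) * pz).sum())
    blocks = np.arange(num.size) // block_size_snps
    d, se, g = _jackknife(num, den, blocks)
    if se > 0:
        z = d / se
    else:
        z = 0.0 if d == 0 else np.copysign(np.inf, d)
    p = 2.0 * stats.norm.sf(abs(z))
    return DStatResult(
        quartet=tuple(quartet),
        D=float(d),
        abba=abba,
        baba=baba,
        Z=float(z),
        p=float(p),
        se=se,
        n_blocks=g,
        n_snps_used=int(num.size),
        block_size=block_size_snps,
    )


class PattersonD:
    """Model wrapper: ``PattersonD(geno, quartet).fit()`` -> DStatResult."""

    def __init__(self, geno: GenotypeDataset, quartet, block_size_snps: int = 500):
        if len(quartet) != 4:
            raise ValueError("quartet must list four population labels")
        self.geno = geno
        self.quartet = tuple(quartet)
        self.block_size_snps = block_size_snps

    def fit(self) -> DStatResult:
        return d_statistic(self.geno, self.quartet, self.block_size_snps)


def _wc_theta(geno: np.ndarray, is_a: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham theta for two populations.

    ``geno`` is the dosage submatrix of the two populations' samples and
    ``is_a`` the boolean assignment to the first population.  Returns the
    ratio-of-sums estimate sum(a) / sum(a + b + c).
    """
    r = 2.0
    comps = []
    for mask in (is_a, ~is_a):
        g = geno[mask].astype(float)
        called = g >= 0
        n_i = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, (g * called).sum(axis=0) / (2 * n_i), np.nan)
            h_i = np.where(n_i > 0, ((g == 1) & called).sum(axis=0) / n_i, np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    n_tot = n1 + n2
    valid = (n1 > 0) & (n2 > 0) & (n_tot > 2)
    if not valid.any():
        raise ValueError("no loci with genotypes in both populations")
    n1, n2, p1, p2, h1, h2 = (v[valid] for v in (n1, n2, p1, p2, h1, h2))
    n_tot = n1 + n2
    nbar = n_tot / r
    nc = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / n_tot
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / n_tot
    inner = pbar * (1 - pbar) - ((r - 1.0) / r) * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
    c = hbar / 2.0
    denom = float((a + b + c).sum())
    if denom == 0:
        raise ValueError("no shared polymorphic loci")
    return float(a.sum()) / denom


def weir_cockerham_fst(geno: GenotypeDataset, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham (1984) theta between two populations."""
    mask = (geno.pops == pop_a) | (geno.pops == pop_b)
    if (geno.pops == pop_a).sum() < 2 or (geno.pops == pop_b).sum() < 2:
        raise ValueError("both populations need at least 2 diploid genotypes")
    sub = geno.genotypes[mask]
    is_a = (geno.pops[mask] == pop_a)
    return _wc_theta(sub, is_a)


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    fst: float
    p_perm: float | None
    n_perm: int
    seed: int | None = None

    def summary(self) -> str:
        p = "NA" if self.p_perm is None else f"{self.p_perm:.4g}"
        return (
            f"Weir-Cockerham F_ST({self.pop_a}, {self.pop_b}) = {self.fst:.4f}"
            f"  (p = {p}, {self.n_perm} permutations)"
        )


def fst_permutation_test(
    geno: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    n_perm: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FstResult:
    """Permutation test of theta: individuals reshuffled between the two
    populations (sizes preserved); p = (count(theta* >= obs) + 1) / (n + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = (geno.pops == pop_a) | (geno.pops == pop_b)
    sub = geno.genotypes[mask]
    is_a = (geno.pops[mask] == pop_a)
    obs = _wc_theta(sub, is_a)
    count = 0
    n_ind = sub.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n_ind)
        if _wc_theta(sub, is_a[perm]) >= obs:
            count += 1
    return FstResult(
        pop_a=pop_a,
        pop_b=pop_b,
        fst=obs,
        p_perm=(count + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )


class WeirCockerhamFst:
    """Model wrapper: ``WeirCockerhamFst(geno, a, b).fit(seed=...)``."""

    def __init__(self, geno: GenotypeDataset, pop_a: str, pop_b: str, n_perm: int = 10000):
        self.geno = geno
        self.pop_a = pop_a
        self.pop_b = pop_b
        self.n_perm = n_perm

    def fit(self, seed: int | None = None) -> FstResult:
        return fst_permutation_test(
            self.geno, self.pop_a, self.pop_b, n_perm=self.n_perm, seed=seed
        )


def fst_matrix(
    geno: GenotypeDataset,
    pops: list[str] | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise F_ST matrix (and p-value matrix when n_perm > 0)."""
    labels = pops if pops is not None else geno.pop_labels()
    n = len(labels)
    fst = np.zeros((n, n))
    pmat = np.full((n, n), np.nan) if n_perm else None
    rng = np.random.default_rng(seed)
    for i in range(n):
        for j in range(i + 1, n):
            if n_perm:
                res = fst_permutation_test(
                    geno, labels[i], labels[j], n_perm=n_perm, rng=rng
                )
                fst[i, j] = fst[j, i] = res.fst
                pmat[i, j] = pmat[j, i] = res.p_perm
            else:
                fst[i, j] = fst[j, i] = weir_cockerham_fst(geno, labels[i], labels[j])
    out_f = pd.DataFrame(fst, index=labels, columns=labels)
    out_p = None if pmat is None else pd.DataFrame(pmat, index=labels, columns=labels)
    return out_f, out_p
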