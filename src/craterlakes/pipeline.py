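"""Orchestration: run whole analysis stages from a config and write a
report bundle (CSV/TSV tables, plots, and a provenance record)."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .association import LakeRegressionSuite, divergence_rate
from .datatypes import LakeTable, LandmarkDataset, ShapeData
from .morphometrics import AllometryRegression, gpa
from .popgen import PattersonD, filter_snps, fst_matrix
from .shape_metrics import (
    DEFAULT_BH_PAIR,
    DEFAULT_SL_PAIR,
    between_group_pca,
    distance_matrices,
    elongation_cv,
    pca,
    shape_variance,
)
from .trajectory import TrajectoryDivergence

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_morphometrics", "run_popgen", "run_regressions"]


@dataclass
class RunConfig:
    """Input paths and analysis knobs for a pipeline run."""

    outdir: str = "results"
    tps_path: str | None = None
    metadata_path: str | None = None
    vcf_path: str | None = None
    pop_map_path: str | None = None
    lake_csv_path: str | None = None
    quartets: list = field(default_factory=list)
    outgroup: str | None = None
    pairs: dict = field(default_factory=dict)  # name -> [crater, source]
    grouping: str = "group"  # "group" (lake x species) or "lake"
    sl_pair: tuple[int, int] = DEFAULT_SL_PAIR
    bh_pair: tuple[int, int] = DEFAULT_BH_PAIR
    n_perm: int = 1000
    n_boot: int = 1000
    n_perm_fst: int = 10000
    block_size: int = 500
    min_per_pop: int = 6
    min_outgroup: int = 3
    flip_y: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("tps_path", "metadata_path", "vcf_path", "pop_map_path",
                     "lake_csv_path"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream below 2**31."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31))


def _write_provenance(cfg: RunConfig, outdir: Path, stage: str) -> None:
    rec = {
        "stage": stage,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "craterlakes_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    (outdir / f"provenance_{stage}.json").write_text(json.dumps(rec, indent=2, default=str))


def _load_landmarks(cfg: RunConfig) -> LandmarkDataset:
    if cfg.tps_path is None:
        raise ValueError("config needs tps_path")
    ds = io.read_tps(cfg.tps_path, flip_y=cfg.flip_y)
    if cfg.metadata_path:
        ds.attach_metadata(io.read_specimen_table(cfg.metadata_path))
    return ds


def run_morphometrics(cfg: RunConfig) -> dict:
    """GPA + allometry correction + distances, variance/CV table,
    ordinations and the pairwise divergence-vector table."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = _load_landmarks(cfg)
    aligned = gpa(raw)
    if cfg.grouping == "lake":
        grouping = aligned.lakes
    else:
        grouping = aligned.groups
    allo = AllometryRegression(aligned, grouping=grouping).fit()
    shape = ShapeData(
        coords=allo.corrected_coords,
        groups=grouping,
        lakes=aligned.lakes,
        specimen_ids=aligned.specimen_ids,
    )
    pd.DataFrame(
        allo.corrected_coords,
        index=aligned.specimen_ids,
    ).to_csv(outdir / "corrected_coordinates.csv")

    pdist, mdist = distance_matrices(shape)
    pdist.to_csv(outdir / "procrustes_distances.csv")
    mdist.to_csv(outdir / "mahalanobis_distances.csv")

    lakes = list(dict.fromkeys(raw.lakes))
    var_rows = []
    for lake in lakes:
        if (raw.lakes == lake).sum() < 3:
            continue
        var_rows.append(
            {
                "lake": lake,
                "shape_variance": shape_variance(raw, lake),
                "cv_ei": elongation_cv(raw, lake, cfg.sl_pair, cfg.bh_pair),
            }
        )
    var_df = pd.DataFrame(var_rows)
    var_df.to_csv(outdir / "shape_variation.csv", index=False)

    ord_res = pca(shape)
    pd.DataFrame(
        ord_res.scores[:, :10],
        index=aligned.specimen_ids,
        columns=[f"PC{i+1}" for i in range(min(10, ord_res.scores.shape[1]))],
    ).to_csv(outdir / "pca_scores.csv")
    bg = None
    if len(shape.group_labels()) >= 3:
        bg = between_group_pca(shape)
        bg.group_mean_scores.to_csv(outdir / "bgpca_group_means.csv")

    from . import plotting

    plotting.plot_ordination(ord_res, shape.groups, outdir / "pca.png")
    if bg is not None:
        pairs_for_plot = {k: tuple(v) for k, v in cfg.pairs.items()}
        plotting.plot_trajectories(bg, pairs_for_plot, outdir / "bgpca_trajectories.png")

    traj = None
    if cfg.pairs:
        pairs = {k: tuple(v) for k, v in cfg.pairs.items()}
        traj = TrajectoryDivergence(
            shape,
            pairs,
            n_perm=cfg.n_perm,
            n_boot=cfg.n_boot,
            seed=cfg.stage_seed("trajectory"),
        ).fit()
        traj.to_frame().to_csv(outdir / "trajectory_comparisons.csv", index=False)
        traj.dL_table.to_csv(outdir / "trajectory_dL_table.csv")
        traj.theta_table.to_csv(outdir / "trajectory_theta_table.csv")

    _write_provenance(cfg, outdir, "morphometrics")
    log.info("morphometrics stage complete: %d specimens, %d groups",
             len(raw), len(shape.group_labels()))
    return {
        "aligned": aligned,
        "allometry": allo,
        "shape": shape,
        "procrustes_distances": pdist,
        "mahalanobis_distances": mdist,
        "variation": var_df,
        "pca": ord_res,
        "bgpca": bg,
        "trajectory": traj,
    }


def run_popgen(cfg: RunConfig) -> dict:
    """SNP filtering, F_ST matrix with permutations, and D-statistics for
    the configured quartets."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.vcf_path is None or cfg.pop_map_path is None:
        raise ValueError("config needs vcf_path and pop_map_path")
    geno = io.read_genotypes(cfg.vcf_path, cfg.pop_map_path, outgroup=cfg.outgroup)
    geno = filter_snps(geno, cfg.min_per_pop, cfg.min_outgroup)

    fst, fst_p = fst_matrix(
        geno, n_perm=cfg.n_perm_fst, seed=cfg.stage_seed("fst")
    )
    fst.to_csv(outdir / "fst_matrix.tsv", sep="\t")
    if fst_p is not None:
        fst_p.to_csv(outdir / "fst_pvalues.tsv", sep="\t")

    drows = []
    for quartet in cfg.quartets:
        res = PattersonD(geno, tuple(quartet), cfg.block_size).fit()
        drows.append(
            {
                "Pop1_W": res.quartet[0],
                "Pop2_X": res.quartet[1],
                "Pop3_Y": res.quartet[2],
                "Pop4_Z": res.quartet[3],
                "D": res.D,
                "BABA": res.baba,
                "ABBA": res.abba,
                "Z": res.Z,
                "p": res.p,
                "significant_p_lt_0.01": res.p < 0.01,
            }
        )
    ddf = pd.DataFrame(drows)
    if len(ddf):
        ddf.to_csv(outdir / "dstat_table.tsv", sep="\t", index=False)
    _write_provenance(cfg, outdir, "popgen")
    return {"genotypes": geno, "fst": fst, "fst_p": fst_p, "dstat": ddf}


def run_regressions(cfg: RunConfig, morpho: dict | None = None) -> dict:
    """Fill the lake table's responses from morphometric outputs (when
    available) and run the regression suite."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.lake_csv_path is None:
        raise ValueError("config needs lake_csv_path")
    table = io.read_lake_table(cfg.lake_csv_path)

    if morpho is not None:
        source = str(table.frame.attrs.get("source_lake", "source"))
        for lake in table.lakes:
            pdist = morpho["procrustes_distances"]
            mdist = morpho["mahalanobis_distances"]
            if lake in pdist.index and source in pdist.columns:
                table.set_response(lake, "procrustes_dist", pdist.loc[lake, source])
                table.set_response(lake, "mahalanobis_dist", mdist.loc[lake, source])
                t_col = float(
                    table.frame.loc[table.frame["lake"] == lake, "t_col"].iloc[0]
                )
                table.set_response(
                    lake, "rate", divergence_rate(mdist.loc[lake, source], t_col)
                )
            var = morpho["variation"]
            row = var[var["lake"] == lake]
            if len(row):
                table.set_response(lake, "shape_variance", float(row["shape_variance"].iloc[0]))
                table.set_response(lake, "cv_ei", float(row["cv_ei"].iloc[0]))

    suite = LakeRegressionSuite(table).fit()
    suite.to_frame().to_csv(outdir / "regression_fits.csv", index=False)
    io.write_lake_table(table, outdir / "lake_table_filled.csv")

    from . import plotting

    for fit in suite.fits:
        if fit.p < 0.05:
            sub = table.frame[[fit.predictor, fit.response]].dropna()
            plotting.plot_regression(
                sub[fit.predictor], sub[fit.response], fit,
                outdir / f"regression_{fit.response}_vs_{fit.predictor}"
                f"{'_log' if fit.transform == 'log10_x' else ''}.png",
            )
    _write_provenance(cfg, outdir, "regressions")
    return {"table": table, "suite": suite}
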