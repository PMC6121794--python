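"""Readers and writers for the formats the pipeline touches.

TPS (the tpsDig dialect) for landmarks, VCF (via cyvcf2) or a plain
tab-separated dosage matrix for genotypes, and CSV for the per-lake
predictor table.  All readers validate into the domain containers of
:mod:`craterlakes.datatypes`.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    GenotypeDataset,
    LakeTable,
    LandmarkConfiguration,
    LandmarkDataset,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_tps",
    "write_tps",
    "read_specimen_table",
    "read_genotypes",
    "read_genotype_matrix",
    "read_pop_map",
    "write_vcf",
    "read_lake_table",
    "write_lake_table",
    "load_crater_lake_predictors",
]

_KEY_RE = re.compile(r"^([A-Za-z]+)\s*=\s*(.*)$")


def read_tps(
    path,
    expected_landmarks: int | None = None,
    flip_y: bool = False,
) -> LandmarkDataset:
    """Parse a TPS file into a raw :class:`LandmarkDataset`.

    Records start at an ``LM=`` line followed by that many coordinate rows;
    ``ID=``, ``IMAGE=`` and ``SCALE=`` lines are honoured and unknown keys
    ignored.  Coordinates are multiplied by the SCALE factor when present.
    ``flip_y`` negates the y axis for files digitised in image-origin
    (top-left) convention.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        m = _KEY_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            continue  # skip anything before the first record
        record_no += 1
        try:
            n_lm = int(m.group(2))
        except ValueError as exc:
            raise ValueError(
                f"{path}:{i}: malformed LM= line in record {record_no}"
            ) from exc
        coords = np.empty((n_lm, 2), dtype=float)
        for j in range(n_lm):
            if i >= len(lines):
                raise ValueError(
                    f"{path}: record {record_no} truncated after "
                    f"{j} of {n_lm} landmarks"
                )
            parts = lines[i].split()
            i += 1
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{i}: expected two coordinates in record "
                    f"{record_no}"
                )
            try:
                coords[j, 0] = float(parts[0])
                coords[j, 1] = float(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{i}: non-numeric coordinate in record "
                    f"{record_no}"
                ) from exc
        spec_id = f"specimen_{record_no}"
        scale = None
        # trailing key=value lines until the next LM=
        while i < len(lines):
            peek = lines[i].strip()
            mk = _KEY_RE.match(peek)
            if mk is None:
                if peek == "":
                    i += 1
                    continue
                raise ValueError(
                    f"{path}:{i + 1}: unexpected line in record {record_no}"
                )
            key = mk.group(1).upper()
            if key == "LM":
                break
            i += 1
            if key == "ID":
                spec_id = mk.group(2).strip()
            elif key == "SCALE":
                scale = float(mk.group(2))
            # IMAGE= and unknown keys are ignored
        if expected_landmarks is not None and n_lm != expected_landmarks:
            raise ValueError(
                f"{path}: record {record_no} ({spec_id!r}) has {n_lm} "
                f"landmarks, expected {expected_landmarks}"
            )
        if scale is not None:
            coords = coords * scale
        if flip_y:
            coords = coords * np.array([1.0, -1.0])
        configs.append(
            LandmarkConfiguration(specimen_id=spec_id, coords=coords, scale=scale)
        )
    return LandmarkDataset(configs, state="raw")


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write a dataset back to TPS text re-readable by :func:`read_tps`.

    Stored shape-unit coordinates are divided by each specimen's scale
    factor (when present) so the file is in original image units.
    """
    if len(dataset) == 0:
        raise ValueError("cannot write an empty dataset")
    out = []
    for c in dataset.configurations:
        coords = c.coords if c.scale is None else c.coords / c.scale
        out.append(f"LM={c.n_landmarks}")
        for x, y in coords:
            out.append(f"{x:.10g} {y:.10g}")
        out.append(f"ID={c.specimen_id}")
        if c.scale is not None:
            out.append(f"SCALE={c.scale:.10g}")
    Path(path).write_text("\n".join(out) + "\n")


def read_specimen_table(path) -> pd.DataFrame:
    """Read a specimen metadata table (CSV/TSV with specimen_id, lake[, group])."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "specimen_id" not in df.columns or "lake" not in df.columns:
        raise ValueError("metadata needs 'specimen_id' and 'lake' columns")
    return df


def read_pop_map(path) -> dict[str, str]:
    """Two-column TSV (specimen, population) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
    return dict(zip(df["sample"], df["pop"]))


def read_genotypes(
    path,
    pop_map,
    outgroup: str | None = None,
) -> GenotypeDataset:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeDataset`.

    ``pop_map`` is a path to a two-column TSV or a dict.  Multi-allelic and
    non-SNP sites are dropped with a logged count.  The VCF ID column is
    used as the RAD-locus identifier (falling back to ``chrom:pos``).
    """
    from cyvcf2 import VCF

    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_map]
    if absent:
        raise KeyError(f"samples absent from population map: {absent}")
    rows: list[np.ndarray] = []
    loci: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        gts = var.genotype.array()
        a = gts[:, 0].astype(np.int16)
        b = gts[:, 1].astype(np.int16)
        dose = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        rows.append(dose)
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if n_dropped:
        log.info("dropped %d multi-allelic/non-SNP sites", n_dropped)
    geno = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    ds = GenotypeDataset(
        genotypes=geno,
        samples=samples,
        pops=np.array([pop_map[s] for s in samples], dtype=object),
        locus_ids=np.array(loci, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=int),
        outgroup=outgroup,
    )
    ds.filter_counts["multiallelic_dropped"] = n_dropped
    return ds


def read_genotype_matrix(path, pop_map, outgroup: str | None = None) -> GenotypeDataset:
    """Read a TSV dosage matrix (rows: samples; columns: SNP locus ids).

    Values are 0/1/2 or empty/NA for missing.
    """
    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    df = pd.read_csv(path, sep="\t", index_col=0)
    absent = [s for s in df.index if s not in pop_map]
    if absent:
        raise KeyError(f"samples absent from population map: {absent}")
    geno = df.to_numpy(dtype=float)
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeDataset(
        genotypes=geno,
        samples=list(df.index),
        pops=np.array([pop_map[s] for s in df.index], dtype=object),
        locus_ids=np.array(df.columns, dtype=object),
        outgroup=outgroup,
    )


def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write a minimal VCF 4.2 file (GT only) for the dataset."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = (
        dataset.chrom
        if dataset.chrom is not None
        else np.array(["chr1"] * dataset.n_snps, dtype=object)
    )
    for c in dict.fromkeys(chroms):
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
    lines.append("\t".join(header[:-1] + ["INFO", "FORMAT"] + dataset.samples))
    pos = (
        dataset.pos
        if dataset.pos is not None
        else np.arange(1, dataset.n_snps + 1) * 100
    )
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j in range(dataset.n_snps):
        col = dataset.genotypes[:, j]
        fields = [
            str(chroms[j]),
            str(int(pos[j])),
            str(dataset.locus_ids[j]),
            "A",
            "T",
            ".",
            "PASS",
            ".",
            "GT",
        ] + [gt_map[int(g)] for g in col]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_pop_map(dataset: GenotypeDataset, path) -> None:
    pd.DataFrame({"sample": dataset.samples, "pop": dataset.pops}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_lake_table(path) -> LakeTable:
    return LakeTable(pd.read_csv(path))


def write_lake_table(table: LakeTable, path) -> None:
    table.frame.to_csv(path, index=False)


def load_crater_lake_predictors() -> LakeTable:
    """The packaged six-crater-lake predictor table.

    Founder size, colonization time and admixture proportion are point
    estimates from demographic inference of the Midas cichlid system;
    long-term Ne and the physico-ecological columns (mean depth, littoral
    area) are left blank for the user to supply.
    """
    with resources.files("craterlakes.data").joinpath(
        "crater_lake_predictors.csv"
    ).open() as fh:
        return LakeTable(pd.read_csv(fh))
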