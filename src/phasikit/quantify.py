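"""Abundance normalization (RPTM) and stage-resolved locus matrices.

RPTM — reads per ten million — scales a feature's raw abundance by
1e7 / (total genome-matched abundance of the library), making libraries of
different depth comparable. Locus x library matrices over an ordered
developmental stage series summarize the spatiotemporal pattern; 24-nt
reproductive phasiRNAs characteristically peak at a meiotic stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import SrnaAlignment
from .phasing import PhasLocus

logger = logging.getLogger(__name__)

RPTM_SCALE = 1e7


@dataclass(frozen=True)
class LibraryInfo:
    """One sequencing library: id, ordered stage label, mapped total."""

    lib_id: str
    stage: str
    order: int
    total_mapped: int

    def __post_init__(self) -> None:
        if self.total_mapped <= 0:
            raise ValueError(f"library {self.lib_id}: total_mapped must be > 0")


@dataclass
class AbundanceMatrix:
    """Feature x library RPTM values with the transform recorded."""

    df: pd.DataFrame  # rows: feature ids, cols: library ids
    transform: str = "rptm"  # rptm | log2_rptm


def compute_rptm_matrix(
    loci: Sequence[PhasLocus],
    alignments_by_lib: dict[str, list[SrnaAlignment]],
    libraries: Sequence[LibraryInfo],
    count_rule: str = "phase_length_only",
    log2: bool = False,
) -> AbundanceMatrix:
    """Locus x library RPTM matrix.

    cell(locus, lib) = 1e7 * (counts of reads overlapping the locus) /
    total_mapped(lib). Under ``phase_length_only`` only reads whose length
    equals the locus phase length P are counted; ``all_lengths`` counts
    every overlapping read.
    """
    if count_rule not in ("phase_length_only", "all_lengths"):
        raise ValueError(f"unknown count_rule '{count_rule}'")
    lib_map = {lib.lib_id: lib for lib in libraries}
    unknown = set(alignments_by_lib) - set(lib_map)
    if unknown:
        raise ValueError(f"alignments given for unknown library id(s): {sorted(unknown)}")

    row_ids = [lc.locus_id for lc in loci]
    col_ids = [lib.lib_id for lib in libraries]
    values = np.zeros((len(loci), len(col_ids)))
    for j, lib in enumerate(libraries):
        alns = alignments_by_lib.get(lib.lib_id, [])
        for i, lc in enumerate(loci):
            total = 0
            for a in alns:
                if a.chrom != lc.chrom:
                    continue
                if count_rule == "phase_length_only" and a.length != lc.P:
                    continue
                if a.start < lc.end and a.end > lc.start:
                    total += a.count
            values[i, j] = RPTM_SCALE * total / lib.total_mapped
    if log2:
        values = np.log2(values + 1.0)
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    return AbundanceMatrix(df=df, transform="log2_rptm" if log2 else "rptm")


def library_rptm_total(alignments: Iterable[SrnaAlignment], total_mapped: int) -> float:
    """RPTM of the whole library; equals 1e7 when all mapped reads are counted."""
    return RPTM_SCALE * sum(a.count for a in alignments) / total_mapped


def peak_stage(
    matrix: AbundanceMatrix,
    row_id: str,
    libraries: Sequence[LibraryInfo],
) -> str:
    """Stage with the maximal summed RPTM for one feature.

    Libraries sharing a stage label are summed; ties resolve to the
    earliest stage in the declared order; an all-zero row returns "none".
    """
    row = matrix.df.loc[row_id]
    stages: dict[str, float] = {}
    order: dict[str, int] = {}
    for lib in libraries:
        stages[lib.stage] = stages.get(lib.stage, 0.0) + float(row.get(lib.lib_id, 0.0))
        order.setdefault(lib.stage, lib.order)
    if all(v == 0.0 for v in stages.values()):
        return "none"
    return max(stages, key=lambda s: (stages[s], -order[s]))


def write_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Tab-separated matrix: header row of library ids, first column feature ids."""
    with open(path, "w") as fh:
        fh.write("# transform=" + matrix.transform + "\n")
        matrix.df.to_csv(fh, sep="\t", index_label="feature", float_format="%.6g")


def read_matrix(path: str | Path) -> AbundanceMatrix:
    """Inverse of :func:`write_matrix`."""
    transform = "rptm"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# transform="):
            transform = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", index_col="feature")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="feature")
    return AbundanceMatrix(df=df, transform=transform)


def write_stage_metadata(libraries: Sequence[LibraryInfo], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lib_id\tstage\torder\ttotal_mapped\n")
        for lib in libraries:
            fh.write(f"{lib.lib_id}\t{lib.stage}\t{lib.order}\t{lib.total_mapped}\n")


def read_stage_metadata(path: str | Path) -> list[LibraryInfo]:
    libs = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            lib_id, stage, order, total = line.rstrip("\n").split("\t")
            libs.append(LibraryInfo(lib_id, stage, int(order), int(total)))
    return libs
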