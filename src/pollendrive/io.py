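"""Plain-text I/O: marker sets (TSV / sites-only VCF), sparse genotype
matrices (TSV / MatrixMarket), tracks (bedGraph) and intervals (BED)."""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .genetics import MarkerSet
from .pollen import SparseGenotypeMatrix

__all__ = [
    "read_markers_tsv",
    "write_markers_tsv",
    "read_markers_vcf",
    "write_markers_vcf",
    "read_genetic_map_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_matrix_mtx",
    "read_matrix_mtx",
    "write_bedgraph",
    "write_bed",
]

MARKER_COLS = ["chrom", "pos", "cm", "ref", "alt"]


def read_markers_tsv(path: str | Path) -> MarkerSet:
    tab = pd.read_csv(path, sep="\t")
    return MarkerSet(tab[MARKER_COLS])


def write_markers_tsv(markers: MarkerSet, path: str | Path) -> None:
    markers.table[MARKER_COLS].to_csv(path, sep="\t", index=False)


def write_markers_vcf(markers: MarkerSet, path: str | Path) -> None:
    """Sites-only VCF; the cM coordinate is carried in INFO/CM."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position (cM)">\n')
        for chrom in markers.chroms:
            sl = markers.chrom_slice(chrom)
            fh.write(f"##contig=<ID={chrom},length={int(markers.pos[sl][-1]) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in markers.table.iterrows():
            ref, alt = str(row["ref"]), str(row["alt"])
            # haplotype labels (e.g. W22/mex) are written as symbolic alleles
            if set(ref) - set("ACGTN"):
                ref, alt = "N", f"<{alt}>"
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{ref}\t{alt}\t.\tPASS\tCM={row['cm']:g}\n"
            )


def read_markers_vcf(path: str | Path) -> MarkerSet:
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
        alt = f[4].strip("<>")
        rows.append(
            {
                "chrom": f[0],
                "pos": int(f[1]),
                "cm": float(info.get("CM", "nan")),
                "ref": f[3],
                "alt": alt,
            }
        )
    return MarkerSet(pd.DataFrame(rows))


def read_genetic_map_tsv(path: str | Path) -> pd.DataFrame:
    """3-column genetic map: chrom, pos (bp), cm."""
    tab = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos", "cm"} <= set(tab.columns):
        raise ValueError("genetic map TSV needs columns chrom, pos, cm")
    return tab


def write_matrix_tsv(matrix: SparseGenotypeMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path, markers: MarkerSet) -> SparseGenotypeMatrix:
    tab = pd.read_csv(path, sep="\t")
    data = tab.drop(columns=["chrom", "pos"]).to_numpy(dtype=np.int8)
    return SparseGenotypeMatrix(data, markers)


def write_matrix_mtx(matrix: SparseGenotypeMatrix, path: str | Path) -> None:
    spio.mmwrite(str(path), sparse.coo_matrix(matrix.data))


def read_matrix_mtx(path: str | Path, markers: MarkerSet) -> SparseGenotypeMatrix:
    data = np.asarray(spio.mmread(str(path)).todense(), dtype=np.int8)
    return SparseGenotypeMatrix(data, markers)


def write_bedgraph(track: pd.DataFrame, path: str | Path, value_col: str = "value") -> None:
    """Write chrom/start/end/value rows; NaN values are skipped."""
    cols = ["chrom", "start", "end", value_col]
    sub = track[cols].dropna(subset=[value_col])
    sub.to_csv(path, sep="\t", header=False, index=False)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "min_q") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)
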