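"""Readers and writers for the pipeline's plain-text formats.

Coordinate conventions: everything in memory is 0-based half-open; sync
files and report TSVs use 1-based positions (stated in their headers); BED
exports are 0-based half-open per the BED standard; GFF3 is 1-based
inclusive.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .linkstats import GenotypeCountTable
from .poolscan import SexRegionCall
from .radassoc import TileMatrix
from .simdata import COUNT_COLUMNS, RadMarkerMatrix

__all__ = [
    "read_sync",
    "write_sync",
    "read_counts_table",
    "write_counts_table",
    "read_rad_matrix",
    "write_rad_matrix",
    "read_sex_map",
    "write_sex_map",
    "read_assay_table",
    "write_assay_table",
    "read_annotation",
    "write_bed",
    "write_genes_gff3",
    "write_track",
    "write_regions",
    "write_tile_matrix",
]

_SYNC_HEADER = "#chrom\tpos\tref\tpool_males\tpool_females  (pos 1-based; A:C:G:T:N:del)"


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def write_sync(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write pooled counts as popoolation2-style sync TSV (1-based pos)."""
    with open(path, "w") as fh:
        fh.write(_SYNC_HEADER + "\n")
        m = sites[list(COUNT_COLUMNS[:6])].to_numpy(dtype=np.int64)
        f = sites[list(COUNT_COLUMNS[6:])].to_numpy(dtype=np.int64)
        chroms = sites["chrom"].to_numpy()
        pos = sites["pos"].to_numpy()
        refs = sites["ref"].to_numpy()
        for i in range(len(sites)):
            fh.write(
                f"{chroms[i]}\t{pos[i] + 1}\t{refs[i]}\t"
                + ":".join(map(str, m[i]))
                + "\t"
                + ":".join(map(str, f[i]))
                + "\n"
            )


def _parse_pool_field(field: str, path: str, lineno: int) -> list[int]:
    parts = field.split(":")
    if len(parts) != 6:
        raise FormatError(f"{path}:{lineno}: pool field needs 6 ':'-separated counts, got {field!r}")
    try:
        vals = [int(x) for x in parts]
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer count in {field!r}") from None
    if any(v < 0 for v in vals):
        raise FormatError(f"{path}:{lineno}: negative count in {field!r}")
    return vals


def read_sync(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sync TSV into the internal pooled-counts table (0-based pos)."""
    path = os.fspath(path)
    rows = []
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            chrom, pos_s, ref, pm, pf = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            if chrom in last and pos <= last[chrom]:
                raise FormatError(f"{path}:{lineno}: unsorted position {chrom}:{pos}")
            last[chrom] = pos
            m = _parse_pool_field(pm, path, lineno)
            f = _parse_pool_field(pf, path, lineno)
            rows.append([chrom, pos - 1, ref, *m, *f])
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", *COUNT_COLUMNS])


def write_counts_table(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    """Long-form equivalent of the sync file: named count columns, 1-based pos."""
    out = sites[["chrom", "pos", "ref", *COUNT_COLUMNS]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos", "ref", *COUNT_COLUMNS}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["pos"] = df["pos"] - 1
    return df


# ---------------------------------------------------------------------------
# RAD matrix / sex map


def write_rad_matrix(matrix: RadMarkerMatrix, depth_path, sex_path) -> None:
    matrix.depth.to_csv(depth_path, sep="\t")
    matrix.sex.rename_axis("individual").to_frame().to_csv(sex_path, sep="\t")


def read_rad_matrix(depth_path, sex_path) -> RadMarkerMatrix:
    depth = pd.read_csv(depth_path, sep="\t", index_col=0)
    sex = read_sex_map(sex_path)
    return RadMarkerMatrix(depth=depth, sex=sex)


def write_sex_map(sex: pd.Series, path) -> None:
    sex.rename("sex").rename_axis("individual").to_frame().to_csv(path, sep="\t")


def read_sex_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "sex" not in df.columns:
        raise FormatError(f"{path}: expected a 'sex' column")
    return df["sex"]


# ---------------------------------------------------------------------------
# genotyping-assay tables

_ASSAY_COLS = ["assay_id", "male_ho", "male_he", "male_u", "female_ho", "female_he", "female_u"]


def write_assay_table(tables: Iterable[GenotypeCountTable], path) -> None:
    pd.DataFrame(
        [[t.assay_id, t.male_ho, t.male_he, t.male_u, t.female_ho, t.female_he, t.female_u] for t in tables],
        columns=_ASSAY_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_assay_table(path) -> list[GenotypeCountTable]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_ASSAY_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        GenotypeCountTable(
            str(r.assay_id),
            male_ho=int(r.male_ho), male_he=int(r.male_he), male_u=int(r.male_u),
            female_ho=int(r.female_ho), female_he=int(r.female_he), female_u=int(r.female_u),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# annotation


def _detect_format(path: str) -> str:
    lower = path.lower()
    if lower.endswith((".gff", ".gff3")):
        return "gff3"
    if lower.endswith(".bed"):
        return "bed"
    raise FormatError(f"{path}: cannot infer format; pass fmt='bed' or 'gff3'")


def read_annotation(path, fmt: str | None = None) -> list[tuple[str, int, int, str, str]]:
    """Read gene intervals from BED or GFF3 into 0-based half-open tuples.

    BED uses columns chrom/start/end[/name[/score[/strand]]]; GFF3
    contributes only ``gene``-type records, converting 1-based inclusive
    coordinates, with the name taken from Name=, gene= or ID= attributes.
    Mixing dialects in one file is rejected.
    """
    path = os.fspath(path)
    fmt = fmt or _detect_format(path)
    genes: list[tuple[str, int, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "gff3":
                if len(fields) != 9:
                    raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(fields)}")
                chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
                if ftype != "gene":
                    continue
                try:
                    start, end = int(start_s) - 1, int(end_s)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad coordinates") from None
                name = ""
                for key in ("Name=", "gene=", "ID="):
                    for item in attrs.split(";"):
                        if item.startswith(key):
                            name = item[len(key):]
                            break
                    if name:
                        break
                if not name:
                    raise FormatError(f"{path}:{lineno}: gene record without Name/gene/ID")
            else:
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad coordinates") from None
                name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
                strand = fields[5] if len(fields) > 5 else "."
            if end <= start or start < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            genes.append((chrom, start, end, strand, name))
    return genes


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start, end[, name[, strand]]) tuples as BED (0-based)."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else "."
            strand = iv[4] if len(iv) > 4 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def write_genes_gff3(genes: Iterable[tuple[str, int, int, str, str]], path) -> None:
    """Write gene intervals as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, strand, name in genes:
            fh.write(
                f"{chrom}\tsdscan\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={name};Name={name}\n"
            )


# ---------------------------------------------------------------------------
# result exports


def write_track(track: pd.DataFrame, path, seed: int | None = None) -> None:
    """Window/bin track TSV; window starts reported 1-based in column 'start'."""
    out = track.copy()
    out["start"] = out["start"] + 1
    with open(path, "w") as fh:
        fh.write("# window track; start is 1-based\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def write_regions(calls: Iterable[SexRegionCall], tsv_path, bed_path=None, seed=None) -> None:
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start + 1,  # 1-based inclusive in the report
            "end": c.end,
            "length": c.length,
            "kind": c.kind,
            "n_windows": c.n_windows,
            "peak_density": c.peak_density,
            "total_snvs": c.total_snvs,
            "mean_depth_m": c.mean_depth_m,
            "mean_depth_f": c.mean_depth_f,
        }
        for c in calls
    ]
    with open(tsv_path, "w") as fh:
        fh.write("# region calls; start/end 1-based inclusive\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "length", "kind", "n_windows",
                "peak_density", "total_snvs", "mean_depth_m", "mean_depth_f",
            ],
        ).to_csv(fh, sep="\t", index=False, float_format="%.3f")
    if bed_path:
        write_bed([(c.chrom, c.start, c.end, c.kind) for c in calls], bed_path)


def write_tile_matrix(tiles: TileMatrix, path, seed=None) -> None:
    """Tile matrix TSV: rows = males present (0..n_m), columns = females."""
    df = pd.DataFrame(
        tiles.counts,
        index=pd.Index(range(tiles.n_males + 1), name="males_present"),
        columns=[str(f) for f in range(tiles.n_females + 1)],
    )
    with open(path, "w") as fh:
        fh.write(f"# tile matrix at min depth d={tiles.d}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t")
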