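"""Pooled-sequencing scan for sex-specific SNVs and coverage anomalies.

Given per-site allele counts for a male pool and a female pool, the scan

1. classifies each site as male-specific (heterozygous in the male pool,
   homozygous in the female pool), female-specific (the mirror image) or
   uninformative,
2. aggregates classifications into sliding-window density tracks and
   genome-wide non-overlapping bins,
3. calls candidate sex-determining regions (SDRs) as runs of
   high-density windows, and
4. flags hemizygous Y-limited segments from the male/female depth ratio
   (half depth in males, near-zero in females).

In an XX/XY system, X/Y-divergent sites inside the non-recombining SDR put
the male pool at ~0.5 alternate-allele frequency while the female pool stays
fixed, which is exactly the site signature in (1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScanParams",
    "SexRegionCall",
    "pool_frequencies",
    "classify_site",
    "classify_sites",
    "window_scan",
    "manhattan_bins",
    "call_sdr",
    "coverage_regions",
    "annotate_region",
    "rank_regions",
]

MALE_SPECIFIC = "male_specific"
FEMALE_SPECIFIC = "female_specific"
NONE = "none"
LOW_DEPTH = "low_depth"

_M_ACGT = ["m_A", "m_C", "m_G", "m_T"]
_F_ACGT = ["f_A", "f_C", "f_G", "f_T"]


@dataclass(frozen=True)
class ScanParams:
    """Thresholds and window geometry for the pooled scan.

    A pool is heterozygous at a site when the frequency of its second most
    frequent base lies within ``0.5 +/- het_delta`` of the A/C/G/T total, and
    homozygous when the major base reaches ``hom_min_major``.  At ~40x pool
    depth the defaults accept the idealized 0.5/1.0 X-Y signature while a
    single stray read (1/40 = 0.025) breaks "homozygous" — a deliberately
    strict default, exposed for noisier data.  Windows of ``window_size`` are
    placed every ``output_resolution`` bp; ``manhattan_bin`` gives the
    non-overlapping genome-plot bin size.
    """

    min_depth: int = 10
    het_delta: float = 0.1
    hom_min_major: float = 0.98
    window_size: int = 5000
    output_resolution: int = 1000
    manhattan_bin: int = 50_000

    def __post_init__(self) -> None:
        if not 0 < self.het_delta < 0.5:
            raise ValueError("het_delta must be in (0, 0.5)")
        if not 0.5 < self.hom_min_major <= 1.0:
            raise ValueError("hom_min_major must be in (0.5, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.output_resolution <= 0 or self.window_size <= 0:
            raise ValueError("window geometry must be positive")
        if self.output_resolution > self.window_size:
            raise ValueError("output_resolution must not exceed window_size")
        if self.manhattan_bin <= 0:
            raise ValueError("manhattan_bin must be positive")


@dataclass(frozen=True)
class SexRegionCall:
    """A called candidate region (allelic SDR or Y-limited insertion)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_density: float
    kind: str  # "allelic_sdr" | "male_limited_insertion" | "allelic_sdr_female"
    total_snvs: int = 0
    mean_depth_m: float = float("nan")
    mean_depth_f: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


# ---------------------------------------------------------------------------
# site classification


def pool_frequencies(counts: np.ndarray, params: ScanParams):
    """Major/minor base frequencies of one pool from a 6-vector of counts.

    Only A/C/G/T enter the denominator (N and deletion reads are ignored).
    Returns ``(major_base_index, major_freq, second_freq, depth)`` or ``None``
    when the pool is below ``min_depth`` and must be excluded.
    """
    acgt = np.asarray(counts[:4], dtype=float)
    if (acgt < 0).any():
        raise ValueError("negative counts")
    depth = acgt.sum()
    if depth < params.min_depth or depth == 0:
        return None
    order = np.argsort(acgt)[::-1]
    return int(order[0]), acgt[order[0]] / depth, acgt[order[1]] / depth, int(depth)


def classify_site(counts_m, counts_f, params: ScanParams) -> str:
    """Classify one site from per-pool 6-vectors of base counts.

    ``male_specific``: male pool heterozygous and female pool homozygous;
    ``female_specific`` is the mirror; ``low_depth`` when either pool fails
    ``min_depth``; else ``none``.
    """
    fm = pool_frequencies(counts_m, params)
    ff = pool_frequencies(counts_f, params)
    if fm is None or ff is None:
        return LOW_DEPTH
    lo, hi = 0.5 - params.het_delta, 0.5 + params.het_delta
    het_m = lo <= fm[2] <= hi
    het_f = lo <= ff[2] <= hi
    hom_m = fm[1] >= params.hom_min_major
    hom_f = ff[1] >= params.hom_min_major
    if het_m and hom_f:
        return MALE_SPECIFIC
    if het_f and hom_m:
        return FEMALE_SPECIFIC
    return NONE


def classify_sites(sites: pd.DataFrame, params: ScanParams) -> pd.Series:
    """Vectorized :func:`classify_site` over a pooled-counts table.

    ``sites`` must carry the twelve ``m_A..f_del`` count columns; returns a
    string Series aligned with ``sites``.
    """
    m = sites[_M_ACGT].to_numpy(dtype=float)
    f = sites[_F_ACGT].to_numpy(dtype=float)
    if (m < 0).any() or (f < 0).any():
        raise ValueError("negative counts")
    dm, df_ = m.sum(axis=1), f.sum(axis=1)
    ok = (dm >= max(params.min_depth, 1)) & (df_ >= max(params.min_depth, 1))
    ms = np.sort(m, axis=1)
    fs = np.sort(f, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maj_m, sec_m = ms[:, 3] / dm, ms[:, 2] / dm
        maj_f, sec_f = fs[:, 3] / df_, fs[:, 2] / df_
    lo, hi = 0.5 - params.het_delta, 0.5 + params.het_delta
    het_m = (sec_m >= lo) & (sec_m <= hi)
    het_f = (sec_f >= lo) & (sec_f <= hi)
    hom_m = maj_m >= params.hom_min_major
    hom_f = maj_f >= params.hom_min_major
    out = np.full(len(sites), NONE, dtype=object)
    out[het_m & hom_f] = MALE_SPECIFIC
    out[het_f & hom_m] = FEMALE_SPECIFIC
    out[~ok] = LOW_DEPTH
    return pd.Series(out, index=sites.index, name="class")


# ---------------------------------------------------------------------------
# windowed tracks


def _check_sorted(sites: pd.DataFrame) -> None:
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    same = chrom[1:] == chrom[:-1]
    bad = np.flatnonzero(same & (pos[1:] < pos[:-1]))
    if bad.size:
        i = int(bad[0]) + 1
        raise ValueError(
            f"sites not sorted by position: row {i} ({chrom[i]}:{pos[i]} after {pos[i - 1]})"
        )
    # chromosomes must be grouped (each name appears in one contiguous block)
    names, first = np.unique(chrom, return_index=True)
    blocks = 1 + int((~same).sum()) if len(chrom) else 0
    if blocks > len(names):
        raise ValueError("sites not grouped by chromosome")


def _chrom_lengths(sites: pd.DataFrame, chrom_sizes: dict[str, int] | None) -> dict[str, int]:
    if chrom_sizes is None:
        chrom_sizes = sites.attrs.get("chrom_sizes")
    if chrom_sizes:
        return dict(chrom_sizes)
    return {c: int(g["pos"].max()) + 1 for c, g in sites.groupby("chrom", sort=False)}


def window_scan(
    sites: pd.DataFrame,
    params: ScanParams,
    chrom_sizes: dict[str, int] | None = None,
    classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Sliding-window track of sex-specific SNV density and pool depth.

    Windows of ``window_size`` bp start at every multiple of
    ``output_resolution`` below the chromosome length; a site at position p
    (0-based) is counted in each window whose half-open span [start,
    start+window_size) contains p.  Depth means average the A/C/G/T depth of
    *all* recorded sites in the window (variant and dense depth records);
    windows without recorded sites carry NaN depths.

    Returns a DataFrame (chrom, start, male_specific_snvs,
    female_specific_snvs, n_sites, depth_m, depth_f) ordered by (chrom,
    start).
    """
    _check_sorted(sites)
    if classes is None:
        classes = classify_sites(sites, params)
    lengths = _chrom_lengths(sites, chrom_sizes)
    res, win = params.output_resolution, params.window_size
    cls = classes.to_numpy()
    dm_all = sites[_M_ACGT].to_numpy(dtype=float).sum(axis=1)
    df_all = sites[_F_ACGT].to_numpy(dtype=float).sum(axis=1)
    tracks = []
    seen = set()
    for chrom, grp in sites.groupby("chrom", sort=False):
        seen.add(chrom)
        length = lengths[chrom]
        n_win = (length - 1) // res + 1
        pos = grp["pos"].to_numpy()
        rows = np.flatnonzero(sites["chrom"].to_numpy() == chrom)
        c = cls[rows]
        dm = dm_all[rows]
        df_ = df_all[rows]
        male = np.zeros(n_win, dtype=np.int64)
        female = np.zeros(n_win, dtype=np.int64)
        nsite = np.zeros(n_win, dtype=np.int64)
        dsum_m = np.zeros(n_win)
        dsum_f = np.zeros(n_win)
        is_m = c == MALE_SPECIFIC
        is_f = c == FEMALE_SPECIFIC
        k = pos // res
        offset = pos - k * res  # position within its rightmost window
        j = 0
        while True:
            inside = offset + j * res < win
            if not inside.any():
                break
            widx = k[inside] - j
            valid = widx >= 0
            widx = widx[valid]
            sel = np.flatnonzero(inside)[valid]
            np.add.at(male, widx, is_m[sel])
            np.add.at(female, widx, is_f[sel])
            np.add.at(nsite, widx, 1)
            np.add.at(dsum_m, widx, dm[sel])
            np.add.at(dsum_f, widx, df_[sel])
            j += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            depth_m = np.where(nsite > 0, dsum_m / np.maximum(nsite, 1), np.nan)
            depth_f = np.where(nsite > 0, dsum_f / np.maximum(nsite, 1), np.nan)
        tracks.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n_win) * res,
                    "male_specific_snvs": male,
                    "female_specific_snvs": female,
                    "n_sites": nsite,
                    "depth_m": depth_m,
                    "depth_f": depth_f,
                }
            )
        )
    # chromosomes with declared length but no recorded sites -> all-zero track
    for chrom, length in lengths.items():
        if chrom in seen:
            continue
        n_win = (length - 1) // res + 1
        tracks.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n_win) * res,
                    "male_specific_snvs": 0,
                    "female_specific_snvs": 0,
                    "n_sites": 0,
                    "depth_m": np.nan,
                    "depth_f": np.nan,
                }
            )
        )
    out = pd.concat(tracks, ignore_index=True)
    out.attrs["window_size"] = win
    out.attrs["output_resolution"] = res
    return out


def manhattan_bins(
    sites: pd.DataFrame,
    params: ScanParams,
    chrom_sizes: dict[str, int] | None = None,
    classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Genome-plot export: SNV counts in non-overlapping ``manhattan_bin`` bins.

    Every classified sex-specific SNV falls in exactly one bin, so bin sums
    equal classified totals.
    """
    _check_sorted(sites)
    if classes is None:
        classes = classify_sites(sites, params)
    lengths = _chrom_lengths(sites, chrom_sizes)
    size = params.manhattan_bin
    cls = classes.to_numpy()
    rows = []
    for chrom, length in lengths.items():
        mask = sites["chrom"].to_numpy() == chrom
        pos = sites.loc[mask, "pos"].to_numpy()
        c = cls[np.flatnonzero(mask)]
        n_bin = (length - 1) // size + 1
        male = np.bincount(pos[c == MALE_SPECIFIC] // size, minlength=n_bin)
        female = np.bincount(pos[c == FEMALE_SPECIFIC] // size, minlength=n_bin)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n_bin) * size,
                    "male_specific_snvs": male,
                    "female_specific_snvs": female,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# region calling


def _runs(flags: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal runs over boolean flags allowing <= max_gap consecutive False
    inside a run.  Returns (first_true_idx, last_true_idx) pairs."""
    hits = np.flatnonzero(flags)
    if hits.size == 0:
        return []
    runs = []
    start = prev = hits[0]
    for h in hits[1:]:
        if h - prev - 1 > max_gap:
            runs.append((start, prev))
            start = h
        prev = h
    runs.append((start, prev))
    return [(int(a), int(b)) for a, b in runs]


def call_sdr(
    track: pd.DataFrame,
    min_count: int = 2,
    min_windows: int = 10,
    max_gap: int = 10,
    which: str = "male",
    window_size: int | None = None,
) -> list[SexRegionCall]:
    """Call candidate SDR intervals from a window track.

    A qualifying window holds at least ``min_count`` sex-specific SNVs
    (male- or female-specific per ``which``).  Qualifying windows are merged
    into maximal runs tolerating up to ``max_gap`` consecutive sub-threshold
    windows; runs with fewer than ``min_windows`` qualifying windows are
    discarded.  A region spans from the first qualifying window start to the
    last qualifying window start plus ``window_size``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if which not in ("male", "female"):
        raise ValueError("which must be 'male' or 'female'")
    col = "male_specific_snvs" if which == "male" else "female_specific_snvs"
    kind = "allelic_sdr" if which == "male" else "allelic_sdr_female"
    win = window_size or track.attrs.get("window_size")
    if not win:
        raise ValueError("window_size unknown; pass it explicitly")
    calls: list[SexRegionCall] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        counts = grp[col].to_numpy()
        starts = grp["start"].to_numpy()
        for a, b in _runs(counts >= min_count, max_gap):
            qual = np.flatnonzero(counts[a : b + 1] >= min_count)
            if qual.size < min_windows:
                continue
            calls.append(
                SexRegionCall(
                    chrom=chrom,
                    start=int(starts[a]),
                    end=int(starts[b]) + int(win),
                    n_windows=int(qual.size),
                    peak_density=float(counts[a : b + 1].max()),
                    kind=kind,
                    total_snvs=int(counts[a : b + 1].sum()),
                )
            )
    return rank_regions(calls)


def rank_regions(calls: list[SexRegionCall]) -> list[SexRegionCall]:
    """Order calls by descending total SNV support, ties by leftmost start."""
    return sorted(calls, key=lambda r: (-r.total_snvs, r.chrom, r.start))


def coverage_regions(
    track: pd.DataFrame,
    f_max_frac: float = 0.1,
    m_band: tuple[float, float] = (0.35, 0.65),
    min_windows: int = 5,
    max_gap: int = 2,
    window_size: int | None = None,
) -> list[SexRegionCall]:
    """Detect Y-limited (male-hemizygous) segments from depth tracks.

    Flags windows whose female depth is at most ``f_max_frac`` of the
    genome-median female depth while male depth sits within ``m_band`` of the
    genome-median male depth — the half-coverage signature of sequence
    present on a single Y haplotype.  Flagged windows are merged like
    :func:`call_sdr`; each call reports mean male/female depth inside it.
    """
    win = window_size or track.attrs.get("window_size")
    if not win:
        raise ValueError("window_size unknown; pass it explicitly")
    med_m = float(np.nanmedian(track["depth_m"].to_numpy()))
    med_f = float(np.nanmedian(track["depth_f"].to_numpy()))
    if not med_m > 0 or not med_f > 0:
        raise ValueError("genome-median depth is zero; coverage calling undefined")
    calls: list[SexRegionCall] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        dm = grp["depth_m"].to_numpy()
        df_ = grp["depth_f"].to_numpy()
        starts = grp["start"].to_numpy()
        with np.errstate(invalid="ignore"):
            flag = (
                (df_ <= f_max_frac * med_f)
                & (dm >= m_band[0] * med_m)
                & (dm <= m_band[1] * med_m)
            )
        flag &= ~np.isnan(dm) & ~np.isnan(df_)
        for a, b in _runs(flag, max_gap):
            qual = np.flatnonzero(flag[a : b + 1])
            if qual.size < min_windows:
                continue
            sel = slice(a, b + 1)
            calls.append(
                SexRegionCall(
                    chrom=chrom,
                    start=int(starts[a]),
                    end=int(starts[b]) + int(win),
                    n_windows=int(qual.size),
                    peak_density=float(np.nanmax(dm[sel])),
                    kind="male_limited_insertion",
                    mean_depth_m=float(np.nanmean(dm[sel])),
                    mean_depth_f=float(np.nanmean(df_[sel])),
                )
            )
    calls.sort(key=lambda r: (r.chrom, r.start))
    return calls


def annotate_region(region: SexRegionCall, genes) -> list[str]:
    """Names of genes overlapping ``[region.start, region.end)`` by >= 1 bp.

    ``genes`` is an iterable of (chrom, start, end, strand, name) with
    0-based half-open coordinates, as produced by
    :func:`sdscan.io.read_annotation`.  Names are returned in genomic order.
    """
    hits = []
    for chrom, start, end, _strand, name in genes:
        if end <= start:
            raise ValueError(f"gene {name}: end <= start")
        if chrom == region.chrom and start < region.end and region.start < end:
            hits.append((start, name))
    return [n for _, n in sorted(hits)]
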