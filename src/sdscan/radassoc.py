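"""RAD-seq presence/absence sex-association screen.

Each RAD marker is reduced to a presence call per individual (read depth at
least ``d``); markers are then binned into a tile (distribution) matrix
``T[m][f]`` counting markers present in exactly ``m`` males and ``f``
females.  Every occupied cell is tested for sex association with a Pearson
chi-square on the 2x2 table of presence proportions, Bonferroni-corrected
over the number of occupied cells — markers in the same cell share one
p-value, so the cell is the testing unit.  A perfectly Y-limited marker
lands in cell (n_males, 0), the bottom-right corner of the tile plot.

Unlike the genotyping-assay statistics in :mod:`sdscan.linkstats`, this
screen uses the uncorrected Pearson statistic (no continuity correction),
matching the RAD screen convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import RadMarkerMatrix

__all__ = ["TileMatrix", "presence", "tile_matrix", "significant_cells", "significant_markers"]


@dataclass
class TileMatrix:
    """Marker counts by (males present, females present) at min depth ``d``."""

    counts: np.ndarray  # (n_males+1, n_females+1) ints
    n_males: int
    n_females: int
    d: int
    #: marker ids per occupied cell, for mapping cells back to markers
    members: dict[tuple[int, int], list[str]]

    @property
    def n_markers(self) -> int:
        return int(self.counts.sum())


def presence(matrix: RadMarkerMatrix, d: int = 1) -> pd.DataFrame:
    """Boolean marker x individual table: present iff depth >= d."""
    if d < 1:
        raise ValueError("min depth d must be >= 1")
    return matrix.depth >= d


def tile_matrix(present: pd.DataFrame, sex: pd.Series, d: int = 1) -> TileMatrix:
    """Build the tile matrix from a presence table and a sex map."""
    males = [c for c in present.columns if sex[c] == "M"]
    females = [c for c in present.columns if sex[c] == "F"]
    if len(males) + len(females) != present.shape[1]:
        raise ValueError("every individual needs an M/F label")
    m_count = present[males].to_numpy(dtype=bool).sum(axis=1)
    f_count = present[females].to_numpy(dtype=bool).sum(axis=1)
    counts = np.zeros((len(males) + 1, len(females) + 1), dtype=np.int64)
    np.add.at(counts, (m_count, f_count), 1)
    members: dict[tuple[int, int], list[str]] = {}
    ids = present.index.to_numpy()
    for i, key in enumerate(zip(m_count.tolist(), f_count.tolist())):
        members.setdefault(key, []).append(ids[i])
    return TileMatrix(
        counts=counts, n_males=len(males), n_females=len(females), d=d, members=members
    )


def _pearson_chi2(m: int, n_m: int, f: int, n_f: int) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on [[m, n_m-m], [f, n_f-f]], df=1.

    Tables with a zero column margin (all present or all absent in both
    sexes) carry no association signal; the statistic is defined as 0.
    """
    tab = np.array([[m, n_m - m], [f, n_f - f]], dtype=float)
    n = tab.sum()
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    det = tab[0, 0] * tab[1, 1] - tab[0, 1] * tab[1, 0]
    chi2 = n * det * det / (rows[0] * rows[1] * cols[0] * cols[1])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def significant_cells(tiles: TileMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square sex-association test for every occupied tile cell.

    Cell (0, 0) — markers absent from everyone at depth d — is excluded from
    testing and from the Bonferroni denominator.  Returns one row per tested
    cell: m, f, n_markers, chi2, p, significant (p < alpha / n_tested_cells).
    """
    if tiles.n_males == 0 or tiles.n_females == 0:
        raise ValueError("need at least one individual of each sex")
    occupied = np.argwhere(tiles.counts > 0)
    cells = [(int(m), int(f)) for m, f in occupied if (m, f) != (0, 0)]
    n_tests = len(cells)
    rows = []
    for m, f in cells:
        chi2, p = _pearson_chi2(m, tiles.n_males, f, tiles.n_females)
        rows.append(
            {
                "m": m,
                "f": f,
                "n_markers": int(tiles.counts[m, f]),
                "chi2": chi2,
                "p": p,
                "significant": bool(n_tests and p < alpha / n_tests),
            }
        )
    out = pd.DataFrame(
        rows, columns=["m", "f", "n_markers", "chi2", "p", "significant"]
    )
    out.attrs["n_tests"] = n_tests
    out.attrs["alpha"] = alpha
    return out


def significant_markers(tiles: TileMatrix, cells: pd.DataFrame) -> list[str]:
    """Marker ids inheriting significance from their tile cell."""
    hits: list[str] = []
    for _, row in cells[cells["significant"]].iterrows():
        hits.extend(tiles.members.get((int(row["m"]), int(row["f"])), []))
    return sorted(hits)
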