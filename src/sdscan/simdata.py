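"""Synthetic XY-population data generator.

Emulates the data shapes produced by a male-heterogametic (XX/XY)
sex-determination study: pooled male/female allele-count tables along a
multi-chromosome genome carrying one small sex-determining region (SDR),
an optional Y-limited insertion segment, a RAD-style marker x individual
read-depth matrix, and genotyping-assay count tables.

Model assumptions
-----------------
* Each male carries one X and one Y haplotype; inside the SDR, X/Y-divergent
  sites carry the alternate base on every Y copy, so the male pool has an
  expected alternate-allele frequency of 0.5 while the female (XX) pool is
  fixed for the reference.  The SDR does not recombine, so divergent sites
  persist along the whole interval.
* Background polymorphism is shared between the sexes: a per-site population
  frequency is drawn once from a symmetric Beta(0.7, 0.7) and each pool's
  allele frequency is the binomial draw of its 2n sampled haplotypes.
* Read depths are Poisson per pool and site.  Inside the Y-limited insertion
  females have no template (depth 0 before error) and males sequence a single
  haplotype, halving the Poisson mean.
* Sequencing error substitutes each read independently to one of the three
  other bases, uniformly.

Counts are emitted only at polymorphic/divergent sites plus a sparse
per-kilobase depth record so that coverage tracks stay desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "SimParams",
    "RadMarkerMatrix",
    "BASES",
    "COUNT_COLUMNS",
    "simulate_pools",
    "simulate_rad",
    "simulate_genotype_table",
]

BASES = ("A", "C", "G", "T")
#: Per-pool count vector layout, sync-file order.
COUNT_FIELDS = ("A", "C", "G", "T", "N", "del")
COUNT_COLUMNS = tuple(f"m_{b}" for b in COUNT_FIELDS) + tuple(f"f_{b}" for b in COUNT_FIELDS)


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus the intervals the analyses must recover.

    All intervals are 0-based half-open.  ``sdr`` is the X/Y-differentiated
    (allelic-diversification) interval; ``y_insertion`` is a Y-limited
    hemizygous segment; ``genes`` are annotation intervals
    (chrom, start, end, strand, name) used for region annotation.
    """

    chromosomes: tuple[tuple[str, int], ...]
    sdr: tuple[str, int, int] | None = None
    y_insertion: tuple[str, int, int] | None = None
    genes: tuple[tuple[str, int, int, str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        sizes = dict(self.chromosomes)
        if len(sizes) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for label, iv in (("sdr", self.sdr), ("y_insertion", self.y_insertion)):
            if iv is None:
                continue
            chrom, start, end = iv
            if chrom not in sizes:
                raise ValueError(f"{label} on unknown chromosome {chrom}")
            if not (0 <= start < end <= sizes[chrom]):
                raise ValueError(f"{label} interval {iv} outside [0, {sizes[chrom]})")
        if self.sdr and self.y_insertion and self.sdr[0] == self.y_insertion[0]:
            a, b = sorted([self.sdr[1:], self.y_insertion[1:]])
            if b[0] < a[1]:
                raise ValueError("sdr and y_insertion overlap")
        for chrom, start, end, strand, name in self.genes:
            if chrom not in sizes or not (0 <= start < end <= sizes[chrom]):
                raise ValueError(f"gene {name} interval invalid")
            if strand not in ("+", "-", "."):
                raise ValueError(f"gene {name} strand must be +, - or .")

    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass(frozen=True)
class SimParams:
    """Scenario parameters for the synthetic XY population.

    Defaults mirror the study design the generator emulates: RAD cohorts of
    35 males and 34 females, ~40x pooled sequencing depth per pool (so a
    hemizygous Y segment reads at ~20x in males), one X/Y-divergent site per
    kilobase inside the SDR, and an Illumina-scale per-read error rate of
    1e-3.  Background pool heterozygosity is not known for this system; the
    0.005/bp default is a plausible placeholder for a wild freshwater-fish
    population and is exposed here rather than hard-coded downstream.
    """

    n_males: int = 35
    n_females: int = 34
    pool_depth: float = 40.0
    background_snp_rate: float = 0.005
    xy_divergent_rate: float = 1e-3
    seq_error_rate: float = 1e-3
    rad_marker_count: int = 10_000
    rad_sex_linked_count: int = 1
    rad_dropout_rate: float = 0.0
    geno_error_rate: float = 0.02
    geno_missing_rate: float = 0.04
    depth_record_step: int = 1000
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "background_snp_rate",
            "xy_divergent_rate",
            "seq_error_rate",
            "rad_dropout_rate",
            "geno_error_rate",
            "geno_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pool_depth < 0:
            raise ValueError("pool_depth must be >= 0")
        for name in ("n_males", "n_females", "rad_marker_count", "rad_sex_linked_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rad_sex_linked_count > self.rad_marker_count:
            raise ValueError("rad_sex_linked_count exceeds rad_marker_count")
        if self.depth_record_step < 0:
            raise ValueError("depth_record_step must be >= 0 (0 disables)")

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


@dataclass
class RadMarkerMatrix:
    """RAD marker x individual read depths with per-individual sex labels."""

    depth: pd.DataFrame  # index marker ids, columns individual ids
    sex: pd.Series  # individual id -> "M" / "F"

    def __post_init__(self) -> None:
        missing = set(self.depth.columns) - set(self.sex.index)
        if missing:
            raise ValueError(f"individuals without sex label: {sorted(missing)[:5]}")
        if (self.depth.to_numpy() < 0).any():
            raise ValueError("negative read depth")
        bad = set(self.sex.unique()) - {"M", "F"}
        if bad:
            raise ValueError(f"sex labels must be M/F, got {bad}")

    @property
    def males(self) -> list[str]:
        return [i for i in self.depth.columns if self.sex[i] == "M"]

    @property
    def females(self) -> list[str]:
        return [i for i in self.depth.columns if self.sex[i] == "F"]


# ---------------------------------------------------------------------------
# pooled counts

_OTHERS = np.array([[b for b in range(4) if b != a] for a in range(4)])  # (4, 3)


def _scatter_errors(counts: np.ndarray, base_idx: np.ndarray, n_err: np.ndarray, rng) -> None:
    """Distribute ``n_err`` error reads per site uniformly over the three
    bases other than ``base_idx``, adding them into ``counts`` (n_sites x 6)."""
    if n_err.sum() == 0:
        return
    split = rng.multinomial(n_err, [1 / 3] * 3)  # (n_sites, 3)
    np.add.at(counts, (np.arange(len(counts))[:, None], _OTHERS[base_idx]), split)


def _pool_counts(
    rng,
    depth_mean: np.ndarray,
    alt_freq: np.ndarray,
    ref_idx: np.ndarray,
    alt_idx: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    """Sample a (n_sites x 6) A/C/G/T/N/del count matrix for one pool."""
    n = len(depth_mean)
    counts = np.zeros((n, 6), dtype=np.int64)
    depth = rng.poisson(depth_mean)
    alt_reads = rng.binomial(depth, alt_freq)
    ref_reads = depth - alt_reads
    ref_err = rng.binomial(ref_reads, error_rate)
    alt_err = rng.binomial(alt_reads, error_rate)
    rows = np.arange(n)
    np.add.at(counts, (rows, ref_idx), ref_reads - ref_err)
    np.add.at(counts, (rows, alt_idx), alt_reads - alt_err)
    _scatter_errors(counts, ref_idx, ref_err, rng)
    _scatter_errors(counts, alt_idx, alt_err, rng)
    return counts


def simulate_pools(layout: GenomeLayout, params: SimParams) -> pd.DataFrame:
    """Generate the pooled male/female allele-count table for ``layout``.

    Returns a DataFrame sorted by (chrom, pos) with columns ``chrom``,
    ``pos`` (0-based), ``ref``, ``alt`` (simulated alternate base, "." at
    monomorphic depth records), ``truth`` (site provenance: ``background``,
    ``xy_divergent`` or ``depth``), and the twelve per-pool count columns
    ``m_A..m_del, f_A..f_del``.  Identical layout/params give bit-identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    sizes = layout.chrom_sizes()
    frames: list[pd.DataFrame] = []
    for chrom, length in layout.chromosomes:
        pos_parts: list[np.ndarray] = []
        kind_parts: list[np.ndarray] = []

        n_bg = rng.binomial(length, params.background_snp_rate)
        bg_pos = np.sort(rng.choice(length, size=n_bg, replace=False))
        pos_parts.append(bg_pos)
        kind_parts.append(np.zeros(n_bg, dtype=np.int8))

        if layout.sdr and layout.sdr[0] == chrom:
            s, e = layout.sdr[1], layout.sdr[2]
            n_div = rng.binomial(e - s, params.xy_divergent_rate)
            div_pos = np.sort(s + rng.choice(e - s, size=n_div, replace=False))
            pos_parts.append(div_pos)
            kind_parts.append(np.ones(n_div, dtype=np.int8))

        if params.depth_record_step:
            dense = np.arange(0, length, params.depth_record_step)
            pos_parts.append(dense)
            kind_parts.append(np.full(len(dense), 2, dtype=np.int8))

        pos = np.concatenate(pos_parts)
        kind = np.concatenate(kind_parts)
        order = np.argsort(pos, kind="stable")
        pos, kind = pos[order], kind[order]
        # collisions: keep the variant record, drop the duplicate
        keep = np.ones(len(pos), dtype=bool)
        dup = np.flatnonzero(pos[1:] == pos[:-1])
        for i in dup:  # rare; at most a handful per chromosome
            drop = i if kind[i] == 2 or kind[i + 1] < kind[i] else i + 1
            keep[drop] = False
        pos, kind = pos[keep], kind[keep]
        n = len(pos)

        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

        # per-pool alternate-allele frequencies
        freq_m = np.zeros(n)
        freq_f = np.zeros(n)
        bg = kind == 0
        p_pop = rng.beta(0.7, 0.7, size=int(bg.sum()))
        freq_m[bg] = rng.binomial(2 * params.n_males, p_pop) / max(2 * params.n_males, 1)
        freq_f[bg] = rng.binomial(2 * params.n_females, p_pop) / max(2 * params.n_females, 1)
        freq_m[kind == 1] = 0.5  # one Y (alt) + one X (ref) per male
        # depth means; Y-limited insertion: no female template, one male haplotype
        depth_m = np.full(n, params.pool_depth)
        depth_f = np.full(n, params.pool_depth)
        if layout.y_insertion and layout.y_insertion[0] == chrom:
            s, e = layout.y_insertion[1], layout.y_insertion[2]
            inside = (pos >= s) & (pos < e)
            depth_m[inside] = params.pool_depth / 2.0
            depth_f[inside] = 0.0

        cm = _pool_counts(rng, depth_m, freq_m, ref_idx, alt_idx, params.seq_error_rate)
        cf = _pool_counts(rng, depth_f, freq_f, ref_idx, alt_idx, params.seq_error_rate)

        frame = pd.DataFrame({"chrom": chrom, "pos": pos})
        frame["ref"] = np.array(BASES)[ref_idx]
        frame["alt"] = np.where(kind == 2, ".", np.array(BASES)[alt_idx])
        frame["truth"] = pd.Categorical.from_codes(
            kind, categories=["background", "xy_divergent", "depth"]
        )
        for j, col in enumerate(COUNT_COLUMNS[:6]):
            frame[col] = cm[:, j]
        for j, col in enumerate(COUNT_COLUMNS[6:]):
            frame[col] = cf[:, j]
        frames.append(frame)

    out = pd.concat(frames, ignore_index=True)
    out.attrs["chrom_sizes"] = sizes
    return out


# ---------------------------------------------------------------------------
# RAD markers


def simulate_rad(layout: GenomeLayout, params: SimParams) -> RadMarkerMatrix:
    """Generate a RAD marker x individual depth matrix with sex labels.

    The first ``rad_sex_linked_count`` markers are Y-limited: present in
    males only (at half depth, one haplotype) and absent from females.  All
    other markers are autosomal-like, present in every individual at Poisson
    ``pool_depth``.  Independent per-cell dropout at ``rad_dropout_rate``
    zeroes depths.  ``layout`` fixes nothing here beyond requiring a valid
    genome; it is accepted so scenarios share one (layout, params) pair.
    """
    del layout  # markers are anonymous; genomic placement is out of scope
    n_ind = params.n_males + params.n_females
    if n_ind == 0:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(params.seed + 1)  # offset: independent of pools
    males = [f"M{i + 1:03d}" for i in range(params.n_males)]
    females = [f"F{i + 1:03d}" for i in range(params.n_females)]
    individuals = males + females
    n_mark = params.rad_marker_count
    k = params.rad_sex_linked_count

    depth = rng.poisson(params.pool_depth, size=(n_mark, n_ind))
    if k:
        depth[:k, :] = rng.poisson(params.pool_depth / 2.0, size=(k, n_ind))
        depth[:k, params.n_males:] = 0  # Y-limited: no female template
    if params.rad_dropout_rate > 0:
        depth[rng.random((n_mark, n_ind)) < params.rad_dropout_rate] = 0

    ids = [f"SL{i + 1:04d}" for i in range(k)] + [f"MK{i + 1:05d}" for i in range(n_mark - k)]
    df = pd.DataFrame(depth, index=pd.Index(ids, name="marker"), columns=individuals)
    sex = pd.Series(["M"] * params.n_males + ["F"] * params.n_females, index=individuals, name="sex")
    return RadMarkerMatrix(depth=df, sex=sex)


# ---------------------------------------------------------------------------
# genotyping assays


def simulate_genotype_table(
    params: SimParams,
    xy_linked: bool,
    assay_id: str = "sim",
    missing_rate_m: float | None = None,
    missing_rate_f: float | None = None,
):
    """Generate one genotyping-assay count table.

    If ``xy_linked``, every male is truly heterozygous (X/Y) and every female
    homozygous (X/X); ``geno_error_rate`` flips a call to the other class and
    missing rates (overridable per sex) move calls to uncalled.  If unlinked,
    each individual is He or Ho with probability 1/2 independent of sex.
    """
    from .linkstats import GenotypeCountTable

    rng = np.random.default_rng(params.seed + 2)
    miss_m = params.geno_missing_rate if missing_rate_m is None else missing_rate_m
    miss_f = params.geno_missing_rate if missing_rate_f is None else missing_rate_f
    for v in (miss_m, miss_f):
        if not 0.0 <= v <= 1.0:
            raise ValueError("missing rate outside [0, 1]")

    def one_sex(n: int, true_he_prob: float, miss: float) -> tuple[int, int, int]:
        u = rng.binomial(n, miss)
        called = n - u
        true_he = rng.binomial(called, true_he_prob)
        # error flips He<->Ho
        he = true_he - rng.binomial(true_he, params.geno_error_rate)
        he += rng.binomial(called - true_he, params.geno_error_rate)
        return called - he, he, u  # ho, he, u

    p_he_m = 1.0 if xy_linked else 0.5
    p_he_f = 0.0 if xy_linked else 0.5
    m_ho, m_he, m_u = one_sex(params.n_males, p_he_m, miss_m)
    f_ho, f_he, f_u = one_sex(params.n_females, p_he_f, miss_f)
    return GenotypeCountTable(
        assay_id, male_ho=m_ho, male_he=m_he, male_u=m_u,
        female_ho=f_ho, female_he=f_he, female_u=f_u,
    )
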