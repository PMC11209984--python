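"""End-to-end pipeline: simulate -> pool scan -> RAD screen -> linkage stats.

A :class:`PipelineConfig` (optionally loaded from a flat YAML file) selects
stages and parameters; :func:`run_pipeline` executes the enabled stages,
writes every result as TSV/BED under an output directory and records a run
manifest (package version, seed, parameters, input checksums).  Re-running
with the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as sdio
from .linkstats import UndefinedTestError, genotype_linkage
from .poolscan import ScanParams, annotate_region, call_sdr, classify_sites, coverage_regions, manhattan_bins, rank_regions, window_scan
from .radassoc import presence, significant_cells, significant_markers, tile_matrix
from .simdata import GenomeLayout, SimParams, simulate_genotype_table, simulate_pools, simulate_rad

__all__ = ["PipelineConfig", "run_pipeline", "default_demo_config"]

log = logging.getLogger("sdscan")


@dataclass
class PipelineConfig:
    """Full parameterization of one pipeline run."""

    outdir: str = "sdscan_out"
    seed: int = 1
    # stage toggles
    simulate: bool = True
    run_poolscan: bool = True
    run_radscan: bool = True
    run_linktest: bool = True
    # synthetic scenario (used when simulate=True)
    sim: SimParams = field(default_factory=SimParams)
    layout: GenomeLayout | None = None
    # scan parameters
    scan: ScanParams = field(default_factory=ScanParams)
    sdr_min_count: int = 2
    sdr_min_windows: int = 10
    sdr_max_gap: int = 10
    rad_min_depth: int = 1
    rad_alpha: float = 0.05
    cohort_size: int | None = None
    # external inputs (used when simulate=False)
    sync_path: str | None = None
    rad_depth_path: str | None = None
    sex_map_path: str | None = None
    assay_path: str | None = None
    annotation_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, target in (("sim", SimParams), ("scan", ScanParams)):
            if section in raw:
                setattr(cfg, section, target(**raw.pop(section)))
        if "layout" in raw:
            lay = raw.pop("layout")
            cfg.layout = GenomeLayout(
                chromosomes=tuple((c["name"], int(c["length"])) for c in lay["chromosomes"]),
                sdr=tuple(lay["sdr"]) if lay.get("sdr") else None,
                y_insertion=tuple(lay["y_insertion"]) if lay.get("y_insertion") else None,
                genes=tuple(tuple(g) for g in lay.get("genes", ())),
            )
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            setattr(cfg, key, value)
        return cfg


def default_demo_config(outdir: str, seed: int = 1) -> PipelineConfig:
    """Desk-scale demo scenario: 3 x 2-Mb chromosomes, a 100-kb SDR with six
    genes on chr2, and a 53-kb Y-limited insertion on chr3."""
    genes = (
        ("chr2", 905_000, 915_000, "+", "c18h1orf198"),
        ("chr2", 918_000, 924_000, "-", "cx32.2"),
        ("chr2", 927_000, 934_000, "+", "gja13.2"),
        ("chr2", 938_000, 945_000, "-", "cx32.7"),
        ("chr2", 952_000, 968_000, "+", "hsdl1"),
        ("chr2", 972_000, 996_000, "-", "tbc1d32"),
    )
    layout = GenomeLayout(
        chromosomes=(("chr1", 2_000_000), ("chr2", 2_000_000), ("chr3", 2_000_000)),
        sdr=("chr2", 900_000, 1_000_000),
        y_insertion=("chr3", 1_200_000, 1_253_000),
        genes=genes,
    )
    return PipelineConfig(outdir=outdir, seed=seed, layout=layout, sim=SimParams(seed=seed))


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return a result bundle.

    The bundle maps stage names to their in-memory results; everything is
    also written under ``config.outdir`` alongside ``manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "sdscan",
        "version": __version__,
        "seed": config.seed,
        "params": {
            "sim": asdict(config.sim),
            "scan": asdict(config.scan),
            "sdr_min_count": config.sdr_min_count,
            "sdr_min_windows": config.sdr_min_windows,
            "sdr_max_gap": config.sdr_max_gap,
            "rad_min_depth": config.rad_min_depth,
            "rad_alpha": config.rad_alpha,
        },
        "inputs": {},
        "outputs": [],
    }
    bundle: dict = {"manifest": manifest}
    seed = config.seed

    sites = rad = assays = genes = None
    if config.simulate:
        layout = config.layout or default_demo_config(str(out), seed).layout
        sim = config.sim.with_seed(seed)
        log.info("simulate: pooled counts for %d chromosomes", len(layout.chromosomes))
        sites = simulate_pools(layout, sim)
        rad = simulate_rad(layout, sim)
        assays = [
            simulate_genotype_table(sim, xy_linked=True, assay_id="sim_linked"),
            simulate_genotype_table(sim.with_seed(seed + 101), xy_linked=False, assay_id="sim_unlinked"),
        ]
        genes = list(layout.genes)
        sdio.write_sync(sites, out / "pooled_counts.sync")
        sdio.write_rad_matrix(rad, out / "rad_depths.tsv", out / "sex_map.tsv")
        sdio.write_assay_table(assays, out / "assays.tsv")
        sdio.write_genes_gff3(genes, out / "genes.gff3")
        manifest["outputs"] += ["pooled_counts.sync", "rad_depths.tsv", "sex_map.tsv", "assays.tsv", "genes.gff3"]
        bundle["layout"] = layout
    else:
        for key in ("sync_path", "rad_depth_path", "sex_map_path", "assay_path", "annotation_path"):
            p = getattr(config, key)
            if p:
                if not os.path.exists(p):
                    raise FileNotFoundError(f"{key}: {p} does not exist")
                manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
        if config.sync_path:
            sites = sdio.read_sync(config.sync_path)
        if config.rad_depth_path and config.sex_map_path:
            rad = sdio.read_rad_matrix(config.rad_depth_path, config.sex_map_path)
        if config.assay_path:
            assays = sdio.read_assay_table(config.assay_path)
        if config.annotation_path:
            genes = sdio.read_annotation(config.annotation_path)

    if config.run_poolscan and sites is not None:
        log.info("poolscan: classifying %d sites", len(sites))
        classes = classify_sites(sites, config.scan)
        track = window_scan(sites, config.scan, classes=classes)
        bins = manhattan_bins(sites, config.scan, classes=classes)
        regions = call_sdr(
            track,
            min_count=config.sdr_min_count,
            min_windows=config.sdr_min_windows,
            max_gap=config.sdr_max_gap,
        )
        regions += call_sdr(
            track,
            min_count=config.sdr_min_count,
            min_windows=config.sdr_min_windows,
            max_gap=config.sdr_max_gap,
            which="female",
        )
        try:
            cov = coverage_regions(track)
        except ValueError:
            cov = []
        regions = rank_regions(regions) + cov
        sdio.write_track(track, out / "window_track.tsv", seed=seed)
        sdio.write_track(bins, out / "manhattan_bins.tsv", seed=seed)
        sdio.write_regions(regions, out / "regions.tsv", out / "regions.bed", seed=seed)
        manifest["outputs"] += ["window_track.tsv", "manhattan_bins.tsv", "regions.tsv", "regions.bed"]
        bundle.update(track=track, bins=bins, regions=regions)
        if genes and regions:
            annotations = {f"{r.chrom}:{r.start}-{r.end}": annotate_region(r, genes) for r in regions}
            (out / "region_genes.json").write_text(json.dumps(annotations, indent=1) + "\n")
            manifest["outputs"].append("region_genes.json")
            bundle["region_genes"] = annotations

    if config.run_radscan and rad is not None:
        log.info("radscan: %d markers x %d individuals", *rad.depth.shape)
        pres = presence(rad, d=config.rad_min_depth)
        tiles = tile_matrix(pres, rad.sex, d=config.rad_min_depth)
        cells = significant_cells(tiles, alpha=config.rad_alpha)
        sdio.write_tile_matrix(tiles, out / "tile_matrix.tsv", seed=seed)
        cells.to_csv(out / "tile_cells.tsv", sep="\t", index=False)
        markers = significant_markers(tiles, cells)
        (out / "significant_markers.txt").write_text("".join(m + "\n" for m in markers))
        manifest["outputs"] += ["tile_matrix.tsv", "tile_cells.tsv", "significant_markers.txt"]
        bundle.update(tiles=tiles, cells=cells, significant_markers=markers)

    if config.run_linktest and assays is not None:
        log.info("linktest: %d assays", len(assays))
        rows = []
        for t in assays:
            try:
                r = genotype_linkage(t, cohort_size=config.cohort_size)
                rows.append(
                    {
                        "assay_id": t.assay_id,
                        "chi2": round(r.chi2, 4),
                        "p": r.p,
                        "p_formatted": r.p_formatted,
                        "pct_genotyped": round(r.pct_genotyped, 1),
                        "pct_assigned": round(r.pct_assigned, 1),
                    }
                )
            except UndefinedTestError as exc:
                rows.append(
                    {
                        "assay_id": t.assay_id, "chi2": float("nan"), "p": float("nan"),
                        "p_formatted": f"undefined ({exc})", "pct_genotyped": float("nan"),
                        "pct_assigned": float("nan"),
                    }
                )
        import pandas as pd

        linkage = pd.DataFrame(rows)
        linkage.to_csv(out / "linkage.tsv", sep="\t", index=False)
        manifest["outputs"].append("linkage.tsv")
        bundle["linkage"] = linkage

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str) + "\n")
    return bundle
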