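"""End-to-end orchestration: VCF -> Fst scan -> effects -> enrichment ->
category statistics (-> coalescent null), with per-stage TSV outputs, a run
manifest and a plain-text summary report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import effects as fx
from .contrasts import bin_spectrum, category_flanking_contrast
from .coalescent import (
    DemographicModel,
    default_dog_wolf_model,
    empirical_exceedance,
    load_demography,
    null_distribution,
)
from .divergence import (
    annotate_window_context,
    attach_effects,
    genes_with_functional_divergence,
    select_divergent_sites,
)
from .effects import classify_variant, load_gene_models
from .enrichment import PathwayTable, enrichment_table
from .fst import compute_site_fst, flag_outlier_windows, window_mean_fst
from .genotypes import PopulationMap, ReadStats, filter_by_call_rate, read_sites

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    gff3: str
    fasta: str
    pathways: str
    out_dir: str
    window_size: int = 500_000
    z_threshold: float = 5.0
    fst_threshold: float = 0.75
    flank_span: int = 50_000
    min_call_rate: float = 0.5
    min_sites: int = 10
    window_estimator: str = "unweighted"  # or "weighted"
    enrichment_mode: str = "binomial"  # or "hypergeometric"
    spectrum_mode: str = "multi"  # or "exclusive"
    run_null: bool = False
    null_reps: int = 200
    demography: str | None = None  # YAML path; None -> illustrative default
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must lie in [0, 1]")
        if self.window_size <= 0 or self.flank_span <= 0:
            raise ValueError("window and flank sizes must be positive")
        if self.window_estimator not in ("unweighted", "weighted"):
            raise ValueError("window_estimator must be unweighted|weighted")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunResult:
    """In-memory handles to everything the run produced."""

    config: RunConfig
    windows: list
    fst_sites: list
    divergent: list
    gene_map: dict
    enrichment: pd.DataFrame
    spectrum: pd.DataFrame
    contrast: object | None
    null: np.ndarray | None
    exceedance: object | None
    out_dir: Path


def _params_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_scan(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write per-stage outputs.

    Stages: genotype ingestion and call-rate filtering; per-site Weir &
    Cockerham Fst; windowed means with genome-wide Z outliers; divergent
    site selection with effect classification and window context; pathway
    over-representation; bin spectra and flanking-Fst contrasts; optionally
    a coalescent null with empirical exceedance probabilities.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    popmap = PopulationMap.from_tsv(config.popmap)
    stats = ReadStats()
    sites = read_sites(config.vcf, popmap, stats=stats)
    sites = filter_by_call_rate(sites, config.min_call_rate)
    log.info("retained %d sites after call-rate filter", len(sites))

    fst_sites = compute_site_fst(sites, populations=popmap.labels)
    pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos, "a": s.a, "b": s.b, "c": s.c,
             "fst": s.fst}
            for s in fst_sites
        ]
    ).to_csv(out / "sites_fst.tsv", sep="\t", index=False)

    windows = window_mean_fst(
        fst_sites, window_size=config.window_size, min_sites=config.min_sites
    )
    if config.window_estimator == "weighted":
        # rank outliers on the ratio-of-sums estimator instead
        for w in windows:
            w.mean_fst, w.weighted_fst = w.weighted_fst, w.mean_fst
    windows = flag_outlier_windows(windows, threshold=config.z_threshold)
    win_df = pd.DataFrame(
        [
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "n_sites": w.n_sites, "mean_fst": w.mean_fst,
                "weighted_fst": w.weighted_fst, "z_fst": w.z_fst,
                "outlier": w.outlier,
            }
            for w in windows
        ]
    )
    win_df.to_csv(out / "windows.tsv", sep="\t", index=False)
    # BED flavour: 0-based half-open
    win_df.assign(bed_start=win_df["start"] - 1)[
        ["chrom", "bed_start", "end", "mean_fst", "z_fst", "outlier"]
    ].to_csv(out / "windows.bed", sep="\t", index=False, header=False)

    models = load_gene_models(config.gff3, config.fasta)
    divergent = select_divergent_sites(
        fst_sites, records=sites, threshold=config.fst_threshold
    )
    by_pos = {(s.chrom, s.pos): s for s in sites}
    effects = [
        e
        for d in divergent
        for e in classify_variant(by_pos[(d.chrom, d.pos)], models)
    ]
    divergent = attach_effects(divergent, effects)
    divergent = annotate_window_context(divergent, windows)
    div_df = pd.DataFrame(
        [
            {
                "chrom": d.chrom, "pos": d.pos, "fst": d.fst, "fixed": d.fixed,
                "gene": e.gene_id or "", "ref": d.record.ref if d.record else "",
                "alt": d.record.alt if d.record else "",
                "consequence": e.consequence, "aa_change": e.aa_change or "",
                "in_outlier_window": d.in_outlier_window,
                "neighbours_outlier_window": d.neighbours_outlier_window,
            }
            for d in divergent
            for e in d.effects
        ]
    )
    div_df.to_csv(out / "divergent_sites.tsv", sep="\t", index=False)

    gene_map = genes_with_functional_divergence(divergent)
    pathway_table = PathwayTable.from_tsv(config.pathways)
    foreground = sorted(set(gene_map) & pathway_table.background)
    dropped = sorted(set(gene_map) - pathway_table.background)
    if dropped:
        log.warning(
            "%d foreground genes absent from the pathway background were "
            "dropped from enrichment", len(dropped),
        )
    enrich_df = enrichment_table(
        pathway_table, foreground, mode=config.enrichment_mode
    )
    enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    spectrum = bin_spectrum(divergent, mode=config.spectrum_mode)
    spec_df = spectrum.to_frame()
    spec_df.to_csv(out / "spectrum.tsv", sep="\t", index=False)

    contrast = None
    try:
        contrast = category_flanking_contrast(
            divergent, fst_sites, span=config.flank_span
        )
        contrast.to_frame().to_csv(out / "contrast.tsv", sep="\t", index=False)
    except ValueError as err:
        log.warning("flanking contrast skipped: %s", err)

    null = exceedance = None
    if config.run_null:
        model = (
            load_demography(config.demography)
            if config.demography
            else default_dog_wolf_model(window_length=config.window_size)
        )
        samples = {lab: 2 * popmap.size(lab) for lab in popmap.labels}
        null = null_distribution(model, samples, config.null_reps, config.seed)
        pd.DataFrame({"mean_fst": null}).to_csv(
            out / "null.tsv", sep="\t", index=False
        )
        exceedance = empirical_exceedance(windows, null)
        pd.DataFrame(
            exceedance.per_window,
            columns=["chrom", "start", "end", "mean_fst", "empirical_p"],
        ).to_csv(out / "exceedance.tsv", sep="\t", index=False)

    manifest = {
        "sweepscan_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "params_hash": _params_hash(config),
        "config": asdict(config),
        "n_records": stats.n_records,
        "n_sites_retained": len(sites),
        "n_windows": len(windows),
        "n_outlier_windows": sum(w.outlier for w in windows),
        "n_divergent_sites": len(divergent),
        "n_fixed_sites": sum(d.fixed for d in divergent),
        "n_genes_functional_divergent": len(gene_map),
        "null_stage_run": bool(config.run_null),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    _write_summary(out, manifest, windows, divergent, gene_map, enrich_df,
                   exceedance)

    return RunResult(
        config=config, windows=windows, fst_sites=fst_sites,
        divergent=divergent, gene_map=gene_map, enrichment=enrich_df,
        spectrum=spec_df, contrast=contrast, null=null, exceedance=exceedance,
        out_dir=out,
    )


def _write_summary(out, manifest, windows, divergent, gene_map, enrich_df,
                   exceedance) -> None:
    lines = ["sweepscan run summary", "=" * 40]
    lines.append(f"sites retained:        {manifest['n_sites_retained']}")
    lines.append(f"windows:               {manifest['n_windows']}")
    lines.append(f"outlier windows:       {manifest['n_outlier_windows']}")
    for w in windows:
        if w.outlier:
            lines.append(
                f"  {w.chrom}:{w.start}-{w.end}  mean Fst "
                f"{w.mean_fst:.4f}  Z {w.z_fst:.2f}"
            )
    lines.append(f"divergent sites:       {manifest['n_divergent_sites']}")
    lines.append(f"fixed sites:           {manifest['n_fixed_sites']}")
    lines.append(
        f"genes w/ functional divergence: "
        f"{manifest['n_genes_functional_divergent']}"
    )
    tested = enrich_df[enrich_df["p_value"].notna()]
    if len(tested):
        top = tested.iloc[0]
        lines.append(
            f"top pathway:           {top['pathway']} "
            f"(p={top['p_value']:.3g}, adjusted {top['p_adjusted']:.3g})"
        )
    if exceedance is not None:
        lines.append(f"max null mean Fst:     {exceedance.max_null:.4f}")
        if exceedance.min_outlier_mean is not None:
            lines.append(
                f"min outlier mean Fst:  {exceedance.min_outlier_mean:.4f} "
                f"(gap {exceedance.gap:+.4f})"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
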