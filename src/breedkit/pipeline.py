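"""End-to-end pipeline: QC → GBC → diversity → PCA → ROH → LD → mate selection.

A :class:`PipelineConfig` names the input genotypes (PLINK prefix or VCF) and
per-stage parameter blocks; :func:`run_pipeline` executes the stages in a
fixed order, writing one TSV per stage into the output directory. Every
output carries a header comment with the package version, a config hash and
the seed, and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

import breedkit
from breedkit.gbc import fit_ancestry_matrix, panel_frequencies
from breedkit.genodata import GenotypeMatrix, SampleTable, read_plink, read_vcf
from breedkit.kinship_select import cluster_families, ibs_matrix, propose_matings
from breedkit.ldstruct import ld_decay, ld_decay_frame, pca
from breedkit.paneldesign import PanelSpec, build_gbc_panel
from breedkit.popstats import population_report
from breedkit.qc import QcThresholds, filter_individuals, filter_sites
from breedkit.roh import (
    RohParams,
    default_autosome_length,
    detect_roh,
    froh_table,
    roh_population_summary,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


def _from_dict(cls, d: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    genotypes: str  # PLINK prefix or .vcf path
    out_dir: str
    seed: int = 0
    input_format: str = "plink"  # plink | vcf
    qc: QcThresholds = field(default_factory=QcThresholds)
    panel: PanelSpec = field(default_factory=lambda: PanelSpec(per_chromosome_target=50))
    roh: RohParams = field(default_factory=RohParams)
    purity_threshold: float = 0.95
    n_families: int = 7
    froh_exclusion: float = 0.3
    ld_max_dist_bp: int = 1_000_000
    ld_bin_width_bp: int = 10_000
    ld_max_pairs_per_chrom: int | None = 200_000
    pca_components: int = 10
    design_panel: bool = True
    plan_matings: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("qc", QcThresholds), ("panel", PanelSpec), ("roh", RohParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = _from_dict(sub, d[key])
        cfg = _from_dict(cls, d)
        if cfg.input_format not in ("plink", "vcf"):
            raise ConfigError(f"input_format must be plink|vcf, got {cfg.input_format!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # analysis identity must not depend on output location
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# breedkit {breedkit.__version__} config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    cfg: PipelineConfig,
    genotypes: GenotypeMatrix | None = None,
    samples: SampleTable | None = None,
) -> dict[str, Path]:
    """Run every stage; returns a dict stage -> output path.

    ``genotypes``/``samples`` may be passed directly (e.g. simulated data),
    bypassing file input.
    """
    out = Path(cfg.out_dir)
    if genotypes is None:
        src = Path(cfg.genotypes)
        if cfg.input_format == "vcf":
            if not src.exists():
                raise ConfigError(f"input VCF not found: {src}")
            genotypes, samples = read_vcf(src)
        else:
            if not src.with_suffix(".bed").exists():
                raise ConfigError(f"input PLINK fileset not found: {src}.bed")
            genotypes, samples = read_plink(src)
    assert samples is not None
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # --- QC ---
    stage("qc")
    g, rep_ind = filter_individuals(genotypes, cfg.qc)
    kept = set(map(str, g.samples))
    keep_idx = np.asarray([i for i, s in enumerate(samples.sample_id) if str(s) in kept])
    samples = samples.take(keep_idx)
    labels = samples.breed_label
    g, rep_site = filter_sites(g, cfg.qc, breed_labels=labels)
    qc_df = pd.concat(
        [rep_ind.to_frame().assign(stage="individuals"),
         rep_site.to_frame().assign(stage="sites")],
        ignore_index=True,
    )
    outputs["qc"] = out / "qc_report.tsv"
    _write_tsv(qc_df, outputs["qc"], cfg)
    if g.n_markers == 0:
        raise RuntimeError("pipeline stage qc: no markers survived filtering")

    # --- panel design + GBC ---
    if cfg.design_panel:
        stage("panel_design")
        panel_res = build_gbc_panel(g, labels, cfg.panel, cfg.qc)
        outputs["panel"] = out / "panel.tsv"
        _write_tsv(panel_res.table, outputs["panel"], cfg)
        panel_markers = panel_res.marker_ids
    else:
        panel_markers = g.markers.marker_id

    stage("gbc")
    freq_panel = panel_frequencies(g, labels, panel_markers)
    gbc_df = fit_ancestry_matrix(g, freq_panel)
    gbc_df["purity_call"] = np.where(
        gbc_df["purity"] >= cfg.purity_threshold, "pure", "admixed"
    )
    outputs["gbc"] = out / "gbc.tsv"
    _write_tsv(gbc_df, outputs["gbc"], cfg)

    # --- diversity ---
    stage("diversity")
    report = population_report(g, labels)
    outputs["stats"] = out / "stats.tsv"
    _write_tsv(report.table, outputs["stats"], cfg)

    # --- PCA ---
    stage("pca")
    pres = pca(g, cfg.pca_components)
    pca_df = pres.to_frame(g.samples)
    pca_df["breed"] = labels
    outputs["pca"] = out / "pca.tsv"
    _write_tsv(pca_df, outputs["pca"], cfg)
    expl = pd.DataFrame(
        {"component": [f"PC{k + 1}" for k in range(len(pres.explained_fraction))],
         "explained_fraction": pres.explained_fraction}
    )
    outputs["pca_explained"] = out / "pca_explained.tsv"
    _write_tsv(expl, outputs["pca_explained"], cfg)

    # --- ROH ---
    stage("roh")
    segments = detect_roh(g, cfg.roh, autosomes=cfg.qc.autosomes)
    seg_df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id, "chromosome": s.chromosome,
                "start_bp": s.start_bp, "end_bp": s.end_bp, "length_bp": s.length_bp,
                "n_snps": s.n_snps, "n_het": s.n_het, "n_missing": s.n_missing,
            }
            for s in segments
        ],
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "length_bp",
                 "n_snps", "n_het", "n_missing"],
    )
    outputs["roh"] = out / "roh.tsv"
    _write_tsv(seg_df, outputs["roh"], cfg)
    l_auto = default_autosome_length(g.markers, cfg.qc.autosomes)
    fr = froh_table(segments, g.samples, l_auto)
    fr["breed"] = labels
    outputs["froh"] = out / "froh.tsv"
    _write_tsv(fr, outputs["froh"], cfg)
    outputs["roh_summary"] = out / "roh_summary.tsv"
    _write_tsv(roh_population_summary(segments, g.samples, labels), outputs["roh_summary"], cfg)

    # --- LD ---
    stage("ld")
    bins = ld_decay(
        g, cfg.ld_max_dist_bp, cfg.ld_bin_width_bp,
        max_pairs_per_chrom=cfg.ld_max_pairs_per_chrom, seed=cfg.seed,
    )
    outputs["ld"] = out / "ld.tsv"
    _write_tsv(ld_decay_frame(bins), outputs["ld"], cfg)

    # --- mate selection ---
    if cfg.plan_matings:
        stage("selection")
        ibs = ibs_matrix(g)
        fam = cluster_families(ibs, cfg.n_families)
        froh_map = dict(zip(fr["sample_id"], fr["froh"]))
        sexes = (
            dict(zip(map(str, samples.sample_id), samples.sex))
            if samples.sex is not None
            else {}
        )
        plan = propose_matings(
            fam, sexes, froh_map, ibs, froh_threshold=cfg.froh_exclusion
        )
        outputs["plan"] = out / "plan.tsv"
        _write_tsv(plan.pairs, outputs["plan"], cfg)
        outputs["families"] = out / "families.tsv"
        _write_tsv(fam.to_frame(), outputs["families"], cfg)

    return outputs


__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]
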