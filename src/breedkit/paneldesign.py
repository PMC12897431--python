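"""ΔMAF breed-informative SNP panel design.

For each target breed, every site gets a score

    ΔMAF = | MAF_target − MAF_other |

where ``MAF_target`` is the folded allele frequency within the target breed
and ``MAF_other`` the folded frequency of the pooled genotypes of all other
breeds (pooled allele counts, i.e. weighted by sample size; an unweighted
mean-of-breed-MAFs variant is available). Sites are ranked per breed in
descending ΔMAF and selected per chromosome under a uniform-coverage rule:
the chromosome span is divided into equal-width positional bins and the
best-scoring site is taken from each bin, backfilling from the remaining
ranked sites when bins are empty or the per-chromosome target exceeds the bin
count. Per-breed selections are merged and deduplicated into the final panel,
keeping a record of every breed that nominated each marker.

Selection is deterministic: ties in ΔMAF break by (chromosome, position,
marker id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from breedkit.genodata import GenotypeMatrix, MISSING
from breedkit.qc import QcThresholds, panel_design_screen

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelSpec:
    """Panel design parameters.

    ``per_chromosome_target`` is the number of SNPs selected per chromosome
    for each target breed; ``coverage_bins`` the number of equal-width
    positional bins used for uniform coverage (defaults to the target).
    """

    per_chromosome_target: int = 1200
    breeds: tuple[str, ...] | None = None  # None = every labelled breed
    dedupe: bool = True
    coverage_bins: int | None = None
    pooled_other: bool = True  # pooled allele counts vs mean of breed MAFs
    folded: bool = True  # ΔMAF on folded MAFs (the printed definition)

    def __post_init__(self) -> None:
        if self.per_chromosome_target < 1:
            raise ValueError("per_chromosome_target must be >= 1")
        if self.coverage_bins is not None and self.coverage_bins < 1:
            raise ValueError("coverage_bins must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.coverage_bins if self.coverage_bins is not None else self.per_chromosome_target


@dataclass(frozen=True)
class PanelResult:
    """Selected panel: one row per (marker, nominating breed) before dedupe."""

    table: pd.DataFrame  # marker_id, chromosome, position_bp, breed, delta_maf, bin

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].unique()

    def __len__(self) -> int:
        return len(self.marker_ids)


def delta_maf(maf_target: float, maf_other: float) -> float:
    """|MAF_target − MAF_other|; both inputs are folded frequencies in [0, 0.5]."""
    for v in (maf_target, maf_other):
        if not 0.0 <= v <= 0.5 + 1e-12:
            raise ValueError(f"MAF {v} outside [0, 0.5]")
    return abs(maf_target - maf_other)


def _pooled_p(dosage: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per site from pooled genotypes (NaN if none)."""
    nonmiss = (dosage != MISSING).sum(axis=0)
    s = np.where(dosage == MISSING, 0, dosage).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nonmiss > 0, s / (2.0 * np.maximum(nonmiss, 1)), np.nan)


def other_breeds_maf(
    g: GenotypeMatrix,
    breed_labels: np.ndarray,
    target_breed: str,
    pooled: bool = True,
) -> np.ndarray:
    """Per-site folded MAF over all non-target individuals.

    ``pooled=True`` pools allele counts across the other breeds (sample-size
    weighted); ``pooled=False`` averages per-breed MAFs unweighted.
    """
    labels = np.asarray(breed_labels)
    others = labels != target_breed
    if not others.any():
        raise ValueError(f"no individuals outside breed {target_breed!r}")
    if pooled:
        p = _pooled_p(g.dosage[others])
        return np.minimum(p, 1.0 - p)
    mafs = []
    for breed in pd.unique(labels[others]):
        p = _pooled_p(g.dosage[labels == breed])
        mafs.append(np.minimum(p, 1.0 - p))
    return np.nanmean(np.vstack(mafs), axis=0)


def rank_sites_for_breed(
    g: GenotypeMatrix,
    breed_labels: np.ndarray,
    breed: str,
    spec: PanelSpec = PanelSpec(),
) -> pd.DataFrame:
    """Sites ranked by descending ΔMAF for one target breed.

    Returns a frame with columns marker_id, chromosome, position_bp,
    delta_maf, sorted stably (ties by chromosome, position, marker_id).
    Sites where either frequency is undefined are dropped.
    """
    labels = np.asarray(breed_labels)
    if not (labels == breed).any():
        raise ValueError(f"breed {breed!r} absent from labels")
    p_t = _pooled_p(g.dosage[labels == breed])
    if spec.folded:
        maf_t = np.minimum(p_t, 1.0 - p_t)
        maf_o = other_breeds_maf(g, labels, breed, pooled=spec.pooled_other)
        score = np.abs(maf_t - maf_o)
    else:
        p_o = _pooled_p(g.dosage[labels != breed])
        score = np.abs(p_t - p_o)
    df = pd.DataFrame(
        {
            "marker_id": g.markers.marker_id,
            "chromosome": g.markers.chromosome.astype(str),
            "position_bp": g.markers.position_bp,
            "delta_maf": score,
        }
    ).dropna(subset=["delta_maf"])
    return df.sort_values(
        ["delta_maf", "chromosome", "position_bp", "marker_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def select_uniform(ranked: pd.DataFrame, spec: PanelSpec, chromosome: str) -> pd.DataFrame:
    """Uniform-coverage selection on one chromosome.

    The chromosome span (first to last candidate position) is split into
    ``spec.n_bins`` equal-width bins; the top-ΔMAF site per bin is taken,
    then remaining slots up to ``per_chromosome_target`` are backfilled with
    the globally next-best unselected sites on the chromosome.
    """
    sites = ranked[ranked["chromosome"] == str(chromosome)]
    if sites.empty:
        logger.info("select_uniform: chromosome %s has no eligible sites", chromosome)
        return sites.assign(bin=pd.Series(dtype=int))
    lo = int(sites["position_bp"].min())
    hi = int(sites["position_bp"].max())
    n_bins = spec.n_bins
    width = max((hi - lo + 1) / n_bins, 1e-9)
    bins = np.minimum(((sites["position_bp"] - lo) / width).astype(int), n_bins - 1)
    sites = sites.assign(bin=bins.to_numpy())
    # per-bin argmax: sites arrive ranked, so first occurrence per bin wins
    per_bin = sites.drop_duplicates(subset="bin", keep="first")
    chosen = per_bin.head(spec.per_chromosome_target)
    if len(chosen) < spec.per_chromosome_target:
        rest = sites.loc[~sites.index.isin(chosen.index)]
        backfill = rest.head(spec.per_chromosome_target - len(chosen))
        chosen = pd.concat([chosen, backfill])
    return chosen.sort_values("position_bp", kind="mergesort").reset_index(drop=True)


def build_gbc_panel(
    g: GenotypeMatrix,
    breed_labels: np.ndarray,
    spec: PanelSpec = PanelSpec(),
    qc_thresholds: QcThresholds = QcThresholds(),
    screen: bool = True,
) -> PanelResult:
    """Full panel build: screen → per-breed ranking → per-chromosome uniform
    selection → union across breeds → dedupe."""
    labels = np.asarray(breed_labels)
    if screen:
        g, _ = panel_design_screen(g, qc_thresholds)
    breeds = spec.breeds if spec.breeds is not None else tuple(pd.unique(labels))
    if len(breeds) < 2:
        logger.warning("panel design with <2 breeds: ΔMAF contrasts a breed with the rest")
    pieces = []
    chroms = pd.unique(g.markers.chromosome.astype(str))
    for breed in breeds:
        ranked = rank_sites_for_breed(g, labels, breed, spec)
        for chrom in chroms:
            sel = select_uniform(ranked, spec, chrom)
            if len(sel):
                pieces.append(sel.assign(breed=breed))
    if not pieces:
        return PanelResult(pd.DataFrame(
            columns=["marker_id", "chromosome", "position_bp", "breed", "delta_maf", "bin"]))
    table = pd.concat(pieces, ignore_index=True)
    if spec.dedupe:
        # one row per (marker, breed) nomination is retained; marker_ids unique
        table = table.drop_duplicates(subset=["marker_id", "breed"])
    table = table.sort_values(
        ["chromosome", "position_bp", "marker_id", "breed"], kind="mergesort"
    ).reset_index(drop=True)
    return PanelResult(table[["marker_id", "chromosome", "position_bp", "breed", "delta_maf", "bin"]])


__all__ = [
    "PanelSpec",
    "PanelResult",
    "delta_maf",
    "other_breeds_maf",
    "rank_sites_for_breed",
    "select_uniform",
    "build_gbc_panel",
]
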