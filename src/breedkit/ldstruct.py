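"""Linkage-disequilibrium decay and population structure (PCA, t-SNE wrapper).

LD between two sites is the squared Pearson correlation of their dosage
vectors over jointly non-missing samples (the composite/genotypic r², which
is phase-free and standard for decay curves). Decay curves average r² over
within-chromosome marker pairs in equal-width physical-distance bins
(defaults: pairs closer than 1,000 kb, 10 kb bins).

PCA uses the standardized-genotype convention: each site centred by its mean
dosage 2p̂ and scaled by sqrt(2p̂(1−p̂)); missing entries contribute 0 after
centring; scores and explained-variance fractions come from the SVD of the
standardized matrix. Signs are fixed so each component's largest-magnitude
loading is positive, making results deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from breedkit.genodata import MISSING, GenotypeMatrix


class MonomorphicSiteError(ValueError):
    """r² is undefined when a site is monomorphic in the complete-pairs subset."""


def pair_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD)."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise MonomorphicSiteError("fewer than two complete pairs")
    va = a.var()
    vb = b.var()
    if va == 0 or vb == 0:
        raise MonomorphicSiteError("monomorphic site in the complete-pairs subset")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


@dataclass(frozen=True)
class LdBin:
    distance_lo_bp: int
    distance_hi_bp: int  # half-open [lo, hi)
    mean_r2: float
    n_pairs: int


def ld_decay(
    g: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    bin_width_bp: int = 10_000,
    max_pairs_per_chrom: int | None = None,
    seed: int = 0,
) -> list[LdBin]:
    """Mean r² per physical-distance bin over within-chromosome pairs.

    ``max_pairs_per_chrom`` caps the number of pairs per chromosome by seeded
    subsampling (recorded in the bin counts) for tractability on dense maps.
    Pairs with an undefined r² (monomorphic member) are dropped.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    chrom_str = g.markers.chromosome.astype(str)
    for chrom in pd.unique(chrom_str):
        cols = np.flatnonzero(chrom_str == chrom)
        pos = g.markers.position_bp[cols]
        m = cols.size
        if m < 2:
            continue
        ii, jj = np.triu_indices(m, k=1)
        dist = pos[jj] - pos[ii]
        keep = dist < max_dist_bp
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
        if max_pairs_per_chrom is not None and ii.size > max_pairs_per_chrom:
            sel = rng.choice(ii.size, size=max_pairs_per_chrom, replace=False)
            ii, jj, dist = ii[sel], jj[sel], dist[sel]
        dos = g.dosage[:, cols]
        for a, b, d in zip(ii, jj, dist):
            try:
                r2 = pair_r2(dos[:, a], dos[:, b])
            except MonomorphicSiteError:
                continue
            k = int(d // bin_width_bp)
            sums[k] += r2
            counts[k] += 1
    bins = []
    for k in range(n_bins):
        lo, hi = k * bin_width_bp, (k + 1) * bin_width_bp
        mean = sums[k] / counts[k] if counts[k] else float("nan")
        bins.append(LdBin(lo, hi, float(mean), int(counts[k])))
    return bins


def ld_decay_frame(bins: list[LdBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "distance_lo_bp": [b.distance_lo_bp for b in bins],
            "distance_hi_bp": [b.distance_hi_bp for b in bins],
            "mean_r2": [b.mean_r2 for b in bins],
            "n_pairs": [b.n_pairs for b in bins],
        }
    )


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray  # n_samples x n_components
    explained_fraction: np.ndarray  # non-increasing, sums <= 1

    def to_frame(self, sample_ids: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"PC{k + 1}" for k in range(self.scores.shape[1])]
        )
        df.insert(0, "sample_id", sample_ids)
        return df


def standardize_genotypes(g: GenotypeMatrix) -> np.ndarray:
    """Centre by 2p̂ and scale by sqrt(2p̂(1−p̂)); missing → 0; drops monomorphic sites."""
    X = g.dosage.astype(float)
    miss = X == MISSING
    X[miss] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = np.isfinite(scale) & (scale > 0)
    Z = (X[:, keep] - 2.0 * p[keep]) / scale[keep]
    Z[~np.isfinite(Z)] = 0.0
    return Z


def pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the standardized genotype matrix (deterministic up to fixed signs)."""
    Z = standardize_genotypes(g)
    n = Z.shape[0]
    k = min(n_components, min(Z.shape))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total = (s ** 2).sum()
    # fix sign: largest-|loading| entry of each component made positive
    for c in range(len(s)):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :k] * s[:k]
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaResult(scores=scores, explained_fraction=frac)


def tsne_embedding(
    g: GenotypeMatrix, perplexity: float = 30.0, seed: int = 0
) -> np.ndarray:
    """Thin wrapper over scikit-learn t-SNE on standardized genotypes (plotting aid)."""
    from sklearn.manifold import TSNE

    Z = standardize_genotypes(g)
    perplexity = min(perplexity, max(1.0, (Z.shape[0] - 1) / 3.0))
    return TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca").fit_transform(Z)


__all__ = [
    "MonomorphicSiteError",
    "pair_r2",
    "LdBin",
    "ld_decay",
    "ld_decay_frame",
    "PcaResult",
    "standardize_genotypes",
    "pca",
    "tsne_embedding",
]
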