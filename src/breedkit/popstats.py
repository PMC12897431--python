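"""Per-population SNP diversity statistics: MAF, Ho, He, Pi, Pn, PIC.

All statistics are per-site and orientation-invariant (flipping which allele
is counted leaves every value unchanged). Conventions, for a biallelic site
with counted-allele frequency ``p`` (``q = 1 - p``) estimated from ``n``
non-missing allele copies:

* MAF  = min(p, q)
* Ho   = heterozygote fraction among non-missing genotypes
* He   = 2pq                      (no small-sample correction)
* Pi   = 2pq * n / (n - 1)        (average pairwise difference per site)
* PIC  = 1 - (p² + q²) - 2p²q²
* Pn   = fraction of panel markers segregating within the population

He deliberately carries no n/(n-1) correction while Pi does; this permits
Ho > He within a population, a pattern real conservation herds show.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from breedkit.genodata import MISSING, GenotypeMatrix


def site_freq(dosages: np.ndarray) -> tuple[float, int]:
    """Counted-allele frequency and non-missing allele count at one site.

    Returns ``(p, n)`` where ``p = Σ dosage / n`` and ``n`` is twice the
    number of non-missing genotypes. Raises on an all-missing site.
    """
    d = np.asarray(dosages)
    d = d[d != MISSING]
    if d.size == 0:
        raise ValueError("site_freq undefined: all genotypes missing")
    n = 2 * d.size
    return float(d.sum() / n), n


def site_maf(dosages: np.ndarray) -> float:
    p, _ = site_freq(dosages)
    return min(p, 1.0 - p)


def site_ho(dosages: np.ndarray) -> float:
    """Observed heterozygosity: heterozygote fraction among non-missing."""
    d = np.asarray(dosages)
    d = d[d != MISSING]
    if d.size == 0:
        raise ValueError("site_ho undefined: all genotypes missing")
    return float((d == 1).mean())


def site_he(p: float) -> float:
    """Expected heterozygosity 2p(1-p)."""
    return 2.0 * p * (1.0 - p)


def site_pi(dosages: np.ndarray) -> float:
    """Nucleotide diversity: mean pairwise allelic difference at the site.

    Equals ``2p(1-p) * n/(n-1)`` with ``n`` the non-missing allele count,
    which is exactly the average difference over all pairs of allele copies.
    """
    p, n = site_freq(dosages)
    if n < 2:
        raise ValueError("site_pi needs at least 2 allele copies")
    return site_he(p) * n / (n - 1)


def site_pic(p: float) -> float:
    """Polymorphic information content for a biallelic marker."""
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


# ---------------------------------------------------------------------------
# vectorised per-matrix forms
# ---------------------------------------------------------------------------

def _site_vectors(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-site p, n (allele count), maf, ho, he, pi, pic; NaN where undefined."""
    d = g.dosage
    nonmiss = (d != MISSING).sum(axis=0)
    s = np.where(d == MISSING, 0, d).sum(axis=0)
    n = 2 * nonmiss
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        ho = np.where(nonmiss > 0, (d == 1).sum(axis=0) / np.maximum(nonmiss, 1), np.nan)
    he = 2.0 * p * (1.0 - p)
    pi = np.where(n > 1, he * n / np.maximum(n - 1, 1), np.nan)
    q = 1.0 - p
    pic = 1.0 - (p * p + q * q) - 2.0 * p * p * q * q
    return pd.DataFrame(
        {
            "marker_id": g.markers.marker_id,
            "p": p,
            "n_alleles": n,
            "maf": np.minimum(p, 1.0 - p),
            "ho": ho,
            "he": he,
            "pi": pi,
            "pic": pic,
        }
    )


def site_maf_vector(g: GenotypeMatrix) -> np.ndarray:
    return _site_vectors(g)["maf"].to_numpy()


def proportion_polymorphic(
    g_pop: GenotypeMatrix,
    panel_marker_ids: np.ndarray | None = None,
    poly_threshold: float = 0.0,
    max_site_missing: float = 0.10,
) -> float:
    """Pn: fraction of panel markers segregating within the population.

    The denominator is every panel marker passing the site call-rate screen in
    this population; the numerator requires within-population MAF strictly
    above ``poly_threshold`` (default: segregating at all).
    """
    g = g_pop if panel_marker_ids is None else g_pop.subset(marker_ids=panel_marker_ids)
    miss = g.missing_mask().mean(axis=0)
    callable_ = miss <= max_site_missing
    if callable_.sum() == 0:
        return float("nan")
    maf = site_maf_vector(g)[callable_]
    maf = maf[~np.isnan(maf)]
    return float((maf > poly_threshold).mean())


@dataclass(frozen=True)
class DiversityReport:
    """Per-population summary (means ± sd across sites) plus per-site vectors."""

    table: pd.DataFrame  # rows = populations; columns maf_mean, maf_sd, ..., pn
    per_site: dict[str, pd.DataFrame]  # population -> _site_vectors frame


def population_report(
    g: GenotypeMatrix,
    breed_labels: np.ndarray,
    poly_threshold: float = 0.0,
) -> DiversityReport:
    """Diversity table with one row per population.

    Sites entirely missing within a population are excluded from that
    population's means. Means/sds are unweighted across sites (sd with
    ``ddof=1``).
    """
    labels = np.asarray(breed_labels)
    if len(labels) != g.n_samples:
        raise ValueError("breed_labels must align with samples")
    rows = []
    per_site: dict[str, pd.DataFrame] = {}
    for breed in pd.unique(labels):
        sub = g.take_samples(np.flatnonzero(labels == breed))
        sv = _site_vectors(sub)
        per_site[str(breed)] = sv
        valid = sv.dropna(subset=["p"])
        row: dict[str, float | str] = {"population": str(breed), "n_samples": int(len(sub.samples))}
        for stat in ("maf", "ho", "he", "pi", "pic"):
            v = valid[stat].dropna()
            row[f"{stat}_mean"] = float(v.mean()) if len(v) else float("nan")
            row[f"{stat}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
        row["pn"] = proportion_polymorphic(sub, poly_threshold=poly_threshold)
        rows.append(row)
    return DiversityReport(table=pd.DataFrame(rows), per_site=per_site)


def rank_sum_compare(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney U p-value (normal approximation, tie-corrected).

    The workhorse for comparing per-site diversity vectors between two
    populations (e.g. a conservation herd and its selected offspring).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_compare needs non-empty samples")
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


__all__ = [
    "site_freq",
    "site_maf",
    "site_ho",
    "site_he",
    "site_pi",
    "site_pic",
    "site_maf_vector",
    "proportion_polymorphic",
    "DiversityReport",
    "population_report",
    "rank_sum_compare",
]
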