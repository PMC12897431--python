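"""Quality control: the panel-design pre-screen and the PLINK-style filter chain.

Two layers of QC are used at different points of the workflow:

* :func:`panel_design_screen` — the light screen applied to candidate sites
  before ΔMAF panel design: site missingness < 0.1 and observed heterozygote
  fraction < 0.5 (both strict).
* :func:`filter_individuals` + :func:`filter_sites` — the analysis-time chain:
  (1) drop individuals with call rate < 90%, then, on the reduced matrix,
  (2) autosomal loci only, (3) site call rate ≥ 90%, (4) MAF ≥ 0.01,
  (5) Hardy–Weinberg exact-test p ≥ 1e-6. Site statistics are recomputed
  after individual removal, and the chain is idempotent.

Boundary semantics follow the thresholds literally: "call rate < 90%" removes
strictly below, "MAF ≥ 0.01" retains at equality, "p < 1e-6" removes strictly
below.

The HWE test is the exact two-sided test on heterozygote counts: conditioning
on the allele totals, every heterozygote count with the observed parity is
enumerated and those no more probable than the observed one contribute to the
p-value (the standard "exact" definition used by PLINK).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from breedkit.genodata import DEFAULT_AUTOSOMES, MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QcThresholds:
    """Thresholds for both QC layers; all fractions in [0, 1]."""

    max_individual_missing: float = 0.10
    max_site_missing: float = 0.10
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    max_site_het: float = 0.5  # panel-design screen only
    autosomes_only: bool = True
    autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES

    def __post_init__(self) -> None:
        for name in ("max_individual_missing", "max_site_missing", "min_maf",
                     "hwe_alpha", "max_site_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Removal counts per rule, in application order; removed+retained = input."""

    stages: list[tuple[str, int]] = field(default_factory=list)
    n_input: int = 0
    n_retained: int = 0

    def add(self, rule: str, n_removed: int) -> None:
        self.stages.append((rule, int(n_removed)))

    @property
    def n_removed(self) -> int:
        return sum(n for _, n in self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["rule", "n_removed"])


class AllMissingSiteError(ValueError):
    """HWE (or any site statistic) is undefined on an all-missing site."""


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy–Weinberg p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts that are no more probable than the observed one.
    Returns a value in (0, 1]; monomorphic sites return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise AllMissingSiteError("HWE undefined: no genotyped individuals")
    n_a = n_Aa + 2 * n_aa  # minor-ish allele count; symmetry handled below
    n_A = n_Aa + 2 * n_AA
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    obs_het = n_Aa
    # P(het = h | allele counts) ∝ n! / (nAA! nAa! naa!) * 2^h; compute in logs
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rr = (rare - hets) // 2
    n_cc = n - hets - n_rr
    logp = (hets * np.log(2.0) - gammaln(n_rr + 1) - gammaln(hets + 1) - gammaln(n_cc + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == obs_het]
    if p_obs.size == 0:  # parity mismatch cannot happen with consistent counts
        raise ValueError("observed heterozygote count inconsistent with allele totals")
    return float(min(1.0, p[p <= p_obs[0] * (1.0 + 1e-12)].sum()))


def hwe_chisq_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Asymptotic 1-df chi-square HWE p-value (optional alternative)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise AllMissingSiteError("HWE undefined: no genotyped individuals")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa])
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def _site_genotype_counts(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_hom_a, n_het, n_hom_b) per column."""
    return (
        (dosage == 0).sum(axis=0),
        (dosage == 1).sum(axis=0),
        (dosage == 2).sum(axis=0),
    )


def site_hwe_pvalues(
    g: GenotypeMatrix, breed_labels: np.ndarray | None = None
) -> np.ndarray:
    """Per-site HWE exact p-values.

    When ``breed_labels`` is given the test is run within each population and
    the minimum p per site is returned — pooling populations with different
    allele frequencies produces spurious heterozygote deficits (the Wahlund
    effect), so the per-population test is the meaningful one.
    """
    if breed_labels is None:
        groups = [np.arange(g.n_samples)]
    else:
        labels = np.asarray(breed_labels)
        groups = [np.flatnonzero(labels == b) for b in pd.unique(labels)]
    pmin = np.ones(g.n_markers)
    for idx in groups:
        n0, n1, n2 = _site_genotype_counts(g.dosage[idx])
        pv = np.ones(g.n_markers)
        for j in range(g.n_markers):
            if n0[j] + n1[j] + n2[j] > 0:
                pv[j] = hwe_exact_pvalue(int(n0[j]), int(n1[j]), int(n2[j]))
        pmin = np.minimum(pmin, pv)
    return pmin


def filter_individuals(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove individuals whose missing fraction exceeds the threshold."""
    rep = QcReport(n_input=g.n_samples)
    if g.n_markers == 0:
        rep.n_retained = g.n_samples
        return g, rep
    miss = g.missing_mask().mean(axis=1)
    keep = miss <= t.max_individual_missing
    rep.add("individual_call_rate", int((~keep).sum()))
    rep.n_retained = int(keep.sum())
    return g.take_samples(np.flatnonzero(keep)), rep


def filter_sites(
    g: GenotypeMatrix,
    t: QcThresholds = QcThresholds(),
    breed_labels: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the site-filter chain: autosomes, call rate, MAF, HWE (in order)."""
    rep = QcReport(n_input=g.n_markers)

    keep = np.ones(g.n_markers, dtype=bool)
    if t.autosomes_only:
        auto = np.isin(g.markers.chromosome.astype(str), t.autosomes)
        rep.add("autosomal_only", int((~auto).sum()))
        keep &= auto
    else:
        rep.add("autosomal_only", 0)
    g = g.take_markers(np.flatnonzero(keep))

    miss = g.missing_mask().mean(axis=0) if g.n_samples else np.zeros(g.n_markers)
    ok = (1.0 - miss) >= (1.0 - t.max_site_missing)
    rep.add("site_call_rate", int((~ok).sum()))
    g = g.take_markers(np.flatnonzero(ok))

    from breedkit.popstats import site_maf_vector

    maf = site_maf_vector(g)
    ok = maf >= t.min_maf
    # sites with zero genotyped individuals have undefined MAF -> removed here
    ok &= ~np.isnan(maf)
    rep.add("maf", int((~ok).sum()))
    g = g.take_markers(np.flatnonzero(ok))

    pv = site_hwe_pvalues(g, breed_labels)
    ok = pv >= t.hwe_alpha
    rep.add("hwe", int((~ok).sum()))
    g = g.take_markers(np.flatnonzero(ok))

    rep.n_retained = g.n_markers
    if g.n_markers == 0:
        import warnings

        warnings.warn("filter_sites removed every marker", stacklevel=2)
    return g, rep


def panel_design_screen(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Pre-design screen: keep sites with missingness < 0.1 and het fraction < 0.5."""
    rep = QcReport(n_input=g.n_markers)
    miss = g.missing_mask().mean(axis=0)
    ok_miss = miss < t.max_site_missing
    rep.add("site_missingness", int((~ok_miss).sum()))
    g = g.take_markers(np.flatnonzero(ok_miss))

    nonmiss = (~g.missing_mask()).sum(axis=0)
    het = (g.dosage == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), 0.0)
    ok_het = het_frac < t.max_site_het
    rep.add("site_heterozygosity", int((~ok_het).sum()))
    g = g.take_markers(np.flatnonzero(ok_het))
    rep.n_retained = g.n_markers
    return g, rep


__all__ = [
    "QcThresholds",
    "QcReport",
    "AllMissingSiteError",
    "hwe_exact_pvalue",
    "hwe_chisq_pvalue",
    "site_hwe_pvalues",
    "filter_individuals",
    "filter_sites",
    "panel_design_screen",
]
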