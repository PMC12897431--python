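"""IBS kinship, molecular-family clustering and purebred mate selection.

The conservation-breeding procedure implemented here mirrors how a
closed-herd manager plans pure matings from genotypes alone:

1. an identity-by-state (IBS) similarity matrix over all candidates,
   ``IBS(i, j) = mean over jointly non-missing sites of (2 − |g_i − g_j|)/2``;
2. average-linkage hierarchical clustering on the distance ``1 − IBS``, cut
   into a fixed number of "molecular families" (a genotype-derived stand-in
   for unknown pedigrees);
3. exclusion of highly inbred animals (F_ROH strictly above a threshold,
   default 0.3);
4. a greedy round-robin mating plan: every family holding an eligible sire
   contributes, each sire is paired with dams from a *different* family,
   preferring the least-used dam family and, on ties, the dam whose IBS with
   the sire is lowest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from breedkit.genodata import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class IbsMatrix:
    sample_ids: np.ndarray
    similarity: np.ndarray  # n x n in [0, 1], symmetric
    n_shared_sites: np.ndarray  # per-pair jointly non-missing counts

    def pair(self, a: str, b: str) -> float:
        ia = int(np.flatnonzero(self.sample_ids == a)[0])
        ib = int(np.flatnonzero(self.sample_ids == b)[0])
        return float(self.similarity[ia, ib])


def ibs_matrix(g: GenotypeMatrix) -> IbsMatrix:
    """All-pairs IBS similarity over jointly non-missing sites."""
    D = g.dosage.astype(np.float64)
    obs = (g.dosage != MISSING).astype(np.float64)
    Dz = np.where(g.dosage == MISSING, 0.0, D)
    # Σ|gi-gj| over shared sites, via expansion on the three dosage levels
    n = g.n_samples
    sim = np.zeros((n, n))
    shared = obs @ obs.T
    # indicator matrices per dosage level
    I0 = ((g.dosage == 0)).astype(np.float64)
    I1 = ((g.dosage == 1)).astype(np.float64)
    I2 = ((g.dosage == 2)).astype(np.float64)
    # |gi-gj| = 0*(same) + 1*(adjacent) + 2*(opposite homs)
    adj = I0 @ I1.T + I1 @ I0.T + I1 @ I2.T + I2 @ I1.T
    opp = I0 @ I2.T + I2 @ I0.T
    absdiff = adj + 2.0 * opp
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(shared > 0, (2.0 * shared - absdiff) / (2.0 * shared), np.nan)
    return IbsMatrix(
        sample_ids=np.asarray(g.samples, dtype=object),
        similarity=sim,
        n_shared_sites=shared.astype(np.int64),
    )


@dataclass(frozen=True)
class FamilyAssignment:
    sample_ids: np.ndarray
    family_id: np.ndarray  # ints 1..n_families
    n_families: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "family_id": self.family_id})

    def family_of(self) -> dict[str, int]:
        return dict(zip(map(str, self.sample_ids), map(int, self.family_id)))


def cluster_families(ibs: IbsMatrix, n_families: int) -> FamilyAssignment:
    """Average-linkage clustering of 1−IBS into ``n_families`` clusters."""
    n = len(ibs.sample_ids)
    if not 1 <= n_families <= n:
        raise ValueError(f"n_families must be in [1, {n}]")
    if n_families == n:
        fam = np.arange(1, n + 1)
    elif n_families == 1:
        fam = np.ones(n, dtype=int)
    else:
        dist = 1.0 - ibs.similarity
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0  # enforce exact symmetry for squareform
        Z = linkage(squareform(dist, checks=False), method="average")
        fam = fcluster(Z, t=n_families, criterion="maxclust")
    return FamilyAssignment(
        sample_ids=ibs.sample_ids.copy(), family_id=np.asarray(fam, dtype=int),
        n_families=int(len(np.unique(fam))),
    )


def exclude_high_froh(
    candidate_ids: np.ndarray, froh_by_sample: dict[str, float], threshold: float = 0.3
) -> np.ndarray:
    """Drop candidates with F_ROH strictly above the threshold (0.30 is retained)."""
    return np.asarray(
        [c for c in candidate_ids if froh_by_sample.get(str(c), 0.0) <= threshold],
        dtype=object,
    )


@dataclass(frozen=True)
class MatingPlan:
    pairs: pd.DataFrame  # sire_id, dam_id, sire_family, dam_family, pair_ibs

    def __len__(self) -> int:
        return len(self.pairs)


class NoCrossFamilyPairError(RuntimeError):
    """Raised when no sire/dam pair across distinct families exists."""


def propose_matings(
    families: FamilyAssignment,
    sexes: dict[str, str],  # sample_id -> "M"/"F"
    froh_by_sample: dict[str, float] | None = None,
    ibs: IbsMatrix | None = None,
    froh_threshold: float = 0.3,
    dams_per_sire: int = 2,
) -> MatingPlan:
    """Greedy round-robin cross-family mating plan.

    Every family containing an eligible sire contributes; each sire receives
    up to ``dams_per_sire`` dams from other families, preferring the
    least-used dam family (ties broken by the lowest sire–dam IBS, then by
    sample order).
    """
    fam_of = families.family_of()
    ids = [str(s) for s in families.sample_ids]
    if froh_by_sample is not None:
        eligible = set(map(str, exclude_high_froh(np.asarray(ids, dtype=object),
                                                  froh_by_sample, froh_threshold)))
    else:
        eligible = set(ids)
    sires = [s for s in ids if s in eligible and sexes.get(s) == "M"]
    dams = [s for s in ids if s in eligible and sexes.get(s) == "F"]
    if not sires or not dams:
        raise NoCrossFamilyPairError("no eligible sires or no eligible dams")
    if all(fam_of[s] == fam_of[d] for s in sires for d in dams):
        raise NoCrossFamilyPairError(
            "every eligible sire/dam pair falls inside one family; "
            f"families represented: sires={sorted({fam_of[s] for s in sires})}, "
            f"dams={sorted({fam_of[d] for d in dams})}"
        )

    def pair_ibs(s: str, d: str) -> float:
        return ibs.pair(s, d) if ibs is not None else 0.0

    dam_family_use: dict[int, int] = {}
    dam_use: dict[str, int] = {s: 0 for s in dams}
    rows = []
    # round-robin over sire families, one sire at a time
    sire_fams = sorted({fam_of[s] for s in sires})
    sires_by_fam = {f: [s for s in sires if fam_of[s] == f] for f in sire_fams}
    for f in sire_fams:
        for sire in sires_by_fam[f]:
            for _ in range(dams_per_sire):
                cands = [d for d in dams if fam_of[d] != fam_of[sire]]
                if not cands:
                    break
                cands.sort(
                    key=lambda d: (
                        dam_family_use.get(fam_of[d], 0),
                        dam_use[d],
                        pair_ibs(sire, d),
                        ids.index(d),
                    )
                )
                dam = cands[0]
                dam_family_use[fam_of[dam]] = dam_family_use.get(fam_of[dam], 0) + 1
                dam_use[dam] += 1
                rows.append(
                    {
                        "sire_id": sire,
                        "dam_id": dam,
                        "sire_family": fam_of[sire],
                        "dam_family": fam_of[dam],
                        "pair_ibs": pair_ibs(sire, dam),
                    }
                )
    return MatingPlan(pairs=pd.DataFrame(rows))


__all__ = [
    "IbsMatrix",
    "ibs_matrix",
    "FamilyAssignment",
    "cluster_families",
    "exclude_high_froh",
    "MatingPlan",
    "NoCrossFamilyPairError",
    "propose_matings",
]
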