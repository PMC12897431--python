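"""Runs of homozygosity (ROH) and the genomic inbreeding coefficient F_ROH.

Detection follows the PLINK sliding-window scheme: a fixed-size window of
``window_snp`` consecutive SNPs slides along each chromosome; a window is
"homozygous" when it contains at most ``max_het_per_window`` heterozygous and
``max_missing_per_window`` missing calls. Each SNP's hit rate is the fraction
of homozygous windows among the windows covering it; SNPs whose rate exceeds
``hit_proportion`` are ROH candidates. Maximal candidate stretches are then
partitioned greedily left-to-right into segments respecting the segment-level
caps (the same het/missing allowances), and a segment is reported when it
holds at least ``min_snp_in_roh`` SNPs and spans at least ``min_length_bp``
(1-based inclusive, length = end − start + 1).

Defaults mirror a conservative conservation-genetics parameterisation:
minimum length 500 kb, 30-SNP windows, at most 1 heterozygote and 5 missing
calls allowed, hit proportion 0.05.

F_ROH = Σ L_ROH / L_AUTO: total autosomal ROH length over the autosomal
genome length. L_AUTO defaults to the summed autosome spans of the analysed
marker map (first to last marker per chromosome); a fixed assembly constant
can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from breedkit.genodata import DEFAULT_AUTOSOMES, MISSING, GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class RohParams:
    min_length_bp: int = 500_000
    window_snp: int = 30
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    hit_proportion: float = 0.05
    min_snp_in_roh: int | None = None  # default: window_snp
    max_het_per_segment: int | None = None  # default: max_het_per_window
    max_missing_per_segment: int | None = None  # default: max_missing_per_window

    def __post_init__(self) -> None:
        if self.min_length_bp < 1 or self.window_snp < 1:
            raise ValueError("min_length_bp and window_snp must be >= 1")
        if min(self.max_het_per_window, self.max_missing_per_window) < 0:
            raise ValueError("window allowances must be >= 0")

    @property
    def snp_floor(self) -> int:
        return self.min_snp_in_roh if self.min_snp_in_roh is not None else self.window_snp

    @property
    def seg_het_cap(self) -> int:
        return self.max_het_per_segment if self.max_het_per_segment is not None \
            else self.max_het_per_window

    @property
    def seg_missing_cap(self) -> int:
        return self.max_missing_per_segment if self.max_missing_per_segment is not None \
            else self.max_missing_per_window


@dataclass(frozen=True)
class RohSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class FrohRecord:
    sample_id: str
    sum_roh_bp: int
    autosome_denominator_bp: int

    @property
    def froh(self) -> float:
        return self.sum_roh_bp / self.autosome_denominator_bp


def _candidate_mask(is_het: np.ndarray, is_miss: np.ndarray, p: RohParams) -> np.ndarray:
    """Per-SNP candidate flags on one chromosome for one individual."""
    m = is_het.size
    W = p.window_snp
    if m < W:
        return np.zeros(m, dtype=bool)
    het_c = np.concatenate([[0], np.cumsum(is_het)])
    mis_c = np.concatenate([[0], np.cumsum(is_miss)])
    n_win = m - W + 1
    starts = np.arange(n_win)
    hom_win = (
        (het_c[starts + W] - het_c[starts] <= p.max_het_per_window)
        & (mis_c[starts + W] - mis_c[starts] <= p.max_missing_per_window)
    ).astype(np.int64)
    hom_cum = np.concatenate([[0], np.cumsum(hom_win)])
    idx = np.arange(m)
    w_lo = np.maximum(idx - W + 1, 0)
    w_hi = np.minimum(idx, n_win - 1)
    covering = (w_hi - w_lo + 1).astype(float)
    hits = hom_cum[w_hi + 1] - hom_cum[w_lo]
    return hits / covering > p.hit_proportion


def _split_segments(
    idx: np.ndarray, is_het: np.ndarray, is_miss: np.ndarray, p: RohParams
) -> list[tuple[int, int, int, int]]:
    """Greedy left-to-right partition of one candidate run into cap-respecting
    segments. Returns (start_i, end_i, n_het, n_miss) index tuples."""
    out = []
    start = 0
    het = mis = 0
    n = idx.size
    for i in range(n):
        h, ms = int(is_het[idx[i]]), int(is_miss[idx[i]])
        if het + h > p.seg_het_cap or mis + ms > p.seg_missing_cap:
            if i > start:
                out.append((start, i - 1, het, mis))
            start, het, mis = i, 0, 0
        het += h
        mis += ms
    if n > start:
        out.append((start, n - 1, het, mis))
    return out


def detect_roh(
    g: GenotypeMatrix,
    params: RohParams = RohParams(),
    autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES,
) -> list[RohSegment]:
    """Detect ROH segments for every individual on the autosomes."""
    if not g.markers.is_sorted():
        raise ValueError(
            "marker map must be sorted by (chromosome, position); sort before ROH detection"
        )
    segments: list[RohSegment] = []
    chrom_str = g.markers.chromosome.astype(str)
    for chrom in pd.unique(chrom_str):
        if str(chrom) not in autosomes:
            continue
        cols = np.flatnonzero(chrom_str == chrom)
        pos = g.markers.position_bp[cols]
        dos = g.dosage[:, cols]
        for i, sid in enumerate(g.samples):
            row = dos[i]
            is_het = row == 1
            is_miss = row == MISSING
            cand = _candidate_mask(is_het, is_miss, params)
            if not cand.any():
                continue
            # maximal candidate runs
            edges = np.diff(np.concatenate([[0], cand.view(np.int8), [0]]))
            run_starts = np.flatnonzero(edges == 1)
            run_ends = np.flatnonzero(edges == -1) - 1
            for rs, re in zip(run_starts, run_ends):
                run_idx = np.arange(rs, re + 1)
                for s, e, nh, nm in _split_segments(run_idx, is_het, is_miss, params):
                    a, b = run_idx[s], run_idx[e]
                    n_snps = b - a + 1
                    length = int(pos[b] - pos[a] + 1)
                    if n_snps >= params.snp_floor and length >= params.min_length_bp:
                        segments.append(
                            RohSegment(
                                sample_id=str(sid),
                                chromosome=str(chrom),
                                start_bp=int(pos[a]),
                                end_bp=int(pos[b]),
                                n_snps=int(n_snps),
                                n_het=nh,
                                n_missing=nm,
                            )
                        )
    return segments


def froh(
    segments: list[RohSegment],
    sample_id: str,
    autosome_denominator_bp: int,
) -> FrohRecord:
    """F_ROH for one individual from its detected segments."""
    if autosome_denominator_bp <= 0:
        raise ValueError("autosome denominator must be positive")
    total = sum(s.length_bp for s in segments if s.sample_id == sample_id)
    return FrohRecord(sample_id, int(total), int(autosome_denominator_bp))


def default_autosome_length(
    markers: MarkerMap, autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES
) -> int:
    """L_AUTO from the analysed map: summed first-to-last spans per autosome."""
    return int(sum(markers.autosome_spans_bp(autosomes).values()))


def froh_table(
    segments: list[RohSegment],
    sample_ids: np.ndarray,
    autosome_denominator_bp: int,
) -> pd.DataFrame:
    rows = [froh(segments, str(sid), autosome_denominator_bp) for sid in sample_ids]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "sum_roh_bp": [r.sum_roh_bp for r in rows],
            "froh": [r.froh for r in rows],
        }
    )


def roh_length_classes(
    segments: list[RohSegment],
    bounds_bp: tuple[int, ...] = (5_000_000, 10_000_000),
    breed_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Segment counts per length class (left-closed bins), optionally per population.

    Default classes: [min, 5 Mb), [5, 10 Mb), [10 Mb, ∞).
    """
    edges = (0, *bounds_bp, np.inf)
    names = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        hi_s = "inf" if np.isinf(hi) else f"{hi / 1e6:g}"
        names.append(f"[{lo / 1e6:g},{hi_s}) Mb")
    rows = []
    for s in segments:
        cls = int(np.searchsorted(bounds_bp, s.length_bp, side="right"))
        rows.append(
            {
                "population": breed_of.get(s.sample_id, "all") if breed_of else "all",
                "length_class": names[cls],
                "sample_id": s.sample_id,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["population", "length_class", "n_segments"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["population", "length_class"], sort=True)
        .size()
        .rename("n_segments")
        .reset_index()
    )


def roh_population_summary(
    segments: list[RohSegment],
    sample_ids: np.ndarray,
    breed_labels: np.ndarray,
) -> pd.DataFrame:
    """Per-population ROH bookkeeping: totals, mean single-ROH length, per-individual
    mean count and mean total length."""
    breed_of = dict(zip(map(str, sample_ids), map(str, breed_labels)))
    per_sample: dict[str, list[int]] = {str(s): [] for s in sample_ids}
    for s in segments:
        per_sample[s.sample_id].append(s.length_bp)
    rows = []
    for breed in pd.unique(np.asarray(breed_labels)):
        members = [str(s) for s in sample_ids if breed_of[str(s)] == str(breed)]
        lengths = [l for m in members for l in per_sample[m]]
        n_roh = len(lengths)
        rows.append(
            {
                "population": str(breed),
                "n_samples": len(members),
                "n_roh_total": n_roh,
                "mean_roh_length_mb": (np.mean(lengths) / 1e6) if n_roh else 0.0,
                "mean_roh_per_individual": n_roh / len(members) if members else 0.0,
                "mean_total_length_mb": (
                    np.mean([sum(per_sample[m]) for m in members]) / 1e6 if members else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "RohParams",
    "RohSegment",
    "FrohRecord",
    "detect_roh",
    "froh",
    "froh_table",
    "default_autosome_length",
    "roh_length_classes",
    "roh_population_summary",
]
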