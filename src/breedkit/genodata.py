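"""Genotype data model and PLINK / VCF readers and writers.

The central container is :class:`GenotypeMatrix`: an ``n_samples x n_markers``
diploid allele-dosage matrix (``int8``, values 0/1/2 counting copies of
``allele_b``, with :data:`MISSING` = -1 as the missing sentinel) together with
a :class:`MarkerMap` of marker coordinates. Sample metadata (breed labels,
sex, cohort) lives in a :class:`SampleTable` aligned 1:1 with the matrix rows.

Coordinates are 1-based inclusive throughout (PLINK/VCF convention); interval
lengths are ``end - start + 1`` bp. Chromosome labels are strings; the default
autosome set is "1".."18" (*Sus scrofa*).

Allele orientation: dosages count VCF ALT copies / bim A1 copies; the matrix
records which via :attr:`GenotypeMatrix.counted_allele`. Every downstream
statistic in this package is orientation-invariant, so the flag is
informational.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype. Never conflated with dosage 0.
MISSING: int = -1

#: Sus scrofa autosomes.
DEFAULT_AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 19))

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


@dataclass(frozen=True)
class MarkerMap:
    """Per-marker coordinates and alleles.

    Parameters
    ----------
    marker_id, chromosome, position_bp, allele_a, allele_b
        Parallel arrays, one entry per marker. ``allele_b`` is the counted
        allele of the companion dosage matrix.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.marker_id)
        for name in ("chromosome", "position_bp", "allele_a", "allele_b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} length mismatch")
        ids, counts = np.unique(self.marker_id, return_counts=True)
        if (counts > 1).any():
            raise ValueError(f"duplicate marker ids: {ids[counts > 1][:5].tolist()}")
        if (np.asarray(self.position_bp) < 1).any():
            raise ValueError("positions must be >= 1 (1-based coordinates)")
        if (self.allele_a == self.allele_b).any():
            bad = self.marker_id[self.allele_a == self.allele_b]
            raise ValueError(f"allele_a == allele_b at markers {bad[:5].tolist()}")

    @classmethod
    def from_arrays(cls, marker_id, chromosome, position_bp, allele_a, allele_b) -> "MarkerMap":
        return cls(
            marker_id=np.asarray(marker_id, dtype=object),
            chromosome=np.asarray(chromosome, dtype=object),
            position_bp=np.asarray(position_bp, dtype=np.int64),
            allele_a=np.asarray(allele_a, dtype=object),
            allele_b=np.asarray(allele_b, dtype=object),
        )

    def __len__(self) -> int:
        return len(self.marker_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )

    def take(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.marker_id[idx],
            self.chromosome[idx],
            self.position_bp[idx],
            self.allele_a[idx],
            self.allele_b[idx],
        )

    def is_sorted(self) -> bool:
        """True if positions are strictly increasing within each chromosome block."""
        for chrom in pd.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                return False
        return True

    def autosome_spans_bp(self, autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES) -> dict[str, int]:
        """Span (last - first position + 1) of every observed autosome, in bp."""
        spans: dict[str, int] = {}
        for chrom in pd.unique(self.chromosome):
            if str(chrom) not in autosomes:
                continue
            pos = self.position_bp[self.chromosome == chrom]
            spans[str(chrom)] = int(pos.max() - pos.min() + 1)
        return spans


@dataclass(frozen=True)
class SampleTable:
    """Sample metadata aligned 1:1 with GenotypeMatrix rows."""

    sample_id: np.ndarray
    breed_label: np.ndarray  # "unknown" where unlabelled
    sex: np.ndarray | None = None  # "M"/"F"/None entries
    cohort: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids, counts = np.unique(self.sample_id, return_counts=True)
        if (counts > 1).any():
            raise ValueError(f"duplicate sample ids: {ids[counts > 1][:5].tolist()}")
        if len(self.breed_label) != len(self.sample_id):
            raise ValueError("breed_label length mismatch")

    @classmethod
    def from_lists(cls, sample_id, breed_label=None, sex=None, cohort=None) -> "SampleTable":
        sid = np.asarray(sample_id, dtype=object)
        if breed_label is None:
            breed_label = np.full(len(sid), "unknown", dtype=object)
        return cls(
            sample_id=sid,
            breed_label=np.asarray(breed_label, dtype=object),
            sex=None if sex is None else np.asarray(sex, dtype=object),
            cohort=None if cohort is None else np.asarray(cohort, dtype=object),
        )

    def __len__(self) -> int:
        return len(self.sample_id)

    def take(self, idx: np.ndarray) -> "SampleTable":
        return SampleTable(
            self.sample_id[idx],
            self.breed_label[idx],
            None if self.sex is None else self.sex[idx],
            None if self.cohort is None else self.cohort[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"sample_id": self.sample_id, "breed_label": self.breed_label}
        if self.sex is not None:
            d["sex"] = self.sex
        if self.cohort is not None:
            d["cohort"] = self.cohort
        return pd.DataFrame(d)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid dosage matrix with marker map.

    ``dosage[i, j]`` counts copies of ``markers.allele_b[j]`` carried by sample
    ``i`` at marker ``j``: 0, 1, 2 or :data:`MISSING`.
    """

    samples: np.ndarray  # sample ids, ordered
    markers: MarkerMap
    dosage: np.ndarray  # int8, n_samples x n_markers
    counted_allele: str = "b"  # orientation note: "b" = ALT/A1 copies

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.dosage.dtype != np.int8:
            object.__setattr__(self, "dosage", self.dosage.astype(np.int8))
        vals = np.unique(self.dosage)
        bad = vals[~np.isin(vals, [MISSING, 0, 1, 2])]
        if bad.size:
            raise ValueError(f"dosage values outside {{0,1,2,missing}}: {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_index(self, sample_ids) -> np.ndarray:
        return _resolve(self.samples, sample_ids, "sample")

    def marker_index(self, marker_ids) -> np.ndarray:
        return _resolve(self.markers.marker_id, marker_ids, "marker")

    def subset(self, sample_ids=None, marker_ids=None) -> "GenotypeMatrix":
        """Order-preserving subset by id; unknown ids raise KeyError listing offenders."""
        if marker_ids is not None and len(marker_ids) == 0:
            raise ValueError("subset to an empty marker list")
        if sample_ids is not None and len(sample_ids) == 0:
            raise ValueError("subset to an empty sample list")
        si = np.arange(self.n_samples) if sample_ids is None else self.sample_index(sample_ids)
        mi = np.arange(self.n_markers) if marker_ids is None else self.marker_index(marker_ids)
        return replace(
            self,
            samples=self.samples[si],
            markers=self.markers.take(mi),
            dosage=self.dosage[np.ix_(si, mi)],
        )

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(self, markers=self.markers.take(idx), dosage=self.dosage[:, idx])

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(self, samples=self.samples[idx], dosage=self.dosage[idx, :])


def _resolve(universe: np.ndarray, requested, kind: str) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(universe)}
    missing = [r for r in requested if r not in lookup]
    if missing:
        raise KeyError(f"unknown {kind} ids: {missing[:10]}")
    return np.asarray([lookup[r] for r in requested], dtype=np.intp)


# ---------------------------------------------------------------------------
# PLINK 1.9 bed/bim/fam
# ---------------------------------------------------------------------------
# SNP-major .bed layout: 3 magic bytes, then per marker ceil(n/4) bytes; each
# sample occupies 2 bits (low bits = earlier samples): 00 hom A1A1, 01 missing,
# 10 het, 11 hom A2A2. With dosage counting A1 copies: 00 -> 2, 10 -> 1,
# 11 -> 0, 01 -> MISSING.

_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, SampleTable]:
    """Read a PLINK 1.9 ``prefix.bed/.bim/.fam`` fileset.

    Dosage counts copies of the bim A1 allele (``allele_b``). The fam FID
    column is kept as the breed label when it is informative (non-zero),
    mirroring the common convention of encoding population in FID.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes {raw[:3].hex()} "
            f"(expected {_BED_MAGIC.hex()}; only SNP-major bed v1 is supported)"
        )
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: payload is {len(raw)} bytes, expected "
            f"{expected} for {n} samples x {m} markers"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_marker)
    # unpack 2-bit codes, low bits first
    codes = np.empty((m, bytes_per_marker * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (payload >> (2 * k)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()  # n x m

    markers = MarkerMap.from_arrays(
        bim["marker_id"], bim["chrom"].astype(str), bim["pos"], bim["a2"], bim["a1"]
    )
    breed = np.where(fam["fid"].values == "0", "unknown", fam["fid"].values)
    sex = np.where(fam["sex"].astype(str).values == "1", "M",
                   np.where(fam["sex"].astype(str).values == "2", "F", "unknown"))
    samples = SampleTable.from_lists(fam["iid"].tolist(), breed.tolist(), sex.tolist())
    g = GenotypeMatrix(samples=np.asarray(fam["iid"], dtype=object), markers=markers, dosage=dosage)
    return g, samples


def write_plink(g: GenotypeMatrix, s: SampleTable, prefix: str | Path) -> None:
    """Write PLINK 1.9 bed/bim/fam; round-trips losslessly through read_plink."""
    if g.n_markers == 0:
        raise ValueError("refusing to write a PLINK fileset with zero markers")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mm = g.markers
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(g.n_markers):
            fh.write(
                f"{mm.chromosome[j]}\t{mm.marker_id[j]}\t0\t{mm.position_bp[j]}"
                f"\t{mm.allele_b[j]}\t{mm.allele_a[j]}\n"
            )
    sex_code = {"M": "1", "F": "2"}
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(g.n_samples):
            fid = s.breed_label[i] if s.breed_label[i] != "unknown" else "0"
            sx = sex_code.get(s.sex[i], "0") if s.sex is not None else "0"
            fh.write(f"{fid}\t{s.sample_id[i]}\t0\t0\t{sx}\t-9\n")
    n, m = g.n_samples, g.n_markers
    bytes_per_marker = (n + 3) // 4
    codes = np.zeros((m, bytes_per_marker * 4), dtype=np.uint8)
    code_lut = np.array([_DOSAGE_TO_CODE[0], _DOSAGE_TO_CODE[1], _DOSAGE_TO_CODE[2]], dtype=np.uint8)
    dos = g.dosage.T  # m x n
    c = np.where(dos == MISSING, np.uint8(1), code_lut[np.clip(dos, 0, 2)])
    codes[:, :n] = c
    payload = np.zeros((m, bytes_per_marker), dtype=np.uint8)
    for k in range(4):
        payload |= codes[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(payload.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, SampleTable]:
    """Read biallelic SNPs from a VCF (v4.x) into a GenotypeMatrix.

    GT fields map to ALT-dosage; half-calls and non-diploid genotypes become
    missing. Non-biallelic or non-SNP records are skipped (count logged).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"{path}: cannot parse VCF header ({exc})") from exc
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    rows: list[np.ndarray] = []
    mid, chrom, pos, ref, alt = [], [], [], [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        mid.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chrom.append(str(v.CHROM))
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", skipped)
    if not rows:
        raise FormatError(f"{path}: no biallelic SNP records")
    dosage = np.vstack(rows).T.astype(np.int8).copy()  # n x m
    markers = MarkerMap.from_arrays(mid, chrom, pos, ref, alt)
    g = GenotypeMatrix(samples=np.asarray(sample_ids, dtype=object), markers=markers, dosage=dosage)
    g = replace(g, counted_allele="b")
    st = SampleTable.from_lists(sample_ids)
    object.__setattr__(g, "_n_skipped_records", skipped)
    return g, st


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT only) readable by read_vcf."""
    mm = g.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(mm.chromosome):
            length = int(mm.position_bp[mm.chromosome == chrom].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in g.samples) + "\n")
        for j in range(g.n_markers):
            gts = "\t".join(_GT_STR[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{mm.chromosome[j]}\t{mm.position_bp[j]}\t{mm.marker_id[j]}"
                f"\t{mm.allele_a[j]}\t{mm.allele_b[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


__all__ = [
    "MISSING",
    "DEFAULT_AUTOSOMES",
    "FormatError",
    "MarkerMap",
    "SampleTable",
    "GenotypeMatrix",
    "read_plink",
    "write_plink",
    "read_vcf",
    "write_vcf",
]
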