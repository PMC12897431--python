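"""Reference bookkeeping for the Shanghai conservation-herd evaluation.

Cohort composition of the genotyped conservation populations and the breed
inventory of the multi-breed GBC reference panel. These are inputs to
reporting and sanity checks (totals, panel dimensioning), not computed
quantities.
"""

from __future__ import annotations

#: Genotyped conservation cohorts (breed code -> sample count).
CONSERVATION_COHORTS: dict[str, int] = {
    "FJ": 364,       # Fengjing
    "MMS": 333,      # Middle-size Meishan
    "PD": 397,       # Pudong White
    "SHW": 199,      # Shanghai White
    "SW": 104,       # Shawutou
    "MMS_NEW": 54,   # Meishan purebred-selection offspring
}

#: Breed codes of the 25-breed GBC reference panel, grouped by region.
REFERENCE_PANEL_BREEDS: dict[str, tuple[str, ...]] = {
    "foreign": ("D", "L", "Y", "P", "B"),
    "shanghai": ("MMS", "FJ", "SW", "PD", "SHW"),
    "jiangsu": ("DC", "EH", "HB", "HD", "SZ", "JQ", "SMS", "MI"),
    "zhejiang": ("BH", "CA", "CL", "JX", "LX", "JHL", "SH"),
}

#: Total individuals in the reference panel.
REFERENCE_PANEL_N_INDIVIDUALS: int = 1248

#: Size of the breed-composition SNP module.
GBC_PANEL_N_SNPS: int = 18_945


def total_samples() -> int:
    """Total genotyped conservation samples across all cohorts."""
    return sum(CONSERVATION_COHORTS.values())


def reference_breed_codes() -> tuple[str, ...]:
    """Flat tuple of the reference panel's breed codes."""
    return tuple(c for codes in REFERENCE_PANEL_BREEDS.values() for c in codes)


def n_reference_breeds() -> int:
    return len(reference_breed_codes())


__all__ = [
    "CONSERVATION_COHORTS",
    "REFERENCE_PANEL_BREEDS",
    "REFERENCE_PANEL_N_INDIVIDUALS",
    "GBC_PANEL_N_SNPS",
    "total_samples",
    "reference_breed_codes",
    "n_reference_breeds",
]
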