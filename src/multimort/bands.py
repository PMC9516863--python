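"""The five standard age bands used for age-standardised expected deaths.

Weekly mortality surveillance files (STMF dialect) report deaths and death
rates in five fixed strata: 0-14, 15-64, 65-74, 75-84 and 85+.  Annual
archive files report 1-year ages which are collapsed onto the same scheme.
The bands are ordered, disjoint and exhaustive over ages.
"""

from __future__ import annotations

AGE_BANDS: tuple[str, ...] = ("0-14", "15-64", "65-74", "75-84", "85+")
N_BANDS: int = len(AGE_BANDS)

# Inclusive (low, high) age bounds; the last band is open-ended.
BAND_BOUNDS: dict[str, tuple[int, int | None]] = {
    "0-14": (0, 14),
    "15-64": (15, 64),
    "65-74": (65, 74),
    "75-84": (75, 84),
    "85+": (85, None),
}

# Column suffixes used by the STMF dialect (D0_14, R0_14, ...).
STMF_SUFFIXES: tuple[str, ...] = ("0_14", "15_64", "65_74", "75_84", "85p")


def band_of_age(age: int) -> str:
    """Return the band label containing a 1-year age (85+ is closed above)."""
    if age < 0:
        raise ValueError(f"negative age {age}")
    for label, (lo, hi) in BAND_BOUNDS.items():
        if hi is None or lo <= age <= hi:
            if age >= lo:
                return label
    raise ValueError(f"age {age} not covered by any band")  # pragma: no cover


def band_index(label: str) -> int:
    return AGE_BANDS.index(label)
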