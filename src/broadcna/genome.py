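"""Shared genome vocabulary: autosome labels, arm-event categories, GRCh38 constants.

An arm-event *category* is a ``(chromosome, arm, direction)`` triple such as
``("1", "q", "gain")``, conventionally abbreviated ``"1qG"``.
"""

from __future__ import annotations

from typing import NamedTuple

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
ARMS: tuple[str, str] = ("p", "q")
DIRECTIONS: tuple[str, str] = ("gain", "loss")

_DIR_ABBREV = {"gain": "G", "loss": "L"}
_ABBREV_DIR = {v: k for k, v in _DIR_ABBREV.items()}


class Category(NamedTuple):
    """One arm-level event category: chromosome arm plus alteration direction."""

    chromosome: str
    arm: str
    direction: str

    def __str__(self) -> str:
        return format_category(self)


#: Every autosomal (arm, direction) category, in karyotype order.  Short arms
#: of the acrocentric chromosomes are included; they are simply rarely hit.
ALL_CATEGORIES: tuple[Category, ...] = tuple(
    Category(c, a, d) for c in AUTOSOMES for a in ARMS for d in DIRECTIONS
)


def format_category(category: Category) -> str:
    """``("16", "q", "loss")`` -> ``"16qL"``."""
    return f"{category.chromosome}{category.arm}{_DIR_ABBREV[category.direction]}"


def parse_category(text: str) -> Category:
    """``"16qL"`` -> ``("16", "q", "loss")``."""
    text = text.strip()
    if len(text) < 3 or text[-2] not in ("p", "q") or text[-1] not in _ABBREV_DIR:
        raise ValueError(f"cannot parse arm-event category {text!r}")
    chrom = text[:-2]
    if chrom not in AUTOSOMES:
        raise ValueError(f"category {text!r} is not autosomal")
    return Category(chrom, text[-2], _ABBREV_DIR[text[-1]])


# Approximate GRCh38 chromosome lengths and centromere midpoints (base pairs).
# Used only to build a default arm map; any user-provided arm table overrides.
GRCH38_CHROM_LENGTH_BP: dict[str, int] = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468,
}

GRCH38_CENTROMERE_BP: dict[str, int] = {
    "1": 123_400_000, "2": 93_900_000, "3": 90_900_000, "4": 50_000_000,
    "5": 48_800_000, "6": 59_800_000, "7": 60_100_000, "8": 45_200_000,
    "9": 43_000_000, "10": 39_800_000, "11": 53_400_000, "12": 35_500_000,
    "13": 17_700_000, "14": 17_200_000, "15": 19_000_000, "16": 36_800_000,
    "17": 25_100_000, "18": 18_500_000, "19": 26_200_000, "20": 28_100_000,
    "21": 12_000_000, "22": 15_000_000,
}
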