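"""Chromosome naming conventions and GRCh37 constants.

All public functions in :mod:`aneuscreen` key chromosomes by their bare
GRCh37 names: ``"1"`` .. ``"22"``, ``"X"``, ``"Y"``.  Input tables and
alignments using the ``chr``-prefixed dialect are normalised on read.
"""

from __future__ import annotations

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES: tuple[str, ...] = ("X", "Y")
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + SEX_CHROMOSOMES

#: GRCh37 (hg19) sequence lengths in base pairs; used for the simulator's
#: default chromosome-proportion weights.
GRCH37_LENGTHS: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
    "X": 155_270_560,
    "Y": 59_373_566,
}

_VALID = frozenset(CHROMOSOMES)


def normalize_chromosome(name: str) -> str | None:
    """Map a reference name to its bare chromosome name.

    Accepts both ``"chr21"`` and ``"21"`` (and lowercase ``x``/``y``).
    Returns ``None`` for anything that is not one of the 24 nuclear
    chromosomes (decoys, unplaced contigs, MT, ...).
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper().lstrip("0") if s not in ("0",) else s
    return s if s in _VALID else None
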