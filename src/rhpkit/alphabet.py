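"""Four-class pseudo-residue alphabet, residue/monomer class maps and HLB tables.

Protein and polymer sequences are coarse-grained onto four pseudo-residue
classes — hydrophilic (P), hydrophobic (H), very hydrophobic (V) and
charged (C) — chosen to balance synthetic accessibility of heteropolymers
against the diversity of segmental interactions they can encode.  Each
residue or monomer additionally carries a hydrophilic–lipophilic balance
(HLB) value on Griffin's 0–20 scale, used downstream as the per-window
hydrophobicity label for the latent model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PSEUDO_CLASSES",
    "CANONICAL_AMINO_ACIDS",
    "MonomerSpec",
    "ResidueClassMap",
    "HlbTable",
    "DEFAULT_RESIDUE_MAP",
    "DEFAULT_MONOMERS",
    "DEFAULT_MONOMER_MAP",
    "DEFAULT_RESIDUE_HLB",
    "DEFAULT_MONOMER_HLB",
    "reduce_sequence",
    "sequence_hlb",
    "load_class_map",
    "save_class_map",
    "load_hlb_table",
    "save_hlb_table",
]

#: The fixed 4-letter pseudo-residue alphabet, in canonical column order.
PSEUDO_CLASSES: tuple[str, ...] = ("P", "H", "V", "C")

CANONICAL_AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Non-canonical amino-acid codes rejected during sequence reduction.
NONCANONICAL_AMINO_ACIDS: frozenset[str] = frozenset("BZXUO")


class UnmappedLetterError(KeyError):
    """A sequence letter without a class-map or HLB-table entry."""

    def __init__(self, letter: str, position: int):
        self.letter = letter
        self.position = position
        super().__init__(
            f"letter {letter!r} at position {position} has no map entry"
        )


@dataclass(frozen=True)
class MonomerSpec:
    """A methacrylate monomer usable in a random-heteropolymer feed.

    Parameters
    ----------
    letter : str
        Single-character code used in chain strings.
    name : str
        Common abbreviation (e.g. ``MMA``, ``EHMA``).
    pseudo_class : str
        One of the four pseudo-residue classes ``P/H/V/C``.
    molar_mass : float
        Monomer molar mass in g/mol.
    hlb : float
        Per-unit hydrophilic–lipophilic balance on the 0–20 scale.
    """

    letter: str
    name: str
    pseudo_class: str
    molar_mass: float
    hlb: float

    def __post_init__(self) -> None:
        if len(self.letter) != 1:
            raise ValueError(f"monomer letter must be one character: {self.letter!r}")
        if self.pseudo_class not in PSEUDO_CLASSES:
            raise ValueError(f"unknown pseudo-class {self.pseudo_class!r}")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if not 0.0 <= self.hlb <= 20.0:
            raise ValueError("hlb must lie in [0, 20]")


class ResidueClassMap(Mapping[str, str]):
    """Mapping of sequence letters onto the four pseudo-residue classes.

    A map over the 20 canonical amino acids must be total and must place
    D, E, K and R in the charged class — that is the definition of
    "charged" in this scheme.
    """

    def __init__(self, entries: Mapping[str, str], *, amino_acid: bool = False):
        entries = dict(entries)
        for letter, cls in entries.items():
            if cls not in PSEUDO_CLASSES:
                raise ValueError(f"{letter!r} maps to unknown class {cls!r}")
            if len(letter) != 1:
                raise ValueError(f"map keys must be single letters: {letter!r}")
        if amino_acid:
            missing = CANONICAL_AMINO_ACIDS - entries.keys()
            if missing:
                raise ValueError(
                    f"amino-acid map missing letters: {sorted(missing)}"
                )
            for aa in "DEKR":
                if entries[aa] != "C":
                    raise ValueError(
                        f"{aa} must map to class C (charged) in a valid amino-acid map"
                    )
        self._entries = entries
        self.amino_acid = amino_acid

    def __getitem__(self, key: str) -> str:
        return self._entries[key]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)


class HlbTable(Mapping[str, float]):
    """Per-unit HLB values keyed by residue or monomer letter."""

    def __init__(self, entries: Mapping[str, float]):
        entries = {k: float(v) for k, v in entries.items()}
        for letter, value in entries.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite HLB for {letter!r}")
        self._entries = entries

    def __getitem__(self, key: str) -> float:
        return self._entries[key]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)


# Default amino-acid assignment.  Charged = {D,E,K,R} by definition; the
# V/H/P split follows a standard side-chain hydrophobicity ordering.  The
# map is a loadable config so an alternative published table can be
# substituted without code changes.
DEFAULT_RESIDUE_MAP = ResidueClassMap(
    {
        **{aa: "C" for aa in "DEKR"},
        **{aa: "V" for aa in "FILVWM"},
        **{aa: "H" for aa in "ACGPY"},
        **{aa: "P" for aa in "STNQH"},
    },
    amino_acid=True,
)

# Monomer set: six methacrylates.  HLB defaults follow Griffin's formula
# HLB = 20 * (hydrophilic-portion mass / molar mass) with the
# hydrophilic-portion masses documented in the methods note; they are
# monotone in hydrophilicity, which is all downstream analyses require.
DEFAULT_MONOMERS: dict[str, MonomerSpec] = {
    m.letter: m
    for m in (
        MonomerSpec("M", "MMA", "H", 100.12, 8.8),
        MonomerSpec("E", "EHMA", "V", 198.30, 4.4),
        MonomerSpec("G", "OEGMA300", "P", 300.0, 15.3),
        MonomerSpec("O", "OEGMA500", "P", 500.0, 17.2),
        MonomerSpec("S", "SPMA", "C", 246.32, 19.0),
        MonomerSpec("D", "DMAEMA", "C", 157.21, 17.5),
    )
}

DEFAULT_MONOMER_MAP = ResidueClassMap(
    {letter: spec.pseudo_class for letter, spec in DEFAULT_MONOMERS.items()}
)

# Amino-acid HLB defaults assigned per class: charged most hydrophilic,
# very-hydrophobic least.
_CLASS_HLB = {"C": 19.0, "P": 15.0, "H": 9.0, "V": 4.0}

DEFAULT_RESIDUE_HLB = HlbTable(
    {aa: _CLASS_HLB[cls] for aa, cls in DEFAULT_RESIDUE_MAP.items()}
)

DEFAULT_MONOMER_HLB = HlbTable(
    {letter: spec.hlb for letter, spec in DEFAULT_MONOMERS.items()}
)

#: HLB values for the pseudo-classes themselves, so reduced sequences can
#: be profiled directly.
PSEUDO_CLASS_HLB = HlbTable(_CLASS_HLB)


def reduce_sequence(seq: str, class_map: Mapping[str, str] | None = None) -> str:
    """Reduce a letter sequence onto the 4-class pseudo-residue alphabet.

    Parameters
    ----------
    seq : str
        Amino-acid or monomer letter string.
    class_map : mapping, optional
        Letter → class map; defaults to the amino-acid map.

    Returns
    -------
    str
        Pseudo-residue string of the same length over ``{P,H,V,C}``.

    Raises
    ------
    UnmappedLetterError
        If a letter has no entry (including the non-canonical amino-acid
        codes B, Z, X, U, O, which are deliberately absent from the
        default map and therefore rejected).
    """
    if class_map is None:
        class_map = DEFAULT_RESIDUE_MAP
    out = []
    for i, letter in enumerate(seq):
        try:
            out.append(class_map[letter])
        except KeyError:
            raise UnmappedLetterError(letter, i) from None
    return "".join(out)


def sequence_hlb(seq: str, table: Mapping[str, float]) -> tuple[np.ndarray, float]:
    """Per-position HLB vector and its arithmetic mean for a sequence.

    The mean is the training label used by the latent model's regression
    head.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence has no HLB")
    values = np.empty(len(seq))
    for i, letter in enumerate(seq):
        try:
            values[i] = table[letter]
        except KeyError:
            raise UnmappedLetterError(letter, i) from None
    return values, float(values.mean())


# ---------------------------------------------------------------------------
# Config file I/O: one "letter<TAB>value" record per line, '#' comments.

def _parse_kv_lines(path: str | Path) -> dict[str, str]:
    entries: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'letter value', got {raw!r}")
        entries[parts[0]] = parts[1]
    return entries


def load_class_map(path: str | Path, *, amino_acid: bool = False) -> ResidueClassMap:
    """Load a letter→class map from a two-column text file."""
    return ResidueClassMap(_parse_kv_lines(path), amino_acid=amino_acid)


def save_class_map(path: str | Path, class_map: Mapping[str, str]) -> None:
    lines = [f"{letter}\t{cls}" for letter, cls in sorted(class_map.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def load_hlb_table(path: str | Path) -> HlbTable:
    """Load a letter→HLB table from a two-column text file."""
    return HlbTable({k: float(v) for k, v in _parse_kv_lines(path).items()})


def save_hlb_table(path: str | Path, table: Mapping[str, float]) -> None:
    lines = [f"{letter}\t{value:g}" for letter, value in sorted(table.items())]
    Path(path).write_text("\n".join(lines) + "\n")


#: Named presets for CLI / config lookup.
CLASS_MAP_PRESETS: dict[str, ResidueClassMap] = {
    "amino-acid": DEFAULT_RESIDUE_MAP,
    "monomer": DEFAULT_MONOMER_MAP,
}

HLB_PRESETS: dict[str, HlbTable] = {
    "amino-acid": DEFAULT_RESIDUE_HLB,
    "monomer": DEFAULT_MONOMER_HLB,
    "pseudo-class": PSEUDO_CLASS_HLB,
}
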