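"""FASTA I/O, 50-mer window extraction and one-hot encoding.

Sequences reduced to the 4-class pseudo-residue alphabet are cut into
fixed-width segments by a sliding window (default width 50, step 15); the
windows are the unit of analysis for the latent model.  Coordinates are
0-based, half-open, and trailing residues not covered by a final full
window are dropped so every window is exactly ``width`` residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import PSEUDO_CLASSES

__all__ = [
    "PseudoSequence",
    "SegmentWindow",
    "WindowSet",
    "extract_windows",
    "extract_windows_many",
    "encode_window",
    "decode_window",
    "encode_windows",
    "read_fasta",
    "write_fasta",
    "write_windows_tsv",
    "read_windows_tsv",
]

logger = logging.getLogger(__name__)

_CLASS_INDEX = {c: i for i, c in enumerate(PSEUDO_CLASSES)}


@dataclass(frozen=True)
class PseudoSequence:
    """A pseudo-residue sequence with provenance.

    ``source`` records whether the sequence came from a protein, a
    simulated polymer chain, or the synthetic generator.
    """

    id: str
    letters: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.letters) - set(PSEUDO_CLASSES)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-alphabet letters {sorted(bad)}"
            )
        if self.source not in ("protein", "polymer", "synthetic"):
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.letters)


@dataclass(frozen=True)
class SegmentWindow:
    """One fixed-width segment cut from a parent sequence."""

    parent_id: str
    start: int
    letters: str

    @property
    def width(self) -> int:
        return len(self.letters)


@dataclass
class WindowSet:
    """A collection of equal-width windows plus the extraction geometry."""

    windows: list[SegmentWindow]
    width: int = 50
    step: int = 15

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def letters(self) -> list[str]:
        return [w.letters for w in self.windows]


def extract_windows(seq: PseudoSequence, width: int = 50, step: int = 15) -> WindowSet:
    """Slide a fixed window over one sequence.

    For a sequence of length ``L >= width`` this yields
    ``floor((L - width) / step) + 1`` windows at starts 0, step, 2*step, …;
    shorter sequences yield an empty set (logged, not an error).
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    L = len(seq)
    if L < width:
        logger.warning(
            "sequence %s (length %d) shorter than window width %d; dropped",
            seq.id, L, width,
        )
        return WindowSet([], width=width, step=step)
    windows = [
        SegmentWindow(seq.id, start, seq.letters[start:start + width])
        for start in range(0, L - width + 1, step)
    ]
    return WindowSet(windows, width=width, step=step)


def extract_windows_many(
    seqs: Iterable[PseudoSequence], width: int = 50, step: int = 15
) -> WindowSet:
    """Window a whole collection of sequences into one pooled set."""
    out: list[SegmentWindow] = []
    for seq in seqs:
        out.extend(extract_windows(seq, width=width, step=step).windows)
    return WindowSet(out, width=width, step=step)


def encode_window(window: SegmentWindow | str) -> np.ndarray:
    """One-hot encode a window as a (width, 4) indicator matrix.

    Column order is fixed as (P, H, V, C); each row sums to one.
    """
    letters = window.letters if isinstance(window, SegmentWindow) else window
    mat = np.zeros((len(letters), len(PSEUDO_CLASSES)))
    for i, letter in enumerate(letters):
        try:
            mat[i, _CLASS_INDEX[letter]] = 1.0
        except KeyError:
            raise ValueError(f"invalid letter {letter!r} at position {i}") from None
    return mat


def decode_window(mat: np.ndarray) -> str:
    """Inverse of :func:`encode_window` via per-row argmax."""
    return "".join(PSEUDO_CLASSES[j] for j in np.asarray(mat).argmax(axis=1))


def encode_windows(windows: WindowSet | Sequence[str]) -> np.ndarray:
    """Encode many windows into an (n, width*4) flattened design matrix."""
    letters = windows.letters() if isinstance(windows, WindowSet) else list(windows)
    if not letters:
        return np.zeros((0, 0))
    return np.stack([encode_window(w).ravel() for w in letters])


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, source: str = "protein") -> list[PseudoSequence]:
    """Read a FASTA file into pseudo-sequences (wrapped lines supported)."""
    seqs: list[PseudoSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seqs.append(PseudoSequence(record.id, str(record.seq).upper(), source=source))
    return seqs


def write_fasta(path: str | Path, seqs: Iterable[PseudoSequence]) -> None:
    records = [
        SeqRecord(Seq(s.letters), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Window TSV export (parent_id, start, letters)

def write_windows_tsv(path: str | Path, windows: WindowSet) -> None:
    with open(path, "w") as fh:
        fh.write("parent_id\tstart\tletters\n")
        for w in windows:
            fh.write(f"{w.parent_id}\t{w.start}\t{w.letters}\n")


def read_windows_tsv(path: str | Path) -> WindowSet:
    windows: list[SegmentWindow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["parent_id", "start", "letters"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed row")
            windows.append(SegmentWindow(parts[0], int(parts[1]), parts[2]))
    width = windows[0].width if windows else 50
    return WindowSet(windows, width=width)
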