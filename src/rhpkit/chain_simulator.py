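"""Monte-Carlo generation of random-heteropolymer (RHP) ensembles.

Chains grow under terminal-model free-radical copolymerization kinetics:
the probability that a chain ending in monomer *i* adds monomer *j* is

    P(i -> j) = (f_j / r_ij) / sum_k (f_k / r_ik)

with f the instantaneous feed mole fractions and r_ij = k_ii / k_ij the
reactivity ratios.  A single finite monomer pool shared by all chains is
decremented after every addition, so the feed drifts with conversion
(compositional drift); chains are grown concurrently in randomized
round-robin order so they all sample the same conversion trajectory.

For two monomers at vanishing conversion the ensemble composition obeys
the Mayo-Lewis closed form

    F1 = (r1 f1^2 + f1 f2) / (r1 f1^2 + 2 f1 f2 + r2 f2^2),

implemented here as an analytic cross-check on the simulator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import PseudoSequence

__all__ = [
    "FeedComposition",
    "ReactivityMatrix",
    "DriftConfig",
    "ChainEnsemble",
    "mayo_lewis_F1",
    "propagation_probs",
    "simulate_ensemble",
    "ensemble_composition",
    "block_length_distribution",
    "block_permutation_library",
    "write_ensemble",
    "read_ensemble",
    "RHP_FEED_PRESETS",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class FeedComposition:
    """Monomer mole fractions of a polymerization feed."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        fracs = dict(self.fractions)
        if not fracs:
            raise ValueError("empty feed")
        if any(f < 0 for f in fracs.values()):
            raise ValueError("feed fractions must be non-negative")
        total = sum(fracs.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"feed fractions sum to {total}, expected 1")
        object.__setattr__(self, "fractions", fracs)

    @classmethod
    def from_percent(cls, percents: Mapping[str, float]) -> "FeedComposition":
        total = sum(percents.values())
        return cls({k: v / total for k, v in percents.items()})

    @property
    def monomers(self) -> tuple[str, ...]:
        return tuple(self.fractions)

    def __getitem__(self, letter: str) -> float:
        return self.fractions[letter]


class ReactivityMatrix:
    """Reactivity ratios r_ij = k_ii / k_ij for ordered monomer pairs.

    Diagonal entries are identically 1.  The default (all ratios 1) is
    ideal copolymerization; experimentally determined matrices can be
    supplied per monomer set.
    """

    def __init__(self, monomers: Sequence[str], ratios: Mapping[tuple[str, str], float] | None = None):
        self.monomers = tuple(monomers)
        self._r = {(i, j): 1.0 for i in self.monomers for j in self.monomers}
        if ratios:
            for (i, j), value in ratios.items():
                if i == j and value != 1.0:
                    raise ValueError("diagonal reactivity ratios must be 1")
                if value <= 0:
                    raise ValueError(f"r[{i},{j}] must be positive")
                if i not in self.monomers or j not in self.monomers:
                    raise ValueError(f"unknown monomer pair ({i}, {j})")
                self._r[(i, j)] = float(value)

    @classmethod
    def ideal(cls, monomers: Sequence[str]) -> "ReactivityMatrix":
        return cls(monomers)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self._r[pair]

    def items(self):
        return self._r.items()


@dataclass(frozen=True)
class DriftConfig:
    """Simulation settings: ensemble size, chain length, conversion, seed."""

    n_chains: int = 2000
    dp: int = 50
    conversion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.dp < 1:
            raise ValueError("dp must be >= 1")
        if not 0.0 < self.conversion <= 1.0:
            raise ValueError("conversion must be in (0, 1]")


@dataclass
class ChainEnsemble:
    """A set of simulated chains with the feed/kinetics that produced it."""

    chains: list[str]
    feed: FeedComposition
    reactivity: ReactivityMatrix
    config: DriftConfig

    def __post_init__(self) -> None:
        dp = self.config.dp
        for chain in self.chains:
            if len(chain) != dp:
                raise ValueError("all chains must have length dp")

    def __len__(self) -> int:
        return len(self.chains)

    def subsample(self, n: int, seed: int = 0) -> "ChainEnsemble":
        """Uniform sample without replacement of ``n`` chains."""
        if n >= len(self.chains):
            return self
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self.chains), size=n, replace=False)
        return ChainEnsemble(
            [self.chains[i] for i in idx], self.feed, self.reactivity, self.config
        )


def mayo_lewis_F1(f1: float, r1: float, r2: float) -> float:
    """Instantaneous copolymer fraction of monomer 1 (binary Mayo-Lewis)."""
    if r1 <= 0 or r2 <= 0:
        raise ValueError("reactivity ratios must be positive")
    if not 0.0 <= f1 <= 1.0:
        raise ValueError("f1 must lie in [0, 1]")
    f2 = 1.0 - f1
    num = r1 * f1 * f1 + f1 * f2
    den = r1 * f1 * f1 + 2.0 * f1 * f2 + r2 * f2 * f2
    if den == 0.0:
        return 0.0
    return num / den


def propagation_probs(
    end_monomer: str, feed: FeedComposition | Mapping[str, float], r: ReactivityMatrix
) -> dict[str, float]:
    """Terminal-model addition probabilities from a given chain end."""
    fracs = feed.fractions if isinstance(feed, FeedComposition) else dict(feed)
    if end_monomer not in fracs:
        raise ValueError(f"end monomer {end_monomer!r} not in feed")
    weights = {j: fracs[j] / r[(end_monomer, j)] for j in fracs}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all feed fractions are zero")
    return {j: w / total for j, w in weights.items()}


def simulate_ensemble(
    monomers: Sequence[str],
    feed: FeedComposition,
    r: ReactivityMatrix,
    cfg: DriftConfig,
) -> ChainEnsemble:
    """Grow an ensemble of fixed-DP chains from a shared finite pool.

    The pool holds ``n_chains * dp / conversion`` monomer units split
    according to the feed; consuming ``n_chains * dp`` of them takes the
    batch to the configured conversion.  Each step advances one uniformly
    chosen unfinished chain.  Deterministic for a fixed seed.
    """
    monomers = tuple(monomers)
    if set(feed.monomers) - set(monomers):
        raise ValueError("feed contains monomers outside the monomer set")
    rng = np.random.default_rng(cfg.seed)

    # integer pool apportioned by largest remainder so the usable units
    # sum to at least n_chains * dp even at full conversion
    total_units = int(math.ceil(cfg.n_chains * cfg.dp / cfg.conversion))
    exact = {m: feed.fractions.get(m, 0.0) * total_units for m in monomers}
    pool = {m: float(int(v)) for m, v in exact.items()}
    short = total_units - int(sum(pool.values()))
    for m in sorted(monomers, key=lambda m: exact[m] - pool[m], reverse=True)[:short]:
        pool[m] += 1.0

    chains: list[list[str]] = [[] for _ in range(cfg.n_chains)]
    unfinished = list(range(cfg.n_chains))
    midx = list(monomers)

    while unfinished:
        pos = int(rng.integers(len(unfinished)))
        ci = unfinished[pos]
        chain = chains[ci]
        # a monomer with less than one whole unit left is unavailable
        avail = [pool[m] if pool[m] >= 1.0 else 0.0 for m in midx]
        pool_total = sum(avail)
        if pool_total <= 0:
            raise RuntimeError("monomer pool exhausted before chains completed")
        if not chain:
            # initiation: draw from the current feed
            weights = [a / pool_total for a in avail]
        else:
            end = chain[-1]
            w = [a / pool_total / r[(end, m)] for m, a in zip(midx, avail)]
            s = sum(w)
            weights = [x / s for x in w]
        u = rng.random()
        acc = 0.0
        choice = next(m for m, wgt in zip(reversed(midx), reversed(weights)) if wgt > 0)
        for m, wgt in zip(midx, weights):
            acc += wgt
            if wgt > 0 and u < acc:
                choice = m
                break
        pool[choice] -= 1.0
        chain.append(choice)
        if len(chain) == cfg.dp:
            unfinished[pos] = unfinished[-1]
            unfinished.pop()

    return ChainEnsemble(["".join(c) for c in chains], feed, r, cfg)


def ensemble_composition(e: ChainEnsemble | Iterable[str]) -> dict[str, float]:
    """Overall monomer fraction table of an ensemble (sums to 1)."""
    chains = e.chains if isinstance(e, ChainEnsemble) else list(e)
    if not chains:
        raise ValueError("empty ensemble has no composition")
    counts: dict[str, int] = {}
    total = 0
    for chain in chains:
        for letter in chain:
            counts[letter] = counts.get(letter, 0) + 1
            total += 1
    return {m: c / total for m, c in sorted(counts.items())}


def block_length_distribution(
    seqs: ChainEnsemble | Iterable[str | PseudoSequence],
    class_map: Mapping[str, str] | None = None,
) -> dict[str, dict[int, int]]:
    """Histogram of maximal-run lengths per letter (or per class).

    When ``class_map`` is given each sequence is reduced first, so runs are
    counted over pseudo-residue classes rather than raw letters.
    """
    if isinstance(seqs, ChainEnsemble):
        strings: Iterable[str] = seqs.chains
    else:
        strings = (s.letters if isinstance(s, PseudoSequence) else s for s in seqs)
    hist: dict[str, dict[int, int]] = {}
    for s in strings:
        if class_map is not None:
            s = "".join(class_map[c] for c in s)
        for letter, run in itertools.groupby(s):
            n = sum(1 for _ in run)
            hist.setdefault(letter, {})[n] = hist.get(letter, {}).get(n, 0) + 1
    return hist


def block_permutation_library(blocks: Sequence[str]) -> list[str]:
    """All distinct concatenations of a set of 1–6 blocks.

    Four distinct blocks give the 4! = 24-member permutation library used
    to illustrate how block order moves a chain in the 2D sequence map.
    """
    if not 1 <= len(blocks) <= 6:
        raise ValueError("need between 1 and 6 blocks")
    seen: dict[str, None] = {}
    for perm in itertools.permutations(blocks):
        seen.setdefault("".join(perm), None)
    return list(seen)


# ---------------------------------------------------------------------------
# Ensemble text format: '# key: value' header lines, then one chain per line.

def write_ensemble(path: str | Path, e: ChainEnsemble) -> None:
    lines = [
        f"# feed: {' '.join(f'{m}={f:.6g}' for m, f in e.feed.fractions.items())}",
        f"# ratios: {' '.join(f'{i}{j}={v:.6g}' for (i, j), v in e.reactivity.items() if i != j)}",
        f"# dp: {e.config.dp}",
        f"# conversion: {e.config.conversion:.6g}",
        f"# seed: {e.config.seed}",
    ]
    lines.extend(e.chains)
    Path(path).write_text("\n".join(lines) + "\n")


def read_ensemble(path: str | Path) -> ChainEnsemble:
    header: dict[str, str] = {}
    chains: list[str] = []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            key, _, value = raw[1:].partition(":")
            header[key.strip()] = value.strip()
        elif raw.strip():
            chains.append(raw.strip())
    feed = FeedComposition(
        {kv.split("=")[0]: float(kv.split("=")[1]) for kv in header["feed"].split()}
    )
    monomers = feed.monomers
    ratios: dict[tuple[str, str], float] = {}
    if header.get("ratios"):
        for kv in header["ratios"].split():
            pair, value = kv.split("=")
            ratios[(pair[0], pair[1])] = float(value)
    cfg = DriftConfig(
        n_chains=len(chains),
        dp=int(header["dp"]),
        conversion=float(header["conversion"]),
        seed=int(header["seed"]),
    )
    return ChainEnsemble(chains, feed, ReactivityMatrix(monomers, ratios), cfg)


#: Feed presets (mole percent) for the RHP/DHP compositions studied;
#: letters follow the default monomer set (M=MMA, O=OEGMA500, E=EHMA,
#: S=SPMA, G=OEGMA300, D=DMAEMA).
RHP_FEED_PRESETS: dict[str, FeedComposition] = {
    name: FeedComposition.from_percent(p)
    for name, p in {
        "RHP1": {"M": 70, "O": 25, "S": 5},
        "RHP2": {"M": 65, "O": 25, "E": 5, "S": 5},
        "RHP3": {"M": 60, "O": 25, "E": 10, "S": 5},
        "RHP4": {"M": 50, "O": 25, "E": 20, "S": 5},
        "RHP5": {"M": 40, "O": 25, "E": 30, "S": 5},
        "RHP6": {"M": 20, "O": 25, "E": 50, "S": 5},
        "RHP7": {"O": 25, "E": 70, "S": 5},
        "RHP8": {"M": 60, "E": 10, "G": 15, "D": 15},
        "RHP9": {"M": 50, "E": 20, "G": 15, "D": 15},
        "RHP10": {"M": 20, "E": 50, "G": 15, "D": 15},
        "RHP11": {"G": 10, "D": 90},
        "RHP12": {"M": 50, "O": 25, "E": 20, "D": 5},
        "RHP13": {"M": 50, "E": 20, "G": 25, "D": 5},
        "RHP14": {"M": 70, "G": 25, "D": 5},
    }.items()
}
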