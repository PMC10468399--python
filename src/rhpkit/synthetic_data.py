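"""Seeded generators for synthetic sequence families and physchem curves.

Every generator here is the forward model of exactly one analysis
operation elsewhere in the package, so each (generator, fitter) pair
forms a closed parameter-recovery loop:

* :func:`generate_family` draws pseudo-residue sequences from a
  semi-Markov run-length process (class from stationary frequencies, run
  length geometric) — the process the block-length statistics and the
  latent model are probed with;
* :func:`make_benchmark_pair` instantiates two contrasting families —
  membrane-like (high very-hydrophobic content, long V blocks) and
  globular-like (shorter, alternating blocks) — standing in for the two
  protein families of the full-scale analysis;
* :func:`synth_saxs`, :func:`synth_frap` and :func:`synth_fec` generate
  noisy curves from the Guinier, exponential-recovery and WLC forward
  models with the ground truth recorded alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .alphabet import PSEUDO_CLASSES, PSEUDO_CLASS_HLB
from .sequence_io import PseudoSequence
from .physchem import (
    ForceExtensionCurve,
    FrapTrace,
    SaxsProfile,
    wlc_curve,
)

__all__ = [
    "FamilyParams",
    "generate_family",
    "make_benchmark_pair",
    "MEMBRANE_LIKE",
    "GLOBULAR_LIKE",
    "synth_saxs",
    "synth_frap",
    "synth_fec",
    "family_mean_hlb",
]


@dataclass(frozen=True)
class FamilyParams:
    """Parameters of one synthetic sequence family.

    ``class_freqs`` are the stationary pseudo-class frequencies;
    ``mean_block_lengths`` give the mean of the geometric run-length
    distribution per class (>= 1).  Lengths are uniform on
    [min_length, max_length].
    """

    name: str
    n_sequences: int = 400
    min_length: int = 80
    max_length: int = 300
    class_freqs: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in PSEUDO_CLASSES}
    )
    mean_block_lengths: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.5 for c in PSEUDO_CLASSES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = dict(self.class_freqs)
        if set(freqs) - set(PSEUDO_CLASSES):
            raise ValueError("class_freqs has unknown classes")
        if any(f < 0 for f in freqs.values()):
            raise ValueError("negative class frequency")
        total = sum(freqs.values())
        if total <= 0:
            raise ValueError("degenerate class frequencies")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class frequencies sum to {total}, expected 1")
        for c, m in self.mean_block_lengths.items():
            if m < 1:
                raise ValueError(f"mean block length for {c} must be >= 1")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("invalid length range")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


def generate_family(p: FamilyParams) -> list[PseudoSequence]:
    """Draw a family of pseudo-residue sequences (seeded, deterministic).

    Sequences realize a semi-Markov run-length process: a class is drawn,
    then a run of geometric length with that class's configured mean, and
    so on until the target length; consecutive runs never repeat a class
    (unless only one class has positive frequency).  The run-length
    structure gives the families genuine block statistics — i.e. a
    "sequential arrangement" signal — rather than i.i.d. letters.
    """
    rng = np.random.default_rng(p.seed)
    classes = [c for c in PSEUDO_CLASSES if p.class_freqs.get(c, 0.0) > 0]
    freqs = np.array([p.class_freqs[c] for c in classes])
    freqs = freqs / freqs.sum()
    seqs: list[PseudoSequence] = []
    for i in range(p.n_sequences):
        L = int(rng.integers(p.min_length, p.max_length + 1))
        letters: list[str] = []
        prev: str | None = None
        while len(letters) < L:
            if len(classes) == 1:
                cls = classes[0]
            else:
                while True:
                    cls = classes[int(rng.choice(len(classes), p=freqs))]
                    if cls != prev:
                        break
            mean = p.mean_block_lengths.get(cls, 1.0)
            # geometric on {1,2,...} with mean m has success prob 1/m
            run = 1 if mean <= 1.0 else int(rng.geometric(1.0 / mean))
            letters.extend(cls * min(run, L - len(letters)))
            prev = cls
        seqs.append(PseudoSequence(f"{p.name}_{i:04d}", "".join(letters)))
    return seqs


# Benchmark presets.  Membrane-like: V-rich with long very-hydrophobic
# blocks (transmembrane-segment caricature); globular-like: hydrophilic-
# leaning with short alternating blocks.  The two families have disjoint
# mean-HLB ranges by construction, which the latent model's regression
# head must learn to separate.
MEMBRANE_LIKE = FamilyParams(
    name="membrane_like",
    class_freqs={"P": 0.20, "H": 0.20, "V": 0.50, "C": 0.10},
    mean_block_lengths={"P": 2.0, "H": 2.0, "V": 8.0, "C": 1.5},
)

GLOBULAR_LIKE = FamilyParams(
    name="globular_like",
    class_freqs={"P": 0.35, "H": 0.25, "V": 0.15, "C": 0.25},
    mean_block_lengths={"P": 2.5, "H": 2.0, "V": 2.0, "C": 2.0},
)


def make_benchmark_pair(
    seed: int = 0, n_sequences: int = 400
) -> tuple[list[PseudoSequence], list[PseudoSequence]]:
    """The (membrane-like, globular-like) benchmark family pair."""
    from dataclasses import replace

    membrane = generate_family(
        replace(MEMBRANE_LIKE, seed=seed, n_sequences=n_sequences)
    )
    globular = generate_family(
        replace(GLOBULAR_LIKE, seed=seed + 1, n_sequences=n_sequences)
    )
    return membrane, globular


def family_mean_hlb(seqs: list[PseudoSequence]) -> float:
    """Mean per-residue HLB of a family under the pseudo-class table."""
    vals = [
        np.mean([PSEUDO_CLASS_HLB[c] for c in s.letters]) for s in seqs
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Curve fixtures

def synth_saxs(Rg: float = 4.4, I0: float = 1.0, noise: float = 0.0,
               n_points: int = 50, q_max: float | None = None,
               seed: int = 0) -> tuple[SaxsProfile, dict]:
    """Synthetic Guinier-regime SAXS profile with multiplicative noise.

    Default q range covers q*Rg up to 1.3 (the Guinier validity cut).
    Returns the profile and a ground-truth record.
    """
    rng = np.random.default_rng(seed)
    if q_max is None:
        q_max = 1.3 / Rg
    q = np.linspace(q_max / n_points, q_max, n_points)
    I = I0 * np.exp(-(Rg ** 2 / 3.0) * q ** 2)
    if noise > 0:
        I = I * (1.0 + noise * rng.standard_normal(n_points))
        I = np.clip(I, 1e-12, None)
    return SaxsProfile(q=q, I=I), {"Rg": Rg, "I0": I0, "noise": noise, "seed": seed}


def synth_frap(A: float = 0.9, tau: float = 385.0, noise: float = 0.0,
               n_points: int = 60, t_max: float | None = None,
               n_prebleach: int = 5, bleach_depth: float = 0.8,
               seed: int = 0) -> tuple[FrapTrace, dict]:
    """Synthetic FRAP trace generated from R(t) = A(1 - exp(-t/tau)).

    Pre-bleach frames sit at ratio r_before = 1; the bleach drops the
    ratio by ``bleach_depth`` and recovery follows the exponential model.
    Additive Gaussian noise of the stated fraction perturbs the bleached
    intensity.
    """
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = 5.0 * tau
    dt = t_max / n_points
    t_pre = np.arange(n_prebleach) * dt
    t_post = t_pre[-1] + dt + np.linspace(0.0, t_max, n_points)
    r_before = 1.0
    r0 = r_before - bleach_depth
    R = A * (1.0 - np.exp(-(t_post - t_post[0]) / tau))
    r_after = r0 + R * (r_before - r0)
    I_u = np.ones(n_prebleach + n_points)
    I_b = np.concatenate([np.full(n_prebleach, r_before), r_after])
    if noise > 0:
        I_b = I_b + noise * rng.standard_normal(len(I_b))
        I_b = np.clip(I_b, 1e-9, None)
    trace = FrapTrace(
        t=np.concatenate([t_pre, t_post]),
        I_b=I_b,
        I_u=I_u,
        pre=np.arange(n_prebleach + n_points) < n_prebleach,
    )
    return trace, {"A": A, "tau": tau, "noise": noise, "seed": seed}


def synth_fec(Lc: float = 300.0, Lp: float = 0.7, K: float = np.inf,
              T: float = 298.0, rip: tuple[float, float] | None = None,
              rip_at: float = 0.5, n_points: int = 400, noise: float = 0.0,
              seed: int = 0) -> tuple[ForceExtensionCurve, ForceExtensionCurve, dict]:
    """Synthetic pull FEC over a WLC baseline, optionally with a
    rectangular excess "rip" of (delta_F pN, delta_x nm) centred at
    fractional extension ``rip_at``.

    Returns (pull, baseline, truth); the constructed excess work is
    delta_F * delta_x, recoverable by the unfolding-work integrator.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 0.9 * Lc, n_points)
    F_base = wlc_curve(x, Lc, Lp, K=K, T=T)
    F_pull = F_base.copy()
    truth: dict = {"Lc": Lc, "Lp": Lp, "noise": noise, "seed": seed}
    if rip is not None:
        dF, dx = rip
        centre = rip_at * 0.9 * Lc
        in_rip = (x >= centre - dx / 2) & (x < centre + dx / 2)
        F_pull = F_pull + np.where(in_rip, dF, 0.0)
        truth["rip"] = {"delta_F": dF, "delta_x": dx, "work_pN_nm": dF * dx}
    if noise > 0:
        F_pull = F_pull + noise * rng.standard_normal(n_points)
    return (
        ForceExtensionCurve(x=x, F=F_pull, phase="pull"),
        ForceExtensionCurve(x=x, F=F_base, phase="pull"),
        truth,
    )


def write_truth_sidecar(path: str | Path, truth: dict) -> None:
    """Write a JSON ground-truth sidecar next to an exported fixture."""
    Path(path).write_text(json.dumps(truth, indent=2, default=float) + "\n")
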