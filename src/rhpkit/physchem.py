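"""Closed-form biophysical calculators and curve fits.

Groups the quantitative estimates used around the sequence-analysis
pipeline: diffusion-limited polymer–protein collision kinetics, the
critical overlap concentration of a polymer coil, Guinier analysis of
small-angle X-ray scattering (SAXS) profiles, sliding-window HLB
hydrophobicity profiles, worm-like-chain (WLC) force–extension mechanics
with unfolding-work integration, and exponential fluorescence recovery
after photobleaching (FRAP) fits.

Units are the field's working units: D in µm²/s, radii in nm, forces in
pN, extensions in nm, q in nm⁻¹, concentrations in g/l or g/cm³, times in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AVOGADRO",
    "KB_PN_NM",
    "PN_NM_PER_KCAL_MOL",
    "CollisionParams",
    "OverlapConcParams",
    "SaxsProfile",
    "ForceExtensionCurve",
    "FrapTrace",
    "CurveFit",
    "k_on",
    "collision_rate",
    "overlap_concentration",
    "guinier_fit",
    "hlb_profile",
    "wlc_force",
    "unfolding_work",
    "frap_recovery",
    "frap_fit",
    "detect_rips",
    "read_xy",
]

AVOGADRO = 6.02214076e23           # mol^-1
KB_PN_NM = 1.380649e-2             # Boltzmann constant, pN nm / K
PN_NM_PER_KCAL_MOL = 6.95          # 1 kcal/mol = 6.95 pN nm (3 s.f.)


@dataclass(frozen=True)
class CollisionParams:
    """Inputs for the diffusion-limited collision-rate estimate."""

    D: float           # diffusion coefficient, µm²/s
    r: float           # encounter radius, nm
    c_inf: float       # bulk mass concentration, g/l
    M: float           # molar mass, g/mol

    def __post_init__(self) -> None:
        if self.D <= 0 or self.r <= 0 or self.M <= 0:
            raise ValueError("D, r and M must be positive")
        if self.c_inf < 0:
            raise ValueError("c_inf must be non-negative")


@dataclass(frozen=True)
class OverlapConcParams:
    """Inputs for the critical overlap concentration c*."""

    M: float                 # g/mol
    Rg: float                # nm (taken as given; see methods note)
    density: float = 1.0     # solution density, g/cm³

    def __post_init__(self) -> None:
        if self.M <= 0 or self.Rg <= 0 or self.density <= 0:
            raise ValueError("M, Rg and density must be positive")


@dataclass
class SaxsProfile:
    """A 1D SAXS profile I(q)."""

    q: np.ndarray               # nm^-1, strictly increasing
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.shape != self.I.shape:
            raise ValueError("q and I must have equal length")
        if np.any(np.diff(self.q) <= 0) or np.any(self.q <= 0):
            raise ValueError("q must be positive and strictly increasing")


@dataclass
class ForceExtensionCurve:
    """A single-molecule force–extension curve."""

    x: np.ndarray      # extension, nm
    F: np.ndarray      # force, pN
    phase: str = "pull"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.x.shape != self.F.shape:
            raise ValueError("x and F must have equal length")
        if self.phase == "pull" and np.any(np.diff(self.x) < 0):
            raise ValueError("extension must be non-decreasing for a pull")


@dataclass
class FrapTrace:
    """Bleached/unbleached region intensities around a photobleach event.

    ``pre`` marks pre-bleach frames; post-bleach times are taken relative
    to the first post-bleach frame.
    """

    t: np.ndarray
    I_b: np.ndarray
    I_u: np.ndarray
    pre: np.ndarray     # boolean mask of pre-bleach frames

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I_b = np.asarray(self.I_b, dtype=float)
        self.I_u = np.asarray(self.I_u, dtype=float)
        self.pre = np.asarray(self.pre, dtype=bool)
        if not (len(self.t) == len(self.I_b) == len(self.I_u) == len(self.pre)):
            raise ValueError("trace columns must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be increasing")
        if np.any(self.I_b < 0) or np.any(self.I_u < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class CurveFit:
    """Fitted parameters with standard errors and residual diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float]
    residuals: np.ndarray
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Collision kinetics

def k_on(D: float, r: float) -> float:
    """Diffusion-limited association rate k_on = 4*pi*D*r (M⁻¹ s⁻¹).

    D in µm²/s and r in nm; the Smoluchowski volume rate 4*pi*D*r (µm³/s)
    is converted to molar units via Avogadro's number and 1e-15 l/µm³.
    """
    if D <= 0 or r <= 0:
        raise ValueError("D and r must be positive")
    r_um = r * 1e-3
    return 4.0 * np.pi * D * r_um * AVOGADRO * 1e-15


def collision_rate(p: CollisionParams) -> float:
    """Collision rate dn/dt = k_on * (c_inf / M) in s⁻¹."""
    return k_on(p.D, p.r) * (p.c_inf / p.M)


# ---------------------------------------------------------------------------
# Critical overlap concentration

def overlap_concentration(p: OverlapConcParams) -> tuple[float, float]:
    """Critical overlap concentration c* = 3M / (4*pi*N_A*Rg³).

    Returns ``(c_star_g_per_cm3, weight_percent)`` where the weight
    percent assumes the configured solution density (default 1 g/cm³).
    """
    rg_cm = p.Rg * 1e-7
    c_star = 3.0 * p.M / (4.0 * np.pi * AVOGADRO * rg_cm ** 3)
    return c_star, 100.0 * c_star / p.density


# ---------------------------------------------------------------------------
# Guinier analysis

def guinier_fit(s: SaxsProfile, qmax_rg: float = 1.3, max_iter: int = 50) -> CurveFit:
    """Fit ln I(q) = ln I0 - (Rg²/3) q² on the Guinier regime.

    The fitted q-range is restricted iteratively to q*Rg <= ``qmax_rg``
    (refit, re-trim, repeat until the range is stable).  A non-negative
    slope means no Guinier decay and is an error.
    """
    mask = s.I > 0
    q2 = s.q[mask] ** 2
    lnI = np.log(s.I[mask])
    if mask.sum() < 4:
        raise ValueError("need at least 4 points with positive intensity")

    sel = np.ones(len(q2), dtype=bool)
    rg = None
    for _ in range(max_iter):
        if sel.sum() < 4:
            raise ValueError("fewer than 4 points remain inside the Guinier range")
        (slope, intercept), cov = np.polyfit(q2[sel], lnI[sel], 1, cov=True)
        if slope >= 0:
            raise ValueError("non-negative Guinier slope: profile shows no decay")
        rg_new = float(np.sqrt(-3.0 * slope))
        new_sel = np.sqrt(q2) * rg_new <= qmax_rg
        if rg is not None and np.array_equal(new_sel, sel):
            break
        sel = new_sel
        rg = rg_new

    slope_err, intercept_err = np.sqrt(np.diag(cov))
    rg = float(np.sqrt(-3.0 * slope))
    i0 = float(np.exp(intercept))
    resid = lnI[sel] - (intercept + slope * q2[sel])
    return CurveFit(
        params={"Rg": rg, "I0": i0},
        stderr={
            "Rg": float(1.5 * slope_err / rg),   # error propagation of Rg = sqrt(-3m)
            "I0": float(i0 * intercept_err),
        },
        residuals=resid,
        meta={"n_points": int(sel.sum()), "qmax_rg": qmax_rg},
    )


# ---------------------------------------------------------------------------
# Sliding-window HLB profile

def hlb_profile(chain: str, table, window: int = 5) -> np.ndarray:
    """Windowed-mean HLB along a chain (centred window, end-clipped).

    The value at position i averages the HLB of letters in the window of
    the given width centred on i, clipped to the chain ends, so the
    profile has the same length as the chain.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.array([table[c] for c in chain], dtype=float)
    half = window // 2
    out = np.empty(len(values))
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


# ---------------------------------------------------------------------------
# Worm-like chain

def wlc_force(x_over_lc: float, Lp: float, K: float = np.inf,
              T: float = 298.0, tol: float = 1e-6, max_iter: int = 500) -> float:
    """Extensible WLC force (pN) at fractional extension x/Lc.

    Marko–Siggia interpolation F = (kB*T/Lp) * [1/(4(1-xi)²) - 1/4 + xi]
    with xi = x/Lc - F/K, solved by damped fixed-point iteration to
    ``tol`` pN.  With K -> inf this reduces to the inextensible form.
    """
    if Lp <= 0 or T <= 0 or K <= 0:
        raise ValueError("Lp, T and K must be positive")
    if x_over_lc < 0:
        raise ValueError("x/Lc must be non-negative")
    if not np.isfinite(K) and x_over_lc >= 1.0:
        raise ValueError("x/Lc must be < 1 for the inextensible chain")
    kt_lp = KB_PN_NM * T / Lp

    def ms(xi: float) -> float:
        return kt_lp * (0.25 / (1.0 - xi) ** 2 - 0.25 + xi)

    F = max(ms(min(x_over_lc, 0.99)), 0.0) if np.isfinite(K) else ms(x_over_lc)
    if not np.isfinite(K):
        return max(F, 0.0)
    for _ in range(max_iter):
        xi = min(x_over_lc - F / K, 1.0 - 1e-9)
        F_new = max(ms(xi), 0.0)
        if abs(F_new - F) < tol:
            return F_new
        F = 0.5 * F + 0.5 * F_new   # damping keeps the iteration stable
    raise RuntimeError("WLC fixed-point iteration did not converge")


def wlc_curve(x: np.ndarray, Lc: float, Lp: float, K: float = np.inf,
              T: float = 298.0) -> np.ndarray:
    """Vectorized WLC force over an extension grid (nm)."""
    return np.array([wlc_force(xi / Lc, Lp, K=K, T=T) for xi in np.asarray(x, float)])


def unfolding_work(pull: ForceExtensionCurve,
                   baseline: ForceExtensionCurve) -> tuple[float, float]:
    """Work of the pull in excess of the baseline, over their shared range.

    Both curves are linearly interpolated onto a common extension grid and
    the difference integrated by the trapezoid rule.  Returns
    ``(work_pN_nm, work_kcal_per_mol)``.
    """
    lo = max(pull.x.min(), baseline.x.min())
    hi = min(pull.x.max(), baseline.x.max())
    if hi <= lo:
        raise ValueError("curves do not overlap in extension")
    grid = np.unique(np.concatenate([
        pull.x[(pull.x >= lo) & (pull.x <= hi)],
        baseline.x[(baseline.x >= lo) & (baseline.x <= hi)],
        [lo, hi],
    ]))
    f_pull = np.interp(grid, pull.x, pull.F)
    f_base = np.interp(grid, baseline.x, baseline.F)
    w = float(np.trapezoid(f_pull - f_base, grid))
    return w, w / PN_NM_PER_KCAL_MOL


def detect_rips(fec: ForceExtensionCurve, min_drop: float = 1.0,
                max_span: float = 5.0) -> list[tuple[float, float]]:
    """Locate unfolding rips: force drops > ``min_drop`` pN within
    < ``max_span`` nm of extension.  Descriptive only, not a calibrated
    classifier."""
    rips = []
    i = 0
    n = len(fec.x)
    while i < n - 1:
        j = i + 1
        while j < n and fec.x[j] - fec.x[i] < max_span:
            drop = fec.F[i] - fec.F[j]
            if drop > min_drop:
                rips.append((float(fec.x[j]), float(drop)))
                i = j
                break
            j += 1
        else:
            i += 1
            continue
    return rips


# ---------------------------------------------------------------------------
# FRAP

def frap_recovery(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Recovery series R(t) from region intensities.

    With r = I_b/I_u, r_before the pre-bleach mean and r_after(t) the
    post-bleach ratio series,

        R(t) = (r_after(t) - r_after(0)) / (r_before - r_after(0)),

    so R(0) = 0 by construction.  Post-bleach times are relative to the
    first post-bleach frame.
    """
    if trace.pre.sum() < 1 or (~trace.pre).sum() < 4:
        raise ValueError("need >= 1 pre-bleach and >= 4 post-bleach frames")
    r = trace.I_b / trace.I_u
    r_before = float(r[trace.pre].mean())
    r_after = r[~trace.pre]
    t_after = trace.t[~trace.pre]
    depth = r_before - r_after[0]
    if depth == 0:
        raise ValueError("no bleach depth: r_before equals r_after(0)")
    R = (r_after - r_after[0]) / depth
    return t_after - t_after[0], R


def frap_fit(trace: FrapTrace) -> CurveFit:
    """Fit the recovery to R(t) = A * (1 - exp(-t/tau)).

    A is the mobile fraction (bounded in [0, 1.5]); tau > 0 is the
    characteristic recovery time in seconds.
    """
    t, R = frap_recovery(trace)

    def model(tt, A, tau):
        return A * (1.0 - np.exp(-tt / tau))

    t_half_guess = max(t[len(t) // 2], t[1] if len(t) > 1 else 1.0, 1e-6)
    popt, pcov = curve_fit(
        model, t, R,
        p0=[max(R[-1], 0.1), t_half_guess],
        bounds=([0.0, 1e-9], [1.5, np.inf]),
        maxfev=20000,
    )
    perr = np.sqrt(np.diag(pcov))
    resid = R - model(t, *popt)
    return CurveFit(
        params={"A": float(popt[0]), "tau": float(popt[1])},
        stderr={"A": float(perr[0]), "tau": float(perr[1])},
        residuals=resid,
        meta={"n_post": len(t)},
    )


# ---------------------------------------------------------------------------
# Delimited-text readers

def read_xy(path: str | Path, n_cols: int = 2) -> np.ndarray:
    """Read whitespace/comma-delimited numeric columns ('#' comments)."""
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < n_cols:
            raise ValueError(f"{path}:{lineno}: expected {n_cols} columns")
        rows.append([float(v) for v in parts[:n_cols]])
    return np.array(rows)


def read_saxs(path: str | Path) -> SaxsProfile:
    data = read_xy(path, n_cols=2)
    return SaxsProfile(q=data[:, 0], I=data[:, 1])


def read_fec(path: str | Path, phase: str = "pull") -> ForceExtensionCurve:
    data = read_xy(path, n_cols=2)
    return ForceExtensionCurve(x=data[:, 0], F=data[:, 1], phase=phase)


def read_frap(path: str | Path, n_prebleach: int | None = None) -> FrapTrace:
    """Read a (t, I_b, I_u[, pre-flag]) FRAP trace.

    A fourth 0/1 column marks pre-bleach frames; alternatively pass
    ``n_prebleach`` for a 3-column file.
    """
    raw = read_xy(path, n_cols=3)
    try:
        raw4 = read_xy(path, n_cols=4)
        pre = raw4[:, 3] > 0.5
    except ValueError:
        if n_prebleach is None:
            raise ValueError("3-column FRAP file needs n_prebleach")
        pre = np.zeros(len(raw), dtype=bool)
        pre[:n_prebleach] = True
    return FrapTrace(t=raw[:, 0], I_b=raw[:, 1], I_u=raw[:, 2], pre=pre)
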