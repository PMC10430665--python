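"""Gs/cAMP signal-transduction simulation and dose-response ranking.

A candidate's predicted affinity (pKd) is converted into equilibrium
receptor occupancy, which drives a minimal mass-action Gs cascade:

    d[G*]/dt   = k_G_act * (f_ag * R_tot) * [G] - k_G_hyd * [G*]
    d[G]/dt    = -d[G*]/dt                      (G-protein conserved)
    d[ATP]/dt  = -k_AC_cat * [G*] * [ATP]
    d[cAMP]/dt = k_AC_cat * [G*] * [ATP] + k_basal
                 - k_PDE * [PDE] * [cAMP]

where f_ag is the fraction of receptors bound by an *activating* ligand,
held at its equilibrium value (quasi-equilibrium binding, no binding
kinetics).  The basal synthesis rate k_basal is chosen so that zero
occupancy is a fixed point at the basal cAMP level.  Running the cascade
over a log-spaced ligand-concentration grid (default 1e-3 to 1e3 uM, 24
points, receptor at 2 uM) yields a dose-response curve of the cAMP
change versus the zero-dose baseline, which a Hill fit condenses into
(top, bottom, x50, slope) for potency ranking.

Antagonist mode simulates competition against a reference agonist tone
(default: agonist at its EC80): rising antagonist dose displaces the
agonist, and the response falls monotonically toward full suppression.

Rate constants are placeholders with plausible magnitudes, exposed in
:class:`CascadeParameters`; the simulation is used for qualitative
potency ranking (curve positions and shapes), not absolute cAMP levels.
Concentrations are in uM, rates in 1/s or 1/(uM*s), time in seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class Affinity:
    """Ligand affinity as pKd = -log10(Kd / M)."""

    pKd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pKd):
            raise ValueError("pKd must be finite")

    @property
    def Kd_molar(self) -> float:
        return 10.0 ** (-self.pKd)

    @property
    def Kd_uM(self) -> float:
        return self.Kd_molar * 1e6

    @classmethod
    def from_Kd_nM(cls, kd_nM: float) -> "Affinity":
        return cls(pKd=-math.log10(kd_nM * 1e-9))


def occupancy(affinity: Affinity, ligand_conc_uM: float) -> float:
    """Equilibrium fraction of receptors bound: L / (L + Kd)."""
    if ligand_conc_uM < 0:
        raise ValueError("ligand concentration must be >= 0")
    return ligand_conc_uM / (ligand_conc_uM + affinity.Kd_uM)


def competitive_occupancy(affinity_ligand: Affinity, affinity_agonist: Affinity,
                          L_uM: float, A_uM: float) -> tuple[float, float]:
    """Two-ligand competition at equilibrium.

    Returns (fraction bound by the ligand, fraction bound by the agonist):
    f_X = (X/KdX) / (1 + L/KdL + A/KdA).
    """
    if L_uM < 0 or A_uM < 0:
        raise ValueError("concentrations must be >= 0")
    kdl, kda = affinity_ligand.Kd_uM, affinity_agonist.Kd_uM
    if kdl == 0 and kda == 0:
        raise ValueError("both Kd values are zero")
    denom = 1.0 + L_uM / kdl + A_uM / kda
    return (L_uM / kdl) / denom, (A_uM / kda) / denom


@dataclass(frozen=True)
class CascadeParameters:
    """Species pools, rate constants and the optional agonist tone.

    Defaults give sub-minute G-protein and cAMP relaxation with modest
    ATP consumption, so the reported end-time response is near steady
    state on the default 100 s window.
    """

    receptor_total_uM: float = 2.0
    g_total_uM: float = 10.0
    atp_uM: float = 1000.0
    camp_basal_uM: float = 0.1
    pde_uM: float = 1.0
    k_G_act: float = 0.1      # 1/(uM*s), per occupied receptor
    k_G_hyd: float = 0.5      # 1/s
    k_AC_cat: float = 2e-4    # 1/(uM*s)
    k_PDE: float = 1.0        # 1/(uM*s), scaled by the PDE pool
    agonist_tone: Optional[tuple[float, float]] = None  # (conc uM, pKd)

    def __post_init__(self) -> None:
        for name in ("receptor_total_uM", "g_total_uM", "atp_uM",
                     "camp_basal_uM", "pde_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("k_G_act", "k_G_hyd", "k_AC_cat", "k_PDE"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def k_basal(self) -> float:
        """Basal cAMP synthesis balancing degradation at the basal level."""
        return self.k_PDE * self.pde_uM * self.camp_basal_uM


@dataclass(frozen=True)
class DoseGrid:
    """Log-spaced ligand concentrations, default 1e-3 to 1e3 uM, 24 points."""

    concentrations_uM: tuple[float, ...] = tuple(
        float(c) for c in np.logspace(-3, 3, 24))

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_uM)
        if len(c) == 0 or (c <= 0).any() or (np.diff(c) <= 0).any():
            raise ValueError("grid must be strictly increasing and positive")

    @classmethod
    def make(cls, lo_uM: float = 1e-3, hi_uM: float = 1e3, n: int = 24
             ) -> "DoseGrid":
        return cls(tuple(float(c) for c in np.logspace(
            math.log10(lo_uM), math.log10(hi_uM), n)))


@dataclass
class HillFit:
    top: float
    bottom: float
    x50_uM: Optional[float]   # EC50/IC50; None when degenerate
    hill_n: Optional[float]
    degenerate: bool = False
    out_of_grid: bool = False


@dataclass
class DoseResponseCurve:
    molecule_id: str
    doses_uM: np.ndarray
    responses_uM: np.ndarray  # cAMP change at end time vs zero-dose baseline
    t_end: float
    mode: str                 # "agonist" | "antagonist"
    hill_fit: Optional[HillFit] = None


def simulate_cascade(params: CascadeParameters, bound_agonist_fraction: float,
                     t_end: float = 100.0, n_steps: int = 1000,
                     camp0_uM: Optional[float] = None, rtol: float = 1e-8,
                     atol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the cascade at a fixed activating occupancy.

    Returns (time grid of ``n_steps`` points, cAMP time course).  The
    output grid interprets the 1000-step convention as reporting points;
    an adaptive stiff-aware integrator runs underneath, so halving the
    reporting step leaves the trajectory unchanged to < 0.1 %.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if not 0.0 <= bound_agonist_fraction <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    r_act = bound_agonist_fraction * params.receptor_total_uM
    camp0 = params.camp_basal_uM if camp0_uM is None else camp0_uM

    def rhs(_t: float, yv: np.ndarray) -> list[float]:
        g_act, atp, camp = yv
        g_inact = max(params.g_total_uM - g_act, 0.0)
        dg = params.k_G_act * r_act * g_inact - params.k_G_hyd * g_act
        synth = params.k_AC_cat * g_act * max(atp, 0.0)
        datp = -synth
        dcamp = synth + params.k_basal - params.k_PDE * params.pde_uM * camp
        return [dg, datp, dcamp]

    t_eval = np.linspace(0.0, t_end, n_steps)
    sol = solve_ivp(rhs, (0.0, t_end), [0.0, params.atp_uM, camp0],
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"cascade integration failed: {sol.message}")
    camp = np.maximum(sol.y[2], 0.0)
    return t_eval, camp


def _end_camp(params: CascadeParameters, frac: float, t_end: float,
              n_steps: int) -> float:
    _, camp = simulate_cascade(params, frac, t_end=t_end, n_steps=n_steps)
    return float(camp[-1])


def agonist_ec80_uM(params: CascadeParameters, affinity: Affinity) -> float:
    """Dose occupying 80 % of receptors: occupancy EC80 = 4 * Kd."""
    return 4.0 * affinity.Kd_uM


def dose_response(params: CascadeParameters, affinity: Affinity,
                  grid: DoseGrid | None = None, mode: str = "agonist",
                  t_end: float = 100.0, n_steps: int = 1000,
                  molecule_id: str = "", fit: bool = True
                  ) -> DoseResponseCurve:
    """Simulated cAMP dose-response curve for one candidate.

    Agonist mode: the candidate itself activates; response rises with
    dose.  Antagonist mode: a reference agonist tone (``params.
    agonist_tone``, (concentration uM, pKd)) sets an elevated baseline
    and the candidate competes it off; response falls with dose toward
    full suppression.  In both modes the response at dose L is
    cAMP_end(L) - cAMP_end(0).
    """
    grid = grid or DoseGrid()
    if mode not in ("agonist", "antagonist"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "antagonist" and params.agonist_tone is None:
        raise ValueError("antagonist mode requires params.agonist_tone")

    def frac_active(L: float) -> float:
        if mode == "agonist":
            return occupancy(affinity, L)
        tone_conc, tone_pkd = params.agonist_tone  # type: ignore[misc]
        _, f_ag = competitive_occupancy(affinity, Affinity(tone_pkd),
                                        L, tone_conc)
        return f_ag

    baseline = _end_camp(params, frac_active(0.0), t_end, n_steps)
    doses = np.asarray(grid.concentrations_uM)
    responses = np.array([
        _end_camp(params, frac_active(L), t_end, n_steps) - baseline
        for L in doses])
    curve = DoseResponseCurve(molecule_id=molecule_id, doses_uM=doses,
                              responses_uM=responses, t_end=t_end, mode=mode)
    if fit:
        curve.hill_fit = fit_hill(curve)
    return curve


def hill(L: np.ndarray, top: float, bottom: float, x50: float, n: float
         ) -> np.ndarray:
    """4-parameter logistic: bottom + (top - bottom) / (1 + (x50/L)^n)."""
    return bottom + (top - bottom) / (1.0 + (x50 / L) ** n)


def fit_hill(curve: DoseResponseCurve) -> HillFit:
    """Least-squares Hill fit of a dose-response curve.

    Returns a degenerate flag (no x50) for flat curves, and flags fits
    whose x50 falls outside the dose grid as unreliable.
    """
    L = np.asarray(curve.doses_uM, dtype=float)
    y = np.asarray(curve.responses_uM, dtype=float)
    if len(L) < 5:
        raise ValueError("need >= 5 dose points for a Hill fit")
    span = float(y.max() - y.min())
    scale = max(abs(y.max()), abs(y.min()), 1e-30)
    if span < 1e-6 * scale or span == 0.0:
        return HillFit(top=float(y.mean()), bottom=float(y.mean()),
                       x50_uM=None, hill_n=None, degenerate=True)
    # initial guesses from the curve shape
    bottom0, top0 = float(y[0]), float(y[-1])
    half = (bottom0 + top0) / 2.0
    idx = int(np.argmin(np.abs(y - half)))
    x50_0 = float(L[idx])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                hill, L, y, p0=[top0, bottom0, x50_0, 1.0],
                bounds=([-np.inf, -np.inf, L[0] / 1e3, 0.05],
                        [np.inf, np.inf, L[-1] * 1e3, 10.0]),
                maxfev=20000)
    except RuntimeError:
        return HillFit(top=top0, bottom=bottom0, x50_uM=None, hill_n=None,
                       degenerate=True)
    top, bottom, x50, n = (float(v) for v in popt)
    return HillFit(top=top, bottom=bottom, x50_uM=x50, hill_n=n,
                   out_of_grid=not (L[0] <= x50 <= L[-1]))


def affinity_gate(pKds: Sequence[Optional[float]], min_pKd: float = 5.5
                  ) -> list[int]:
    """Indices of candidates whose predicted pKd meets the affinity floor.

    Boundary inclusive (pKd >= min_pKd retained); pKd 5.5 corresponds to
    Kd = 10^-5.5 M ~ 3.16 uM.  A missing pKd is an error naming the
    candidate position.
    """
    out = []
    for i, pkd in enumerate(pKds):
        if pkd is None or (isinstance(pkd, float) and math.isnan(pkd)):
            raise ValueError(f"candidate at index {i} has no predicted pKd")
        if pkd >= min_pKd:
            out.append(i)
    if not out:
        warnings.warn("affinity gate removed every candidate",
                      RuntimeWarning, stacklevel=2)
    return out


def plot_dose_response(curves: Sequence[DoseResponseCurve], path: str,
                       title: str = "simulated cAMP dose-response") -> None:
    """Render dose-response curves (log-dose axis) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.semilogx(curve.doses_uM, curve.responses_uM, marker="o",
                    markersize=3, label=curve.molecule_id or None)
    ax.set_xlabel("ligand concentration (uM)")
    ax.set_ylabel("cAMP change (uM)")
    ax.set_title(title)
    if any(c.molecule_id for c in curves):
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def linear_cascade_camp(params: CascadeParameters, bound_agonist_fraction: float,
                        t: np.ndarray) -> np.ndarray:
    """Closed-form cAMP course of the linearized cascade (constant ATP).

    With ATP pinned at its initial value the system is linear:
    G*(t) relaxes exponentially to its fixed point and cAMP follows a
    first-order equation with exponential forcing.  Used as the analytic
    reference for integrator verification in the no-depletion regime.
    """
    a = params.k_G_act * bound_agonist_fraction * params.receptor_total_uM
    h = params.k_G_hyd
    lam = a + h
    g_ss = params.g_total_uM * a / lam if lam > 0 else 0.0
    c = params.k_AC_cat * params.atp_uM
    kd = params.k_PDE * params.pde_uM
    # cAMP' = c*G*(t) + k_basal - kd*cAMP,  G*(t) = g_ss*(1 - exp(-lam t))
    camp_ss = (c * g_ss + params.k_basal) / kd
    t = np.asarray(t, dtype=float)
    if lam == kd:
        # resonant case: particular solution carries a t*exp(-kd t) term
        forced = c * g_ss * t * np.exp(-kd * t)
        return camp_ss - (camp_ss - params.camp_basal_uM) * np.exp(-kd * t) - forced
    transient = c * g_ss / (kd - lam) * (np.exp(-lam * t) - np.exp(-kd * t))
    homog = (params.camp_basal_uM - camp_ss) * np.exp(-kd * t)
    return camp_ss + homog - transient
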