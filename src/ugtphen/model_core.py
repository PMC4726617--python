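"""Structural PK model: transit-compartment oral absorption of raltegravir,
first-order elimination, and fractional conversion to its glucuronide.

The parent drug is absorbed through a chain of hypothetical transit
compartments (mean transit time ``MTT``, a continuous number ``NN`` of
compartments, realized through the analytic gamma input function), then a
depot with first-order rate ``ka`` feeding a single central compartment with
apparent clearance ``CL/F`` and volume ``V/F``.  A fraction ``FMET`` of
parent clearance forms the glucuronide, which is modelled directly in
concentration units against a distribution volume fixed to 1 L and cleared
with first-order clearance ``CL_GLU``.  Because the metabolite volume is a
fixed convention rather than a measured quantity, ``FMET`` is interpreted as
the ratio of glucuronide formation rate to that unit volume — its literal
"fraction" reading is therefore unit-dependent.

The derived phenotyping constants are

    k23 = FMET * (CL/F) / (V/F)       (glucuronide formation, 1/h)
    k12 = 0.6 * CL / V                (1-OH-midazolam formation, 1/h)

k23 summarizes in vivo UGT1A1 glucuronidation activity; k12 plays the same
role for CYP3A4 with midazolam as the probe (the 0.6 is the assumed
conversion fraction of midazolam to 1-OH-midazolam).

Units package-wide: hours, mg, litres, mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import special
from scipy.integrate import solve_ivp

from . import _kinetics

__all__ = [
    "ANALYTES",
    "StructuralParams",
    "DoseEvent",
    "ConcentrationProfile",
    "transit_rate_constant",
    "transit_input_rate",
    "simulate_profile",
    "k23",
    "k12_midazolam",
]

#: Analytes the package knows about.
ANALYTES = (
    "raltegravir",
    "raltegravir_glucuronide",
    "midazolam",
    "1OH_midazolam",
    "irinotecan",
    "SN38",
    "SN38G",
)


@dataclass(frozen=True)
class StructuralParams:
    """Fixed-effect parameters of the raltegravir–glucuronide model.

    Parameters
    ----------
    cl_f : float
        Apparent oral clearance of the parent, CL/F (L/h).
    v_f : float
        Apparent central volume of the parent, V/F (L).
    ka : float
        First-order absorption rate constant (1/h).
    mtt : float
        Mean transit time of the absorption delay chain (h).
    nn : float
        Number of hypothetical transit compartments (dimensionless, >= 0,
        continuous).
    f : float
        Oral bioavailability, fixed to 1 by convention (relative
        bioavailability interpretation; sampled individual values may
        exceed 1).
    fmet : float
        Fraction of parent clearance forming the glucuronide, under the
        1 L metabolite-volume convention.
    cl_glu : float
        Glucuronide clearance (L/h).
    v_glu : float
        Glucuronide distribution volume (L), fixed to 1 by convention.
    """

    cl_f: float
    v_f: float
    ka: float
    mtt: float
    nn: float
    f: float = 1.0
    fmet: float = 0.0324
    cl_glu: float = 0.715
    v_glu: float = 1.0

    def __post_init__(self):
        for name in ("cl_f", "v_f", "ka", "mtt", "cl_glu", "v_glu"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.nn < 0.0:
            raise ValueError("nn must be >= 0")
        if not 0.0 < self.fmet <= 1.0:
            raise ValueError("fmet must be in (0, 1]")
        if not 0.0 < self.f <= 1.0:
            raise ValueError("f must be in (0, 1] at the population level")

    def replace(self, **kw) -> "StructuralParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: ``amount`` mg given at ``time`` h."""

    time: float
    amount: float
    route: str = "oral"

    def __post_init__(self):
        if self.amount < 0.0:
            raise ValueError("dose amount must be >= 0")
        if self.time < 0.0:
            raise ValueError("dose time must be >= 0")


@dataclass
class ConcentrationProfile:
    """One subject x one analyte concentration–time series with dose events."""

    subject_id: str
    analyte: str
    times: np.ndarray
    concentrations: np.ndarray
    doses: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self):
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


def transit_rate_constant(mtt: float, nn: float) -> float:
    """Transit rate constant ktr = (NN + 1) / MTT (1/h).

    ``MTT`` is the mean time a molecule spends in the chain of ``NN``
    transit compartments plus the depot stage, each with rate ``ktr``.
    """
    if not mtt > 0.0:
        raise ValueError("mtt must be strictly positive")
    if nn < 0.0:
        raise ValueError("nn must be >= 0")
    return (nn + 1.0) / mtt


def transit_input_rate(t, dose: float, f: float, ktr: float, nn: float):
    """Drug input rate (mg/h) into the depot at time ``t`` since dose.

    rate(t) = dose*f*ktr*(ktr t)**nn * exp(-ktr t) / Gamma(nn+1); the gamma
    density form lets ``nn`` be continuous, and the rate integrates to
    ``dose * f`` over [0, inf).
    """
    return _kinetics.gamma_input_rate(t, dose, f, ktr, nn)


def _ode_rhs(t, y, doses, p: StructuralParams, ktr: float):
    a_d, a_c, c_m, _elim = y
    rate = 0.0
    for d in doses:
        if t >= d.time:
            rate += float(_kinetics.gamma_input_rate(t - d.time, d.amount,
                                                     p.f, ktr, p.nn))
    k = p.cl_f / p.v_f
    km = p.cl_glu / p.v_glu
    return [
        rate - p.ka * a_d,
        p.ka * a_d - k * a_c,
        p.fmet * k * a_c / p.v_glu - km * c_m,
        k * a_c,  # cumulative parent elimination (incl. metabolized fraction)
    ]


def simulate_profile(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    subject_id: str = "sim",
    method: str = "analytic",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[ConcentrationProfile, ConcentrationProfile]:
    """Simulate parent and metabolite concentrations at the requested times.

    Solves the depot/central/metabolite ODE system

        dA_d/dt = input(t) - ka*A_d
        dA_c/dt = ka*A_d - (CL/V)*A_c
        dC_m/dt = FMET*(CL/V)*A_c/V_glu - (CL_glu/V_glu)*C_m

    with the gamma transit input.  ``method="analytic"`` (default) evaluates
    the exact convolution solution; ``method="ivp"`` integrates numerically
    with a stiff-capable solver (LSODA) and dense output.  Returns
    ``(parent, metabolite)`` profiles; parent concentration is A_c / (V/F).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")

    dose_times = [d.time for d in doses]
    dose_amounts = [d.amount for d in doses]

    if method == "analytic":
        cp, cm = _kinetics.conc_profile(
            times, dose_times, dose_amounts,
            params.cl_f, params.v_f, params.ka, params.mtt, params.nn,
            params.f, params.fmet, params.cl_glu, params.v_glu,
        )
    elif method == "ivp":
        ktr = transit_rate_constant(params.mtt, params.nn)
        t_end = float(times[-1]) if len(times) else 0.0
        if t_end == 0.0 or not dose_amounts or sum(dose_amounts) == 0.0:
            cp = np.zeros_like(times)
            cm = np.zeros_like(times)
        else:
            sol = solve_ivp(
                _ode_rhs, (0.0, t_end), [0.0, 0.0, 0.0, 0.0],
                args=(list(doses), params, ktr),
                method="LSODA", dense_output=True, rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"ODE solver failed: {sol.message}")
            y = sol.sol(times)
            cp = np.maximum(y[1] / params.v_f, 0.0)
            cm = np.maximum(y[2], 0.0)
        if np.any(~np.isfinite(cp)) or np.any(~np.isfinite(cm)):
            raise RuntimeError("ODE solution contains non-finite values")
    else:
        raise ValueError(f"unknown method {method!r}")

    parent = ConcentrationProfile(subject_id, "raltegravir", times,
                                  np.asarray(cp, float), list(doses))
    metab = ConcentrationProfile(subject_id, "raltegravir_glucuronide", times,
                                 np.asarray(cm, float), list(doses))
    return parent, metab


def simulate_amounts_ivp(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> dict[str, np.ndarray]:
    """Numerically integrate the full state, including cumulative elimination.

    Returns depot amount, central amount, metabolite concentration,
    cumulative parent amount eliminated, and the cumulative transit-chain
    input (mg) at each time — the pieces of the mass-balance identity
    depot + central + eliminated == delivered, and
    delivered + in-flight == F * total dose.
    """
    times = np.asarray(times, dtype=float)
    ktr = transit_rate_constant(params.mtt, params.nn)
    sol = solve_ivp(
        _ode_rhs, (0.0, float(times[-1])), [0.0, 0.0, 0.0, 0.0],
        args=(list(doses), params, ktr),
        method="LSODA", dense_output=True, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    y = sol.sol(times)
    delivered = np.zeros_like(times)
    for d in doses:
        dt = np.maximum(times - d.time, 0.0)
        delivered += d.amount * params.f * special.gammainc(params.nn + 1.0, ktr * dt)
    return {
        "depot": y[0],
        "central": y[1],
        "metabolite_conc": y[2],
        "eliminated": y[3],
        "delivered": delivered,
    }


def k23(params: StructuralParams) -> float:
    """Glucuronide formation rate constant k23 = FMET * (CL/F) / (V/F) (1/h).

    The phenotyping metric: a subject's in vivo UGT1A1 glucuronidation
    activity summarized from their individual parameter estimates.
    Dimensionless-scaling invariant: unchanged when clearance and volume are
    scaled together.
    """
    return params.fmet * params.cl_f / params.v_f


def k12_midazolam(cl: float, v: float) -> float:
    """1-OH-midazolam formation rate constant k12 = 0.6 * CL / V (1/h).

    ``cl`` and ``v`` are midazolam clearance (L/h) and central volume (L);
    0.6 is the assumed midazolam-to-metabolite conversion fraction.
    """
    if not (cl > 0.0 and v > 0.0):
        raise ValueError("cl and v must be strictly positive")
    return 0.6 * cl / v
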