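"""Non-compartmental analysis: AUC, terminal slope, clearance, AUC ratios.

Model-free exposure summaries per subject and analyte.  The default AUC
rule is linear-up/log-down (linear trapezoid on rising or flat segments,
log trapezoid on strictly decreasing positive segments), the common
pharmacometric convention; pure linear is available.  Terminal slope
selection is automated: among candidate terminal windows of >= 3 points
(always including the last positive observation), the one maximizing
adjusted R^2 of the log-linear regression wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ConcentrationProfile

__all__ = ["NCAResult", "auc_trapezoid", "terminal_slope", "nca_summary",
           "metabolic_ratio"]


@dataclass
class NCAResult:
    """NCA summary for one profile.  Fields are NaN when not estimable."""

    auc_last: float
    auc_inf: float = float("nan")
    lambda_z: float = float("nan")
    t_half: float = float("nan")
    cl_or_cl_f: float = float("nan")
    n_lambda_points: int = 0
    r2_lambda: float = float("nan")

    @property
    def extrapolated_fraction(self) -> float:
        """(auc_inf - auc_last) / auc_inf; NaN when auc_inf unavailable."""
        if not np.isfinite(self.auc_inf) or self.auc_inf <= 0:
            return float("nan")
        return (self.auc_inf - self.auc_last) / self.auc_inf


def auc_trapezoid(profile: ConcentrationProfile,
                  method: str = "linear-up/log-down") -> float:
    """AUC from first to last observation (mg·h/L) by trapezoidal rules.

    ``"linear"`` applies the linear trapezoid everywhere.
    ``"linear-up/log-down"`` switches to the log trapezoid
    ``(c1 - c2) * dt / ln(c1/c2)`` on segments where concentration strictly
    decreases through positive values (exact for mono-exponential decline);
    segments touching a zero fall back to linear.
    """
    t = profile.times
    c = profile.concentrations
    if len(t) < 2:
        raise ValueError("need >= 2 time points for AUC")
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    linear = (c1 + c2) * dt / 2.0
    if method == "linear":
        return float(np.sum(linear))
    if method != "linear-up/log-down":
        raise ValueError(f"unknown AUC method {method!r}")
    down = (c2 < c1) & (c2 > 0.0)
    seg = linear.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        logseg = (c1 - c2) * dt / np.log(c1 / c2)
    seg[down] = logseg[down]
    return float(np.sum(seg))


def terminal_slope(profile: ConcentrationProfile,
                   min_points: int = 3) -> tuple[float, float, int]:
    """Terminal elimination slope lambda_z (1/h) by log-linear regression.

    Candidate windows are the last ``m`` strictly positive observations
    after the profile maximum (m = min_points .. all available); the window
    maximizing adjusted R^2 is selected, the last point always included.
    Returns ``(lambda_z, r2, n_points)``.

    Raises ``ValueError`` when fewer than ``min_points`` positive terminal
    concentrations exist or no window yields a negative slope.
    """
    t = profile.times
    c = profile.concentrations
    pos = c > 0.0
    if pos.sum() < min_points:
        raise ValueError("need >= 3 strictly positive terminal concentrations")
    i_max = int(np.argmax(c))
    # terminal candidates: positive observations at/after tmax (tmax itself
    # admitted only when points are scarce)
    idx = np.flatnonzero(pos & (np.arange(len(c)) >= i_max))
    if len(idx) < min_points:
        idx = np.flatnonzero(pos)
    if not pos[-1] or len(idx) < min_points:
        raise ValueError("no usable positive terminal segment")
    best = None
    for m in range(min_points, len(idx) + 1):
        sel = idx[-m:]
        x, y = t[sel], np.log(c[sel])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0.0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        if best is None or adj > best[0] + 1e-12:
            best = (adj, -slope, r2, m)
    if best is None:
        raise ValueError("terminal slope not estimable (no declining window)")
    _, lam, r2, m = best
    return float(lam), float(r2), int(m)


def nca_summary(profile: ConcentrationProfile, dose: float | None = None,
                method: str = "linear-up/log-down") -> NCAResult:
    """Full NCA for one profile: AUC_last, lambda_z, AUC_inf, t1/2, CL(/F).

    AUC_inf = AUC_last + C_last / lambda_z; clearance = dose / AUC_inf when
    the dose is known.  Terminal-slope failures leave the extrapolated
    quantities NaN rather than raising — the AUC_last row is still useful.
    """
    res = NCAResult(auc_last=auc_trapezoid(profile, method))
    try:
        lam, r2, m = terminal_slope(profile)
    except ValueError:
        return res
    c_last = profile.concentrations[-1]
    res.lambda_z = lam
    res.r2_lambda = r2
    res.n_lambda_points = m
    res.t_half = float(np.log(2.0) / lam)
    res.auc_inf = res.auc_last + float(c_last) / lam
    if dose is not None and res.auc_inf > 0:
        res.cl_or_cl_f = dose / res.auc_inf
    return res


def metabolic_ratio(metabolite: NCAResult, parent: NCAResult) -> tuple[float, str]:
    """Metabolite/parent AUC ratio, the NCA-level phenotyping index.

    Prefers AUC(0->inf) when both are available, otherwise falls back to
    AUC(0->last); returns ``(ratio, basis)`` with basis ``"auc_inf"`` or
    ``"auc_last"`` so reports can flag which was used.
    """
    if (np.isfinite(metabolite.auc_inf) and np.isfinite(parent.auc_inf)
            and parent.auc_inf > 0):
        return metabolite.auc_inf / parent.auc_inf, "auc_inf"
    if parent.auc_last > 0:
        return metabolite.auc_last / parent.auc_last, "auc_last"
    raise ValueError("parent AUC is zero; ratio undefined")
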