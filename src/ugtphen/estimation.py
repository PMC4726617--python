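"""Nonlinear mixed-effects estimation for the parent–metabolite model.

The estimator is a FOCE-I/Laplace-style approximate marginal likelihood:
for each subject the random-effect vector eta is set to its conditional
mode (penalized weighted log-residual least squares, solved by a damped
Gauss-Newton iteration vectorized across the whole cohort), and the
marginal likelihood is approximated by the Laplace formula with either the
Gauss-Newton curvature (``method="foce_i"``) or a finite-difference Hessian
(``method="laplace"``).  The objective function value (OFV) is -2 log L
including all constants.

Fixed effects are optimized on the log scale (positivity by construction),
IIV standard deviations on the log scale, the CL-V correlation through
atanh, so the outer problem is unconstrained; it is driven by a damped
BFGS with Armijo backtracking and batched central-difference gradients.
Standard errors come from the inverse finite-difference Hessian of the OFV
at the optimum, reported as percent relative standard errors (RSE).

The covariate search reproduces the classical stepwise procedure: greedy
forward inclusion at dOFV >= 3.84 per candidate (with a mandatory decline
in the unexplained IIV of the affected parameter), then backward
elimination of any covariate whose removal costs < 10.8 OFV points.

Observation model: additive residual error on log concentrations, one SD
per analyte.  Pre-dose/zero concentrations carry no log-scale information
and are excluded from the likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from . import _kinetics
from .model_core import ConcentrationProfile, StructuralParams
from .population import (IIV_PARAMS, IndividualParams, PopulationModel,
                         cv_to_omega, eta_shrinkage, omega_to_cv)

__all__ = [
    "CovariateEffect",
    "PopulationFit",
    "CovariateSearchResult",
    "fit_individual",
    "ofv",
    "fit_population",
    "covariate_search",
    "forward_admissible",
    "backward_retained",
    "format_fit_report",
]

STRUCTURAL_FREE = ("cl_f", "v_f", "ka", "mtt", "nn", "fmet", "cl_glu")

#: OFV drop required to add a covariate in the forward step (chi2, p<0.05).
FORWARD_DOFV = 3.84
#: OFV rise required to keep a covariate in the backward step (p<0.001).
BACKWARD_DOFV = 10.8

_PRED_FLOOR = 1e-12
_ETA_FD_STEP = 1e-5


class EstimationWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# covariate effects

@dataclass
class CovariateEffect:
    """One covariate-parameter relation with multiplier semantics.

    form "power":      theta_i *= (cov / ref) ** beta
    form "linear":     theta_i *= 1 + beta * (cov - ref) / ref
    form "fractional": theta_i *= 1 + beta   for the non-reference category
                       of a binary covariate (0 = reference).
    ``ref`` defaults to the cohort median (continuous) or 0 (categorical).
    """

    parameter: str
    covariate: str
    form: str
    beta: float = 0.0
    ref: float = float("nan")

    def label(self) -> str:
        return f"{self.covariate}->{self.parameter}({self.form})"

    def resolve_ref(self, values: np.ndarray) -> "CovariateEffect":
        if np.isfinite(self.ref):
            return self
        ref = 0.0 if self.form == "fractional" else float(np.median(values))
        return CovariateEffect(self.parameter, self.covariate, self.form,
                               self.beta, ref)

    def multiplier(self, values: np.ndarray, beta: float) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.form == "power":
            return np.power(np.maximum(v / self.ref, 1e-12), beta)
        if self.form == "linear":
            return np.maximum(1.0 + beta * (v - self.ref) / max(abs(self.ref), 1e-12),
                              1e-6)
        if self.form == "fractional":
            return np.where(v != self.ref, np.maximum(1.0 + beta, 1e-6), 1.0)
        raise ValueError(f"unknown covariate form {self.form!r}")


# ---------------------------------------------------------------------------
# cohort data layout

class _Cohort:
    """Padded array view of a list of (parent, metabolite) profile pairs."""

    def __init__(self, data: Sequence[tuple[ConcentrationProfile, ConcentrationProfile]]):
        self.n = len(data)
        if self.n == 0:
            raise ValueError("empty cohort")
        self.subject_ids = []
        times, masks_p, masks_m, logs_p, logs_m, doses = [], [], [], [], [], []
        for parent, metab in data:
            if parent.subject_id != metab.subject_id:
                raise ValueError("profile pair must belong to one subject")
            self.subject_ids.append(parent.subject_id)
            t = np.union1d(parent.times, metab.times)
            lp = np.full(t.shape, np.nan)
            lm = np.full(t.shape, np.nan)
            for prof, log_arr in ((parent, lp), (metab, lm)):
                usable = (prof.concentrations > 0.0) & (prof.times > 0.0)
                idx = np.searchsorted(t, prof.times[usable])
                log_arr[idx] = np.log(prof.concentrations[usable])
            times.append(t)
            logs_p.append(lp)
            logs_m.append(lm)
            masks_p.append(~np.isnan(lp))
            masks_m.append(~np.isnan(lm))
            doses.append([(d.time, d.amount) for d in parent.doses])
            if not parent.doses or sum(d.amount for d in parent.doses) == 0.0:
                raise ValueError(
                    f"subject {parent.subject_id}: no non-zero dose event; "
                    "profile carries no information")
            if np.any(masks_p[-1] | masks_m[-1]):
                first = t[masks_p[-1] | masks_m[-1]][0]
                if first < min(d.time for d in parent.doses):
                    raise ValueError(
                        f"subject {parent.subject_id}: observation before first dose")
        m = max(len(t) for t in times)
        nd = max(len(d) for d in doses)
        self.t = np.zeros((self.n, m))
        self.lp = np.zeros((self.n, m))
        self.lm = np.zeros((self.n, m))
        self.mp = np.zeros((self.n, m), dtype=bool)
        self.mm = np.zeros((self.n, m), dtype=bool)
        self.dose_t = np.zeros((self.n, nd))
        self.dose_a = np.zeros((self.n, nd))
        for i, t in enumerate(times):
            k = len(t)
            self.t[i, :k] = t
            self.lp[i, :k] = np.nan_to_num(logs_p[i])
            self.lm[i, :k] = np.nan_to_num(logs_m[i])
            self.mp[i, :k] = masks_p[i]
            self.mm[i, :k] = masks_m[i]
            for j, (td, amt) in enumerate(doses[i]):
                self.dose_t[i, j] = td
                self.dose_a[i, j] = amt
        self.n_obs = self.mp.sum() + self.mm.sum()
        self.n_obs_i = self.mp.sum(axis=1) + self.mm.sum(axis=1)
        if np.any(self.n_obs_i == 0):
            bad = [self.subject_ids[i] for i in np.flatnonzero(self.n_obs_i == 0)]
            raise ValueError(f"subjects with no usable observations: {bad}")

    def simulate(self, fields: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Cohort-vectorized model prediction at the padded times."""
        col = {k: v[:, None] for k, v in fields.items()}
        cp = np.zeros_like(self.t)
        cm = np.zeros_like(self.t)
        for j in range(self.dose_t.shape[1]):
            p, m = _kinetics.conc_single_dose(
                self.t - self.dose_t[:, j:j + 1], self.dose_a[:, j:j + 1],
                col["cl_f"], col["v_f"], col["ka"], col["mtt"], col["nn"],
                col["f"], col["fmet"], col["cl_glu"], col["v_glu"])
            cp += p
            cm += m
        return cp, cm


# ---------------------------------------------------------------------------
# individual (fixed-effect) fit

def fit_individual(
    parent: ConcentrationProfile,
    metabolite: ConcentrationProfile,
    init: StructuralParams,
    fixed: Sequence[str] = ("f", "v_glu"),
    sigma_ral: float = 1.0,
    sigma_glu: float = 1.0,
) -> tuple[StructuralParams, dict]:
    """Per-subject nonlinear least squares on log concentrations.

    Minimizes the weighted sum of squared log residuals over both analytes;
    free parameters are optimized on the log scale so positivity holds by
    construction.  ``fixed`` names parameters held at their ``init`` value
    (F and V_glu by default, matching the population model convention).
    Returns ``(params, diagnostics)``; non-convergence sets
    ``diagnostics["converged"] = False`` with best-so-far parameters rather
    than raising.
    """
    cohort = _Cohort([(parent, metabolite)])
    all_fields = ("cl_f", "v_f", "ka", "mtt", "nn", "f", "fmet", "cl_glu", "v_glu")
    free = [p for p in all_fields if p not in set(fixed)]
    if cohort.n_obs < len(free):
        raise ValueError(
            f"{int(cohort.n_obs)} usable observations for {len(free)} free "
            "parameters; under-determined")
    base = {p: np.array([getattr(init, p)], dtype=float) for p in all_fields}
    wp, wm = 1.0 / sigma_ral, 1.0 / sigma_glu

    def resid(x):
        fields = dict(base)
        for p, v in zip(free, np.exp(x)):
            fields[p] = np.array([v])
        cp, cm = cohort.simulate(fields)
        rp = (cohort.lp - np.log(np.maximum(cp, _PRED_FLOOR)))[cohort.mp] * wp
        rm = (cohort.lm - np.log(np.maximum(cm, _PRED_FLOOR)))[cohort.mm] * wm
        return np.concatenate([rp, rm])

    x0 = np.log([getattr(init, p) for p in free])
    sol = optimize.least_squares(resid, x0, method="trf", xtol=1e-12,
                                 ftol=1e-12, gtol=1e-12, max_nfev=2000)
    est = dict(zip(free, np.exp(sol.x)))
    params = StructuralParams.__new__(StructuralParams)
    for p in all_fields:
        object.__setattr__(params, p, float(est.get(p, getattr(init, p))))
    diag = {"converged": bool(sol.success), "cost": float(sol.cost),
            "nfev": int(sol.nfev), "message": sol.message,
            "free": tuple(free)}
    if not sol.success:
        warnings.warn(f"individual fit did not converge: {sol.message}",
                      EstimationWarning, stacklevel=2)
    return params, diag


# ---------------------------------------------------------------------------
# FOCE-I machinery

class _FoceProblem:
    """Batched OFV evaluation: K outer-parameter points x n subjects at once.

    Every inner quantity (residuals, eta modes, Gauss-Newton curvature) is
    computed on a flattened batch axis of N = K*n pseudo-subjects with
    per-pseudo-subject sigma and Omega^-1, so a finite-difference gradient
    over the outer parameters costs one batched inner solve instead of one
    solve per parameter.
    """

    def __init__(self, cohort: _Cohort, pop: PopulationModel,
                 effects: Sequence[CovariateEffect] = (),
                 covariates=None, anchors: np.ndarray | None = None):
        self.cohort = cohort
        self.pop = pop
        self.iiv_names = pop.iiv_names
        self.d = len(self.iiv_names)
        self.effects = list(effects)
        # anchors: (n, d) log-scale individual NLS estimates per IIV
        # parameter; eta = anchors - log(theta_i) reproduces each subject's
        # own curve and guards the mode search against bad local modes
        self.anchors = anchors
        self._tiles: dict[int, dict[str, np.ndarray]] = {}
        if self.effects:
            if covariates is None:
                raise ValueError("covariate effects given without covariate table")
            self.cov_values = {
                e.label(): np.asarray(
                    [covariates.loc[s, e.covariate] for s in cohort.subject_ids],
                    dtype=float)
                for e in self.effects}
        else:
            self.cov_values = {}

    # -- batched data views -------------------------------------------------

    def _tile(self, K: int) -> dict[str, np.ndarray]:
        if K not in self._tiles:
            c = self.cohort
            self._tiles[K] = {
                "t": np.tile(c.t, (K, 1)),
                "lp": np.tile(c.lp, (K, 1)),
                "lm": np.tile(c.lm, (K, 1)),
                "mp": np.tile(c.mp, (K, 1)),
                "mm": np.tile(c.mm, (K, 1)),
                "dose_t": np.tile(c.dose_t, (K, 1)),
                "dose_a": np.tile(c.dose_a, (K, 1)),
            }
        return self._tiles[K]

    def _fields0(self, thetas: dict[str, np.ndarray],
                 betas: np.ndarray) -> dict[str, np.ndarray]:
        """Per-pseudo-subject parameter fields before eta (shape (K*n,))."""
        n = self.cohort.n
        K = len(next(iter(thetas.values())))
        fields = {k: np.repeat(np.asarray(v, float), n) for k, v in thetas.items()}
        for j, e in enumerate(self.effects):
            mult = np.concatenate([
                e.multiplier(self.cov_values[e.label()], betas[k, j])
                for k in range(K)])
            fields[e.parameter] = fields[e.parameter] * mult
        return fields

    def _quad(self, tiles, fields0, etas, inv_sp2, inv_sm2, omega_inv):
        """2*U per pseudo-subject plus residual matrices."""
        fields = dict(fields0)
        for j, name in enumerate(self.iiv_names):
            fields[name] = fields0[name] * np.exp(etas[:, j])
        col = {k: v[:, None] for k, v in fields.items()}
        cp = np.zeros_like(tiles["t"])
        cm = np.zeros_like(tiles["t"])
        for j in range(tiles["dose_t"].shape[1]):
            p, m = _kinetics.conc_single_dose(
                tiles["t"] - tiles["dose_t"][:, j:j + 1],
                tiles["dose_a"][:, j:j + 1],
                col["cl_f"], col["v_f"], col["ka"], col["mtt"], col["nn"],
                col["f"], col["fmet"], col["cl_glu"], col["v_glu"])
            cp += p
            cm += m
        rp = np.where(tiles["mp"],
                      tiles["lp"] - np.log(np.maximum(cp, _PRED_FLOOR)), 0.0)
        rm = np.where(tiles["mm"],
                      tiles["lm"] - np.log(np.maximum(cm, _PRED_FLOOR)), 0.0)
        quad = (rp**2).sum(axis=1) * inv_sp2 + (rm**2).sum(axis=1) * inv_sm2
        if self.d:
            quad = quad + np.einsum("ij,ijk,ik->i", etas, omega_inv, etas)
        return quad, rp, rm

    def eta_modes(self, tiles, fields0, inv_sp2, inv_sm2, omega_inv,
                  eta0=None, max_iter=200, gtol=1e-4):
        """Conditional eta modes per pseudo-subject, Levenberg-Marquardt.

        Each subject iterates until first-order stationarity
        (||grad U||_inf < ``gtol``), with adaptive per-subject damping of
        the Gauss-Newton system; converged subjects leave the working set
        so stragglers do not force whole-batch model evaluations.  The
        stationarity criterion (rather than a progress criterion) makes
        the returned modes a continuous function of the structural
        parameters, which keeps the outer OFV surface smooth.

        Returns (etas, A, quad) with A the undamped Gauss-Newton Hessian
        of the joint -log density at each subject's mode (the FOCE-I
        curvature).
        """
        N = tiles["t"].shape[0]
        d = self.d
        if d == 0:
            quad, _, _ = self._quad(tiles, fields0, np.zeros((N, 0)),
                                    inv_sp2, inv_sm2, omega_inv)
            return np.zeros((N, 0)), np.zeros((N, 0, 0)), quad
        etas = np.zeros((N, d)) if eta0 is None else eta0.copy()
        quad, rp_full, rm_full = self._quad(tiles, fields0, etas, inv_sp2,
                                            inv_sm2, omega_inv)
        A_out = np.empty((N, d, d))
        A_set = np.zeros(N, dtype=bool)
        act = np.ones(N, dtype=bool)
        lam = np.zeros(N)  # per-subject LM damping
        eye = np.eye(d)
        for _ in range(max_iter):
            ia = np.flatnonzero(act)
            sub = {k: v[ia] for k, v in tiles.items()}
            f0 = {k: v[ia] for k, v in fields0.items()}
            sp2, sm2, oi = inv_sp2[ia], inv_sm2[ia], omega_inv[ia]
            ea, qa = etas[ia], quad[ia]
            rp, rm = rp_full[ia], rm_full[ia]
            na, m = len(ia), tiles["t"].shape[1]
            Jp = np.empty((na, m, d))
            Jm = np.empty((na, m, d))
            for j in range(d):
                e2 = ea.copy()
                e2[:, j] += _ETA_FD_STEP
                _, rp2, rm2 = self._quad(sub, f0, e2, sp2, sm2, oi)
                Jp[:, :, j] = (rp - rp2) / _ETA_FD_STEP
                Jm[:, :, j] = (rm - rm2) / _ETA_FD_STEP
            A = (np.einsum("imj,imk->ijk", Jp, Jp) * sp2[:, None, None]
                 + np.einsum("imj,imk->ijk", Jm, Jm) * sm2[:, None, None]
                 + oi)
            grad = (-np.einsum("imj,im->ij", Jp, rp) * sp2[:, None]
                    - np.einsum("imj,im->ij", Jm, rm) * sm2[:, None]
                    + np.einsum("ijk,ik->ij", oi, ea))
            A_out[ia] = A
            A_set[ia] = True
            # stationarity check: 2U gradient is 2*grad; compare |grad|
            gnorm = np.abs(grad).max(axis=1)
            done = gnorm < gtol
            if done.any():
                act[ia[done]] = False
                keep = ~done
                if not keep.any():
                    if not act.any():
                        break
                    continue
                ia = ia[keep]
                sub = {k: v[keep] for k, v in sub.items()}
                f0 = {k: v[keep] for k, v in f0.items()}
                sp2, sm2, oi = sp2[keep], sm2[keep], oi[keep]
                ea, qa, rp, rm = ea[keep], qa[keep], rp[keep], rm[keep]
                A, grad = A[keep], grad[keep]
                na = len(ia)
            damped = A + lam[ia, None, None] * eye[None, :, :]
            try:
                step = -np.linalg.solve(damped, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step = -grad / (1.0 + lam[ia, None])
            # backtracking Armijo search, vectorized per pseudo-subject
            alpha = np.ones(na)
            searching = np.ones(na, dtype=bool)
            new_ea = ea.copy()
            new_qa = qa.copy()
            for _bt in range(6):
                trial = ea + alpha[:, None] * step
                q_t, rp_t, rm_t = self._quad(sub, f0, trial, sp2, sm2, oi)
                improved = searching & (q_t < qa)
                new_ea[improved] = trial[improved]
                new_qa[improved] = q_t[improved]
                if improved.any():
                    rp = np.where(improved[:, None], rp_t, rp)
                    rm = np.where(improved[:, None], rm_t, rm)
                searching = searching & ~improved
                if not searching.any():
                    break
                alpha[searching] *= 0.25
            # damping update: success relaxes, failure inflates and retries
            lam[ia[~searching]] = np.maximum(lam[ia[~searching]] * 0.3, 0.0)
            lam[ia[searching]] = np.maximum(lam[ia[searching]], 1e-3) * 10.0
            stuck = searching & (lam[ia] > 1e10)
            if stuck.any():
                act[ia[stuck]] = False  # numerically at the mode already
            etas[ia], quad[ia] = new_ea, new_qa
            rp_full[ia], rm_full[ia] = rp, rm
            if not act.any():
                break
        if not A_set.all():
            A_out[~A_set] = omega_inv[~A_set]
        return etas, A_out, quad

    # -- OFV ----------------------------------------------------------------

    def ofv_batch(self, thetas, betas, sig_p, sig_m, omegas, eta0=None,
                  method="foce_i", inner_max_iter=200, explore=None):
        """OFV for each of K outer points; returns (ofv (K,), etas (K*n, d)).

        ``thetas``: dict name -> (K,); ``betas``: (K, n_effects);
        ``sig_p``/``sig_m``: (K,); ``omegas``: (K, d, d).
        ``inner_max_iter`` caps the mode search; warm-started
        finite-difference batches only need mutual consistency, so a low
        cap there is safe and much cheaper.  ``explore`` forces (or
        suppresses) the dual-start basin exploration; by default it runs
        whenever no warm start is supplied.
        """
        cohort = self.cohort
        n = cohort.n
        K = len(sig_p)
        tiles = self._tile(K)
        fields0 = self._fields0(thetas, betas)
        inv_sp2 = np.repeat(1.0 / np.asarray(sig_p, float)**2, n)
        inv_sm2 = np.repeat(1.0 / np.asarray(sig_m, float)**2, n)
        if self.d:
            omega_inv = np.repeat(np.linalg.inv(omegas), n, axis=0)
        else:
            omega_inv = np.zeros((K * n, 0, 0))
        if explore is None:
            explore = eta0 is None
        if explore and self.anchors is not None and self.d:
            # dual-start mode search: run the base start (warm modes, or
            # zero) and the individual-fit anchor start to convergence side
            # by side (one doubled batch) and keep each subject's deeper
            # mode — guards the conditional-mode search against shallow
            # local modes
            anchor_eta = np.tile(self.anchors, (K, 1)) - np.stack(
                [np.log(np.maximum(fields0[name], _PRED_FLOOR))
                 for name in self.iiv_names], axis=1)
            anchor_eta = np.nan_to_num(anchor_eta, nan=0.0)
            base_eta = eta0 if eta0 is not None else np.zeros((K * n, self.d))
            big_tiles = {k: np.concatenate([v, v]) for k, v in tiles.items()}
            big_fields = {k: np.concatenate([v, v]) for k, v in fields0.items()}
            init_eta = np.concatenate([base_eta, anchor_eta])
            etas2, A2, quad2 = self.eta_modes(
                big_tiles, big_fields,
                np.concatenate([inv_sp2, inv_sp2]),
                np.concatenate([inv_sm2, inv_sm2]),
                np.concatenate([omega_inv, omega_inv]), eta0=init_eta,
                max_iter=inner_max_iter)
            half = K * n
            pick = quad2[half:] < quad2[:half]
            etas = np.where(pick[:, None], etas2[half:], etas2[:half])
            A = np.where(pick[:, None, None], A2[half:], A2[:half])
            quad = np.where(pick, quad2[half:], quad2[:half])
        else:
            etas, A, quad = self.eta_modes(tiles, fields0, inv_sp2, inv_sm2,
                                           omega_inv, eta0=eta0,
                                           max_iter=inner_max_iter)
        n_p = cohort.mp.sum(axis=1)
        n_m = cohort.mm.sum(axis=1)
        per = (quad.reshape(K, n).sum(axis=1)
               + cohort.n_obs * np.log(2.0 * np.pi)
               + 2.0 * n_p.sum() * np.log(np.asarray(sig_p, float))
               + 2.0 * n_m.sum() * np.log(np.asarray(sig_m, float)))
        if self.d:
            sign, logdet_om = np.linalg.slogdet(omegas)
            if np.any(sign <= 0):
                raise ValueError("Omega is not positive definite")
            if method == "laplace":
                A = self._fd_hessians(tiles, fields0, etas, inv_sp2, inv_sm2,
                                      omega_inv)
            elif method != "foce_i":
                raise ValueError(f"unknown OFV method {method!r}")
            sgn, logdet_a = np.linalg.slogdet(A)
            if np.any(sgn <= 0):
                warnings.warn(
                    f"{int((sgn <= 0).sum())} subject(s) with non-PD curvature "
                    "at the eta mode; first-order fallback applied",
                    EstimationWarning, stacklevel=2)
                fb = np.linalg.slogdet(np.eye(self.d)[None] + omega_inv)[1]
                logdet_a = np.where(sgn <= 0, fb, logdet_a)
            per = per + n * logdet_om + logdet_a.reshape(K, n).sum(axis=1)
        return per, etas

    def ofv(self, theta, betas, sig_p, sig_m, omega, eta0=None,
            method="foce_i"):
        """Single-point OFV; thin wrapper over :meth:`ofv_batch` with K=1."""
        thetas = {k: np.array([v]) for k, v in theta.items()}
        b = np.asarray(betas, float).reshape(1, -1)
        per, etas = self.ofv_batch(
            thetas, b, np.array([sig_p]), np.array([sig_m]),
            np.asarray(omega, float).reshape(1, self.d, self.d),
            eta0=eta0, method=method)
        return float(per[0]), etas

    def _fd_hessians(self, tiles, fields0, etas, inv_sp2, inv_sm2, omega_inv):
        """Central finite-difference Hessian of U(eta) per pseudo-subject."""
        N, d = etas.shape
        h = 1e-4

        def u(e):
            q, _, _ = self._quad(tiles, fields0, e, inv_sp2, inv_sm2, omega_inv)
            return 0.5 * q

        H = np.empty((N, d, d))
        u0 = u(etas)
        for j in range(d):
            for k in range(j, d):
                if j == k:
                    ep = etas.copy(); ep[:, j] += h
                    em = etas.copy(); em[:, j] -= h
                    H[:, j, j] = (u(ep) - 2 * u0 + u(em)) / h**2
                else:
                    epp = etas.copy(); epp[:, j] += h; epp[:, k] += h
                    epm = etas.copy(); epm[:, j] += h; epm[:, k] -= h
                    emp = etas.copy(); emp[:, j] -= h; emp[:, k] += h
                    emm = etas.copy(); emm[:, j] -= h; emm[:, k] -= h
                    H[:, j, k] = H[:, k, j] = (u(epp) - u(epm) - u(emp) + u(emm)) / (4 * h**2)
        return H


def ofv(pop: PopulationModel,
        data: Sequence[tuple[ConcentrationProfile, ConcentrationProfile]],
        method: str = "foce_i",
        covariate_effects: Sequence[CovariateEffect] = (),
        covariates=None) -> float:
    """-2 log (approximate) marginal likelihood of the cohort under ``pop``.

    With all IIV terms absent (``omega_cv`` empty) this reduces exactly to
    the fixed-effect Gaussian -2 log-likelihood of the log residuals.
    """
    cohort = _Cohort(data)
    effects = [e.resolve_ref(np.asarray(
        [covariates.loc[s, e.covariate] for s in cohort.subject_ids], float))
        if covariates is not None else e for e in covariate_effects]
    prob = _FoceProblem(cohort, pop, effects, covariates)
    theta = {k: getattr(pop.theta, k)
             for k in ("cl_f", "v_f", "ka", "mtt", "nn", "f", "fmet",
                       "cl_glu", "v_glu")}
    betas = [e.beta for e in effects]
    val, _ = prob.ofv(theta, betas, pop.sigma_ral, pop.sigma_glu,
                      pop.omega_matrix(), method=method)
    return val


class _BfgsResult:
    def __init__(self, x, fun, nit, success, message):
        self.x, self.fun, self.nit = x, fun, nit
        self.success, self.message = success, message


def _minimize_bfgs_armijo(fun, grad, x0, maxiter=120, ftol=1e-8,
                          gtol=2e-4, f0=None, g0=None):
    """Damped-BFGS with Armijo backtracking.

    Unlike Wolfe-based quasi-Newton drivers this needs only the (cheap)
    function at line-search trial points; the (expensive, batched) gradient
    is evaluated once per accepted iterate.  Powell damping keeps the
    inverse-Hessian approximation positive definite without a curvature
    line-search condition.
    """
    x = np.asarray(x0, float).copy()
    p = len(x)
    f = fun(x) if f0 is None else f0
    g = grad(x) if g0 is None else g0
    eye = np.eye(p)
    H = eye.copy()
    scaled = False
    message = "maxiter reached"
    success = False
    it = 0
    for it in range(1, maxiter + 1):
        d = -H @ g
        gd = float(g @ d)
        if not np.isfinite(gd) or gd >= 0.0:
            H = eye.copy()
            scaled = False
            d = -g
            gd = float(g @ d)
            if gd >= 0.0:
                message = "zero gradient"
                success = True
                break
        # cap the very first trial step: with H = I the raw Newton step
        # can be wildly out of scale
        alpha = min(1.0, 10.0 / np.linalg.norm(d)) if not scaled else 1.0
        f_t = None
        for _bt in range(30):
            x_t = x + alpha * d
            f_t = fun(x_t)
            if f_t <= f + 1e-4 * alpha * gd:
                break
            alpha *= 0.5
        else:
            message = "line search failed (at numerical floor)"
            success = True
            break
        g_new = grad(x_t)
        s = x_t - x
        y = g_new - g
        f_prev, x, f, g = f, x_t, f_t, g_new
        sy = float(s @ y)
        if sy > 1e-12 * np.linalg.norm(s) * np.linalg.norm(y):
            if not scaled:
                H = (sy / float(y @ y)) * eye
                scaled = True
            rho = 1.0 / sy
            v = eye - rho * np.outer(s, y)
            H = v @ H @ v.T + rho * np.outer(s, s)
        if abs(f_prev - f) <= ftol * max(abs(f), 1.0):
            message = "ftol satisfied"
            success = True
            break
        if np.max(np.abs(g)) < gtol:
            message = "gtol satisfied"
            success = True
            break
    return _BfgsResult(x, f, it, success, message)


# ---------------------------------------------------------------------------
# outer parameter packing

class _Packing:
    """Bijective map between the free model parameters and an R^p vector."""

    def __init__(self, pop: PopulationModel, fixed: set[str],
                 effects: Sequence[CovariateEffect]):
        self.pop = pop
        self.iiv_names = pop.iiv_names
        self.effects = list(effects)
        self.free_theta = [p for p in STRUCTURAL_FREE if p not in fixed]
        self.free_omega = [p for p in self.iiv_names if f"omega:{p}" not in fixed]
        self.has_corr = ("cl_f" in self.iiv_names and "v_f" in self.iiv_names
                         and "corr_cl_v" not in fixed)
        self.free_sigma = [s for s in ("sigma_ral", "sigma_glu") if s not in fixed]
        self.names = ([f"theta:{p}" for p in self.free_theta]
                      + [f"omega:{p}" for p in self.free_omega]
                      + (["corr_cl_v"] if self.has_corr else [])
                      + list(self.free_sigma)
                      + [f"beta:{e.label()}" for e in self.effects])

    def pack(self, pop: PopulationModel, betas: Sequence[float]) -> np.ndarray:
        x = [np.log(getattr(pop.theta, p)) for p in self.free_theta]
        omega_sd = dict(zip(pop.iiv_names, pop.omega_sd()))
        x += [np.log(max(omega_sd[p], 1e-8)) for p in self.free_omega]
        if self.has_corr:
            x.append(np.arctanh(np.clip(pop.corr_cl_v, -0.999, 0.999)))
        for s in self.free_sigma:
            x.append(np.log(getattr(pop, s)))
        x += list(betas)
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray):
        x = np.clip(x, -40.0, 40.0)  # keep exp() finite on optimizer excursions
        i = 0
        theta = {k: getattr(self.pop.theta, k)
                 for k in ("cl_f", "v_f", "ka", "mtt", "nn", "f", "fmet",
                           "cl_glu", "v_glu")}
        for p in self.free_theta:
            theta[p] = float(np.exp(x[i])); i += 1
        omega_sd = dict(zip(self.pop.iiv_names, self.pop.omega_sd()))
        for p in self.free_omega:
            omega_sd[p] = float(np.exp(x[i])); i += 1
        corr = self.pop.corr_cl_v
        if self.has_corr:
            corr = float(np.tanh(x[i])); i += 1
        sig = {"sigma_ral": self.pop.sigma_ral, "sigma_glu": self.pop.sigma_glu}
        for s in self.free_sigma:
            sig[s] = float(np.exp(x[i])); i += 1
        betas = [float(b) for b in x[i:]]
        d = len(self.iiv_names)
        sd = np.array([omega_sd[p] for p in self.iiv_names])
        omega = np.diag(sd**2)
        if "cl_f" in self.iiv_names and "v_f" in self.iiv_names:
            a, b = self.iiv_names.index("cl_f"), self.iiv_names.index("v_f")
            omega[a, b] = omega[b, a] = corr * sd[a] * sd[b]
        return theta, omega, corr, sig["sigma_ral"], sig["sigma_glu"], betas, d


def _fit_individuals(data, theta_init):
    """Per-subject NLS estimates (None where the fit is impossible)."""
    out = []
    for parent, metab in data:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EstimationWarning)
                est, diag = fit_individual(parent, metab, theta_init)
            out.append((est, diag))
        except ValueError:
            out.append((None, None))
    return out


def _anchor_matrix(individual_fits, iiv_names) -> np.ndarray | None:
    """Log-scale anchor matrix (n, d) for the inner mode search."""
    if not any(est is not None for est, _ in individual_fits):
        return None
    rows = []
    for est, _ in individual_fits:
        if est is None:
            rows.append([np.nan] * len(iiv_names))
        else:
            rows.append([np.log(getattr(est, name)) for name in iiv_names])
    # NaN rows (failed fits) fall back to the eta = 0 start in eta_modes
    return np.asarray(rows, dtype=float)


def two_stage_init(
    data: Sequence[tuple[ConcentrationProfile, ConcentrationProfile]],
    init: PopulationModel,
    individual_fits=None,
) -> PopulationModel:
    """Naive-pooled two-stage starting values for the population fit.

    Fits every subject individually (log-scale NLS), then summarizes:
    typical values as geometric medians of the individual estimates, IIV
    %CVs from the robust (MAD-based) spread of the log estimates, the CL-V
    correlation from the log estimates, and a pooled residual SD.  These
    are starting values only — the two-stage spread overstates omega
    (individual F is not separately identifiable, so its variability is
    absorbed by V) — but they land the outer optimizer close to the
    optimum.
    """
    if individual_fits is None:
        individual_fits = _fit_individuals(data, init.theta)
    logs: dict[str, list[float]] = {p: [] for p in STRUCTURAL_FREE}
    ss_res = 0.0
    n_res = 0
    for (est, diag), (parent, metab) in zip(individual_fits, data):
        if est is None:
            continue
        for p in STRUCTURAL_FREE:
            logs[p].append(np.log(getattr(est, p)))
        ss_res += 2.0 * diag["cost"]
        n_res += sum(len(prof) for prof in (parent, metab))
    if len(logs["cl_f"]) < 3:
        return init
    theta_kw = {p: float(np.exp(np.median(logs[p]))) for p in STRUCTURAL_FREE}
    theta = init.theta.replace(**theta_kw)
    mad = {p: 1.4826 * float(np.median(np.abs(np.asarray(logs[p])
                                              - np.median(logs[p]))))
           for p in STRUCTURAL_FREE}
    var = {p: m**2 for p, m in mad.items()}
    # F is fixed in the individual fits, so its variability is absorbed by
    # the scale-bearing estimates: Var(log cl_hat) ~ w_cl^2 + w_f^2, same
    # for v_f and fmet.  Split half the smallest shared variance out as the
    # F term so the starting point is not next to the label-swapped mode
    # where F-variability is reassigned to correlated CL/V/FMET effects.
    if "f" in init.iiv_names:
        shared = [var[p] for p in ("cl_f", "v_f", "fmet") if p in init.iiv_names]
        var_f = 0.5 * min(shared) if shared else 0.09
        var["f"] = var_f
        for p in ("cl_f", "v_f", "fmet"):
            if p in var:
                var[p] = max(var[p] - var_f, 0.01)
    omega_cv = {}
    for p in init.iiv_names:
        sd = np.sqrt(var.get(p, 0.0))
        omega_cv[p] = float(omega_to_cv(np.clip(sd, 0.1, 1.5),
                                        init.cv_convention))
    corr = init.corr_cl_v
    if "cl_f" in omega_cv and "v_f" in omega_cv:
        c = np.corrcoef(logs["cl_f"], logs["v_f"])[0, 1]
        if np.isfinite(c):
            corr = float(np.clip(c, -0.9, 0.9))
    sigma = float(np.sqrt(ss_res / max(n_res, 1))) if n_res else init.sigma_ral
    sigma = float(np.clip(sigma, 0.05, 1.0))
    return PopulationModel(theta=theta, omega_cv=omega_cv, corr_cl_v=corr,
                           sigma_ral=sigma, sigma_glu=sigma,
                           cv_convention=init.cv_convention)


# ---------------------------------------------------------------------------
# population fit

@dataclass
class PopulationFit:
    """Result of a population fit: estimates, OFV, RSEs, EBEs, shrinkage."""

    theta_hat: StructuralParams
    omega_cv_hat: dict[str, float]
    corr_cl_v_hat: float
    sigma_hat: dict[str, float]
    ofv: float
    rse: dict[str, float]
    ebes: dict[str, np.ndarray]
    shrinkage: dict[str, float]
    convergence: str
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)
    n_subjects: int = 0
    n_obs: int = 0
    cv_convention: str = "lognormal"
    n_function_evals: int = 0

    def individual_params(self) -> list[IndividualParams]:
        """Empirical-Bayes individual parameters theta_hat * exp(eta_hat).

        Covariate effects in the final model are applied before the eta
        terms, matching the fitted parameterization.
        """
        names = list(self.ebes)
        out = []
        for i, sid in enumerate(self.subject_ids):
            kw = {}
            for name in names:
                kw[name] = getattr(self.theta_hat, name) * float(
                    np.exp(self.ebes[name][i]))
            p = StructuralParams.__new__(StructuralParams)
            for fld in ("cl_f", "v_f", "ka", "mtt", "nn", "f", "fmet",
                        "cl_glu", "v_glu"):
                object.__setattr__(p, fld, kw.get(fld, getattr(self.theta_hat, fld)))
            out.append(IndividualParams(sid, p,
                                        {n: float(self.ebes[n][i]) for n in names}))
        return out

    def to_population_model(self) -> PopulationModel:
        return PopulationModel(
            theta=self.theta_hat,
            omega_cv=dict(self.omega_cv_hat),
            corr_cl_v=self.corr_cl_v_hat,
            sigma_ral=self.sigma_hat["sigma_ral"],
            sigma_glu=self.sigma_hat["sigma_glu"],
            cv_convention=self.cv_convention)

    def to_dict(self) -> dict:
        return {
            "theta": {k: getattr(self.theta_hat, k)
                      for k in ("cl_f", "v_f", "ka", "mtt", "nn", "f", "fmet",
                                "cl_glu", "v_glu")},
            "omega_cv": dict(self.omega_cv_hat),
            "corr_cl_v": self.corr_cl_v_hat,
            "sigma": dict(self.sigma_hat),
            "ofv": self.ofv,
            "rse_percent": dict(self.rse),
            "shrinkage_percent": dict(self.shrinkage),
            "convergence": self.convergence,
            "covariates": [{"parameter": e.parameter, "covariate": e.covariate,
                            "form": e.form, "beta": e.beta, "ref": e.ref}
                           for e in self.covariate_effects],
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "cv_convention": self.cv_convention,
        }


def fit_population(
    data: Sequence[tuple[ConcentrationProfile, ConcentrationProfile]],
    init: PopulationModel,
    fixed: Sequence[str] = ("f", "v_glu"),
    covariate_effects: Sequence[CovariateEffect] = (),
    covariates=None,
    n_starts: int = 3,
    jitter: float = 0.2,
    seed: int = 0,
    method: str = "foce_i",
    maxiter: int = 400,
    compute_rse: bool = True,
    min_subjects: int = 6,
    init_strategy: str = "given",
) -> PopulationFit:
    """Maximize the FOCE-I marginal likelihood over theta, Omega, sigma.

    Multi-start quasi-Newton (damped BFGS with Armijo backtracking on the
    transformed parameters): start 0 is ``init`` itself, further starts
    jitter the free fixed effects log-normally by ``jitter``.  ``fixed`` holds structural names
    (theta fixed), ``"omega:<name>"``, ``"corr_cl_v"``, ``"sigma_ral"`` /
    ``"sigma_glu"``; F and V_glu are fixed by default per the model
    convention.  RSEs come from the inverse finite-difference Hessian of
    the OFV; EBEs and shrinkage are evaluated at the final estimates.

    Never raises on failure to improve: the convergence flag is
    ``"converged"`` or ``"failed"`` and best-so-far results are returned.
    """
    cohort = _Cohort(data)
    if cohort.n < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects, got {cohort.n}")
    individual_fits = _fit_individuals(data, init.theta)
    if init_strategy == "two_stage":
        init = two_stage_init(data, init, individual_fits)
    elif init_strategy != "given":
        raise ValueError(f"unknown init_strategy {init_strategy!r}")
    fixed = set(fixed)
    effects = [
        e.resolve_ref(np.asarray(
            [covariates.loc[s, e.covariate] for s in cohort.subject_ids], float))
        if covariates is not None else e
        for e in covariate_effects]
    anchors = _anchor_matrix(individual_fits, init.iiv_names)
    prob = _FoceProblem(cohort, init, effects, covariates, anchors=anchors)
    packing = _Packing(init, fixed, effects)
    x0 = packing.pack(init, [e.beta for e in effects])
    rng = np.random.default_rng(seed)
    p = len(x0)
    n = cohort.n
    d = len(packing.iiv_names)
    state = {"eta": None, "x_eta": None, "nfev": 0}
    grad_h = 1e-5

    def _batch_args(xs):
        cols = [packing.unpack(x) for x in xs]
        thetas = {k: np.array([c[0][k] for c in cols])
                  for k in cols[0][0]}
        omegas = np.stack([c[1] for c in cols]) if d else np.zeros((len(xs), 0, 0))
        sp = np.array([c[3] for c in cols])
        sm = np.array([c[4] for c in cols])
        betas = np.array([c[5] for c in cols]).reshape(len(xs), -1)
        return thetas, omegas, sp, sm, betas

    def objective(x, explore=False):
        # the inner modes satisfy a stationarity criterion, so for nearby
        # points continuation (warm start) reaches the same modes as a cold
        # solve and the OFV stays a well-defined function of x; the
        # dual-start anchor exploration runs on large jumps, on cold calls
        # and (via ``explore``) once per accepted iterate
        thetas, omegas, sp, sm, betas = _batch_args([x])
        state["nfev"] += 1
        eta0 = None
        if (state["eta"] is not None and state["x_eta"] is not None
                and np.max(np.abs(x - state["x_eta"])) < 0.3):
            eta0 = state["eta"]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EstimationWarning)
                per, etas = prob.ofv_batch(thetas, betas, sp, sm, omegas,
                                           eta0=eta0, method=method,
                                           explore=explore or eta0 is None)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e12
        val = float(per[0])
        # a -2 log-likelihood this negative is numerically impossible for
        # this data scale; treat as an invalid (overflowed) region
        if not np.isfinite(val) or val < -1e8:
            return 1e12
        state["eta"] = etas
        state["x_eta"] = x.copy()
        return val

    def gradient(x):
        # solve the base point, then one batched inner solve over the 2p
        # central-difference points warm-started from the base modes: the
        # perturbed modes are within a Newton step, and the envelope
        # property makes the FD differences first-order exact
        objective(x, explore=True)
        eye = np.eye(p)
        xs = ([x + grad_h * eye[i] for i in range(p)]
              + [x - grad_h * eye[i] for i in range(p)])
        thetas, omegas, sp, sm, betas = _batch_args(xs)
        state["nfev"] += 2 * p
        eta0 = np.tile(state["eta"], (2 * p, 1)) if state["eta"] is not None else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EstimationWarning)
                per, etas = prob.ofv_batch(thetas, betas, sp, sm, omegas,
                                           eta0=eta0, method=method,
                                           inner_max_iter=12)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return np.zeros(p)
        if not np.all(np.isfinite(per)):
            return np.zeros(p)
        return (per[:p] - per[p:]) / (2.0 * grad_h)

    best = None
    n_theta = len(packing.free_theta)
    for s in range(max(1, n_starts)):
        xs = x0.copy()
        if s > 0:
            xs[:n_theta] += rng.normal(0.0, jitter, size=n_theta)
        state["eta"] = None
        state["x_eta"] = None
        res = _minimize_bfgs_armijo(objective, gradient, xs,
                                    maxiter=maxiter, ftol=1e-8, gtol=2e-4)
        # fresh-memory restarts recover progress lost to stale curvature
        # estimates; repeat while they keep making real progress (long
        # curved valleys), with a hard cap on total extra iterations
        for _restart in range(6):
            res2 = _minimize_bfgs_armijo(objective, gradient, res.x,
                                         maxiter=min(maxiter // 2, 25),
                                         ftol=1e-8, gtol=2e-4)
            improved = res.fun - res2.fun
            if res2.fun < res.fun:
                res2.success = res2.success or res.success
                res = res2
            if improved < 1.0:
                break
        res.success = res.success or res.fun < 1e11
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and best.fun < 1e11
    x_hat = best.x
    theta, omega, corr, sp, sm, betas, d = packing.unpack(x_hat)
    # final clean OFV + EBEs from cold start at the optimum
    state["eta"] = None
    final_ofv, etas = prob.ofv(theta, betas, sp, sm, omega, method=method)

    iiv = packing.iiv_names
    omega_sd_hat = np.sqrt(np.diag(omega)) if d else np.array([])
    omega_cv_hat = {p: float(omega_to_cv(sd, init.cv_convention))
                    for p, sd in zip(iiv, omega_sd_hat)}
    ebes = {p: etas[:, j].copy() for j, p in enumerate(iiv)}
    shrink = {}
    for j, p in enumerate(iiv):
        if omega_sd_hat[j] > 0 and cohort.n >= 2:
            shrink[p] = eta_shrinkage(etas[:, j], omega_sd_hat[j])

    rse: dict[str, float] = {}
    if compute_rse and converged:
        rse = _rse_from_hessian(objective, x_hat, packing, corr)

    theta_hat = StructuralParams.__new__(StructuralParams)
    for fld in ("cl_f", "v_f", "ka", "mtt", "nn", "f", "fmet", "cl_glu", "v_glu"):
        object.__setattr__(theta_hat, fld, float(theta[fld]))

    for e, b in zip(effects, betas):
        e.beta = float(b)
    return PopulationFit(
        theta_hat=theta_hat,
        omega_cv_hat=omega_cv_hat,
        corr_cl_v_hat=float(corr),
        sigma_hat={"sigma_ral": float(sp), "sigma_glu": float(sm)},
        ofv=float(final_ofv),
        rse=rse,
        ebes=ebes,
        shrinkage=shrink,
        convergence="converged" if converged else "failed",
        covariate_effects=effects,
        subject_ids=list(cohort.subject_ids),
        n_subjects=cohort.n,
        n_obs=int(cohort.n_obs),
        cv_convention=init.cv_convention,
        n_function_evals=state["nfev"],
    )


def _rse_from_hessian(objective, x_hat, packing: _Packing, corr: float,
                      h: float = 2e-3) -> dict[str, float]:
    """Percent RSEs from the inverse FD Hessian of the OFV.

    The OFV is -2 log L, so the covariance of the estimates is
    2 * H^{-1}.  Log-scale SEs are RSEs directly (SE(log x) ~ SD(x)/x);
    the atanh-correlation SE is delta-transformed.
    """
    p = len(x_hat)
    H = np.empty((p, p))
    f0 = objective(x_hat)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        xi = x_hat.copy(); xi[i] += h
        fp[i] = objective(xi)
        xi = x_hat.copy(); xi[i] -= h
        fm[i] = objective(xi)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(p):
        for j in range(i + 1, p):
            xpp = x_hat.copy(); xpp[[i, j]] += h
            xmm = x_hat.copy(); xmm[[i, j]] -= h
            fpp = objective(xpp)
            fmm = objective(xmm)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0
                                 + fmm - fm[i] - fm[j] + f0) / (2 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = 2.0 * np.linalg.pinv(H)
        warnings.warn("OFV Hessian singular; pseudo-inverse used for RSEs",
                      EstimationWarning, stacklevel=2)
    var = np.diag(cov)
    rse = {}
    for name, v in zip(packing.names, var):
        if v <= 0 or not np.isfinite(v):
            rse[name] = float("nan")
            continue
        se = float(np.sqrt(v))
        if name == "corr_cl_v":
            se_rho = se * (1.0 - corr**2)
            rse[name] = 100.0 * se_rho / abs(corr) if corr != 0 else float("nan")
        elif name.startswith("beta:"):
            rse[name] = float("nan") if corr is None else se  # absolute SE
        else:
            rse[name] = 100.0 * se
    return rse


# ---------------------------------------------------------------------------
# stepwise covariate search

def forward_admissible(delta_ofv: float, iiv_before: float, iiv_after: float,
                       threshold: float = FORWARD_DOFV) -> bool:
    """Forward-inclusion rule: dOFV >= threshold AND unexplained IIV declined.

    ``delta_ofv`` is OFV(without) - OFV(with); IIV values are the %CV of
    the affected parameter before and after inclusion.  The boundary is
    strict chi-square style: exactly 3.83 fails, 3.84 passes.
    """
    return bool(delta_ofv >= threshold and iiv_after < iiv_before)


def backward_retained(delta_ofv_removal: float,
                      threshold: float = BACKWARD_DOFV) -> bool:
    """Backward rule: keep the covariate iff removing it costs >= threshold."""
    return bool(delta_ofv_removal >= threshold)


@dataclass
class CovariateSearchResult:
    """Trace of the stepwise covariate search plus the final model."""

    steps: list[dict]
    final_model: PopulationFit
    included: list[CovariateEffect] = field(default_factory=list)


def covariate_search(
    base: PopulationFit,
    data,
    covariates,
    candidates: Sequence[CovariateEffect],
    fit_kwargs: dict | None = None,
) -> CovariateSearchResult:
    """Forward-inclusion / backward-elimination over candidate covariates.

    Greedy forward phase: each round refits the current model with every
    remaining candidate added (warm-started from the current estimates) and
    admits the best one with dOFV >= 3.84 that also reduces the affected
    parameter's unexplained IIV; ties break by larger IIV reduction, then
    candidate label.  Backward phase: any included covariate whose removal
    costs < 10.8 OFV points is eliminated (weakest first).

    Candidates whose covariate column is missing or incomplete are excluded
    with a warning.  ``fit_kwargs`` is forwarded to :func:`fit_population`
    (e.g. ``{"n_starts": 1, "maxiter": 150}`` to bound runtime).
    """
    if base.convergence != "converged":
        raise ValueError("base fit did not converge; covariate search refused")
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_starts", 1)

    usable: list[CovariateEffect] = []
    for c in candidates:
        if c.covariate not in covariates.columns:
            warnings.warn(f"candidate {c.label()}: covariate column missing; skipped",
                          EstimationWarning, stacklevel=2)
            continue
        vals = covariates[c.covariate]
        if vals.isna().any():
            warnings.warn(f"candidate {c.label()}: missing values; skipped",
                          EstimationWarning, stacklevel=2)
            continue
        usable.append(c)

    steps: list[dict] = []
    current = base
    included: list[CovariateEffect] = []
    remaining = list(usable)

    def refit(effects):
        return fit_population(
            data, current.to_population_model(),
            covariate_effects=[CovariateEffect(e.parameter, e.covariate,
                                               e.form, e.beta, e.ref)
                               for e in effects],
            covariates=covariates, **fit_kwargs)

    # forward phase
    while remaining:
        trials = []
        for cand in remaining:
            fit = refit(included + [cand])
            dofv = current.ofv - fit.ofv
            iiv_b = current.omega_cv_hat.get(cand.parameter, float("inf"))
            iiv_a = fit.omega_cv_hat.get(cand.parameter, float("inf"))
            ok = forward_admissible(dofv, iiv_b, iiv_a)
            trials.append((cand, fit, dofv, iiv_b - iiv_a, ok))
            steps.append({"phase": "forward", "candidate": cand.label(),
                          "delta_ofv": dofv, "iiv_change": iiv_a - iiv_b,
                          "included": ok})
        admitted = [t for t in trials if t[4]]
        if not admitted:
            break
        admitted.sort(key=lambda t: (-t[2], -t[3], t[0].label()))
        cand, fit, _, _, _ = admitted[0]
        final_cand = fit.covariate_effects[-1]
        included.append(final_cand)
        remaining = [c for c in remaining if c is not cand]
        current = fit

    # backward phase
    while included:
        removals = []
        for e in included:
            reduced = [c for c in included if c is not e]
            fit = refit(reduced)
            dofv = fit.ofv - current.ofv
            removals.append((e, fit, dofv))
            steps.append({"phase": "backward", "candidate": e.label(),
                          "delta_ofv": dofv,
                          "included": backward_retained(dofv)})
        removals.sort(key=lambda t: t[2])
        weakest, fit, dofv = removals[0]
        if backward_retained(dofv):
            break
        included = [c for c in included if c is not weakest]
        current = fit

    return CovariateSearchResult(steps=steps, final_model=current,
                                 included=included)


# ---------------------------------------------------------------------------
# reporting

def format_fit_report(fit: PopulationFit) -> str:
    """Human-readable fit table: estimate (RSE%), omega %CV, sigma SD."""
    lines = ["Population pharmacokinetic fit", "=" * 46,
             f"Subjects: {fit.n_subjects}   Observations: {fit.n_obs}",
             f"OFV (-2LL): {fit.ofv:.3f}   Convergence: {fit.convergence}",
             "", "Fixed effects"]

    def fmt(name, value, key, unit=""):
        r = fit.rse.get(key, float("nan"))
        rs = f" ({r:.1f})" if np.isfinite(r) else " (fixed)" if key is None else ""
        return f"  {name:<14}{value:.4g}{rs} {unit}"

    t = fit.theta_hat
    lines.append(fmt("CL_RAL/F", t.cl_f, "theta:cl_f", "L/h"))
    lines.append(fmt("MTT", t.mtt, "theta:mtt", "h"))
    lines.append(f"  {'F':<14}{t.f:.4g} FIXED")
    lines.append(fmt("ka", t.ka, "theta:ka", "1/h"))
    lines.append(fmt("NN", t.nn, "theta:nn", ""))
    lines.append(fmt("V_RAL/F", t.v_f, "theta:v_f", "L"))
    lines.append(fmt("FMET", t.fmet, "theta:fmet", ""))
    lines.append(fmt("CL_GLU", t.cl_glu, "theta:cl_glu", "L/h"))
    lines.append(f"  {'V_GLU':<14}{t.v_glu:.4g} FIXED L")
    for e in fit.covariate_effects:
        lines.append(f"  {e.label():<28}beta = {e.beta:.4g}")
    lines.append("")
    lines.append(f"Interindividual variability (%CV, {fit.cv_convention} convention)")
    for p, cv in fit.omega_cv_hat.items():
        r = fit.rse.get(f"omega:{p}", float("nan"))
        sh = fit.shrinkage.get(p, float("nan"))
        extra = f"  shrinkage {sh:.1f}%" if np.isfinite(sh) else ""
        rs = f" ({r:.1f})" if np.isfinite(r) else ""
        lines.append(f"  omega {p:<9}{cv:.1f}{rs}{extra}")
    if np.isfinite(fit.corr_cl_v_hat):
        lines.append(f"  corr(CL/F,V/F) {fit.corr_cl_v_hat:.3f}")
    lines.append("")
    lines.append("Residual error (SD, additive on log scale)")
    lines.append(f"  sigma RAL     {fit.sigma_hat['sigma_ral']:.4g}")
    lines.append(f"  sigma GLU     {fit.sigma_hat['sigma_glu']:.4g}")
    return "\n".join(lines)
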