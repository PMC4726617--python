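"""Vectorized closed-form kinetics of the transit-absorption parent-metabolite model.

The structural model is a chain: gamma-distributed transit input -> depot
(first-order ka) -> central (first-order elimination CL/V) -> metabolite
compartment of fixed volume with first-order clearance.  Because every stage
after the transit input is linear with constant coefficients, the whole
system reduces by partial fractions to convolutions of the gamma input
density with single exponentials,

    G_a(t) = int_0^t g(s; ktr, nn) exp(-a (t - s)) ds,

which have exact expressions in the lower incomplete gamma function
(a < ktr) or Kummer's confluent hypergeometric 1F1 (a > ktr).  Everything
here broadcasts over numpy arrays, so a whole cohort is simulated in one
call; the mixed-effects estimator depends on that.

Units package-wide: hours, mg, litres, mg/L.
"""

from __future__ import annotations

import numpy as np
from scipy import special

# Relative separation below which two rate constants are nudged apart to
# avoid catastrophic cancellation in the partial-fraction coefficients.
_RATE_SEP = 1e-7


def gamma_input_rate(t, dose, f, ktr, nn):
    """Drug input rate (mg/h) of the transit chain at time ``t`` since dose.

    rate(t) = dose*f * ktr*(ktr*t)**nn * exp(-ktr*t) / Gamma(nn+1),
    i.e. dose*f times the gamma(shape nn+1, rate ktr) density; its integral
    over [0, inf) is dose*f exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since dose must be non-negative")
    ktr = np.asarray(ktr, dtype=float)
    nn = np.asarray(nn, dtype=float)
    x = ktr * t
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rate = np.log(ktr) + nn * np.log(x) - x - special.gammaln(nn + 1.0)
    rate = np.asarray(dose, dtype=float) * np.asarray(f, dtype=float) * np.exp(log_rate)
    # x == 0: rate is 0 for nn > 0, dose*f*ktr for nn == 0
    rate = np.where(x == 0.0, np.where(nn > 0.0, 0.0, dose * f * ktr), rate)
    return rate


def _conv_gamma_exp(t, a, ktr, nn):
    """G_a(t) = int_0^t g(s; ktr, nn) exp(-a(t-s)) ds, elementwise.

    g is the gamma(nn+1, rate ktr) density.  Let c = a - ktr:

      c < 0:  G = exp(-a t) * (ktr/(ktr-a))**(nn+1) * P(nn+1, (ktr-a) t)
      c > 0:  G = exp(-a t) * (ktr t)**(nn+1)/Gamma(nn+2) * 1F1(nn+1; nn+2; c t)
      c = 0:  limit of either branch.

    P is the regularized lower incomplete gamma.  Both branches are exact;
    the 1F1 branch never overflows because exp(-a t) * exp(c t) = exp(-ktr t).
    """
    t, a, ktr, nn = np.broadcast_arrays(
        np.asarray(t, float), np.asarray(a, float),
        np.asarray(ktr, float), np.asarray(nn, float),
    )
    c = a - ktr
    z = c * t
    out = np.zeros(t.shape, dtype=float)

    # |z| ~ 0 (including the a == ktr pole): series limit of either branch,
    # G = exp(-a t) (ktr t)^(nn+1) / Gamma(nn+2), relative error O(z/(nn+2))
    near = np.abs(z) < 1e-8
    lower = (c < 0.0) & ~near
    upper = (c > 0.0) & ~near & (t > 0.0)
    if np.any(near):
        tt, aa, kk, vv = t[near], a[near], ktr[near], nn[near]
        with np.errstate(divide="ignore"):
            lg = -aa * tt + (vv + 1.0) * np.log(kk * tt) - special.gammaln(vv + 2.0)
        out[near] = np.where(tt == 0.0, 0.0, np.exp(lg))
    if np.any(lower):
        tt, aa, kk, vv = t[lower], a[lower], ktr[lower], nn[lower]
        b = kk - aa
        p = special.gammainc(vv + 1.0, b * tt)
        with np.errstate(divide="ignore"):
            lg = (-aa * tt + (vv + 1.0) * (np.log(kk) - np.log(b))
                  + np.log(p))
        out[lower] = np.where(p > 0.0, np.exp(lg), 0.0)
    # c > 0 splits at z = 30: Kummer 1F1 below (accurate, cheap for small z),
    # the integration-by-parts asymptotic series above (1F1 is slow and
    # overflow-prone at large argument)
    mod = upper & (z <= 30.0)
    big = upper & (z > 30.0)
    if np.any(mod):
        tt, aa, kk, vv, zz = t[mod], a[mod], ktr[mod], nn[mod], z[mod]
        log_pref = (-aa * tt + (vv + 1.0) * np.log(kk * tt)
                    - special.gammaln(vv + 2.0))
        with np.errstate(over="ignore", invalid="ignore"):
            val = np.exp(log_pref) * special.hyp1f1(vv + 1.0, vv + 2.0, zz)
        out[mod] = val
    if np.any(big):
        # int_0^t s^v e^{cs} ds ~ e^{ct} t^v / c * sum_k (-1)^k (v)_k / (ct)^k
        tt, kk, vv, zz = t[big], ktr[big], nn[big], z[big]
        cc = zz / tt
        s_sum = np.ones_like(zz)
        term = np.ones_like(zz)
        for k in range(1, 12):
            term = term * (-(vv - (k - 1.0)) / zz)
            s_sum = s_sum + term
        s_sum = np.maximum(s_sum, 1e-300)
        log_g = (-kk * tt + (vv + 1.0) * np.log(kk) + vv * np.log(tt)
                 - np.log(cc) - special.gammaln(vv + 1.0) + np.log(s_sum))
        out[big] = np.exp(log_g)
    return out


def _separate(a, b):
    """Nudge ``a`` away from ``b`` where they nearly coincide (pole guard)."""
    a = np.array(np.broadcast_to(a, np.broadcast_shapes(np.shape(a), np.shape(b))),
                 dtype=float, copy=True)
    b = np.asarray(b, dtype=float)
    close = np.abs(a - b) < _RATE_SEP * np.maximum(np.abs(a), np.abs(b))
    if np.any(close):
        a = np.where(close, b * (1.0 + 2.0 * _RATE_SEP), a)
    return a


def conc_single_dose(t, dose, cl, v, ka, mtt, nn, f, fmet, cl_glu, v_glu):
    """Parent and metabolite concentrations (mg/L) after one oral dose at t=0.

    All arguments broadcast; typical use has parameter arrays of shape
    (n_subjects, 1) against times of shape (n_times,) or (n_subjects, n_times).
    Negative times (pre-dose) yield 0.  Returns ``(c_parent, c_metabolite)``.
    """
    t = np.asarray(t, dtype=float)
    pre = t < 0.0
    tt = np.where(pre, 0.0, t)

    ktr = (np.asarray(nn, float) + 1.0) / np.asarray(mtt, float)
    k = np.asarray(cl, float) / np.asarray(v, float)
    km = np.asarray(cl_glu, float) / np.asarray(v_glu, float)
    ka = _separate(ka, k)
    km = _separate(_separate(km, k), ka)

    g_ka = _conv_gamma_exp(tt, ka, ktr, nn)
    g_k = _conv_gamma_exp(tt, k, ktr, nn)
    g_km = _conv_gamma_exp(tt, km, ktr, nn)

    # extreme optimizer excursions can overflow intermediates; downstream
    # consumers guard non-finite results, so the arithmetic runs silenced
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        amt = np.asarray(dose, float) * np.asarray(f, float)
        a_c = amt * ka / (ka - k) * (g_k - g_ka)
        c_parent = a_c / v
        c_met = (amt * np.asarray(fmet, float) * k * ka
                 / (np.asarray(v_glu, float) * (ka - k))
                 * ((g_k - g_km) / (km - k) - (g_ka - g_km) / (km - ka)))

        c_parent = np.where(pre, 0.0, np.maximum(c_parent, 0.0))
        c_met = np.where(pre, 0.0, np.maximum(c_met, 0.0))
    return c_parent, c_met


def conc_profile(times, dose_times, dose_amounts, cl, v, ka, mtt, nn, f,
                 fmet, cl_glu, v_glu):
    """Superpose :func:`conc_single_dose` over a list of dose events."""
    times = np.asarray(times, dtype=float)
    cp = np.zeros(np.broadcast_shapes(times.shape, np.shape(cl)), dtype=float)
    cm = np.zeros_like(cp)
    for td, amt in zip(dose_times, dose_amounts):
        p, m = conc_single_dose(times - td, amt, cl, v, ka, mtt, nn, f,
                                fmet, cl_glu, v_glu)
        cp = cp + p
        cm = cm + m
    return cp, cm
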