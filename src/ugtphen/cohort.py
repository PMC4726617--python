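"""Virtual probe-drug study generator.

Emulates the statistical structure of a 24-patient UGT1A1-phenotyping
study: a single 400 mg oral raltegravir dose with sampling at 0, 0.5, 1,
2, 4, 6, 8 and 24 h; covariates drawn within the published cohort's ranges
and genotype frequencies; individual PK parameters from the population
model; concentration profiles with log-scale residual error; nadir
absolute neutrophil count (ANC) generated from the published linear
relation ANC = 129.2 + 89461.5 * K23 plus Gaussian noise calibrated to a
target correlation; and a dose-delay indicator whose probability falls
with ANC (logistic), echoing the observed 16/24 delay rate.

The ANC noise model is a generative completion, not an observed quantity:
only the fitted line and its correlation are published, and Gaussian
additive noise calibrated to that correlation is the simplest model that
reproduces both.  ANC is kept on the arbitrary count scale of the
published regression and may be negative in the tails of the calibrated
noise; an optional floor is available but disabled by default because
truncation would distort the calibrated correlation.

Covariate marginals are sampled independently (no covariate-covariate
correlation is published), and genotypes are independent of PK parameters
by default; ``genotype_fmet_effect`` injects a genotype effect on FMET for
covariate-search power experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ConcentrationProfile, DoseEvent, StructuralParams, k23
from .population import (IndividualParams, PopulationModel,
                         apply_residual_error, sample_individuals)

__all__ = [
    "CohortConfig",
    "CohortTable",
    "default_population",
    "generate_cohort",
    "calibrate_anc_noise",
    "simulate_irinotecan_like",
]

#: Published sampling schedule (h post-dose), pre-dose baseline included.
SAMPLING_TIMES = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 24.0)

#: ANC ~ K23 regression line used as the generative truth.
ANC_INTERCEPT = 129.2
ANC_SLOPE = 89461.5
ANC_TARGET_R = 0.598

#: Genotype class frequencies (wt, het, var) out of 24 patients.
GENOTYPE_FREQS = {
    "UGT1A1_6": (17, 7, 0),
    "UGT1A1_28": (17, 7, 0),
    "UGT1A1_60": (12, 9, 3),
    "CYP3A5_3": (6, 7, 11),
}

#: Continuous covariate ranges (min, max) for uniform sampling.
COVARIATE_RANGES = {
    "bodyweight": (42.4, 81.1),
    "age": (39.0, 79.0),
    "creatinine_clearance": (36.7, 124.3),
    "bilirubin": (6.0, 27.0),
}

#: Male fraction (19 of 24).
MALE_FRACTION = 19.0 / 24.0

#: Dose-delay base rate (16 of 24 subjects delayed).
DELAY_FRACTION = 16.0 / 24.0


def default_population() -> PopulationModel:
    """The published final-model estimates as generative truth."""
    return PopulationModel(
        theta=StructuralParams(cl_f=41.7, v_f=157.0, ka=4.23, mtt=1.04,
                               nn=1.07, f=1.0, fmet=0.0324, cl_glu=0.715,
                               v_glu=1.0),
        omega_cv={"cl_f": 30.5, "v_f": 81.4, "mtt": 107.2, "f": 123.7,
                  "fmet": 37.7, "cl_glu": 13.6},
        corr_cl_v=0.57,
        sigma_ral=0.15,
        sigma_glu=0.18,
    )


@dataclass
class CohortConfig:
    """Study-design and generative settings for one virtual cohort."""

    n_subjects: int = 24
    dose_mg: float = 400.0
    sampling_times: tuple = SAMPLING_TIMES
    population: PopulationModel = field(default_factory=default_population)
    anc_intercept: float = ANC_INTERCEPT
    anc_slope: float = ANC_SLOPE
    anc_target_r: float = ANC_TARGET_R
    anc_sigma: float | None = None   # None -> calibrate to anc_target_r
    anc_floor: float | None = None   # None -> no positivity floor
    delay_fraction: float = DELAY_FRACTION
    delay_slope: float = -0.8        # logistic slope per SD of ANC
    genotype_fmet_effect: dict[str, float] = field(default_factory=dict)
    lloq: float = 0.0
    n_calibration: int = 20000

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be >= 0")
        if self.anc_sigma is not None and self.anc_sigma < 0:
            raise ValueError("anc_sigma must be >= 0")
        if not 0.0 <= self.delay_fraction <= 1.0:
            raise ValueError("delay_fraction must be in [0, 1]")


@dataclass
class CohortTable:
    """One generated virtual study.

    ``covariates`` holds one row per subject (demographics, genotypes,
    nadir ANC, dose-delay flag, individual PK parameters and K23);
    ``profiles`` maps subject id to the (parent, metabolite) profile pair
    with residual error applied; ``individuals`` keeps the exact sampled
    parameters and etas; ``anc_sigma`` records the noise SD actually used.
    """

    covariates: pd.DataFrame
    profiles: dict[str, tuple[ConcentrationProfile, ConcentrationProfile]]
    individuals: list[IndividualParams]
    anc_sigma: float
    config: CohortConfig

    def profile_pairs(self) -> list[tuple[ConcentrationProfile, ConcentrationProfile]]:
        return [self.profiles[s] for s in self.covariates.index]


def calibrate_anc_noise(pop: PopulationModel, target_r: float,
                        n_mc: int = 20000, seed: int = 0,
                        slope: float = ANC_SLOPE) -> float:
    """Noise SD making corr(ANC, K23) equal ``target_r`` in expectation.

    With ANC = a + b*K23 + eps, the population correlation is
    b*SD(K23) / sqrt(b^2 Var(K23) + sigma^2), so
    sigma = |b| * SD(K23) * sqrt(1/r^2 - 1).  SD(K23) is estimated by
    Monte-Carlo from the population model (``n_mc`` draws).
    """
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must be in (0, 1)")
    inds = sample_individuals(pop, n_mc, seed)
    k = np.array([k23(i.params) for i in inds])
    sd_k = float(np.std(k, ddof=1))
    return abs(slope) * sd_k * float(np.sqrt(1.0 / target_r**2 - 1.0))


def _sample_genotypes(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    out = {}
    for locus, counts in GENOTYPE_FREQS.items():
        p = np.asarray(counts, dtype=float)
        p = p / p.sum()
        out[locus] = rng.choice(3, size=n, p=p)
    return out


def generate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> CohortTable:
    """Generate one virtual study; fully reproducible given ``seed``.

    Returns the cohort table plus per-subject (parent, metabolite)
    concentration profiles simulated at the configured schedule with
    residual error.  The pre-dose sample is included as a zero
    concentration and carries no noise.
    """
    config = config or CohortConfig()
    pop = config.population
    rng = np.random.default_rng(seed)
    n = config.n_subjects

    individuals = sample_individuals(pop, n, rng)
    genotypes = _sample_genotypes(rng, n)

    # optional genotype effect on FMET: multiplier (1 + frac) per variant
    # allele, for covariate-search power experiments
    if config.genotype_fmet_effect:
        mult = np.ones(n)
        for locus, frac in config.genotype_fmet_effect.items():
            mult = mult * (1.0 + frac) ** genotypes[locus]
        for i, ind in enumerate(individuals):
            p = StructuralParams.__new__(StructuralParams)
            for fld in ("cl_f", "v_f", "ka", "mtt", "nn", "f", "fmet",
                        "cl_glu", "v_glu"):
                object.__setattr__(p, fld, getattr(ind.params, fld))
            object.__setattr__(p, "fmet", ind.params.fmet * mult[i])
            ind.params = p

    cov = {
        name: rng.uniform(lo, hi, size=n)
        for name, (lo, hi) in COVARIATE_RANGES.items()
    }
    sex = (rng.random(n) < MALE_FRACTION).astype(int)  # 1 = male

    sigma_anc = (config.anc_sigma if config.anc_sigma is not None
                 else calibrate_anc_noise(pop, config.anc_target_r,
                                          config.n_calibration, seed + 1,
                                          config.anc_slope))

    k23_i = np.array([k23(ind.params) for ind in individuals])
    anc = (config.anc_intercept + config.anc_slope * k23_i
           + rng.standard_normal(n) * sigma_anc)
    if config.anc_floor is not None:
        anc = np.maximum(anc, config.anc_floor)

    # dose delay: logistic in standardized ANC, centred to hit the
    # configured base rate at the median
    z = (anc - np.median(anc)) / max(np.std(anc), 1e-12)
    logit0 = np.log(config.delay_fraction / max(1.0 - config.delay_fraction, 1e-12))
    p_delay = 1.0 / (1.0 + np.exp(-(logit0 + config.delay_slope * z)))
    delay = (rng.random(n) < p_delay).astype(int)

    times = np.asarray(config.sampling_times, dtype=float)
    doses = [DoseEvent(0.0, config.dose_mg)]
    profiles = {}
    from .model_core import simulate_profile
    for ind in individuals:
        parent, metab = simulate_profile(ind.params, doses, times,
                                         subject_id=ind.subject_id)
        parent = apply_residual_error(parent, pop.sigma_ral, rng,
                                      lloq=config.lloq)
        metab = apply_residual_error(metab, pop.sigma_glu, rng,
                                     lloq=config.lloq)
        profiles[ind.subject_id] = (parent, metab)

    rows = {
        "bodyweight": cov["bodyweight"],
        "age": cov["age"],
        "sex": sex,
        "creatinine_clearance": cov["creatinine_clearance"],
        "bilirubin": cov["bilirubin"],
        **genotypes,
        "cl_f": [i.params.cl_f for i in individuals],
        "v_f": [i.params.v_f for i in individuals],
        "mtt": [i.params.mtt for i in individuals],
        "f": [i.params.f for i in individuals],
        "fmet": [i.params.fmet for i in individuals],
        "cl_glu": [i.params.cl_glu for i in individuals],
        "k23": k23_i,
        "nadir_anc": anc,
        "dose_delay": delay,
    }
    table = pd.DataFrame(rows, index=[i.subject_id for i in individuals])
    table.index.name = "subject_id"
    return CohortTable(covariates=table, profiles=profiles,
                       individuals=individuals, anc_sigma=float(sigma_anc),
                       config=config)


def simulate_irinotecan_like(
    n: int = 24,
    seed: int = 0,
    dose_mg: float = 300.0,
    times=(0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 22.0, 24.0, 28.0),
    cl: float = 25.0,
    v: float = 150.0,
    fmet: float = 0.05,
    cl_met: float = 12.0,
    frac_glu: float = 0.6,
    cl_glu: float = 9.0,
    iiv_cv: float = 40.0,
    sigma: float = 0.2,
) -> dict[str, tuple[ConcentrationProfile, ConcentrationProfile, ConcentrationProfile]]:
    """SYNTHETIC irinotecan/SN-38/SN-38G stand-in profiles for NCA testing.

    A deliberately simple one-compartment bolus parent with two sequential
    first-order metabolite compartments (unit volumes), log-normal IIV on
    all clearances and log-scale residual noise.  This is a synthetic
    exercise model only — no published compartmental model exists for
    these analytes in the study this package emulates — and it must not be
    interpreted pharmacologically.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    omega = np.sqrt(np.log1p((iiv_cv / 100.0) ** 2))
    out = {}
    for i in range(n):
        e = rng.standard_normal(3) * omega
        cli, clmi, clgi = cl * np.exp(e[0]), cl_met * np.exp(e[1]), cl_glu * np.exp(e[2])
        k10, k1m = cli / v, fmet * cli / v
        km = clmi  # unit metabolite volume
        kg = clgi
        # Bateman chains (distinct-rate assumption; IIV makes ties measure-zero)
        c_par = dose_mg / v * np.exp(-k10 * times)
        a = k1m * dose_mg
        c_met = a / (km - k10) * (np.exp(-k10 * times) - np.exp(-km * times))
        b = frac_glu * km
        c_glu = a * b * (
            np.exp(-k10 * times) / ((km - k10) * (kg - k10))
            + np.exp(-km * times) / ((k10 - km) * (kg - km))
            + np.exp(-kg * times) / ((k10 - kg) * (km - kg)))
        sid = f"I{i + 1:03d}"
        doses = [DoseEvent(0.0, dose_mg, route="oral")]
        profs = []
        for analyte, c in (("irinotecan", c_par), ("SN38", c_met),
                           ("SN38G", c_glu)):
            prof = ConcentrationProfile(sid, analyte, times,
                                        np.maximum(c, 0.0), doses)
            profs.append(apply_residual_error(prof, sigma, rng))
        out[sid] = tuple(profs)
    return out
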