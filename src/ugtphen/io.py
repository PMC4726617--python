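"""Dataset readers/writers, run configuration, and the pipeline driver.

The on-disk concentration dataset follows the conventional nonlinear
mixed-effects tabular layout: one CSV with columns

    ID, TIME, AMT, DV, EVID, MDV, CMT  (+ any per-subject covariate columns)

* dose rows:        EVID=1, MDV=1, AMT=dose (mg), CMT=1 (depot), DV empty
* observation rows: EVID=0, MDV=0, DV=concentration (mg/L),
                    CMT=2 parent (raltegravir), CMT=3 glucuronide
* pre-dose/below-limit rows: EVID=0, MDV=1 (kept, excluded from fitting)

Times are hours, concentrations mg/L, doses mg; comma-separated, period
decimal, UTF-8, mandatory header.  Lines starting with ``#`` are comments;
every file this package writes carries its provenance (config hash, seed)
in such comments.  ``write_dataset`` -> ``read_dataset`` round-trips
losslessly.

`RunConfig` is schema-validated (unknown keys rejected) before any
computation; `run_pipeline` executes generate -> fit -> covariate search ->
NCA -> derived constants -> associations and writes one report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .model_core import ConcentrationProfile, DoseEvent, StructuralParams, k23
from .population import PopulationModel
from . import association as assoc
from . import nca as nca_mod
from .cohort import (ANC_INTERCEPT, ANC_SLOPE, ANC_TARGET_R, SAMPLING_TIMES,
                     CohortConfig, CohortTable, generate_cohort)
from .estimation import (CovariateEffect, covariate_search, fit_population,
                         format_fit_report)

__all__ = [
    "RunConfig",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("ugtphen")

_CMT_ANALYTE = {2: "raltegravir", 3: "raltegravir_glucuronide"}
_ANALYTE_CMT = {v: k for k, v in _CMT_ANALYTE.items()}
_REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "MDV", "CMT")


class DatasetError(ValueError):
    """Malformed dataset; message carries the offending line/column."""


# ---------------------------------------------------------------------------
# configuration schema

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThetaBlock(_Strict):
    cl_f: float = 41.7
    v_f: float = 157.0
    ka: float = 4.23
    mtt: float = 1.04
    nn: float = 1.07
    f: float = 1.0
    fmet: float = 0.0324
    cl_glu: float = 0.715
    v_glu: float = 1.0


class PopulationBlock(_Strict):
    theta: ThetaBlock = Field(default_factory=ThetaBlock)
    omega_cv: dict[str, float] = Field(default_factory=lambda: {
        "cl_f": 30.5, "v_f": 81.4, "mtt": 107.2, "f": 123.7,
        "fmet": 37.7, "cl_glu": 13.6})
    corr_cl_v: float = 0.57
    sigma_ral: float = 0.15
    sigma_glu: float = 0.18
    cv_convention: Literal["lognormal", "naive"] = "lognormal"

    def build(self) -> PopulationModel:
        return PopulationModel(
            theta=StructuralParams(**self.theta.model_dump()),
            omega_cv=dict(self.omega_cv),
            corr_cl_v=self.corr_cl_v,
            sigma_ral=self.sigma_ral,
            sigma_glu=self.sigma_glu,
            cv_convention=self.cv_convention,
        )


class DesignBlock(_Strict):
    n_subjects: int = 24
    dose_mg: float = 400.0
    sampling_times: list[float] = Field(
        default_factory=lambda: list(SAMPLING_TIMES))
    anc_intercept: float = ANC_INTERCEPT
    anc_slope: float = ANC_SLOPE
    anc_target_r: float = ANC_TARGET_R
    anc_sigma: Optional[float] = None
    lloq: float = 0.0

    @field_validator("sampling_times")
    @classmethod
    def _increasing(cls, v):
        if len(v) < 2 or np.any(np.diff(v) <= 0):
            raise ValueError("sampling_times must be strictly increasing")
        return v


class EstimationBlock(_Strict):
    enabled: bool = True
    method: Literal["foce_i", "laplace"] = "foce_i"
    n_starts: int = 3
    jitter: float = 0.2
    maxiter: int = 400
    fixed: list[str] = Field(default_factory=lambda: ["f", "v_glu"])
    compute_rse: bool = True
    init_strategy: Literal["given", "two_stage"] = "two_stage"


class CovariateCandidate(_Strict):
    covariate: str
    parameter: str
    form: Literal["linear", "power", "fractional"]


class AssociationBlock(_Strict):
    anc_transform: Literal["raw", "log10"] = "raw"


class RunConfig(_Strict):
    """Validated configuration for one pipeline run."""

    seed: int = 0
    population: PopulationBlock = Field(default_factory=PopulationBlock)
    design: DesignBlock = Field(default_factory=DesignBlock)
    estimation: EstimationBlock = Field(default_factory=EstimationBlock)
    covariate_candidates: list[CovariateCandidate] = Field(default_factory=list)
    association: AssociationBlock = Field(default_factory=AssociationBlock)
    output_dir: str = "ugtphen_out"

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def cohort_config(self) -> CohortConfig:
        d = self.design
        return CohortConfig(
            n_subjects=d.n_subjects,
            dose_mg=d.dose_mg,
            sampling_times=tuple(d.sampling_times),
            population=self.population.build(),
            anc_intercept=d.anc_intercept,
            anc_slope=d.anc_slope,
            anc_target_r=d.anc_target_r,
            anc_sigma=d.anc_sigma,
            lloq=d.lloq,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML (or JSON) run configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# dataset I/O

def write_dataset(cohort: CohortTable, path: str | Path,
                  config_hash: str = "", seed: int | None = None) -> None:
    """Write the cohort's profiles (+ covariates) as one NONMEM-style CSV."""
    rows = []
    cov = cohort.covariates
    cov_cols = [c for c in cov.columns
                if c not in ("k23",)]  # k23 is derived, not a data column
    for sid in cov.index:
        parent, metab = cohort.profiles[sid]
        covariate_values = {c: cov.loc[sid, c] for c in cov_cols}
        for d in parent.doses:
            rows.append({"ID": sid, "TIME": d.time, "AMT": d.amount,
                         "DV": np.nan, "EVID": 1, "MDV": 1, "CMT": 1,
                         **covariate_values})
        for prof in (parent, metab):
            cmt = _ANALYTE_CMT[prof.analyte]
            for t, c in zip(prof.times, prof.concentrations):
                mdv = 1 if c <= 0.0 else 0
                rows.append({"ID": sid, "TIME": t, "AMT": np.nan, "DV": c,
                             "EVID": 0, "MDV": mdv, "CMT": cmt,
                             **covariate_values})
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(["ID", "TIME", "CMT"], kind="stable")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# ugtphen concentration dataset; times h, conc mg/L, dose mg\n")
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        frame.to_csv(fh, index=False)


def read_dataset(path: str | Path):
    """Parse a NONMEM-style CSV into profile pairs plus a covariate table.

    Returns ``(data, covariates)`` where ``data`` is a list of
    (parent, metabolite) :class:`ConcentrationProfile` pairs, one per
    subject in file order, and ``covariates`` is a per-subject DataFrame of
    the remaining columns.  Raises :class:`DatasetError` naming the line
    and column for malformed input.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise DatasetError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"{path}: missing required column(s) {missing}")

    # line numbers for error messages: comment/header offset
    with open(path, encoding="utf-8") as fh:
        offsets = [i + 1 for i, line in enumerate(fh)
                   if not line.startswith("#")]
    data_lines = offsets[1:]  # first non-comment line is the header

    def lineno(idx: int) -> int:
        return data_lines[idx] if idx < len(data_lines) else -1

    for col in ("TIME", "EVID", "MDV", "CMT"):
        bad = frame[col].isna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise DatasetError(
                f"{path}:{lineno(i)}: missing value in column {col}")
    obs = frame[frame["EVID"] == 0]
    bad_cmt = ~obs["CMT"].isin(_CMT_ANALYTE)
    if bad_cmt.any():
        i = int(obs.index[np.flatnonzero(bad_cmt)[0]])
        raise DatasetError(
            f"{path}:{lineno(i)}: observation row with unknown CMT "
            f"{frame.loc[i, 'CMT']!r} (expected 2 or 3)")
    bad_dv = (obs["MDV"] == 0) & obs["DV"].isna()
    if bad_dv.any():
        i = int(obs.index[np.flatnonzero(bad_dv)[0]])
        raise DatasetError(f"{path}:{lineno(i)}: MDV=0 observation without DV")

    cov_cols = [c for c in frame.columns if c not in _REQUIRED_COLUMNS]
    data = []
    cov_rows = {}
    for sid, grp in frame.groupby("ID", sort=False):
        doses_rows = grp[grp["EVID"] == 1]
        if doses_rows.empty:
            i = int(grp.index[0])
            raise DatasetError(
                f"{path}:{lineno(i)}: subject {sid!r} has no dose row")
        first_dose = doses_rows["TIME"].min()
        obs_g = grp[grp["EVID"] == 0]
        early = obs_g[(obs_g["TIME"] < first_dose)]
        if not early.empty:
            i = int(early.index[0])
            raise DatasetError(
                f"{path}:{lineno(i)}: subject {sid!r} has an observation at "
                f"t={early.iloc[0]['TIME']} before the first dose "
                f"(t={first_dose})")
        doses = [DoseEvent(float(r.TIME), float(r.AMT))
                 for r in doses_rows.itertuples()]
        pair = []
        for cmt, analyte in _CMT_ANALYTE.items():
            sub = obs_g[obs_g["CMT"] == cmt].sort_values("TIME")
            if sub["TIME"].duplicated().any():
                i = int(sub.index[sub["TIME"].duplicated()][0])
                raise DatasetError(
                    f"{path}:{lineno(i)}: duplicate time for subject "
                    f"{sid!r}, CMT {cmt}")
            pair.append(ConcentrationProfile(
                str(sid), analyte, sub["TIME"].to_numpy(float),
                np.nan_to_num(sub["DV"].to_numpy(float)), doses))
        data.append((pair[0], pair[1]))
        cov_rows[str(sid)] = {c: grp.iloc[0][c] for c in cov_cols}
    covariates = pd.DataFrame.from_dict(cov_rows, orient="index")
    covariates.index.name = "subject_id"
    return data, covariates


def _provenance_header(config: RunConfig) -> str:
    return f"# config_hash={config.config_hash()} seed={config.seed}\n"


def _write_csv(frame: pd.DataFrame, path: Path, config: RunConfig,
               index: bool = True) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_header(config))
        frame.to_csv(fh, index=index)


# ---------------------------------------------------------------------------
# pipeline

def _nca_table(cohort: CohortTable, dose_mg: float) -> pd.DataFrame:
    rows = []
    for sid in cohort.covariates.index:
        parent, metab = cohort.profiles[sid]
        res_p = nca_mod.nca_summary(parent, dose=dose_mg)
        res_m = nca_mod.nca_summary(metab)
        ratio, basis = nca_mod.metabolic_ratio(res_m, res_p)
        for analyte, r in (("raltegravir", res_p),
                           ("raltegravir_glucuronide", res_m)):
            rows.append({
                "subject_id": sid, "analyte": analyte,
                "auc_last": r.auc_last, "auc_inf": r.auc_inf,
                "lambda_z": r.lambda_z, "t_half": r.t_half,
                "cl_or_cl_f": r.cl_or_cl_f,
                "n_lambda_points": r.n_lambda_points,
                "r2_lambda": r.r2_lambda,
                "metabolic_ratio": ratio, "ratio_basis": basis,
            })
    return pd.DataFrame(rows).set_index(["subject_id", "analyte"])


def _association_table(table: pd.DataFrame, transform: str) -> pd.DataFrame:
    anc = table["nadir_anc"].to_numpy(float)
    label = "nadir_anc"
    if transform == "log10":
        anc = np.log10(np.maximum(anc, 1e-6))
        label = "log10_nadir_anc"
    k = table["k23"].to_numpy(float)
    out = []

    r = assoc.pearson(k, anc)
    out.append({"association": f"{label}~k23", "method": r.method,
                "estimate": r.estimate, "intercept": r.intercept,
                "p_value": r.p_value, "n": r.n})
    reg = assoc.linear_regression(k, anc)
    out.append({"association": f"{label}~k23", "method": reg.method,
                "estimate": reg.estimate, "intercept": reg.intercept,
                "p_value": reg.p_value, "n": reg.n})
    delay = table["dose_delay"].to_numpy(int)
    if 0 < delay.sum() < len(delay):
        w = assoc.wilcoxon_rank_sum(k[delay == 1], k[delay == 0])
        out.append({"association": "k23|dose_delay", "method": w.method,
                    "estimate": w.estimate, "intercept": np.nan,
                    "p_value": w.p_value, "n": w.n})
    for locus in ("UGT1A1_6", "UGT1A1_28", "UGT1A1_60", "CYP3A5_3"):
        if locus not in table.columns:
            continue
        groups = [anc[table[locus].to_numpy(int) == g] for g in (0, 1, 2)]
        groups = [g for g in groups if len(g)]
        if len(groups) >= 2:
            kw = assoc.kruskal_wallis(groups)
            out.append({"association": f"{label}|{locus}",
                        "method": kw.method, "estimate": kw.estimate,
                        "intercept": np.nan, "p_value": kw.p_value,
                        "n": kw.n})
    frame = pd.DataFrame(out)
    frame["note"] = "raw p-values; no multiplicity adjustment"
    return frame


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 dataset: str | Path | None = None) -> dict:
    """Execute the full pipeline and write the report bundle.

    Stages: generate (or load ``dataset``) -> population fit (optional) ->
    covariate search (optional) -> NCA -> per-subject K23 -> associations.
    Any stage failure raises with the stage name; outputs written so far
    are preserved.  Returns a dict of the in-memory results.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    stage = "generate"
    try:
        if dataset is None:
            cohort = generate_cohort(config.cohort_config(), seed=config.seed)
            log.info("generated cohort: n=%d subjects, sigma_anc=%.1f",
                     config.design.n_subjects, cohort.anc_sigma)
        else:
            data, cov = read_dataset(dataset)
            cohort = CohortTable(
                covariates=cov,
                profiles={p.subject_id: (p, m) for p, m in data},
                individuals=[], anc_sigma=float("nan"),
                config=config.cohort_config())
            log.info("loaded dataset %s: n=%d subjects", dataset, len(data))
        write_dataset(cohort, out / "dataset.csv", config.config_hash(),
                      config.seed)
        _write_csv(cohort.covariates, out / "cohort.csv", config)
        (out / "config.yaml").write_text(
            yaml.safe_dump(config.model_dump(), sort_keys=True),
            encoding="utf-8")
        results["cohort"] = cohort

        stage = "fit_population"
        fit = None
        if config.estimation.enabled:
            est = config.estimation
            fit = fit_population(
                cohort.profile_pairs(), config.population.build(),
                fixed=tuple(est.fixed), n_starts=est.n_starts,
                jitter=est.jitter, seed=config.seed, method=est.method,
                maxiter=est.maxiter, compute_rse=est.compute_rse,
                init_strategy=est.init_strategy)
            results["fit"] = fit
            (out / "fit_report.txt").write_text(
                _provenance_header(config) + format_fit_report(fit),
                encoding="utf-8")
            (out / "fit.json").write_text(
                json.dumps({"provenance": {"config_hash": config.config_hash(),
                                           "seed": config.seed},
                            **fit.to_dict()}, indent=1, default=float),
                encoding="utf-8")
            log.info("population fit: OFV=%.2f (%s)", fit.ofv, fit.convergence)

        stage = "covariate_search"
        if fit is not None and config.covariate_candidates:
            cands = [CovariateEffect(c.parameter, c.covariate, c.form)
                     for c in config.covariate_candidates]
            sr = covariate_search(fit, cohort.profile_pairs(),
                                  cohort.covariates, cands,
                                  fit_kwargs={"n_starts": 1,
                                              "maxiter": config.estimation.maxiter,
                                              "compute_rse": False})
            results["covariate_search"] = sr
            pd.DataFrame(sr.steps).to_csv(out / "covariate_steps.csv",
                                          index=False)
            fit = sr.final_model
            log.info("covariate search: %d included",
                     len(sr.included))

        stage = "nca"
        nca_frame = _nca_table(cohort, config.design.dose_mg)
        _write_csv(nca_frame, out / "nca.csv", config)
        results["nca"] = nca_frame

        stage = "derived_constants"
        table = cohort.covariates.copy()
        if fit is not None:
            k23_hat = {ip.subject_id: k23(ip.params)
                       for ip in fit.individual_params()}
            table["k23"] = [k23_hat[s] for s in table.index]
        if "k23" in table.columns:
            results["k23"] = table["k23"]

        stage = "associations"
        if {"k23", "nadir_anc", "dose_delay"} <= set(table.columns):
            assoc_frame = _association_table(
                table, config.association.anc_transform)
            _write_csv(assoc_frame, out / "associations.csv", config,
                       index=False)
            results["associations"] = assoc_frame
        else:
            log.warning("associations skipped: dataset lacks k23/nadir_anc/"
                        "dose_delay columns and no fit is available")

        stage = "provenance"
        prov = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
            "numpy_version": np.__version__,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=1),
                                             encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
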