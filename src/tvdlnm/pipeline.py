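"""End-to-end orchestration: fit, indicators, trends, report, sensitivity.

``run_pipeline`` takes a daily series and a configuration and produces, for
every stratum: the fitted time-varying DLNM, the interaction Wald test,
per-year MMT/cRR indicators, trend and coupling regressions, annual curve
CSVs, and a combined first/last-year report table.  All randomness flows
from one root seed, split deterministically per stratum, so identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .dataio import DailySeries, get_logger
from .indicators import annual_indicators, predict_curve, temperature_trends
from .inference import coupling_regression, wald_interaction_test, wls_trend
from .qpoisson import qaic
from .tvmodel import assemble_design, coefficients_at_time, fit_tv_model

__all__ = ["StratumResult", "PipelineResult", "run_pipeline",
           "run_sensitivity", "analyse_stratum"]

_ANCHORS = ("extreme_cold", "moderate_cold", "moderate_heat", "extreme_heat")


@dataclass
class StratumResult:
    stratum: str
    fit: object
    design: object
    wald: object
    annual: list                  # AnnualIndicators per year
    mmt_trend: object
    crr_trends: dict              # anchor -> TrendResult
    couplings: dict               # name -> TrendResult


@dataclass
class PipelineResult:
    config: RunConfig
    strata: dict = field(default_factory=dict)
    temp_trends: pd.DataFrame = None
    report: pd.DataFrame = None


def _stratum_rng(seed: int, stratum: str) -> np.random.Generator:
    digest = hashlib.sha256(stratum.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def analyse_stratum(series: DailySeries, stratum: str,
                    config: RunConfig) -> StratumResult:
    """Fit one stratum and compute all of its indicators and tests."""
    design = assemble_design(series, stratum, config)
    fit = fit_tv_model(design)
    wald = wald_interaction_test(fit, design) if config.interaction else None
    rng = _stratum_rng(config.seed, stratum)
    years = sorted(series.frame["date"].dt.year.unique())
    annual = [annual_indicators(fit, design, y, rng) for y in years]

    yrs = np.array([a.year for a in annual], dtype=float)
    mmt_vals = np.array([a.mmt.mmt for a in annual])
    mmt_ses = np.array([max(a.mmt.se, 1e-6) for a in annual])
    mmt_trend = wls_trend(yrs, mmt_vals, mmt_ses)
    crr_trends = {}
    for name in _ANCHORS:
        est = np.array([a.crr[name][0] for a in annual])
        se = np.array([max((np.log(a.crr[name][2]) - np.log(a.crr[name][1]))
                          / (2 * 1.959963984540054), 1e-6) for a in annual])
        crr_trends[name] = wls_trend(yrs, np.log(est), se)
    amt = np.array([a.amt for a in annual])
    p1 = np.array([a.p1 for a in annual])
    p99 = np.array([a.p99 for a in annual])
    heat = np.log([a.crr["extreme_heat"][0] for a in annual])
    cold = np.log([a.crr["extreme_cold"][0] for a in annual])
    couplings = {
        "mmt_vs_amt": coupling_regression(amt, mmt_vals, mmt_ses),
        "crr_heat_vs_p99": coupling_regression(p99, heat),
        "crr_cold_vs_p1": coupling_regression(p1, cold),
    }
    return StratumResult(stratum=stratum, fit=fit, design=design, wald=wald,
                         annual=annual, mmt_trend=mmt_trend,
                         crr_trends=crr_trends, couplings=couplings)


def _fmt_trend(name, tr):
    return {"indicator": name, "slope": tr.slope, "intercept": tr.intercept,
            "slope_se": tr.slope_se, "r_squared": tr.r_squared,
            "f_statistic": tr.f_statistic, "p_value": tr.p_value,
            "pearson_r": tr.pearson_r}


def _write_stratum(res: StratumResult, outdir: str, written: list) -> None:
    s = res.stratum
    cfg = res.design.config

    def emit(df, name):
        path = os.path.join(outdir, name)
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    if res.wald is not None:
        emit(pd.DataFrame([{"statistic": res.wald.statistic,
                            "df": res.wald.df,
                            "p_value": res.wald.p_value}]), f"wald_{s}.csv")
    emit(pd.DataFrame([{
        "year": a.year, "mmt": a.mmt.mmt, "eci_low": a.mmt.eci_low,
        "eci_high": a.mmt.eci_high, "se": a.mmt.se,
        "boundary_dominated": int(a.mmt.boundary_dominated),
        "outside_eci": int(a.mmt.outside_eci)} for a in res.annual]),
        f"mmt_{s}.csv")
    rows = []
    for a in res.annual:
        row = {"year": a.year, "amt": a.amt, "p1": a.p1, "p10": a.p10,
               "p90": a.p90, "p99": a.p99, "mmt": a.mmt.mmt}
        for name in _ANCHORS:
            est, lo, hi = a.crr[name]
            row.update({f"crr_{name}": est, f"crr_{name}_low": lo,
                        f"crr_{name}_high": hi})
        rows.append(row)
    emit(pd.DataFrame(rows), f"indicators_{s}.csv")
    trend_rows = [_fmt_trend("mmt", res.mmt_trend)]
    trend_rows += [_fmt_trend(f"log_crr_{k}", v)
                   for k, v in res.crr_trends.items()]
    trend_rows += [_fmt_trend(k, v) for k, v in res.couplings.items()]
    emit(pd.DataFrame(trend_rows), f"trends_{s}.csv")

    for a in res.annual:
        centre = pd.Timestamp(year=a.year, month=cfg.centre_month,
                              day=cfg.centre_day)
        tslice = coefficients_at_time(res.fit, res.design, centre)
        grid = np.round(np.arange(np.floor(a.p1), np.ceil(a.p99) + 0.05, 0.1),
                        6)
        curve = predict_curve(tslice, grid, a.mmt.mmt,
                              res.design.exposure_spec, res.design.lag_spec,
                              cfg.max_lag)
        emit(pd.DataFrame({"temperature": curve.grid, "crr": curve.crr,
                           "crr_low": curve.crr_low,
                           "crr_high": curve.crr_high}),
             f"curves_{s}_{a.year}.csv")


def _report_frame(results: dict) -> pd.DataFrame:
    rows = []
    for s, res in results.items():
        first, last = res.annual[0], res.annual[-1]
        for a in (first, last):
            row = {"stratum": s, "year": a.year, "mmt": a.mmt.mmt}
            for name in _ANCHORS:
                est, lo, hi = a.crr[name]
                row[f"crr_{name}"] = est
                row[f"crr_{name}_ci"] = f"({lo:.2f};{hi:.2f})"
            row["wald_p"] = res.wald.p_value if res.wald else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(series: DailySeries, config: RunConfig,
                 outdir: str) -> PipelineResult:
    """Run the full analysis for every configured stratum and write outputs.

    On any stratum failure, partial outputs written so far are removed and
    the error re-raised with stratum context.
    """
    log = get_logger()
    os.makedirs(outdir, exist_ok=True)
    written = []
    result = PipelineResult(config=config)
    strata = [s for s in config.strata if s in series.strata]
    if not strata:
        raise ValueError(f"none of the configured strata {config.strata} "
                         f"present in series (has {series.strata})")
    try:
        for s in strata:
            log.info("pipeline: analysing stratum %r", s)
            res = analyse_stratum(series, s, config)
            result.strata[s] = res
            _write_stratum(res, outdir, written)
        result.temp_trends = temperature_trends(series, config)
        path = os.path.join(outdir, "temperature_trends.csv")
        result.temp_trends.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
        result.report = _report_frame(result.strata)
        path = os.path.join(outdir, "report.csv")
        result.report.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = os.path.join(outdir, "run_manifest.txt")
    cfg_text = "\n".join(f"{k}: {v}" for k, v in sorted(
        config.to_dict().items()))
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    with open(manifest, "w") as fh:
        fh.write(f"tvdlnm version: {__version__}\n"
                 f"config hash: {cfg_hash}\nseed: {config.seed}\n\n"
                 f"{cfg_text}\n")
    return result


def run_sensitivity(series: DailySeries, base_config: RunConfig,
                    deltas: list, stratum: str, outdir: str = None):
    """Fit a grid of alternative parametrizations and rank them by qAIC.

    ``deltas`` is a list of config-override dicts (an empty dict is the
    base model).  The selected model has minimal qAIC among the entries
    that fit; ties break by fewest parameters, then declaration order.
    Failing entries are marked and the grid continues.
    """
    if len(deltas) < 2:
        raise ValueError("sensitivity grid needs at least 2 entries")
    log = get_logger()
    from .qpoisson import fit_quasipoisson

    descs = [",".join(f"{k}={v}" for k, v in d.items()) or "base"
             for d in deltas]
    designs = {}
    for i, delta in enumerate(deltas):
        try:
            cfg = base_config.replace(**delta)
            designs[i] = assemble_design(series, stratum, cfg)
        except Exception as exc:
            log.warning("sensitivity entry %d (%s) failed to assemble: %s",
                        i, descs[i], exc)
    if not designs:
        raise RuntimeError("every sensitivity entry failed")
    # likelihoods are compared on the rows usable by *every* candidate so
    # that differing lag windows do not change the data under comparison
    common = np.logical_and.reduce([d.rows_used for d in designs.values()])
    fits = {}
    rows = []
    per_entry = {}
    years = sorted(series.frame["date"].dt.year.unique())
    for i, delta in enumerate(deltas):
        if i not in designs:
            rows.append({"model": i, "description": descs[i], "qaic": np.nan,
                         "loglik": np.nan, "dispersion": np.nan,
                         "n_params": np.nan, "status": "failed"})
            continue
        design = designs[i]
        try:
            sub = common[design.rows_used]
            fit = fit_quasipoisson(design.y[sub], design.X[sub],
                                   col_names=design.col_names)
            fits[i] = (fit, design)
            rng = _stratum_rng(design.config.seed, f"{stratum}:grid{i}")
            ann = [annual_indicators(fit, design, y, rng) for y in years]
            per_entry[i] = pd.DataFrame([{
                "model": i, "year": a.year, "mmt": a.mmt.mmt,
                "crr_extreme_heat": a.crr["extreme_heat"][0],
                "crr_extreme_cold": a.crr["extreme_cold"][0]} for a in ann])
            rows.append({"model": i, "description": descs[i], "qaic": np.nan,
                         "loglik": fit.poisson_loglik,
                         "dispersion": fit.dispersion,
                         "n_params": fit.n_params, "status": "ok"})
        except Exception as exc:
            log.warning("sensitivity entry %d (%s) failed: %s", i, descs[i],
                        exc)
            rows.append({"model": i, "description": descs[i], "qaic": np.nan,
                         "loglik": np.nan, "dispersion": np.nan,
                         "n_params": np.nan, "status": "failed"})
    grid = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError("every sensitivity entry failed")
    # common dispersion from the most complex candidate (ties: best fit),
    # so qAIC is monotone in likelihood at equal dimension
    ref = max(fits, key=lambda i: (fits[i][0].n_params,
                                   fits[i][0].poisson_loglik))
    phi_ref = fits[ref][0].dispersion
    for i, (fit, _) in fits.items():
        grid.loc[grid["model"] == i, "qaic"] = qaic(fit, dispersion=phi_ref)
    grid["ref_dispersion"] = phi_ref
    ok = grid[grid["status"] == "ok"]
    ranked = ok.sort_values(["qaic", "n_params", "model"], kind="stable")
    selected = int(ranked["model"].iloc[0])
    grid["selected"] = (grid["model"] == selected).astype(int)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        grid.to_csv(os.path.join(outdir, f"sensitivity_{stratum}.csv"),
                    index=False, float_format="%.6g")
        if per_entry:
            pd.concat(per_entry.values()).to_csv(
                os.path.join(outdir, f"sensitivity_series_{stratum}.csv"),
                index=False, float_format="%.6g")
    return grid, selected
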