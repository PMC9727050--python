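"""Shared scenario and paths for the numbered analysis drivers."""

import os

from tvdlnm import RunConfig, ScenarioTruth, read_daily_series, simulate_city

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
DATA_DIR = os.path.join(ROOT, "scratch", "data")
RESULTS_DIR = os.path.join(ROOT, "results")
SERIES_CSV = os.path.join(DATA_DIR, "daily_series.csv")

SEED = 20260901
N_YEARS = 19
N_BOOT = 300


def scenario() -> ScenarioTruth:
    """Default study scenario: 19-year city, ~600 deaths/day overall plus a
    half-rate subgroup, MMT drifting 0.09 C/year."""
    return ScenarioTruth(strata={"all": 1.0, "female": 0.5})


def run_config(**kw) -> RunConfig:
    base = dict(seed=SEED, n_boot=N_BOOT, strata=("all", "female"))
    base.update(kw)
    return RunConfig(**base)


def load_series():
    """Read the simulated series, regenerating it if 01 has not been run."""
    if not os.path.exists(SERIES_CSV):
        from tvdlnm import write_daily_series
        os.makedirs(DATA_DIR, exist_ok=True)
        series, truth_mmt, truth_crr = simulate_city(scenario(), N_YEARS,
                                                     seed=SEED)
        write_daily_series(series, SERIES_CSV)
        truth_mmt.to_csv(os.path.join(DATA_DIR, "truth_mmt.csv"), index=False)
        truth_crr.to_csv(os.path.join(DATA_DIR, "truth_crr.csv"), index=False)
        return series
    return read_daily_series(SERIES_CSV)
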