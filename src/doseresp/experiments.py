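"""Monte-Carlo experiment harness: type-I error / power of the flat-null
test and coverage of the inverted-test confidence bands under the two
benchmark simulation settings.

Every replicate is generated and analyzed from a seed derived
deterministically from the base seed and the replicate index, so a report
is reproducible bit for bit from its configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import synthetic
from .bands import BandConfig, BandInfeasibleError, confidence_band
from .nuisance import LearnerConfig
from .testing import TestConfig, flat_null_test

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_size_power_experiment",
    "run_coverage_experiment",
]

log = logging.getLogger(__name__)

#: fraction of replicates allowed to fail before the experiment aborts
FAILURE_BUDGET = 0.02


@dataclass(frozen=True)
class ExperimentConfig:
    setting: str = "flat_null"
    n_list: tuple[int, ...] = (100, 300, 500)
    reps: int = 250
    alpha: float = 0.05
    estimator: str = "one_step"
    kappa: float | str = "oracle"  # "oracle" | "adaptive" | numeric
    nu: float | str = "oracle"  # coverage experiments only
    M: int = 1000
    base_seed: int = 0
    grid_size: int = 50
    learner: str = "ridge_poly"
    oracle_nuisances: bool = False

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    rates: pd.DataFrame  # per-n summary rates with Monte-Carlo SEs
    records: pd.DataFrame  # per-replicate records


def _resolve_kappa(config: ExperimentConfig):
    if config.kappa == "oracle":
        return synthetic.oracle_kappa()
    return config.kappa


def _test_config(config: ExperimentConfig, seed: int) -> TestConfig:
    return TestConfig(
        estimator=config.estimator,
        kappa=_resolve_kappa(config),
        M=config.M,
        alpha=config.alpha,
        seed=seed,
        learner=LearnerConfig(learner=config.learner),
    )


def _nuisances(sample, config: ExperimentConfig):
    if not config.oracle_nuisances:
        return None, None
    return (
        synthetic.OracleOutcomeRegression(config.setting),
        synthetic.OracleConditionalDensity(),
    )


def _mc_se(p: float, reps: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / reps))


def run_size_power_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Rejection rates of the flat-null test across sample sizes.

    Under ``flat_null`` the rejection rate at alpha estimates the type-I
    error; under ``cubic_alt`` it estimates power.  Individual replicate
    failures are logged and tolerated up to a small budget.
    """
    rows, rates = [], []
    idx = 0
    for n in config.n_list:
        failures = 0
        for rep in range(config.reps):
            seed = config.base_seed + idx
            idx += 1
            try:
                sample = synthetic.generate_dataset(
                    synthetic.DgpSpec(config.setting, n, seed)
                )
                qfit, gfit = _nuisances(sample, config)
                res = flat_null_test(
                    sample, None, _test_config(config, seed), qfit=qfit, gfit=gfit
                )
                rows.append(
                    dict(n=n, rep=rep, seed=seed, statistic=res.statistic,
                         p_value=res.p_value, kappa=res.kappa_used,
                         reject=res.p_value <= config.alpha)
                )
            except Exception as exc:
                failures += 1
                log.warning("replicate (n=%d, rep=%d) failed: %s", n, rep, exc)
                if failures > max(1, FAILURE_BUDGET * config.reps):
                    raise
        done = config.reps - failures
        rate = float(np.mean([r["reject"] for r in rows if r["n"] == n]))
        rates.append(
            dict(n=n, rejection_rate=rate, se=_mc_se(rate, done),
                 reps=done, failures=failures)
        )
    return ExperimentReport(config, pd.DataFrame(rates), pd.DataFrame(rows))


def run_coverage_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Simultaneous and average pointwise coverage of the bands.

    Each replicate builds the band on an equispaced exposure grid and
    checks containment of the true centered dose-response curve
    (quadrature-centered under the population exposure law) at every grid
    point.
    """
    if config.setting != "cubic_alt":
        raise ValueError("coverage experiments use the cubic_alt setting")
    nu = synthetic.oracle_nu() if config.nu == "oracle" else config.nu
    rows, rates = [], []
    idx = 0
    for n in config.n_list:
        failures = 0
        grid = np.linspace(*synthetic.EXPOSURE_BOUNDS, config.grid_size)
        truth = synthetic.true_theta_centered(grid, "cubic_alt")
        for rep in range(config.reps):
            seed = config.base_seed + idx
            idx += 1
            try:
                sample = synthetic.generate_dataset(
                    synthetic.DgpSpec("cubic_alt", n, seed)
                )
                qfit, gfit = _nuisances(sample, config)
                band = confidence_band(
                    sample, grid, config.alpha,
                    BandConfig(test=_test_config(config, seed), nu=nu,
                               grid_size=config.grid_size),
                    qfit=qfit, gfit=gfit,
                )
                hit = band.contains(truth)
                ok = ~band.failed_points
                rows.append(
                    dict(n=n, rep=rep, seed=seed,
                         simultaneous=bool(np.all(hit[ok])) and bool(np.all(ok)),
                         pointwise=float(np.mean(hit[ok])),
                         width=float(np.median(band.width[ok])),
                         nu=band.nu, t_star=band.t_star)
                )
            except BandInfeasibleError:
                # empty confidence set: every candidate rejected -> the
                # band fails to cover anywhere (not a numerical failure)
                rows.append(
                    dict(n=n, rep=rep, seed=seed, simultaneous=False,
                         pointwise=0.0, width=0.0, nu=np.nan, t_star=np.nan)
                )
            except Exception as exc:
                failures += 1
                log.warning("replicate (n=%d, rep=%d) failed: %s", n, rep, exc)
                if failures > max(1, FAILURE_BUDGET * config.reps):
                    raise
        sub = [r for r in rows if r["n"] == n]
        sim = float(np.mean([r["simultaneous"] for r in sub]))
        rates.append(
            dict(n=n,
                 simultaneous_coverage=sim,
                 pointwise_coverage=float(np.mean([r["pointwise"] for r in sub])),
                 median_width=float(np.median([r["width"] for r in sub])),
                 se=_mc_se(sim, len(sub)),
                 reps=len(sub), failures=failures)
        )
    return ExperimentReport(config, pd.DataFrame(rates), pd.DataFrame(rows))
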