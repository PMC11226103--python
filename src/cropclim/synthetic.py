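"""Synthetic climate tables and production panels with known ground truth.

The generator draws data from the same model the inference engine fits: a
monthly climate process (mean + per-municipality offset + linear yearly trend
+ sinusoidal seasonality + Gaussian noise) aggregated to yearly covariates,
and a recursive Poisson production panel

    y_{i,1} ~ round(LogNormal(baseline_log_mean, baseline_log_sd))
    y_{i,t} ~ Poisson(y_{i,t-1} * exp(alpha + gamma_i + delta_t + beta*x_it))

with iid Gaussian municipality effects gamma and a sum-to-zero Gaussian
random walk delta over years.  Because the offset is the previous observed
value, a chain that reaches zero stays at zero; the design builder later
drops those rows, mirroring how real panels with non-producing years are
handled.  The default baseline (log 5000) makes extinction negligible at the
default effect scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .climate import MONTHLY_COLUMNS, MONTHLY_TO_YEARLY, aggregate_yearly
from .model import CROPS, validate_panel

FIRST_YEAR = 2007


@dataclass
class SimConfig:
    """Ground-truth parameters and dimensions of a simulated study.

    Defaults reproduce the parameter-recovery study design: 150
    municipalities over 14 years with alpha=0.05, beta=0.025 on the average
    temperature, sd(gamma)=0.3 and RW innovation sd 0.1.  The climate process
    defaults give a tropical mean of 25 degC, a 0.05 degC/yr warming trend
    and unit monthly noise so the covariate varies across municipalities and
    years.
    """

    n_municipalities: int = 150
    n_years: int = 14
    crops: tuple = ("coffee",)
    alpha_true: float = 0.05
    beta_true: float = 0.025
    sigma_gamma: float = 0.3
    sigma_delta: float = 0.1
    baseline_log_mean: float = float(np.log(5000.0))
    baseline_log_sd: float = 1.0
    covariate_mean: float = 25.0
    covariate_sd: float = 1.0
    covariate_trend: float = 0.05
    seed: int = 0
    # climate-process plumbing
    season_amplitude: float = 2.0
    temp_spread: float = 5.0
    monthly_variables: tuple = ("tmin", "tmax", "ppt")
    model_variable: str = "avg_temperature"

    def __post_init__(self) -> None:
        if self.n_municipalities <= 0 or self.n_years < 2:
            raise ValueError(
                "need n_municipalities >= 1 and n_years >= 2 "
                f"(got {self.n_municipalities}, {self.n_years})"
            )
        if self.sigma_gamma < 0 or self.sigma_delta < 0:
            raise ValueError("random-effect scales must be non-negative")
        if not self.crops:
            raise ValueError("at least one crop label is required")
        unknown = set(self.monthly_variables) - set(MONTHLY_TO_YEARLY)
        if unknown:
            raise ValueError(f"unknown monthly variables: {sorted(unknown)}")

    @property
    def municipality_codes(self) -> list:
        return [f"{i + 1:05d}" for i in range(self.n_municipalities)]

    @property
    def years(self) -> list:
        return [FIRST_YEAR + t for t in range(self.n_years)]


@dataclass
class SimTruth:
    """Simulated data together with every latent quantity that generated it."""

    config: SimConfig
    gamma_true: np.ndarray
    delta_true: np.ndarray
    panel: pd.DataFrame
    climate: pd.DataFrame
    monthly: pd.DataFrame = field(repr=False, default=None)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_climate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (yearly, monthly) climate tables for the configured grid.

    The latent monthly process for municipality i, year index k, month m is

        c = covariate_mean + offset_i + covariate_trend*k
            + season_amplitude*sin(2*pi*(m-1)/12) + Normal(0, covariate_sd)

    with offset_i ~ Normal(0, covariate_sd).  Temperature variables are
    tmin = c - temp_spread and tmax = c + temp_spread so the yearly midpoint
    average recovers the process mean exactly when the noise is zero; other
    requested variables get independent draws of the same process shape.
    """
    rng = _rng(config, 1)
    N, Y = config.n_municipalities, config.n_years
    codes = config.municipality_codes
    years = config.years

    muni_offset = rng.normal(0.0, config.covariate_sd, size=N)
    kk = np.arange(Y)
    mm = np.arange(12)
    season = config.season_amplitude * np.sin(2.0 * np.pi * mm / 12.0)
    base = (
        config.covariate_mean
        + muni_offset[:, None, None]
        + config.covariate_trend * kk[None, :, None]
        + season[None, None, :]
    )  # (N, Y, 12)

    temp_vars = [v for v in config.monthly_variables if v in ("tmin", "tmax")]
    other_vars = [v for v in config.monthly_variables if v not in ("tmin", "tmax")]

    frames = []
    idx = pd.MultiIndex.from_product(
        [codes, years, range(1, 13)], names=["municipality_code", "year", "month"]
    )
    if temp_vars:
        c = base + rng.normal(0.0, config.covariate_sd, size=base.shape)
        for v in temp_vars:
            spread = -config.temp_spread if v == "tmin" else config.temp_spread
            frames.append(
                pd.DataFrame(
                    {"variable": v, "value": (c + spread).ravel()}, index=idx
                )
            )
    for v in other_vars:
        c = base + rng.normal(0.0, config.covariate_sd, size=base.shape)
        frames.append(pd.DataFrame({"variable": v, "value": c.ravel()}, index=idx))

    monthly = pd.concat(frames).reset_index()[list(MONTHLY_COLUMNS)]
    yearly = aggregate_yearly(monthly)
    return yearly, monthly


def simulate_panel(config: SimConfig, climate: pd.DataFrame) -> SimTruth:
    """Draw a production panel from the generative model, returning the truth.

    Requires ``climate`` to cover every configured municipality-year with the
    configured model covariate.  The same gamma/delta realizations apply to
    every crop; Poisson draws are independent across crops.
    """
    rng = _rng(config, 2)
    N, Y = config.n_municipalities, config.n_years
    codes = config.municipality_codes
    years = config.years

    xt = climate.set_index(["municipality_code", "year"])[config.model_variable]
    try:
        x = (
            xt.loc[pd.MultiIndex.from_product([codes, years])]
            .to_numpy(dtype=float)
            .reshape(N, Y)
        )
    except KeyError as exc:
        raise ValueError("climate does not cover every municipality-year") from exc
    if np.isnan(x).any():
        raise ValueError("climate has missing covariate values")

    gamma = rng.normal(0.0, config.sigma_gamma, size=N) if config.sigma_gamma else np.zeros(N)
    innov = rng.normal(0.0, config.sigma_delta, size=Y - 1) if config.sigma_delta else np.zeros(Y - 1)
    delta = np.concatenate([[0.0], np.cumsum(innov)])
    delta -= delta.mean()  # sum-to-zero identification

    records = []
    for crop in config.crops:
        y = np.zeros((N, Y), dtype=np.int64)
        y[:, 0] = np.rint(
            rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=N)
        ).astype(np.int64)
        for t in range(1, Y):
            eta = config.alpha_true + gamma + delta[t] + config.beta_true * x[:, t]
            lam = y[:, t - 1] * np.exp(eta)
            alive = lam > 0
            draw = np.zeros(N, dtype=np.int64)
            if alive.any():
                draw[alive] = rng.poisson(lam[alive])
            y[:, t] = draw  # dead chains stay at zero
        for i, code in enumerate(codes):
            for t, yr in enumerate(years):
                records.append((code, yr, crop, int(y[i, t])))

    panel = validate_panel(
        pd.DataFrame(records, columns=["municipality_code", "year", "crop", "production"])
    )
    return SimTruth(
        config=config, gamma_true=gamma, delta_true=delta, panel=panel, climate=climate
    )


def default_study_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard five-crop study grid with default true parameters."""
    kwargs = dict(crops=CROPS, seed=seed)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def write_truth(truth: SimTruth, path) -> None:
    """Persist ground-truth parameters as flat key=value lines."""
    lines = []
    for k, v in asdict(truth.config).items():
        if isinstance(v, (tuple, list)):
            v = ",".join(str(u) for u in v)
        lines.append(f"config.{k}={v}")
    for i, g in enumerate(truth.gamma_true):
        lines.append(f"gamma.{i}={g!r}")
    for t, d in enumerate(truth.delta_true):
        lines.append(f"delta.{t}={d!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
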