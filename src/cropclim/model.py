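"""Core probability model for municipal crop production.

Yearly production ``y_it`` of a crop in municipality ``i`` at year ``t`` is
modelled as a Poisson count whose mean is the previous year's production
(the offset) scaled by a rate of change:

    y_it ~ Poisson(rho_it * eps_it),      eps_it = y_{i,t-1}
    log(rho_it) = eta_it = alpha + gamma_i + delta_t + beta * x_it

with ``gamma_i`` iid Gaussian municipality effects, ``delta_t`` a first-order
random walk (RW1) over years constrained to sum to zero, and ``beta`` the
effect of one environmental covariate in its original units.  The headline
quantity is ``100 * (exp(beta) - 1)``: the percent change in production per
unit increase of the covariate.

Everything here is a pure function of plain arrays so the likelihood and
priors can be checked against independent oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

CROPS = ("coffee", "corn", "palm_oil", "rice", "sugarcane")

#: The eleven yearly covariates, with the units they carry.
YEARLY_VARIABLES = {
    "min_temperature": "degC",
    "max_temperature": "degC",
    "avg_temperature": "degC",
    "actual_evapotranspiration": "mm",
    "reference_evapotranspiration": "mm",
    "precipitation": "mm",
    "runoff": "mm",
    "soil_moisture": "mm",
    "vapor_pressure": "kPa",
    "radiation": "W/m2",
    "wind_speed": "m/s",
}

PANEL_COLUMNS = ("municipality_code", "year", "crop", "production")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a long-format production panel.

    Requires columns municipality_code, year, crop, production; production
    must be non-negative and is rounded half-to-even to integer tons (with a
    warning) if fractional values are present, since the Poisson response
    requires integer support.  Duplicate (municipality, year, crop) keys are
    rejected.
    """
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    panel = panel.loc[:, list(PANEL_COLUMNS)].copy()
    prod = pd.to_numeric(panel["production"])
    if (prod < 0).any():
        raise ValueError("production must be non-negative")
    rounded = np.rint(prod.to_numpy(dtype=float))  # rint = round half-to-even
    if not np.allclose(rounded, prod.to_numpy(dtype=float), atol=0, rtol=0):
        warnings.warn(
            "fractional production values rounded half-to-even to integer tons",
            stacklevel=2,
        )
    panel["production"] = rounded.astype(np.int64)
    panel["year"] = panel["year"].astype(int)
    key = ["municipality_code", "year", "crop"]
    if panel.duplicated(key).any():
        raise ValueError("duplicate (municipality, year, crop) rows in panel")
    return panel


@dataclass
class ModelData:
    """A single crop-covariate design in dense index form.

    ``y`` is the response (production in year t), ``offset_eps`` the strictly
    positive previous-year production, ``x`` the covariate at year t in its
    original units.  ``muni_index``/``year_index`` are dense 0-based codes
    into ``muni_codes``/``years`` (the years are response years).
    """

    y: np.ndarray
    offset_eps: np.ndarray
    x: np.ndarray
    muni_index: np.ndarray
    year_index: np.ndarray
    N: int
    T: int
    muni_codes: list = field(default_factory=list)
    years: list = field(default_factory=list)
    crop: str = ""
    variable: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.offset_eps = np.asarray(self.offset_eps, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.muni_index = np.asarray(self.muni_index, dtype=np.int64)
        self.year_index = np.asarray(self.year_index, dtype=np.int64)
        n = len(self.y)
        for name in ("offset_eps", "x", "muni_index", "year_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length != len(y)")
        if n and (self.y < 0).any():
            raise ValueError("y must be non-negative")
        if n and (self.offset_eps <= 0).any():
            raise ValueError("offset_eps must be strictly positive")
        if n and (
            self.muni_index.min() < 0
            or self.muni_index.max() >= self.N
            or self.year_index.min() < 0
            or self.year_index.max() >= self.T
        ):
            raise ValueError("index out of range")

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class Params:
    """Model unknowns: intercept, covariate effect, random effects, precisions."""

    alpha: float
    beta: float
    gamma: np.ndarray
    delta: np.ndarray
    tau_gamma: float
    tau_delta: float

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.tau_gamma <= 0 or self.tau_delta <= 0:
            raise ValueError("precisions must be strictly positive")
        if self.delta.size and abs(self.delta.sum()) > 1e-10 * max(
            1.0, np.abs(self.delta).max()
        ):
            raise ValueError("delta must sum to zero")

    def validate_against(self, data: ModelData) -> None:
        if len(self.gamma) != data.N or len(self.delta) != data.T:
            raise ValueError(
                f"params sized (N={len(self.gamma)}, T={len(self.delta)}) do not "
                f"match data (N={data.N}, T={data.T})"
            )


@dataclass
class FittedRates:
    eta: np.ndarray
    rho: np.ndarray
    lam: np.ndarray


@dataclass
class PriorConfig:
    """Prior specification.

    ``fixed_effect_precision`` is the Gaussian precision on alpha and beta
    (default 0.001, i.e. sd ~ 31.6 on the log scale).  ``hyper_shape`` /
    ``hyper_rate`` parameterize the Gamma(a, b) hyperprior shared by the two
    random-effect precisions; the default rate 5e-5 with shape 1 is the
    standard weakly-informative default for log-precision hyperpriors.
    """

    fixed_effect_precision: float = 0.001
    hyper_shape: float = 1.0
    hyper_rate: float = 0.00005

    def __post_init__(self) -> None:
        if min(self.fixed_effect_precision, self.hyper_shape, self.hyper_rate) <= 0:
            raise ValueError("all prior parameters must be strictly positive")


def build_design(
    panel: pd.DataFrame,
    climate: pd.DataFrame,
    crop: str,
    variable: str,
) -> ModelData:
    """Pair each year's production with the previous year's as offset.

    For every municipality growing ``crop``, consecutive calendar years
    (t-1, t) yield one row (y = production_t, eps = production_{t-1},
    x = covariate at year t).  Rows with eps == 0 or missing covariate are
    dropped; municipality and response-year indices are densely renumbered.

    Raises ``ValueError`` if no estimable rows remain.
    """
    panel = validate_panel(panel)
    if variable not in climate.columns:
        raise ValueError(
            f"no estimable data for crop={crop!r}, variable={variable!r}: "
            "variable absent from climate table"
        )
    sub = panel[panel["crop"] == crop]
    cl = climate[["municipality_code", "year", variable]]

    sub = sub.sort_values(["municipality_code", "year"])
    prev = sub.groupby("municipality_code")[["year", "production"]].shift(1)
    rows = sub.assign(prev_year=prev["year"], eps=prev["production"])
    rows = rows[rows["prev_year"] == rows["year"] - 1]
    rows = rows[rows["eps"] > 0]
    rows = rows.merge(cl, on=["municipality_code", "year"], how="left")
    rows = rows[rows[variable].notna()]

    if rows.empty:
        raise ValueError(
            f"no estimable data for crop={crop!r}, variable={variable!r} "
            "after offset/covariate filtering"
        )

    muni_codes = sorted(rows["municipality_code"].unique())
    years = sorted(rows["year"].unique())
    muni_map = {c: i for i, c in enumerate(muni_codes)}
    year_map = {y: i for i, y in enumerate(years)}
    return ModelData(
        y=rows["production"].to_numpy(),
        offset_eps=rows["eps"].to_numpy(dtype=np.int64),
        x=rows[variable].to_numpy(dtype=float),
        muni_index=rows["municipality_code"].map(muni_map).to_numpy(),
        year_index=rows["year"].map(year_map).to_numpy(),
        N=len(muni_codes),
        T=len(years),
        muni_codes=list(muni_codes),
        years=[int(y) for y in years],
        crop=crop,
        variable=variable,
    )


def compute_rates(data: ModelData, params: Params) -> FittedRates:
    """Linear predictor, rate and Poisson mean for every observation."""
    params.validate_against(data)
    eta = (
        params.alpha
        + params.gamma[data.muni_index]
        + params.delta[data.year_index]
        + params.beta * data.x
    )
    rho = np.exp(eta)
    return FittedRates(eta=eta, rho=rho, lam=rho * data.offset_eps)


def log_likelihood(data: ModelData, params: Params) -> float:
    """Poisson log-likelihood sum over all observations."""
    rates = compute_rates(data, params)
    y = data.y
    return float(np.sum(y * np.log(rates.lam) - rates.lam - gammaln(y + 1.0)))


def rw1_penalty(delta: np.ndarray) -> float:
    """Sum of squared successive differences of the year effects."""
    d = np.diff(np.asarray(delta, dtype=float))
    return float(d @ d)


_LOG_2PI = float(np.log(2.0 * np.pi))


def log_prior(params: Params, prior: PriorConfig) -> float:
    """Joint log-prior density.

    Gaussian terms (alpha, beta, iid gamma) carry their full normalizing
    constants.  The RW1 term is the improper density
    ((T-1)/2) log(tau_delta) - (tau_delta/2) * sum (delta_t - delta_{t-1})^2
    with its arbitrary constant fixed at zero, evaluated under the
    sum-to-zero constraint.  The two precisions get full Gamma(a, b)
    log-densities.
    """
    p0 = prior.fixed_effect_precision
    out = 0.0
    for v in (params.alpha, params.beta):
        out += 0.5 * (np.log(p0) - _LOG_2PI) - 0.5 * p0 * v * v
    g = params.gamma
    n = len(g)
    out += 0.5 * n * (np.log(params.tau_gamma) - _LOG_2PI)
    out -= 0.5 * params.tau_gamma * float(g @ g)
    T = len(params.delta)
    if T >= 2:
        out += 0.5 * (T - 1) * np.log(params.tau_delta)
        out -= 0.5 * params.tau_delta * rw1_penalty(params.delta)
    a, b = prior.hyper_shape, prior.hyper_rate
    for tau in (params.tau_gamma, params.tau_delta):
        out += a * np.log(b) - gammaln(a) + (a - 1) * np.log(tau) - b * tau
    return float(out)


def percent_change(beta_value: float) -> float:
    """Percent change in production per unit covariate: 100*(exp(beta)-1)."""
    return float(100.0 * np.expm1(beta_value))
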