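"""End-to-end orchestration: one model per crop per environmental variable.

The full experiment fits the lagged-offset Poisson model once for every
requested (crop, covariate) pair — single-covariate designs are used
deliberately so collinear environmental variables never share a fit — and
collects the percent-change effect of each covariate into one consolidated
table.  Failures (e.g. a crop with no estimable municipalities for some
variable) are recorded per pair and never abort the sweep.  No
multiple-comparison adjustment is applied across the fits; the consolidated
table notes this caveat in its metadata header.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import McmcConfig, sample_posterior, summarize
from .model import (
    CROPS,
    YEARLY_VARIABLES,
    PriorConfig,
    build_design,
    percent_change,
    validate_panel,
)

logger = logging.getLogger("cropclim")

EFFECT_COLUMNS = [
    "crop", "variable", "units", "status", "n_observations",
    "beta_mean", "beta_sd", "beta_q2.5", "beta_q97.5",
    "percent_change_mean", "percent_change_median",
    "percent_change_q2.5", "percent_change_q97.5",
    "rhat", "ess", "error",
]


@dataclass
class RunConfig:
    """Configuration of a sweep: which pairs to fit, from which inputs."""

    panel_path: str
    climate_path: str
    crops: tuple = CROPS
    variables: tuple = tuple(YEARLY_VARIABLES)
    prior: PriorConfig = field(default_factory=PriorConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.crops or not self.variables:
            raise ValueError("crops and variables must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        prior = PriorConfig(**raw.pop("prior", {}))
        mcmc = McmcConfig(**raw.pop("mcmc", {}))
        if "crops" in raw:
            raw["crops"] = tuple(raw["crops"])
        if "variables" in raw:
            raw["variables"] = tuple(raw["variables"])
        return cls(prior=prior, mcmc=mcmc, **raw)


@dataclass
class EffectEstimate:
    """Machine-readable effect of one covariate on one crop."""

    crop: str
    variable: str
    n_observations: int
    beta_mean: float
    beta_sd: float
    beta_q2_5: float
    beta_q97_5: float
    percent_change_mean: float
    percent_change_median: float
    percent_change_q2_5: float
    percent_change_q97_5: float
    rhat: float
    ess: float

    def to_row(self) -> dict:
        return {
            "crop": self.crop,
            "variable": self.variable,
            "units": YEARLY_VARIABLES.get(self.variable, ""),
            "status": "ok",
            "n_observations": self.n_observations,
            "beta_mean": self.beta_mean,
            "beta_sd": self.beta_sd,
            "beta_q2.5": self.beta_q2_5,
            "beta_q97.5": self.beta_q97_5,
            "percent_change_mean": self.percent_change_mean,
            "percent_change_median": self.percent_change_median,
            "percent_change_q2.5": self.percent_change_q2_5,
            "percent_change_q97.5": self.percent_change_q97_5,
            "rhat": self.rhat,
            "ess": self.ess,
            "error": "",
        }


def complete_panel(panel: pd.DataFrame, municipalities, years, crops) -> pd.DataFrame:
    """Fill the full crops x municipalities x years cross with zero production.

    Makes record counts well-defined: the output always has exactly
    ``len(crops) * len(municipalities) * len(years)`` rows.  Idempotent.
    """
    panel = validate_panel(panel)
    idx = pd.MultiIndex.from_product(
        [sorted(set(crops)), sorted(set(municipalities)), sorted(set(years))],
        names=["crop", "municipality_code", "year"],
    )
    out = (
        panel.set_index(["crop", "municipality_code", "year"])["production"]
        .reindex(idx, fill_value=0)
        .astype(np.int64)
        .reset_index()
    )
    return out[["municipality_code", "year", "crop", "production"]]


def run_single(
    panel: pd.DataFrame,
    climate: pd.DataFrame,
    crop: str,
    variable: str,
    prior: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    out_dir=None,
) -> EffectEstimate:
    """Fit one crop-covariate model and report its percent-change effect.

    The percent-change posterior is the pushforward of the beta posterior
    through 100*(exp(beta)-1); both its mean and median are reported because
    the transform is non-linear.
    """
    prior = prior or PriorConfig()
    mcmc = mcmc or McmcConfig()
    t0 = time.perf_counter()
    data = build_design(panel, climate, crop, variable)
    draws = sample_posterior(data, prior, mcmc)
    summary = summarize(draws)

    beta_row = summary.set_index("parameter").loc["beta"]
    pooled = draws.beta.reshape(-1)
    pct = 100.0 * np.expm1(pooled)
    est = EffectEstimate(
        crop=crop,
        variable=variable,
        n_observations=data.n_obs,
        beta_mean=float(beta_row["mean"]),
        beta_sd=float(beta_row["sd"]),
        beta_q2_5=float(beta_row["q2.5"]),
        beta_q97_5=float(beta_row["q97.5"]),
        percent_change_mean=float(pct.mean()),
        percent_change_median=float(np.median(pct)),
        percent_change_q2_5=percent_change(float(beta_row["q2.5"])),
        percent_change_q97_5=percent_change(float(beta_row["q97.5"])),
        rhat=float(beta_row["rhat"]),
        ess=float(beta_row["ess"]),
    )
    elapsed = time.perf_counter() - t0
    logger.info(
        "fit %s/%s: n=%d seed=%d elapsed=%.1fs beta_mean=%.5f",
        crop, variable, data.n_obs, mcmc.seed, elapsed, est.beta_mean,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = f"{crop}_{variable}"
        draws.to_dataframe().to_csv(out_dir / f"{stem}_draws.csv", index=False)
        summary.to_csv(out_dir / f"{stem}_summary.csv", index=False)
    return est


def run_all(config: RunConfig) -> pd.DataFrame:
    """Run the full sweep; one row per requested (crop, variable) pair.

    Per-pair seeds derive deterministically from the base seed and the pair
    index so the sweep is reproducible and each fit independent.  Raises
    ``RuntimeError`` only if every pair fails.
    """
    panel = validate_panel(
        pd.read_csv(config.panel_path, dtype={"municipality_code": str})
    )
    climate = pd.read_csv(config.climate_path, dtype={"municipality_code": str})
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    pairs = [(c, v) for c in config.crops for v in config.variables]
    for k, (crop, variable) in enumerate(pairs):
        mcmc = McmcConfig(**{**config.mcmc.__dict__, "seed": config.mcmc.seed + k})
        try:
            est = run_single(
                panel, climate, crop, variable,
                prior=config.prior, mcmc=mcmc, out_dir=out_dir / "fits",
            )
            rows.append(est.to_row())
        except Exception as exc:  # isolate per-pair failures
            logger.warning("fit %s/%s failed: %s", crop, variable, exc)
            row = {c: np.nan for c in EFFECT_COLUMNS}
            row.update(
                crop=crop, variable=variable,
                units=YEARLY_VARIABLES.get(variable, ""),
                status="failed", error=str(exc),
            )
            rows.append(row)

    table = pd.DataFrame(rows, columns=EFFECT_COLUMNS)
    if (table["status"] == "failed").all():
        raise RuntimeError(
            "all fits failed: "
            + "; ".join(f"{r['crop']}/{r['variable']}: {r['error']}" for r in rows)
        )
    table.to_csv(out_dir / "effects.csv", index=False)
    manifest = {
        "seed": config.mcmc.seed,
        "n_pairs": len(pairs),
        "n_failed": int((table["status"] == "failed").sum()),
        "note": "no multiple-comparison adjustment across fits",
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return table
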