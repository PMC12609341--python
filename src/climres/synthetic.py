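"""Synthetic province-year panel generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
balanced 30-unit x 12-year panel whose outcome follows a partially linear
model

    FASCR = b0 + theta_T*TEMP + theta_R*RAIN + theta_int*(SID_c x TEMP_c)
            + g(X) + unit FE + year FE + eps,

with climate exposures confounded by a subset of the controls through a
(optionally nonlinear) first-stage m(X), a crop-diversification moderator
SID strictly inside (0, 1), and 22 resilience indicators generated as
monotone noisy transforms of the latent resilience signal with their
declared direction signs respected.  Missing values are injected at a small
missing-at-random rate into indicator columns only.

Every random draw descends from a single seed, so equal configurations
produce byte-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .indicators import IndicatorSpec, default_indicator_specs
from .panel_ops import (
    CONTROLS,
    CROP_SHARES,
    CROPS,
    MODERATOR,
    OUTCOME,
    PanelDataset,
    UNIT,
    YEAR,
)

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_panel", "make_crop_shares"]


# Output location/scale of each control (mean, sd), loosely matching the
# descriptive statistics of a Chinese provincial panel.  The nuisance g and
# the confounding first stages operate on the standardized versions.
_CONTROL_SCALES = {
    "UL": (0.60, 0.12),
    "RTSI": (1.27, 0.72),
    "EPA": (320.0, 327.0),
    "EUE": (0.79, 0.48),
    "VAFA": (196.0, 183.0),
    "RECA": (0.22, 0.14),
    "RGPBE": (0.26, 0.11),
}

# Nuisance forms on standardized controls Z.  The linear form is
# g(Z) = sum_j alpha_j Z_j.  The nonlinear form is built from centered
# threshold ("regime") terms H_j = I(Z_j > 0) - 1/2 and one regime
# interaction H_jk = I(Z_j > 0) I(Z_k > 0) - 1/4: piecewise-constant
# nuisances that a linear adjustment is genuinely misspecified for, while
# lying squarely inside the function class tree-ensemble learners estimate
# consistently at panel sample sizes.
_G_LINEAR = {0: 0.10, 1: 0.08, 2: 0.06, 3: 0.05}
_G_THRESH = {0: 0.125, 1: 0.10, 2: 0.15, 3: 0.12}  # coef on H_j
_G_THRESH_CROSS = ((0, 1), 0.10)  # coef on H_01

# First-stage (confounding) loadings of the two climate exposures on the
# same regime terms; each exposure loads on two controls plus one regime
# interaction, so naive regressions are biased and the de-biasing step is
# actually exercised.
_TEMP_SERIES = dict(mean=13.0, thresh={0: 1.5, 1: 1.0}, cross=((0, 1), 0.8), noise_sd=3.0)
_RAIN_SERIES = dict(mean=77.0, thresh={1: 6.0, 2: 4.0}, cross=((1, 2), 3.0), noise_sd=30.0)

_OUTCOME_INTERCEPT = 1.3
_INDICATOR_NOISE_SD = 0.8


@dataclass
class SyntheticConfig:
    """Generating parameters of the synthetic panel (defaults = study conditions)."""

    n_units: int = 30
    year_start: int = 2011
    year_end: int = 2022
    theta_temp: float = -0.015
    theta_rain: float = -0.001
    theta_interaction: float = 0.15
    nuisance_form: str = "nonlinear"
    fe_unit_sd: float = 0.05
    fe_year_sd: float = 0.05
    noise_sd: float = 0.1
    missing_rate: float = 0.02
    n_indicators: int = 22
    major_producer_fraction: float = 13 / 30
    confounding_scale: float = 1.0
    climate_convention: str = "corrected"
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_units < 2:
            raise ValueError("SyntheticConfig.n_units must be >= 2")
        if self.year_end <= self.year_start:
            raise ValueError("SyntheticConfig.year_end must exceed year_start")
        if not (0 <= self.missing_rate < 0.5):
            raise ValueError("SyntheticConfig.missing_rate must lie in [0, 0.5)")
        if self.noise_sd <= 0:
            raise ValueError("SyntheticConfig.noise_sd must be > 0")
        if self.nuisance_form not in ("linear", "nonlinear"):
            raise ValueError("SyntheticConfig.nuisance_form must be 'linear' or 'nonlinear'")
        if not (0 < self.major_producer_fraction < 1):
            raise ValueError("SyntheticConfig.major_producer_fraction must lie in (0, 1)")
        if self.n_indicators < 1:
            raise ValueError("SyntheticConfig.n_indicators must be >= 1")
        if self.fe_unit_sd < 0 or self.fe_year_sd < 0:
            raise ValueError("SyntheticConfig.fe_unit_sd / fe_year_sd must be >= 0")
        if self.climate_convention not in ("corrected", "printed"):
            raise ValueError(
                "SyntheticConfig.climate_convention must be 'corrected' or 'printed'"
            )
        return self

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1


@dataclass
class SyntheticTruth:
    """Ground truth of a generated panel, for recovery tests."""

    theta_by_treatment: dict[str, float]
    nuisance: str
    g_values: np.ndarray
    m_values: dict[str, np.ndarray]
    unit_effects: dict[str, float]
    year_effects: dict[int, float]
    intercept: float
    params: dict[str, Any]
    seed: int


def _indicator_specs_for(config: SyntheticConfig) -> list[IndicatorSpec]:
    if config.n_indicators == 22:
        return default_indicator_specs()
    groups = ("resistance", "adaptability", "innovation")
    return [
        IndicatorSpec(
            f"ind_{k + 1:02d}",
            "negative" if k % 4 == 3 else "positive",
            groups[k % 3],
        )
        for k in range(config.n_indicators)
    ]


def _rngs(config: SyntheticConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(5)
    return [np.random.default_rng(c) for c in children]


def make_crop_shares(config: SyntheticConfig, profile: str = "random") -> pd.DataFrame:
    """Six-crop planting-share table, one row per unit-year, shares sum to 1.

    ``profile="random"`` draws a Dirichlet planting profile per unit with
    mild year-to-year jitter; ``"equal"`` gives each crop 1/6;
    ``"degenerate"`` plants a single crop (first listed) everywhere.
    """
    config.validate()
    rng = _rngs(config)[1]
    units = [f"P{i + 1:02d}" for i in range(config.n_units)]
    years = list(range(config.year_start, config.year_end + 1))
    rows = []
    for u in units:
        if profile == "random":
            base = rng.dirichlet(np.full(len(CROPS), 2.5))
        elif profile == "equal":
            base = np.full(len(CROPS), 1.0 / len(CROPS))
        elif profile == "degenerate":
            base = np.zeros(len(CROPS))
            base[0] = 1.0
        else:
            raise ValueError(f"unknown crop profile {profile!r}")
        for y in years:
            if profile == "random":
                jitter = base * np.exp(0.15 * rng.standard_normal(len(CROPS)))
                shares = jitter / jitter.sum()
            else:
                shares = base
            rows.append([u, y, *shares])
    return pd.DataFrame(rows, columns=[UNIT, YEAR, *CROP_SHARES])


def _regime(z: np.ndarray, j: int) -> np.ndarray:
    """Centered threshold term H_j = I(Z_j > 0) - 1/2."""
    return (z[:, j] > 0).astype(float) - 0.5


def _regime_cross(z: np.ndarray, j: int, k: int) -> np.ndarray:
    """Centered regime interaction I(Z_j > 0) I(Z_k > 0) - 1/4."""
    return ((z[:, j] > 0) & (z[:, k] > 0)).astype(float) - 0.25


def _series_value(
    z: np.ndarray, spec: dict, rng: np.random.Generator, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (systematic m(X), noisy series) for one climate exposure."""
    m = np.zeros(z.shape[0])
    for j, w in spec["thresh"].items():
        m += w * _regime(z, j)
    (j, k), w = spec["cross"]
    m += w * _regime_cross(z, j, k)
    m = scale * m
    series = spec["mean"] + m + rng.normal(0.0, spec["noise_sd"], z.shape[0])
    return m, series


def generate_panel(config: SyntheticConfig) -> tuple[PanelDataset, SyntheticTruth]:
    """Generate a balanced synthetic panel and its generating truth."""
    config.validate()
    rng_main, _, rng_ind, rng_miss, rng_grp = _rngs(config)

    units = [f"P{i + 1:02d}" for i in range(config.n_units)]
    years = list(range(config.year_start, config.year_end + 1))
    n = config.n_units * config.n_years
    unit_col = np.repeat(units, config.n_years)
    year_col = np.tile(years, config.n_units)

    # standardized controls
    z = rng_main.standard_normal((n, len(CONTROLS)))

    # climate exposures (temperature-scale and rainfall-scale series)
    m_a, series_a = _series_value(z, _TEMP_SERIES, rng_main, config.confounding_scale)
    m_b, series_b = _series_value(z, _RAIN_SERIES, rng_main, config.confounding_scale)
    if config.climate_convention == "corrected":
        temp, m_temp, rain, m_rain = series_a, m_a, series_b, m_b
    else:  # printed convention: scales as the descriptive table prints them
        temp, m_temp, rain, m_rain = series_b, m_b, series_a, m_a

    # nuisance g on standardized controls
    g = np.zeros(n)
    if config.nuisance_form == "linear":
        for j, w in _G_LINEAR.items():
            g += w * z[:, j]
    else:
        for j, w in _G_THRESH.items():
            g += w * _regime(z, j)
        (jc, kc), wc = _G_THRESH_CROSS
        g += wc * _regime_cross(z, jc, kc)

    # crop shares and the Simpson diversification moderator
    crops = make_crop_shares(config)
    shares = crops[list(CROP_SHARES)].to_numpy()
    sid = 1.0 - np.sum((shares / shares.sum(axis=1, keepdims=True)) ** 2, axis=1)

    # fixed effects and noise
    fe_unit = rng_main.normal(0.0, config.fe_unit_sd, config.n_units)
    fe_year = rng_main.normal(0.0, config.fe_year_sd, config.n_years)
    eps = rng_main.normal(0.0, config.noise_sd, n)

    sid_c = sid - sid.mean()
    temp_c = temp - temp.mean()
    interaction = sid_c * temp_c

    outcome = (
        _OUTCOME_INTERCEPT
        + config.theta_temp * temp
        + config.theta_rain * rain
        + config.theta_interaction * interaction
        + g
        + np.repeat(fe_unit, config.n_years)
        + np.tile(fe_year, config.n_units)
        + eps
    )

    # indicators: monotone noisy transforms of the latent resilience signal
    latent = (outcome - outcome.mean()) / outcome.std()
    specs = _indicator_specs_for(config)
    ind_cols = {}
    for k, spec in enumerate(specs):
        sign = 1.0 if spec.direction == "positive" else -1.0
        inner = sign * latent + rng_ind.normal(0.0, _INDICATOR_NOISE_SD, n)
        vals = np.exp(0.6 * inner) if k % 3 == 2 else inner
        ind_cols[spec.name] = 10.0 + 3.0 * k + (1.0 + 0.2 * k) * vals

    # group labels
    n_major = int(round(config.major_producer_fraction * config.n_units))
    major_units = set(rng_grp.choice(units, size=n_major, replace=False))
    mech_base = np.exp(rng_grp.normal(0.0, 0.4, config.n_units))
    mech = np.repeat(mech_base, config.n_years) * (
        1.0 + 0.02 * (year_col - config.year_start)
    )

    df = pd.DataFrame({UNIT: unit_col, YEAR: year_col})
    for name, vals in ind_cols.items():
        df[name] = vals
    df["TEMP"] = temp
    df["RAIN"] = rain
    df[MODERATOR] = sid
    for j, c in enumerate(CONTROLS):
        loc, scale = _CONTROL_SCALES[c]
        df[c] = loc + scale * z[:, j]
    for c in CROP_SHARES:
        df[c] = crops[c].to_numpy()
    df["major_producer"] = [u in major_units for u in unit_col]
    df["mech_score"] = mech
    df[OUTCOME] = outcome

    # inject missingness into indicator columns only, keeping at least one
    # observed value per unit-column series
    if config.missing_rate > 0:
        names = [s.name for s in specs]
        mask = rng_miss.random((n, len(names))) < config.missing_rate
        unit_idx = np.repeat(np.arange(config.n_units), config.n_years)
        for c_idx, name in enumerate(names):
            col_mask = mask[:, c_idx]
            for u_idx in range(config.n_units):
                rows = np.where(unit_idx == u_idx)[0]
                if col_mask[rows].all():
                    col_mask[rows[0]] = False
            vals = df[name].to_numpy(dtype=float)
            vals[col_mask] = np.nan
            df[name] = vals

    truth = SyntheticTruth(
        theta_by_treatment={
            "TEMP": config.theta_temp,
            "RAIN": config.theta_rain,
            "SID_x_TEMP": config.theta_interaction,
        },
        nuisance=(
            "g(Z) = sum_j alpha_j Z_j on standardized controls"
            if config.nuisance_form == "linear"
            else "g(Z) = sum_j w_j (I(Z_j>0)-1/2) + w_01 (I(Z_0>0)I(Z_1>0)-1/4)"
        ),
        g_values=g,
        m_values={"TEMP": m_temp, "RAIN": m_rain},
        unit_effects=dict(zip(units, fe_unit)),
        year_effects=dict(zip(years, fe_year)),
        intercept=_OUTCOME_INTERCEPT,
        params={
            "config": asdict(config),
            "g_linear": dict(_G_LINEAR),
            "g_thresh": dict(_G_THRESH),
            "g_thresh_cross": _G_THRESH_CROSS,
            "temp_series": dict(_TEMP_SERIES),
            "rain_series": dict(_RAIN_SERIES),
            "interaction": "centered SID x centered TEMP",
        },
        seed=config.seed,
    )
    return PanelDataset(df).validate(), truth
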