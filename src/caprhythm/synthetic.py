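"""Seeded generators for hourly and monthly capacitation-indicator series.

The generators emulate the statistical structure the detectors are designed
for, so every stage of the pipeline can be exercised and calibrated without
donor data:

* hourly series (24 points, t = 0..23 h of capacitating incubation): a
  saturating rise ``trend_max * t / (t + trend_halftime)`` plus, for the
  chemotaxis indicator, a 2-hour oscillation, plus replicate noise that is
  iid Gaussian (chex) or AR(1) (ari — the short-range-correlated null);
* monthly panels (36 points, month index 1 = the first January, sampled
  mid-month): a 12-month cosine for %ARi peaking in November (spring at a
  southern site) with noise-free peak/valley levels 46 / 12, a 6-month
  cosine for %Chex peaking late March/April and late September/October with
  levels 12 / 5, a temperature sinusoid peaking mid-January, and the
  deterministic photoperiod of the site latitude (31.82° S);
* white / AR(1) null series for type-I-error studies.

Percentages are clipped to [0, 100] after noise. A seed fully determines
every generated panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .errors import DomainError, ParameterError
from .timeseries import ReplicatePanel, TimeSeries

__all__ = [
    "HourlyParams",
    "MonthlyParams",
    "SiteParams",
    "SyntheticConfig",
    "MonthlyPanel",
    "HOURLY_PRESETS",
    "simulate_hourly_capacitation",
    "simulate_monthly_panel",
    "simulate_null_series",
    "day_length",
    "noise_free",
    "FIXTURE_SEED",
]

#: canonical seed for the frozen fixture datasets (the fixtures CLI command)
FIXTURE_SEED = 20190412


@dataclass(frozen=True)
class HourlyParams:
    """Generative parameters of one hourly indicator series (percent units)."""

    n_hours: int = 24
    trend_max: float = 15.0        # plateau of the saturating rise, %
    trend_halftime: float = 6.0    # hours to half-plateau
    osc_amplitude: float = 3.0     # % amplitude of the ultradian oscillation
    osc_period_h: float = 2.0      # hours
    osc_phase: float = 0.5         # hours; 0.5 puts extremes on the hourly grid
    noise_sd: float = 1.5          # % (marginal sd)
    ar1_coeff: float = 0.0         # AR(1) coefficient of the noise (0 = iid)

    def __post_init__(self) -> None:
        if self.osc_amplitude < 0 or self.noise_sd < 0:
            raise DomainError("amplitudes and noise sd must be >= 0")
        if not -1 < self.ar1_coeff < 1:
            raise ParameterError("|ar1_coeff| must be < 1 for stationarity")


@dataclass(frozen=True)
class MonthlyParams:
    """Generative parameters of the 36-month seasonal panel (percent units).

    The default ARi levels put the noise-free peak at 46 % and valley at
    12 % (mean 29, amplitude 17); Chex at 12 % / 5 % (mean 8.5, amplitude
    3.5). Phases are the month-of-year at which the cosine peaks.
    """

    n_months: int = 36
    ari_mean: float = 29.0
    ari_amp12: float = 17.0
    ari_phase12: float = 11.0      # November peak (southern-spring)
    chex_mean: float = 8.5
    chex_amp6: float = 3.5
    chex_phase6: float = 4.0       # April peak (and October), on the grid
    chex_amp12: float = 0.0        # optional 12-month admixture for Chex
    chex_phase12: float = 11.0
    ari_noise_sd: float = 2.5      # % (iid per month); scales with the
    chex_noise_sd: float = 1.2     # indicator's reported uncertainty

    def __post_init__(self) -> None:
        if min(self.ari_amp12, self.chex_amp6, self.chex_amp12,
               self.ari_noise_sd, self.chex_noise_sd) < 0:
            raise DomainError("amplitudes and noise sd must be >= 0")


@dataclass(frozen=True)
class SiteParams:
    """Study-site climate: latitude and a sinusoidal mean-temperature model."""

    latitude_deg: float = -31.82
    temp_mean: float = 18.0        # deg C, annual mean
    temp_amplitude: float = 7.0    # deg C
    temp_peak_month: float = 1.5   # mid-January (southern summer)
    temp_noise_sd: float = 1.0     # deg C


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the generative models, seed included."""

    seed: int = FIXTURE_SEED
    n_replicates: int = 8
    #: explicit hourly parameters; None means "take them from the preset"
    hourly: HourlyParams | None = None
    monthly: MonthlyParams = field(default_factory=MonthlyParams)
    site: SiteParams = field(default_factory=SiteParams)


#: hourly presets: chex carries the 2-h oscillation with iid noise; ari has
#: no oscillation and AR(1) noise (the short-range stochastic contrast)
HOURLY_PRESETS: dict[str, HourlyParams] = {
    "chex_hourly": HourlyParams(),
    "ari_hourly": HourlyParams(
        trend_max=30.0, trend_halftime=8.0, osc_amplitude=0.0,
        noise_sd=2.0, ar1_coeff=0.5,
    ),
}


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    innov_sd = sd * math.sqrt(1.0 - phi**2)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        eps[t] = phi * eps[t - 1] + shocks[t - 1]
    return eps


def simulate_hourly_capacitation(
    config: SyntheticConfig | None = None,
    preset: str = "chex_hourly",
) -> ReplicatePanel:
    """Replicate panel of hourly indicator series for a named preset.

    The preset supplies the generative parameters unless an explicit
    ``HourlyParams`` is set on ``config.hourly``.
    """
    if config is None:
        config = SyntheticConfig()
    if preset not in HOURLY_PRESETS:
        raise ParameterError(
            f"unknown preset {preset!r}; choose from {sorted(HOURLY_PRESETS)}"
        )
    params = config.hourly if config.hourly is not None else HOURLY_PRESETS[preset]
    rng = np.random.default_rng(config.seed)
    t = np.arange(params.n_hours, dtype=float)
    trend = params.trend_max * t / (t + params.trend_halftime)
    osc = params.osc_amplitude * np.sin(
        2.0 * math.pi * (t - params.osc_phase) / params.osc_period_h
    )
    signal = trend + osc
    reps = []
    for r in range(config.n_replicates):
        if params.ar1_coeff != 0.0:
            eps = _ar1_noise(rng, params.n_hours, params.noise_sd, params.ar1_coeff)
        else:
            eps = rng.normal(0.0, params.noise_sd, size=params.n_hours)
        values = np.clip(signal + eps, 0.0, 100.0)
        reps.append(
            TimeSeries(t, values, sampling_interval=1.0, time_unit="hour",
                       label=f"{preset}:{r + 1}")
        )
    return ReplicatePanel(tuple(reps))


class MonthlyPanel(NamedTuple):
    """The four co-sampled monthly series of the seasonal analysis."""

    ari: TimeSeries
    chex: TimeSeries
    temperature: TimeSeries
    photoperiod: TimeSeries


#: day of year of the 15th of each month (non-leap calendar, reused per year)
_MID_MONTH_DOY = (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)


def day_length(latitude_deg: float, day_of_year: int) -> float:
    """Hours of daylight from standard solar geometry.

    declination δ = −23.44° · cos(2π (day + 10) / 365.25);
    day length = (24/π) · arccos(−tan(lat) · tan(δ)), clamped to [0, 24].
    Polar latitudes (|lat| >= 66.5°) are rejected — the study site is
    subtropical and the formula's clamping behaviour is untested there.
    """
    if abs(latitude_deg) >= 66.5:
        raise DomainError("polar latitudes are not supported")
    decl = -math.radians(23.44) * math.cos(
        2.0 * math.pi * (day_of_year + 10) / 365.25
    )
    cos_h = -math.tan(math.radians(latitude_deg)) * math.tan(decl)
    cos_h = min(1.0, max(-1.0, cos_h))
    return (24.0 / math.pi) * math.acos(cos_h)


def simulate_monthly_panel(config: SyntheticConfig | None = None) -> MonthlyPanel:
    """Generate the 36-month (ari, chex, temperature, photoperiod) panel.

    All four series share the month axis 1..n_months; percentages are
    clipped to [0, 100] after noise, photoperiod is deterministic.
    """
    if config is None:
        config = SyntheticConfig()
    p, site = config.monthly, config.site
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x6D6F6E]).generate_state(1)[0]
    )
    m = np.arange(1, p.n_months + 1, dtype=float)

    ari_signal = p.ari_mean + p.ari_amp12 * np.cos(2 * math.pi * (m - p.ari_phase12) / 12)
    chex_signal = (
        p.chex_mean
        + p.chex_amp6 * np.cos(2 * math.pi * (m - p.chex_phase6) / 6)
        + p.chex_amp12 * np.cos(2 * math.pi * (m - p.chex_phase12) / 12)
    )
    ari = np.clip(ari_signal + rng.normal(0, p.ari_noise_sd, p.n_months), 0, 100)
    chex = np.clip(chex_signal + rng.normal(0, p.chex_noise_sd, p.n_months), 0, 100)
    temp = (
        site.temp_mean
        + site.temp_amplitude * np.cos(2 * math.pi * (m - site.temp_peak_month) / 12)
        + rng.normal(0, site.temp_noise_sd, p.n_months)
    )
    photo = np.array(
        [
            day_length(site.latitude_deg, _MID_MONTH_DOY[(int(mm) - 1) % 12])
            for mm in m
        ]
    )

    def _ts(values: np.ndarray, label: str) -> TimeSeries:
        return TimeSeries(m, values, sampling_interval=1.0, time_unit="month",
                          label=label)

    return MonthlyPanel(
        ari=_ts(ari, "ari_monthly"),
        chex=_ts(chex, "chex_monthly"),
        temperature=_ts(temp, "temperature_monthly"),
        photoperiod=_ts(photo, "photoperiod_monthly"),
    )


def simulate_null_series(
    n: int,
    model: str = "white",
    sd: float = 1.0,
    ar1_coeff: float = 0.5,
    seed: int = 0,
) -> TimeSeries:
    """White-noise or AR(1) null series for false-positive studies."""
    if n < 8:
        raise ParameterError("null series need n >= 8")
    if model not in ("white", "ar1"):
        raise ParameterError(f"unknown null model {model!r}")
    if model == "ar1" and not -1 < ar1_coeff < 1:
        raise ParameterError("|ar1_coeff| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    if model == "white":
        values = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
    else:
        values = _ar1_noise(rng, n, sd, ar1_coeff)
    return TimeSeries(
        np.arange(n, dtype=float), values, sampling_interval=1.0,
        label=f"null:{model}",
    )


def noise_free(config: SyntheticConfig | None = None,
               preset: str = "chex_hourly") -> SyntheticConfig:
    """Copy of a config with every stochastic term switched off."""
    if config is None:
        config = SyntheticConfig()
    hourly = config.hourly if config.hourly is not None else HOURLY_PRESETS[preset]
    return replace(
        config,
        hourly=replace(hourly, noise_sd=0.0),
        monthly=replace(config.monthly, ari_noise_sd=0.0, chex_noise_sd=0.0),
        site=replace(config.site, temp_noise_sd=0.0),
    )
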