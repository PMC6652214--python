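"""Group-structured logistic growth curves for per-plot height trajectories.

Maize height over a season is monotone and saturating; a 3-parameter
logistic ``h(t) = K / (1 + exp(-r (t - t0)))`` is the simplest curve with
that shape.  Each genetic background has its own (K, r, t0); plots inherit
their background's curve plus small seeded plot-level variation, and a
stated fraction of plots is flagged abnormal (lodging / aberrant growth)
for downstream record cleaning.

Default observation days (24, 45, 57, 74, 81 days after sowing) follow the
five-campaign timing of the emulated trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FieldDesign

__all__ = ["LogisticParams", "GrowthModel", "simulate_growth_profiles", "DEFAULT_DAYS"]

DEFAULT_DAYS = (24, 45, 57, 74, 81)


@dataclass
class LogisticParams:
    """3-parameter logistic growth curve.

    asymptote_cm: final height K (cm); rate_per_day: growth rate r
    (1/day); inflection_day: day of fastest growth t0 (days after sowing).
    """

    asymptote_cm: float
    rate_per_day: float
    inflection_day: float

    def __post_init__(self) -> None:
        if self.asymptote_cm <= 0:
            raise ValueError("asymptote must be positive")

    def height(self, days: np.ndarray) -> np.ndarray:
        days = np.asarray(days, float)
        return self.asymptote_cm / (1.0 + np.exp(-self.rate_per_day * (days - self.inflection_day)))


# Defaults: a taller, later-flowering tropical/subtropical (TST) pool, an
# earlier temperate (TEM) pool, and an intermediate mixed pool.
DEFAULT_CURVES = {
    "TEM": LogisticParams(asymptote_cm=240.0, rate_per_day=0.14, inflection_day=52.0),
    "TST": LogisticParams(asymptote_cm=290.0, rate_per_day=0.11, inflection_day=62.0),
    "mixed": LogisticParams(asymptote_cm=265.0, rate_per_day=0.12, inflection_day=57.0),
}


@dataclass
class GrowthModel:
    """Study-condition parameters for simulated height trajectories.

    height_noise_sd is per-observation measurement noise (cm);
    plot_sd_frac scales plot-level variation of the asymptote;
    lodging_fraction is the expected share of abnormal plots (the emulated
    trial excluded 19.4% of its sampling plots for abnormal growth or
    lodging).
    """

    curves: dict[str, LogisticParams] = field(default_factory=lambda: dict(DEFAULT_CURVES))
    observation_days: tuple[int, ...] = DEFAULT_DAYS
    height_noise_sd: float = 2.0
    plot_sd_frac: float = 0.04
    lodging_fraction: float = 0.194

    def __post_init__(self) -> None:
        days = np.asarray(self.observation_days)
        if not np.all(np.diff(days) > 0):
            raise ValueError("observation_days must be strictly increasing")
        if not 0 <= self.lodging_fraction < 1:
            raise ValueError("lodging_fraction must be in [0, 1)")
        if self.height_noise_sd < 0 or self.plot_sd_frac < 0:
            raise ValueError("noise parameters must be non-negative")


def simulate_growth_profiles(
    design: FieldDesign,
    model: GrowthModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate true per-plot heights at each observation day.

    Returns
    -------
    heights : DataFrame, index plot_id, columns observation days (cm).
    abnormal : boolean Series over plot_id flagging lodged/abnormal plots.
    """
    if model is None:
        model = GrowthModel()
    missing = set(design.backgrounds) - set(model.curves)
    if missing:
        raise ValueError(f"no growth curve for backgrounds: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    days = np.asarray(model.observation_days, float)
    heights = np.empty((design.n_plots, len(days)))
    for i, bg in enumerate(design.backgrounds):
        base = model.curves[bg]
        k = base.asymptote_cm * (1.0 + model.plot_sd_frac * rng.standard_normal())
        curve = LogisticParams(max(k, 1e-6), base.rate_per_day, base.inflection_day)
        h = curve.height(days)
        h = h + model.height_noise_sd * rng.standard_normal(len(days))
        heights[i] = np.clip(h, 0.0, None)

    abnormal = rng.random(design.n_plots) < model.lodging_fraction
    hdf = pd.DataFrame(heights, index=pd.Index(design.plot_ids, name="plot_id"),
                       columns=[int(d) for d in days])
    return hdf, pd.Series(abnormal, index=hdf.index, name="abnormal")
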