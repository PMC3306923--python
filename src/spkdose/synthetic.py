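"""Synthetic study generator with the statistical structure the analysis assumes.

Emulates the 1998 field design: 13 children ages 3-6, sampled in two
seasons, each 24-h period contributing four spot voids (before-bedtime on
day 1; first-morning, lunch and dinner on day 2) after a single dietary
bolus at dinner on day 1 (19:00).  True absorbed doses are lognormal,
measurement error is multiplicative lognormal on concentrations, and voids
go missing independently at a configurable rate.

The generator shares the forward kinetics of :mod:`spkdose.pk` and the
perfect-bladder assumption of the excretion-rate formula: the metabolite
amount in a void is the cumulative-excretion increment between consecutive
void times.  With zero noise and zero missingness the full pipeline
therefore recovers every true dose exactly — the core round-trip property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .pk import PKParameters, cumulative_excreted
from .study_io import (
    InputRecord,
    ReferenceTables,
    Season,
    Slot,
    compute_uer,
)

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticTruth",
    "CorruptionSpec",
    "generate_study",
    "corrupt_for_robustness",
]

# Chronological void order within a period
_VOID_ORDER = (Slot.BEDTIME, Slot.FIRST_MORNING, Slot.LUNCH, Slot.DINNER)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study-design and noise parameters for :func:`generate_study`.

    Defaults mirror the emulated design: 13 children over two seasons, a
    6/13 agricultural fraction, true doses lognormal with median 0.5 and
    97.5th percentile ~5 µg/kg/day, 30% concentration measurement CV, and
    10% of voids missing.
    """

    n_children: int = 13
    seasons: int = 2
    p_agricultural: float = 6.0 / 13.0
    dose_meanlog: float = math.log(0.5)  # ln(µg/kg/day)
    dose_sdlog: float = 1.17
    noise_cv: float = 0.3
    p_missing_void: float = 0.1
    pk: PKParameters = field(default_factory=PKParameters)
    tables: ReferenceTables = field(default_factory=ReferenceTables.default)
    time_jitter_hr: float = 0.5
    volume_cv: float = 0.25
    weight_cv: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.n_children < 1 or self.seasons not in (1, 2):
            raise ConfigError("need n_children >= 1 and seasons in {1, 2}")
        for name in ("p_agricultural", "p_missing_void"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("noise_cv", "volume_cv", "weight_cv", "time_jitter_hr"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.dose_sdlog < 0:
            raise ConfigError("dose_sdlog must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth, joinable 1:1 to the generated input table.

    ``periods``: one row per subject-period (true dose, weight, age, sex).
    ``voids``: one row per void (window, volume, metabolite amount,
    noise-free and observed concentration, missingness flag).
    """

    periods: pd.DataFrame
    voids: pd.DataFrame


def _lognormal_mean_one(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative error with E[X] = 1 and the given coefficient of variation."""
    if cv == 0.0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def generate_study(config: SyntheticStudyConfig) -> tuple[list[InputRecord], SyntheticTruth]:
    """Draw one synthetic study; fully reproducible from ``config.seed``.

    For each child x season: the child's weight comes from the age/sex
    reference jittered multiplicatively; a true dose is drawn; the forward
    model allocates cumulative excretion between consecutive (jittered) void
    times into void amounts; volumes scale with the collection interval;
    observed concentration = amount/volume x lognormal noise; voids drop out
    independently.  Returns the 9-variable records and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    tables, pk = config.tables, config.pk
    t0 = tables.exposure_time

    records: list[InputRecord] = []
    period_rows, void_rows = [], []

    for child in range(1, config.n_children + 1):
        subject_id = f"C{child:02d}"
        agricultural = bool(rng.random() < config.p_agricultural)
        age = int(rng.integers(3, 7))
        sex = str(rng.choice(["m", "f"]))
        weight = tables.default_body_weight[(age, sex)] * float(
            _lognormal_mean_one(rng, config.weight_cv)
        )
        v24 = tables.v_avg24_liters(age, sex)

        for period in (Season.SUMMER, Season.FALL)[: config.seasons]:
            true_dose = float(rng.lognormal(config.dose_meanlog, config.dose_sdlog))
            dose_umol = true_dose * weight / pk.mw_parent

            times = {
                slot: tables.default_event_times[int(slot)]
                + float(rng.uniform(-config.time_jitter_hr, config.time_jitter_hr))
                for slot in _VOID_ORDER
            }
            period_rows.append(
                dict(
                    subject_id=subject_id,
                    period=int(period),
                    agricultural=agricultural,
                    age=age,
                    sex=sex,
                    body_weight_kg=weight,
                    true_dose_ug_per_kg=true_dose,
                )
            )

            prev_time = t0  # the bedtime window opens at the exposure itself
            for slot in _VOID_ORDER:
                t_c = times[slot]
                t_p = prev_time
                prev_time = t_c
                amount = dose_umol * (
                    cumulative_excreted(pk, t_c - t0) - cumulative_excreted(pk, max(t_p - t0, 0.0))
                )
                volume = (
                    v24 * (t_c - t_p) / 24.0 * float(_lognormal_mean_one(rng, config.volume_cv))
                )
                conc_true = amount / volume
                conc_obs = conc_true * float(_lognormal_mean_one(rng, config.noise_cv))
                missing = bool(rng.random() < config.p_missing_void)

                void_rows.append(
                    dict(
                        subject_id=subject_id,
                        period=int(period),
                        slot=int(slot),
                        t_p=t_p,
                        t_c=t_c,
                        volume_L=volume,
                        amount_umol=amount,
                        conc_true_umol_per_L=conc_true,
                        conc_obs_umol_per_L=conc_obs,
                        missing=missing,
                    )
                )
                if missing:
                    continue
                uer = compute_uer(conc_obs, volume, t_p, t_c)
                records.append(
                    InputRecord(
                        subject_id=subject_id,
                        period=period,
                        agricultural=agricultural,
                        route_code=int(slot),
                        uer_avg=uer.uer_avg,
                        body_weight=weight,
                        exposure_start=t0,
                        t_p=t_p,
                        t_c=t_c,
                        concentration=conc_obs,
                        volume=volume,
                    )
                )

    truth = SyntheticTruth(periods=pd.DataFrame(period_rows), voids=pd.DataFrame(void_rows))
    return records, truth


@dataclass(frozen=True)
class CorruptionSpec:
    """Missing-data patterns to inject, as independent drop probabilities.

    Each probability applies per record (1.0 drops the field everywhere).
    Dropping void times while volumes are kept forces the interval
    imputation path of the default cascade; dropping the excretion rate
    forces its recomputation from the raw concentration and volume.
    """

    p_drop_body_weight: float = 0.0
    p_drop_void_times: float = 0.0
    p_drop_volume: float = 0.0
    p_drop_uer: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("p_drop_body_weight", "p_drop_void_times", "p_drop_volume", "p_drop_uer"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")

    @property
    def is_identity(self) -> bool:
        return not any(
            (self.p_drop_body_weight, self.p_drop_void_times, self.p_drop_volume, self.p_drop_uer)
        )


def corrupt_for_robustness(
    records: Sequence[InputRecord], spec: CorruptionSpec
) -> list[InputRecord]:
    """Blank out fields per ``spec`` so the default cascade is exercised.

    An all-zero spec is the identity.  Fields are dropped to ``None``; the
    records remain valid partial inputs for ``resolve_defaults``.
    """
    if spec.is_identity:
        return list(records)
    rng = np.random.default_rng(spec.seed)
    out = []
    for rec in records:
        changes = {}
        if rng.random() < spec.p_drop_body_weight:
            changes["body_weight"] = None
        if rng.random() < spec.p_drop_void_times:
            changes["t_p"] = None
            changes["t_c"] = None
        if rng.random() < spec.p_drop_volume:
            changes["volume"] = None
        if rng.random() < spec.p_drop_uer:
            changes["uer_avg"] = None
        out.append(replace(rec, **changes) if changes else rec)
    return out
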