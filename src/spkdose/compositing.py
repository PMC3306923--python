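"""Daily-dose composites from void-level reconstructions.

Each void of a subject-period yields its own dose estimate for the same
day-1 dinner bolus, so in a noise-free world all four would agree.  Three
composites trade robustness against contamination by later exposures:

* **SPK I** — the first-morning void alone (longest accumulation window,
  least contaminated by day-2 intake).
* **SPK II** — before-bedtime and first-morning estimates, averaged with
  void-volume weights (w_i = V_i / sum V).
* **SPK III** — all four voids (bedtime, first-morning, lunch, dinner),
  unweighted mean, every void inverted against the day-1 dinner anchor.

Missing voids never fail a composite: each scheme uses whatever constituents
are available, and is itself missing only when none are.  A zero dose is an
observation, not a missing value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .errors import DomainError
from .pk import DoseEstimate
from .study_io import Slot

logger = logging.getLogger(__name__)

__all__ = ["Scheme", "CompositeDose", "spk1", "spk2", "spk3", "composite_all"]


class Scheme(str, Enum):
    SPK_I = "SPK_I"
    SPK_II = "SPK_II"
    SPK_III = "SPK_III"


@dataclass(frozen=True)
class CompositeDose:
    """A daily dose built from one or more void-level estimates.

    ``constituents`` records each (slot, dose, void volume or None) actually
    used; the composite always lies within their [min, max].
    """

    scheme: Scheme
    dose: float  # µg/kg/day
    constituents: tuple[tuple[int, float, float | None], ...]
    subject_period: object | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.constituents:
            raise DomainError("a composite needs at least one constituent")
        if not (math.isfinite(self.dose) and self.dose >= 0):
            raise DomainError("composite dose must be finite and non-negative")

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)

    @property
    def slots_used(self) -> tuple[int, ...]:
        return tuple(s for s, _, _ in self.constituents)


def _dose_value(d) -> float:
    return d.dose if isinstance(d, DoseEstimate) else float(d)


def _available(estimates: Mapping[int, object], slots) -> dict[int, float]:
    return {
        int(s): _dose_value(estimates[s])
        for s in slots
        if s in estimates and estimates[s] is not None
    }


def spk1(
    estimates: Mapping[int, object], *, subject_period=None
) -> CompositeDose | None:
    """First composite: the first-morning void estimate alone.

    Returns ``None`` when the first-morning void is missing (missingness
    propagates, it is not an error).
    """
    doses = _available(estimates, [Slot.FIRST_MORNING])
    if not doses:
        return None
    d = doses[int(Slot.FIRST_MORNING)]
    return CompositeDose(
        Scheme.SPK_I, d, ((int(Slot.FIRST_MORNING), d, None),), subject_period
    )


def spk2(
    estimates: Mapping[int, object],
    volumes: Mapping[int, float] | None = None,
    *,
    subject_period=None,
) -> CompositeDose | None:
    """Second composite: bedtime + first-morning, volume-weighted mean.

    dose = sum(V_i d_i) / sum(V_i) over the available constituents among the
    bedtime and first-morning voids; with a single constituent it is that
    value.  When both doses are present but a volume is missing, falls back
    to the unweighted mean with a logged warning.
    """
    slots = [Slot.BEDTIME, Slot.FIRST_MORNING]
    doses = _available(estimates, slots)
    if not doses:
        return None
    vols = {
        s: float(volumes[s])
        for s in doses
        if volumes is not None and volumes.get(s) is not None
    }
    if len(doses) == 1 or set(vols) >= set(doses):
        weights = vols if len(doses) > 1 else {s: 1.0 for s in doses}
    else:
        logger.warning(
            "SPK II: void volume missing for slots %s; using unweighted mean",
            sorted(set(doses) - set(vols)),
        )
        weights = {s: 1.0 for s in doses}
    total_w = sum(weights[s] for s in doses)
    dose = sum(weights[s] * doses[s] for s in doses) / total_w
    constituents = tuple((s, doses[s], vols.get(s)) for s in sorted(doses))
    return CompositeDose(Scheme.SPK_II, dose, constituents, subject_period)


def spk3(
    estimates: Mapping[int, object], *, subject_period=None
) -> CompositeDose | None:
    """Third composite: unweighted mean over all four voids available.

    All constituents must have been inverted against the day-1 dinner
    anchor, so later voids attribute their whole metabolite content to that
    single composite meal exposure.
    """
    doses = _available(
        estimates, [Slot.BEDTIME, Slot.FIRST_MORNING, Slot.LUNCH, Slot.DINNER]
    )
    if not doses:
        return None
    dose = sum(doses.values()) / len(doses)
    constituents = tuple((s, doses[s], None) for s in sorted(doses))
    return CompositeDose(Scheme.SPK_III, dose, constituents, subject_period)


def composite_all(
    estimates: Mapping[int, object],
    volumes: Mapping[int, float] | None = None,
    *,
    subject_period=None,
) -> dict[Scheme, CompositeDose | None]:
    """All three composites for one subject-period."""
    return {
        Scheme.SPK_I: spk1(estimates, subject_period=subject_period),
        Scheme.SPK_II: spk2(estimates, volumes, subject_period=subject_period),
        Scheme.SPK_III: spk3(estimates, subject_period=subject_period),
    }
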