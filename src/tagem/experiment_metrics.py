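"""Injection-success metrics for microinjection experiments.

Each metric is a simple percentage ``100 * numerator / denominator`` with
the numerator/denominator pairing fixed by the assay:

==============  ==========================================  =====================
kind            numerator                                   denominator
==============  ==========================================  =====================
survival        larvae / zebrafish alive at day 5           embryos injected
insertion       transposon-mediated transgenic vials        fertile crosses
integration     PhiC31-mediated transgenic vials            fertile crosses
mutagenesis     mutant vials                                fertile crosses
injection       transgenic or mutant vials                  embryos injected
transformation  fluorescent (GFP/RFP) zebrafish embryos     embryos injected
==============  ==========================================  =====================

``cumulative_detection_success`` composes the per-stage success rates of
sequentially applied detection models (plate-level embryo detection, then
micropipette/injection-point detection) into the fraction of embryos the
whole cascade can target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "ExperimentCounts",
    "EFFICIENCY_KINDS",
    "UndefinedMetricError",
    "efficiency",
    "round_half_up",
    "cumulative_detection_success",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is zero or a count is missing."""


@dataclass(frozen=True)
class ExperimentCounts:
    """Raw counts from one injection experiment.

    Every field is optional: a given assay only fills in the counts it
    measured (a Drosophila transgenesis run has no fluorescent-embryo
    count, a zebrafish somatic run has no fertile-cross count).
    """

    n_injected: Optional[int] = None
    n_surviving_day5: Optional[int] = None
    n_fertile_crosses: Optional[int] = None
    n_transgenic_vials: Optional[int] = None
    n_mutant_vials: Optional[int] = None
    n_fluorescent_embryos: Optional[int] = None

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


def _injection_numerator(counts: ExperimentCounts) -> Optional[int]:
    # "transgenic or mutant vials": whichever of the two was scored; both
    # when both were (a combined screen).
    parts = [
        v for v in (counts.n_transgenic_vials, counts.n_mutant_vials) if v is not None
    ]
    return sum(parts) if parts else None


EFFICIENCY_KINDS = {
    "survival": ("n_surviving_day5", "n_injected"),
    "insertion": ("n_transgenic_vials", "n_fertile_crosses"),
    "integration": ("n_transgenic_vials", "n_fertile_crosses"),
    "mutagenesis": ("n_mutant_vials", "n_fertile_crosses"),
    "injection": (_injection_numerator, "n_injected"),
    "transformation": ("n_fluorescent_embryos", "n_injected"),
}


def efficiency(kind: str, counts: ExperimentCounts) -> float:
    """Percentage efficiency of one assay, at full precision.

    Parameters
    ----------
    kind
        One of ``survival``, ``insertion``, ``integration``,
        ``mutagenesis``, ``injection``, ``transformation``.
    counts
        The experiment's raw counts; the fields required by *kind* must be
        present and the denominator positive.

    Returns
    -------
    float
        ``100 * numerator / denominator``.  Use :func:`round_half_up` for
        the integer percent conventionally reported.
    """
    try:
        num_field, den_field = EFFICIENCY_KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown efficiency kind {kind!r}; expected one of "
            f"{sorted(EFFICIENCY_KINDS)}"
        ) from None
    numerator = num_field(counts) if callable(num_field) else getattr(counts, num_field)
    denominator = getattr(counts, den_field)
    if numerator is None or denominator is None:
        raise UndefinedMetricError(
            f"{kind} efficiency requires counts for both numerator and denominator"
        )
    if denominator == 0:
        raise UndefinedMetricError(f"{kind} efficiency undefined: denominator is zero")
    if numerator > denominator:
        raise ValueError(
            f"{kind} efficiency numerator {numerator} exceeds denominator {denominator}"
        )
    return 100.0 * numerator / denominator


def round_half_up(percent: float) -> int:
    """Round a percentage to the nearest integer, halves away from zero.

    99/187 fertile crosses producing transgenics is 52.94...%, reported
    as 53%.
    """
    return int(math.floor(percent + 0.5))


def cumulative_detection_success(stage_rates: Iterable[float]) -> float:
    """Fraction of embryos successfully handled by a cascade of stages.

    The detection models run sequentially (an embryo must first be found
    on the plate, then its injection site located), so the cascade
    succeeds only when every stage does; assuming independent failures
    the cumulative rate is the product of the per-stage rates.  Two
    stages at 90% give 0.81.

    Raises
    ------
    ValueError
        If the list is empty or any rate is outside [0, 1].
    """
    rates = list(stage_rates)
    if not rates:
        raise ValueError("at least one stage rate is required")
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"stage rate {r} outside [0, 1]")
    return math.prod(rates)
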