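"""Nanofiltration membrane characterization: rejection, MWCO, Stokes radii.

Solute rejection is R = (1 - Cp/Cf) * 100%.  The molecular weight cut-off
(MWCO) of a membrane is the molecular weight of the smallest tested neutral
solute rejected at >= 90% (threshold configurable).  Stokes-Einstein radii
for the standard PEG/sucrose series are tabulated; intermediate weights are
interpolated log-log and flagged with a warning.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass

log = logging.getLogger(__name__)

__all__ = [
    "SoluteSpec",
    "RejectionRecord",
    "MwcoStatus",
    "MwcoResult",
    "STANDARD_SOLUTES",
    "rejection",
    "determine_mwco",
    "stokes_radius",
    "ExtrapolationError",
    "InterpolatedRadiusWarning",
]


@dataclass(frozen=True)
class SoluteSpec:
    name: str
    molecular_weight: float     # g/mol
    stokes_radius: float        # nm

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValueError("molecular_weight must be positive")
        if not self.stokes_radius > 0:
            raise ValueError("stokes_radius must be positive")


# Standard neutral-solute series for MWCO analysis (PEG oligomers + sucrose)
STANDARD_SOLUTES: tuple[SoluteSpec, ...] = (
    SoluteSpec("PEG 200", 200.0, 0.41),
    SoluteSpec("Sucrose", 342.3, 0.47),
    SoluteSpec("PEG 400", 400.0, 0.57),
    SoluteSpec("PEG 600", 600.0, 0.68),
    SoluteSpec("PEG 1000", 1000.0, 0.94),
)


@dataclass(frozen=True)
class RejectionRecord:
    solute: SoluteSpec
    rejection_pct: float
    uncertainty_pct: float | None = None
    c_feed: float | None = None
    c_permeate: float | None = None
    concentration_unit: str | None = None

    @classmethod
    def from_concentrations(cls, solute: SoluteSpec, c_feed: float,
                            c_permeate: float, unit: str = "ppm",
                            uncertainty_pct: float | None = None
                            ) -> "RejectionRecord":
        r = rejection(c_feed, c_permeate)
        return cls(solute=solute, rejection_pct=r,
                   uncertainty_pct=uncertainty_pct, c_feed=c_feed,
                   c_permeate=c_permeate, concentration_unit=unit)

    def __post_init__(self) -> None:
        if self.rejection_pct < 0.0:
            log.warning("negative rejection %.3f%% for %s clamped to 0",
                        self.rejection_pct, self.solute.name)
            object.__setattr__(self, "rejection_pct", 0.0)
        if self.rejection_pct > 100.0:
            raise ValueError("rejection_pct cannot exceed 100")


def rejection(c_feed: float, c_permeate: float) -> float:
    """Apparent solute rejection R = (1 - Cp/Cf) * 100 in percent.

    Negative values (permeate above feed, possible with measurement noise)
    clamp to 0 with a logged warning.
    """
    if not c_feed > 0:
        raise ValueError("c_feed must be strictly positive")
    if c_permeate < 0:
        raise ValueError("c_permeate must be nonnegative")
    r = (1.0 - c_permeate / c_feed) * 100.0
    if r < 0.0:
        log.warning("permeate exceeds feed (R = %.3f%%); clamping to 0", r)
        return 0.0
    return r


class MwcoStatus(str, enum.Enum):
    DETERMINED = "determined"
    AT_OR_BELOW_LIGHTEST = "at_or_below_lightest_tested"
    NOT_REACHED = "no_mwco_within_tested_range"


@dataclass(frozen=True)
class MwcoResult:
    mwco: float | None              # g/mol
    defining_solute: SoluteSpec | None
    threshold_pct: float
    status: MwcoStatus

    @property
    def determined(self) -> bool:
        return self.status is not MwcoStatus.NOT_REACHED


def determine_mwco(records: list[RejectionRecord],
                   threshold: float = 90.0) -> MwcoResult:
    """Smallest-molecular-weight tested solute rejected at >= threshold.

    Order-invariant.  If every tested solute meets the threshold the
    lightest is reported flagged "at or below"; if none does, an explicit
    no-MWCO-within-tested-range result is returned.  The comparison is
    inclusive (a 90.0% rejection meets the 90% rule).
    """
    if not records:
        raise ValueError("records must be non-empty")
    by_mw = sorted(records, key=lambda r: r.solute.molecular_weight)
    passing = [r for r in by_mw if r.rejection_pct >= threshold]
    if not passing:
        return MwcoResult(mwco=None, defining_solute=None,
                          threshold_pct=threshold,
                          status=MwcoStatus.NOT_REACHED)
    defining = passing[0]
    status = (MwcoStatus.AT_OR_BELOW_LIGHTEST
              if len(passing) == len(by_mw) else MwcoStatus.DETERMINED)
    return MwcoResult(mwco=defining.solute.molecular_weight,
                      defining_solute=defining.solute,
                      threshold_pct=threshold, status=status)


class ExtrapolationError(ValueError):
    pass


class InterpolatedRadiusWarning(UserWarning):
    pass


def stokes_radius(molecular_weight: float,
                  allow_extrapolation: bool = False) -> float:
    """Stokes-Einstein radius (nm) for a neutral solute.

    Exact lookup for the tabulated series; log-log interpolation between
    neighbours otherwise (flagged with :class:`InterpolatedRadiusWarning`).
    Weights outside the tabulated range raise unless
    ``allow_extrapolation`` is set.
    """
    if not molecular_weight > 0:
        raise ValueError("molecular_weight must be positive")
    table = sorted(STANDARD_SOLUTES, key=lambda s: s.molecular_weight)
    for s in table:
        if math.isclose(molecular_weight, s.molecular_weight,
                        rel_tol=1e-9):
            return s.stokes_radius
    lo, hi = table[0], table[-1]
    if molecular_weight < lo.molecular_weight or \
            molecular_weight > hi.molecular_weight:
        if not allow_extrapolation:
            raise ExtrapolationError(
                f"molecular weight {molecular_weight} outside tabulated "
                f"range [{lo.molecular_weight}, {hi.molecular_weight}]")
        a, b = (table[0], table[1]) if \
            molecular_weight < lo.molecular_weight else (table[-2], table[-1])
    else:
        a = max((s for s in table
                 if s.molecular_weight <= molecular_weight),
                key=lambda s: s.molecular_weight)
        b = min((s for s in table
                 if s.molecular_weight >= molecular_weight),
                key=lambda s: s.molecular_weight)
    warnings.warn(
        f"Stokes radius for MW {molecular_weight} obtained by log-log "
        f"interpolation between {a.name} and {b.name}",
        InterpolatedRadiusWarning, stacklevel=2)
    t = (math.log(molecular_weight) - math.log(a.molecular_weight)) / \
        (math.log(b.molecular_weight) - math.log(a.molecular_weight))
    return math.exp(math.log(a.stokes_radius) +
                    t * (math.log(b.stokes_radius) - math.log(a.stokes_radius)))
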