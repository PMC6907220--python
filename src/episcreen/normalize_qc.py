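"""Control-anchored viability normalization and automated plate QC.

Raw luminescence counts are converted to percent viability using the in-plate
controls as anchors: the DMSO (vehicle) mean maps to 100 % and the
benzethonium-chloride (cytotoxic) mean to 0 %:

    viability(w) = 100 * (counts(w) - mean_pos) / (mean_neg - mean_pos)

Growth inhibition is its complement (100 - viability). Values are clamped to
[-20, 120] so overshoot is retained but bounded before it reaches downstream
scores.

Plate quality is assessed automatically from the control distributions:
Z' factor, negative-control coefficient of variation, and the fold signal
window between the anchors. Thresholds are conventional screening defaults
and fully configurable; failure comparisons are strict (Z' = 0.39 fails a
0.4 threshold, Z' = 0.4 passes).
"""

from __future__ import annotations

import enum
import logging
import statistics
from dataclasses import dataclass

from .errors import DegenerateWindowError, MissingControlsError
from .screen_model import PlateLayout, RawPlate, WellKind, validate_plate_pair

logger = logging.getLogger(__name__)

DEFAULT_CLAMP = (-20.0, 120.0)


class QCFailure(str, enum.Enum):
    LOW_ZPRIME = "LOW_ZPRIME"
    HIGH_CONTROL_CV = "HIGH_CONTROL_CV"
    LOW_SIGNAL_WINDOW = "LOW_SIGNAL_WINDOW"
    MISSING_CONTROLS = "MISSING_CONTROLS"


@dataclass(frozen=True)
class QCThresholds:
    """Cutoffs for automated plate QC (all configurable)."""

    min_z_prime: float = 0.4
    max_control_cv: float = 0.2
    min_signal_window: float = 3.0  # fold ratio mean_neg / mean_pos


@dataclass(frozen=True)
class QCReport:
    passed: bool
    reasons: tuple[QCFailure, ...] = ()

    def __post_init__(self):
        assert self.passed == (len(self.reasons) == 0)


@dataclass(frozen=True)
class ControlStats:
    """Summary of the in-plate control distributions and Z'-factor."""

    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    n_neg: int
    n_pos: int

    @property
    def cv_neg(self) -> float:
        return self.sd_neg / self.mean_neg if self.mean_neg else float("inf")

    @property
    def cv_pos(self) -> float:
        return self.sd_pos / self.mean_pos if self.mean_pos else float("inf")

    @property
    def z_prime(self) -> float:
        """Z' = 1 - 3 (sd_pos + sd_neg) / |mean_neg - mean_pos|; 1 is ideal."""
        window = abs(self.mean_neg - self.mean_pos)
        if window == 0:
            return float("-inf")
        return 1.0 - 3.0 * (self.sd_pos + self.sd_neg) / window

    @property
    def signal_window(self) -> float:
        return self.mean_neg / self.mean_pos if self.mean_pos else float("inf")


@dataclass
class NormalizedPlate:
    plate_id: str
    cell_line: str
    arm: object
    viability: dict[str, float]  # percent, clamped
    control_stats: ControlStats
    qc: QCReport
    n_clamped: int = 0

    def inhibition(self, well: str) -> float:
        """Percent growth inhibition; complements viability to exactly 100."""
        return 100.0 - self.viability[well]


def control_stats(raw: RawPlate, layout: PlateLayout) -> ControlStats:
    """Means/SDs of the declared control wells and the derived Z'-factor.

    Requires at least two readable wells of each control type; a missing type
    raises :class:`MissingControlsError` (surfaced in QC as MISSING_CONTROLS).
    """
    validate_plate_pair(layout, raw)
    neg = [raw.readings[w] for w in layout.wells_of_kind(WellKind.NEG_CONTROL) if w in raw.readings]
    pos = [raw.readings[w] for w in layout.wells_of_kind(WellKind.POS_CONTROL) if w in raw.readings]
    if len(neg) < 2 or len(pos) < 2:
        raise MissingControlsError(
            f"plate {raw.plate_id}: need >= 2 readable wells per control type, "
            f"found {len(neg)} negative / {len(pos)} positive"
        )
    return ControlStats(
        mean_neg=statistics.fmean(neg),
        sd_neg=statistics.stdev(neg),
        mean_pos=statistics.fmean(pos),
        sd_pos=statistics.stdev(pos),
        n_neg=len(neg),
        n_pos=len(pos),
    )


def qc_from_stats(stats: ControlStats, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    reasons = []
    if stats.z_prime < thresholds.min_z_prime:
        reasons.append(QCFailure.LOW_ZPRIME)
    if stats.cv_neg > thresholds.max_control_cv:
        reasons.append(QCFailure.HIGH_CONTROL_CV)
    if stats.signal_window < thresholds.min_signal_window:
        reasons.append(QCFailure.LOW_SIGNAL_WINDOW)
    return QCReport(passed=not reasons, reasons=tuple(reasons))


def qc_plate(norm: "NormalizedPlate", thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Re-evaluate QC of a normalized plate under (possibly different) thresholds."""
    return qc_from_stats(norm.control_stats, thresholds)


def normalize_plate(
    raw: RawPlate,
    layout: PlateLayout,
    thresholds: QCThresholds = QCThresholds(),
    clamp: tuple[float, float] = DEFAULT_CLAMP,
) -> NormalizedPlate:
    """Anchor raw counts on the in-plate controls and return percent viability.

    Every well with a reading is normalized (controls included, which makes the
    anchor identities directly checkable). If a control type is missing the
    plate is returned un-normalized with a MISSING_CONTROLS QC failure.
    """
    try:
        stats = control_stats(raw, layout)
    except MissingControlsError:
        logger.warning("plate %s: controls missing; QC fail, no normalization", raw.plate_id)
        empty = ControlStats(0.0, 0.0, 0.0, 0.0, 0, 0)
        return NormalizedPlate(
            plate_id=raw.plate_id,
            cell_line=layout.cell_line,
            arm=layout.arm,
            viability={},
            control_stats=empty,
            qc=QCReport(passed=False, reasons=(QCFailure.MISSING_CONTROLS,)),
        )
    window = stats.mean_neg - stats.mean_pos
    if window == 0:
        raise DegenerateWindowError(
            f"plate {raw.plate_id}: control means coincide ({stats.mean_neg})"
        )
    lo, hi = clamp
    viability: dict[str, float] = {}
    n_clamped = 0
    for well, counts in raw.readings.items():
        v = 100.0 * (counts - stats.mean_pos) / window
        if v < lo or v > hi:
            n_clamped += 1
            v = min(max(v, lo), hi)
        viability[well] = v
    if n_clamped:
        logger.info("plate %s: clamped %d wells to [%g, %g]", raw.plate_id, n_clamped, lo, hi)
    return NormalizedPlate(
        plate_id=raw.plate_id,
        cell_line=layout.cell_line,
        arm=layout.arm,
        viability=viability,
        control_stats=stats,
        qc=qc_from_stats(stats, thresholds),
        n_clamped=n_clamped,
    )
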