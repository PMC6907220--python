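"""Per-(cell line, compound, arm) dose-response profiles and optional 4PL fits.

Profiles aggregate normalized wells across replicate plates into per-dose
mean/SD/n; plates failing QC are excluded (and logged) unless explicitly
overridden. Curve fitting is auxiliary: the sensitization score downstream
operates on the measured per-dose means, while the four-parameter logistic
fit serves cytotoxic-dose (IC50) estimation and plotting.

The 4PL is parameterized in the inhibitory orientation,

    v(d) = emax + (e0 - emax) / (1 + (d / ic50)^slope),

fit by bounded least squares against log10 dose, with e0 >= emax enforced
through a non-negative span parameter.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import EmptyProfileError, ValidationError
from .normalize_qc import NormalizedPlate
from .screen_model import Arm, PlateLayout, WellKind

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoseResponsePoint:
    dose: float  # nM
    mean_viability: float  # percent
    sd: float  # percent; 0 when n == 1
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("a dose-response point needs at least one well")


@dataclass(frozen=True)
class DoseResponseProfile:
    cell_line: str
    compound_id: str
    arm: Arm
    points: tuple[DoseResponsePoint, ...]  # sorted by descending dose
    source_plates: tuple[str, ...]
    qc_pass: bool = True  # False only when QC-failing plates were force-included

    def __post_init__(self):
        doses = [p.dose for p in self.points]
        if len(set(doses)) != len(doses):
            raise ValidationError("doses within a profile must be unique")
        if any(a <= b for a, b in zip(doses, doses[1:])):
            raise ValidationError("points must be sorted by descending dose")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(p.dose for p in self.points)

    def viability_at(self, dose: float) -> float:
        for p in self.points:
            if p.dose == dose:
                return p.mean_viability
        raise KeyError(dose)


@dataclass(frozen=True)
class CurveFit:
    """4PL summary; ``converged=False`` carries descriptive fields only (no IC50)."""

    e0: float
    emax: float
    ic50: float | None
    hill_slope: float | None
    r_squared: float | None
    converged: bool


def aggregate_profile(
    plates: Sequence[NormalizedPlate],
    layouts: Sequence[PlateLayout],
    cell_line: str,
    compound_id: str,
    arm: Arm | str,
    include_qc_failed: bool = False,
) -> DoseResponseProfile:
    """Pool wells matching (cell line, compound, arm) across plates into a profile.

    Each dose level gets the mean/SD over all contributing wells on all
    QC-passing replicate plates. Raises :class:`EmptyProfileError` when no
    eligible well matches (e.g. every source plate failed QC).
    """
    arm = Arm(arm)
    if len(plates) != len(layouts):
        raise ValidationError("plates and layouts must pair up one-to-one")
    per_dose: dict[float, list[float]] = {}
    used_plates: list[str] = []
    any_match = False
    used_failed = False
    for plate, layout in zip(plates, layouts):
        if plate.plate_id != layout.plate_id:
            raise ValidationError(
                f"plate/layout mismatch: {plate.plate_id} vs {layout.plate_id}"
            )
        if layout.cell_line != cell_line or layout.arm is not arm:
            continue
        has_wells = bool(layout.compound_wells(compound_id))
        if not has_wells:
            continue
        any_match = True
        if not plate.qc.passed:
            if not include_qc_failed:
                logger.info("excluding QC-failing plate %s from profile", plate.plate_id)
                continue
            used_failed = True
        used_plates.append(plate.plate_id)
        for well in layout.compound_wells(compound_id):
            if well not in plate.viability:
                continue
            dose = layout.assignments[well].dose
            per_dose.setdefault(dose, []).append(plate.viability[well])
    if not per_dose:
        detail = "all source plates failed QC" if any_match else "no matching wells"
        raise EmptyProfileError(
            f"no eligible wells for cell_line={cell_line!r} compound={compound_id!r} "
            f"arm={arm.value} ({detail})"
        )
    points = tuple(
        DoseResponsePoint(
            dose=d,
            mean_viability=statistics.fmean(vs),
            sd=statistics.stdev(vs) if len(vs) > 1 else 0.0,
            n=len(vs),
        )
        for d in sorted(per_dose, reverse=True)
        for vs in [per_dose[d]]
    )
    return DoseResponseProfile(
        cell_line=cell_line,
        compound_id=compound_id,
        arm=arm,
        points=points,
        source_plates=tuple(used_plates),
        qc_pass=not used_failed,
    )


def aggregate_all_profiles(
    plates: Sequence[NormalizedPlate],
    layouts: Sequence[PlateLayout],
    include_qc_failed: bool = False,
) -> dict[tuple[str, str, Arm], DoseResponseProfile]:
    """One pass over all plates: profiles keyed by (cell_line, compound_id, arm)."""
    keys: set[tuple[str, str, Arm]] = set()
    for layout in layouts:
        for a in layout.assignments.values():
            if a.kind is WellKind.COMPOUND:
                keys.add((layout.cell_line, a.compound_id, layout.arm))
    out: dict[tuple[str, str, Arm], DoseResponseProfile] = {}
    for cell_line, compound_id, arm in sorted(keys, key=lambda k: (k[0], k[1], k[2].value)):
        try:
            out[(cell_line, compound_id, arm)] = aggregate_profile(
                plates, layouts, cell_line, compound_id, arm, include_qc_failed
            )
        except EmptyProfileError:
            logger.warning(
                "no usable data for %s / %s / %s", cell_line, compound_id, arm.value
            )
    return out


def _four_pl(log_dose: np.ndarray, emax: float, span: float, log_ic50: float, slope: float):
    return emax + span / (1.0 + 10.0 ** (slope * (log_dose - log_ic50)))


def fit_curve(profile: DoseResponseProfile, min_r_squared: float = 0.3) -> CurveFit:
    """Bounded least-squares 4PL fit of mean viability against log10 dose.

    Needs >= 4 distinct doses; otherwise a not-fittable marker is returned.
    Fits with R^2 below ``min_r_squared`` (or optimizer failure) come back with
    ``converged=False`` and descriptive e0/emax only.
    """
    doses = np.array([p.dose for p in profile.points], dtype=float)
    viab = np.array([p.mean_viability for p in profile.points], dtype=float)
    e0_desc = float(viab.max())
    emax_desc = float(viab.min())
    if len(doses) < 4:
        return CurveFit(e0_desc, emax_desc, None, None, None, converged=False)
    log_d = np.log10(doses)
    span0 = max(e0_desc - emax_desc, 1e-6)
    # start the midpoint at the dose whose response is nearest half-span
    mid_target = emax_desc + span0 / 2.0
    log_ic50_0 = float(log_d[np.argmin(np.abs(viab - mid_target))])
    lo = [-20.0, 0.0, log_d.min() - 2.0, 0.05]
    hi = [120.0, 160.0, log_d.max() + 2.0, 10.0]
    try:
        popt, _ = curve_fit(
            _four_pl,
            log_d,
            viab,
            p0=[emax_desc, span0, log_ic50_0, 1.0],
            bounds=(lo, hi),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return CurveFit(e0_desc, emax_desc, None, None, None, converged=False)
    pred = _four_pl(log_d, *popt)
    ss_res = float(np.sum((viab - pred) ** 2))
    ss_tot = float(np.sum((viab - viab.mean()) ** 2))
    if ss_tot == 0.0:
        # flat profile: midpoint undefined
        return CurveFit(e0_desc, emax_desc, None, None, None, converged=False)
    r2 = 1.0 - ss_res / ss_tot
    emax, span, log_ic50, slope = popt
    if r2 < min_r_squared:
        return CurveFit(e0_desc, emax_desc, None, None, r2, converged=False)
    return CurveFit(
        e0=float(emax + span),
        emax=float(emax),
        ic50=float(10.0**log_ic50),
        hill_slope=float(slope),
        r_squared=r2,
        converged=True,
    )


def profiles_to_frame(profiles: Iterable[DoseResponseProfile]):
    """Long-format export: cell_line, compound_id, arm, dose_nM, mean_viability, sd, n."""
    import pandas as pd

    rows = [
        {
            "cell_line": p.cell_line,
            "compound_id": p.compound_id,
            "arm": p.arm.value,
            "dose_nM": pt.dose,
            "mean_viability": pt.mean_viability,
            "sd": pt.sd,
            "n": pt.n,
        }
        for p in profiles
        for pt in p.points
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_line", "compound_id", "arm", "dose_nM", "mean_viability", "sd", "n"],
    )
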