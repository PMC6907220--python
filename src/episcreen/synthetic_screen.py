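"""Synthetic screen generator: plates, paired arms, passaging dynamics, ground truth.

The real screen's raw plates are not public, so every downstream stage is
exercised against simulated data generated from a declared ground truth.
The generative model mirrors the assay:

* mono-arm viability follows a Hill curve per (cell line, compound);
* the combination arm subtracts a planted sensitization effect (in viability
  percentage points) at and above a per-compound sensitizing dose, floored
  at 0 — which makes the planted effect exactly the reprogramming score the
  pipeline should recover;
* viabilities map to luminescence counts through the same two anchors the
  normalizer uses, then multiplicative and additive Gaussian noise applies;
* DMSO / benzethonium-chloride control wells are placed at randomized
  positions under the seed.

The on-plate passaging robot protocol (five pipetting steps per 3-day cycle
at 40 uL working volume) is simulated step by step; per cycle it exchanges
3/4 of the media and removes half of the cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .reprogramming import HitMatrix
from .screen_model import (
    Arm,
    CompoundRecord,
    PlateLayout,
    RawPlate,
    WellAssignment,
    WellKind,
    default_library,
    format_well,
    PLATE_FORMATS,
)
from .synergy import SynergyGrid, bliss_expected

DEFAULT_CELL_LINES = ("RIVA-I", "SU-DHL-4", "OCI-LY-19", "OCI-LY-3")


# ---------------------------------------------------------------------------
# Hill viability
# ---------------------------------------------------------------------------

def hill_viability(dose: float, e0: float = 100.0, emax: float = 0.0,
                   ic50: float = 100.0, slope: float = 1.0) -> float:
    """Viability (percent) at ``dose`` under a four-parameter Hill model.

    v(d) = emax + (e0 - emax) / (1 + (d / ic50)^slope); monotone
    non-increasing in dose, equal to e0 at dose 0 and to the e0/emax midpoint
    at dose == ic50.
    """
    if not (ic50 > 0 and math.isfinite(ic50)):
        raise ValidationError(f"ic50 must be finite and > 0, got {ic50}")
    if not (slope > 0 and math.isfinite(slope)):
        raise ValidationError(f"slope must be finite and > 0, got {slope}")
    if dose < 0:
        raise ValidationError(f"dose must be >= 0, got {dose}")
    if dose == 0:
        return e0
    return emax + (e0 - emax) / (1.0 + (dose / ic50) ** slope)


# ---------------------------------------------------------------------------
# On-plate passaging
# ---------------------------------------------------------------------------

WORKING_VOLUME_UL = 40.0
TRANSFER_VOLUME_UL = 20.0


@dataclass(frozen=True)
class PassageState:
    """Well state tracked through passaging cycles (perfect mixing assumed).

    ``old_media_fraction`` is the fraction of current media that dates from
    before the first simulated cycle; ``cells`` and ``drug_concentration``
    are relative to their initial count and the nominal media concentration.
    """

    total_volume: float = WORKING_VOLUME_UL  # uL
    old_media_fraction: float = 1.0
    cells: float = 1.0
    drug_concentration: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.old_media_fraction <= 1.0:
            raise ValidationError("old_media_fraction must lie in [0, 1]")
        if self.cells < 0 or self.drug_concentration < 0:
            raise ValidationError("cells and drug_concentration must be >= 0")


def _passage_one_cycle(state: PassageState, fresh_drug: float) -> PassageState:
    """The five robot steps, with explicit volume bookkeeping.

    1. aspirate 20 uL cell-free media (cells sit at the well bottom);
    2. dispense 20 uL fresh media carrying the pretreatment drug;
    3. resuspend (mix);
    4. aspirate 20 uL of the mixed suspension (half the media, half the cells);
    5. dispense 20 uL fresh media.
    """
    v, t = state.total_volume, TRANSFER_VOLUME_UL
    old, drug = state.old_media_fraction, state.drug_concentration
    # step 1: cell-free removal leaves composition unchanged
    vol = v - t
    # step 2: dilution with fresh media
    old = old * vol / (vol + t)
    drug = (drug * vol + fresh_drug * t) / (vol + t)
    vol += t
    # steps 3-4: mixed removal — composition unchanged, half the cells leave
    cells = state.cells * (1.0 - t / vol)
    vol -= t
    # step 5: second fresh addition
    old = old * vol / (vol + t)
    drug = (drug * vol + fresh_drug * t) / (vol + t)
    vol += t
    return PassageState(
        total_volume=vol, old_media_fraction=old, cells=cells, drug_concentration=drug
    )


def simulate_passage(
    state: PassageState, cycles: int, fresh_drug: float = 1.0
) -> PassageState:
    """Apply ``cycles`` passaging cycles (one per 3-day interval).

    With the standard 40 uL volume and 20 uL transfers each cycle multiplies
    the old-media fraction by 0.25 (three quarters of the media exchanged)
    and the cell count by 0.5; drug concentration relaxes toward the fresh-
    media concentration as c <- c/4 + 3/4 * fresh.
    """
    if cycles < 0:
        raise ValidationError(f"cycles must be >= 0, got {cycles}")
    for _ in range(cycles):
        state = _passage_one_cycle(state, fresh_drug)
    return state


def passage_closed_form(cycles: int, fresh_drug: float = 1.0) -> PassageState:
    """Closed-form state after ``cycles`` cycles from a fresh well (for cross-checks)."""
    if cycles < 0:
        raise ValidationError(f"cycles must be >= 0, got {cycles}")
    old = 0.25**cycles
    cells = 0.5**cycles
    # geometric relaxation of c_{k+1} = c_k/4 + (3/4) fresh from c_0 = 1
    drug = fresh_drug + (1.0 - fresh_drug) * 0.25**cycles
    return PassageState(
        old_media_fraction=old, cells=cells, drug_concentration=drug
    )


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundTruth:
    """Generating parameters for one (cell line, compound) pair."""

    e0: float = 100.0
    emax: float = 0.0
    ic50: float = 10000.0  # nM
    slope: float = 1.0
    sensitization_effect: float = 0.0  # percentage points
    sensitizing_dose: float | None = None  # nM; None for non-sensitizers

    def __post_init__(self):
        if (self.sensitization_effect > 0) != (self.sensitizing_dose is not None):
            raise ValidationError(
                "sensitizing_dose must be set iff sensitization_effect > 0"
            )

    @property
    def is_sensitizer(self) -> bool:
        return self.sensitization_effect > 0

    def mono_viability(self, dose: float) -> float:
        return hill_viability(dose, self.e0, self.emax, self.ic50, self.slope)

    def combo_viability(self, dose: float, baseline: float = 0.0) -> float:
        v = self.mono_viability(dose) - baseline
        if self.sensitizing_dose is not None and dose >= self.sensitizing_dose:
            v -= self.sensitization_effect
        return max(v, 0.0)


@dataclass
class GroundTruth:
    """Declared truth for a whole screen, keyed by (cell_line, compound_id)."""

    entries: dict[tuple[str, str], CompoundTruth]
    combo_baseline: float = 0.0  # combo-arm effect applied at every dose

    def expected_score(self, cell_line: str, compound_id: str,
                       doses: Sequence[float]) -> float:
        """The reprogramming score a noise-free pipeline run should report."""
        t = self.entries[(cell_line, compound_id)]
        return max(
            t.mono_viability(d) - t.combo_viability(d, self.combo_baseline)
            for d in doses
        )


@dataclass
class SimConfig:
    """Study conditions for a simulated screen. The seed is mandatory."""

    seed: int
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    library: Sequence[CompoundRecord] = field(default_factory=default_library)
    plate_format: int = 384
    n_neg_controls: int = 16
    n_pos_controls: int = 16
    mean_neg: float = 100000.0  # DMSO anchor counts
    mean_pos: float = 2000.0  # BzCl anchor counts
    multiplicative_cv: float = 0.03
    additive_sd: float = 300.0  # counts
    replicates: int = 2  # plates per (cell line, arm)

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        nrow, ncol = PLATE_FORMATS[self.plate_format]
        n_wells_needed = (
            sum(r.n_doses for r in self.library)
            + self.n_neg_controls + self.n_pos_controls
        )
        if n_wells_needed > nrow * ncol:
            raise ValidationError(
                f"{n_wells_needed} wells needed exceed the "
                f"{self.plate_format}-well format"
            )


def default_ground_truth(
    config: SimConfig,
    n_sensitizers: int = 12,
    effect: float = 50.0,
    dilutions_below_ic50: int = 2,
) -> GroundTruth:
    """Plant ``n_sensitizers`` sensitizing compounds per cell line.

    Sensitizers get a cytotoxic IC50 at their top dose and a sensitizing dose
    ``dilutions_below_ic50`` ladder steps lower — sensitization kicks in well
    below the cytotoxic range, as observed for real reprogramming compounds.
    Non-sensitizers get varied Hill parameters (seeded) and no combo-specific
    effect. Selection and parameters derive from the config seed, so the
    truth is as reproducible as the plates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    entries: dict[tuple[str, str], CompoundTruth] = {}
    ids = [r.compound_id for r in config.library]
    for cell_line in config.cell_lines:
        chosen = set(rng.choice(ids, size=min(n_sensitizers, len(ids)), replace=False))
        for rec in config.library:
            if rec.compound_id in chosen:
                sens_dose = rec.top_dose / rec.dilution_factor**dilutions_below_ic50
                entries[(cell_line, rec.compound_id)] = CompoundTruth(
                    ic50=rec.top_dose,
                    slope=1.0,
                    sensitization_effect=effect,
                    sensitizing_dose=sens_dose,
                )
            else:
                # inactive-to-mildly-cytotoxic mono profiles, no sensitization
                log_ic50 = rng.uniform(
                    math.log10(rec.top_dose), math.log10(rec.top_dose) + 2.0
                )
                entries[(cell_line, rec.compound_id)] = CompoundTruth(
                    ic50=10.0**log_ic50,
                    slope=float(rng.uniform(0.8, 2.0)),
                    emax=float(rng.uniform(0.0, 20.0)),
                )
    return GroundTruth(entries=entries)


@dataclass
class SimulatedScreen:
    layouts: list[PlateLayout]
    raw_plates: list[RawPlate]
    truth: GroundTruth
    config: SimConfig


def _randomized_layout(
    config: SimConfig, cell_line: str, arm: Arm, plate_id: str, rng: np.random.Generator
) -> PlateLayout:
    nrow, ncol = PLATE_FORMATS[config.plate_format]
    wells = [format_well(r, c) for r in range(nrow) for c in range(ncol)]
    order = rng.permutation(len(wells))
    assignments: dict[str, WellAssignment] = {}
    slots = iter(order)
    for rec in config.library:
        for dose in rec.dose_series:
            assignments[wells[next(slots)]] = WellAssignment(
                kind=WellKind.COMPOUND, compound_id=rec.compound_id, dose=dose
            )
    for _ in range(config.n_neg_controls):
        assignments[wells[next(slots)]] = WellAssignment(kind=WellKind.NEG_CONTROL)
    for _ in range(config.n_pos_controls):
        assignments[wells[next(slots)]] = WellAssignment(kind=WellKind.POS_CONTROL)
    return PlateLayout(
        plate_id=plate_id,
        cell_line=cell_line,
        arm=arm,
        assignments=assignments,
        plate_format=config.plate_format,
    )


def _viability_to_counts(v: float, config: SimConfig) -> float:
    return config.mean_pos + (v / 100.0) * (config.mean_neg - config.mean_pos)


def simulate_screen(config: SimConfig, truth: GroundTruth) -> SimulatedScreen:
    """Generate layouts and raw plates for both arms from the declared truth.

    One plate per (cell line, arm, replicate); layouts and noise draw from
    independent substreams of the config seed, so identical (config, truth,
    seed) triples are byte-identical through the CSV writers.
    """
    for cell_line in config.cell_lines:
        for rec in config.library:
            if (cell_line, rec.compound_id) not in truth.entries:
                raise ValidationError(
                    f"truth missing entry for ({cell_line}, {rec.compound_id})"
                )
    ss = np.random.SeedSequence([int(config.seed), 7])
    layout_rng = np.random.default_rng(ss.spawn(1)[0])
    noise_rng = np.random.default_rng(ss.spawn(1)[0])
    layouts: list[PlateLayout] = []
    raws: list[RawPlate] = []
    for cell_line in config.cell_lines:
        for arm in (Arm.PRETREAT_ONLY, Arm.PRETREAT_PLUS_COMBO):
            for rep in range(1, config.replicates + 1):
                tag = "MONO" if arm is Arm.PRETREAT_ONLY else "COMBO"
                plate_id = f"{cell_line}_{tag}_R{rep}"
                layout = _randomized_layout(config, cell_line, arm, plate_id, layout_rng)
                readings: dict[str, float] = {}
                for well, a in layout.assignments.items():
                    if a.kind is WellKind.COMPOUND:
                        t = truth.entries[(cell_line, a.compound_id)]
                        v = (
                            t.mono_viability(a.dose)
                            if arm is Arm.PRETREAT_ONLY
                            else t.combo_viability(a.dose, truth.combo_baseline)
                        )
                    elif a.kind is WellKind.NEG_CONTROL:
                        v = 100.0
                    elif a.kind is WellKind.POS_CONTROL:
                        v = 0.0
                    else:
                        continue
                    counts = _viability_to_counts(v, config)
                    if config.multiplicative_cv > 0:
                        counts *= 1.0 + noise_rng.normal(0.0, config.multiplicative_cv)
                    if config.additive_sd > 0:
                        counts += noise_rng.normal(0.0, config.additive_sd)
                    readings[well] = max(counts, 0.0)
                layouts.append(layout)
                raws.append(RawPlate(plate_id=plate_id, readings=readings))
    return SimulatedScreen(layouts=layouts, raw_plates=raws, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Synergy-matrix simulation
# ---------------------------------------------------------------------------

def simulate_synergy_grid(
    cell_line: str,
    compound_id: str,
    epi_doses: Sequence[float],
    combo_doses: Sequence[float],
    mono_epi_ic50: float = 1000.0,
    mono_combo_ic50: float = 1.0,
    excess: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    model: Callable = bliss_expected,
) -> SynergyGrid:
    """A dose matrix whose observed inhibition is the null expectation plus
    a constant planted excess, with optional Gaussian noise (clipped to [0,1])."""
    rng = rng or np.random.default_rng(0)
    epi = np.asarray(epi_doses, dtype=float)
    combo = np.asarray(combo_doses, dtype=float)
    mono_epi = np.array([1.0 - hill_viability(d, ic50=mono_epi_ic50) / 100.0 for d in epi])
    mono_combo = np.array([1.0 - hill_viability(d, ic50=mono_combo_ic50) / 100.0 for d in combo])
    observed = model(mono_epi[:, None], mono_combo[None, :]) + excess
    if noise_sd > 0:
        observed = observed + rng.normal(0.0, noise_sd, observed.shape)
    observed = np.clip(observed, 0.0, 1.0)
    return SynergyGrid(
        cell_line=cell_line,
        compound_id=compound_id,
        epi_doses=tuple(epi),
        combo_doses=tuple(combo),
        observed=observed,
        mono_epi=np.clip(mono_epi, 0, 1),
        mono_combo=np.clip(mono_combo, 0, 1),
    )


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryRecord:
    """Precision/recall of hit calls against the planted sensitizers."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0


def evaluate_recovery(hits: HitMatrix, truth: GroundTruth) -> RecoveryRecord:
    """Compare called hits with planted sensitizers over the same pairs."""
    hit_keys = {(cl, c) for (c, cl) in hits.entries}
    if hit_keys != set(truth.entries):
        raise ValidationError(
            "hit matrix and ground truth cover different (cell line, compound) pairs"
        )
    tp = fp = fn = tn = 0
    for (cell_line, compound_id), t in truth.entries.items():
        called = hits.entries[(compound_id, cell_line)].hit
        if t.is_sensitizer and called:
            tp += 1
        elif t.is_sensitizer:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return RecoveryRecord(tp=tp, fp=fp, fn=fn, tn=tn)
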