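"""The reprogramming (sensitization) score and hit calling.

A compound's reprogramming score for a cell line is the maximum, over the
tested doses, of the difference in percent viability between the pretreatment-
alone arm and the pretreatment-followed-by-doxorubicin+rituximab arm:

    delta(d) = viability_mono(d) - viability_combo(d)
    score    = max_d delta(d)

A large positive score means the pretreatment left cells alive on its own but
made them vulnerable to the subsequent standard treatment - the sensitization
phenotype the screen exists to find. Hits are scores strictly above a 30-point
threshold on plates that passed QC. The score uses replicate-mean viabilities
at the tested doses only; no interpolation between the 5-point ladder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dose_response import CurveFit, DoseResponseProfile
from .errors import ValidationError
from .screen_model import Arm, CompoundRecord

logger = logging.getLogger(__name__)

DEFAULT_HIT_THRESHOLD = 30.0  # percentage points


@dataclass(frozen=True)
class ReprogrammingResult:
    """The score for one (cell line, compound) pair with its per-dose deltas."""

    cell_line: str
    compound_id: str
    score: float  # percentage points
    best_dose: float  # nM; lowest dose among ties
    per_dose_deltas: tuple[tuple[float, float], ...]  # (dose, delta), descending dose
    qc_pass: bool
    hit: bool

    def __post_init__(self):
        if self.hit and not self.qc_pass:
            raise ValidationError("hit flag requires qc_pass")


def reprogramming_score(
    mono: DoseResponseProfile,
    combo: DoseResponseProfile,
    threshold: float = DEFAULT_HIT_THRESHOLD,
) -> ReprogrammingResult:
    """Score a paired-arm profile set; doses present in only one arm are dropped.

    ``mono`` must be the PRETREAT_ONLY arm and ``combo`` the
    PRETREAT_PLUS_COMBO arm of the same (cell line, compound).
    """
    if mono.cell_line != combo.cell_line or mono.compound_id != combo.compound_id:
        raise ValidationError(
            f"profile pair mismatch: ({mono.cell_line}, {mono.compound_id}) vs "
            f"({combo.cell_line}, {combo.compound_id})"
        )
    if mono.arm is not Arm.PRETREAT_ONLY or combo.arm is not Arm.PRETREAT_PLUS_COMBO:
        raise ValidationError(
            f"arm mismatch: expected PRETREAT_ONLY/PRETREAT_PLUS_COMBO, got "
            f"{mono.arm.value}/{combo.arm.value}"
        )
    shared = sorted(set(mono.doses) & set(combo.doses), reverse=True)
    dropped = (set(mono.doses) | set(combo.doses)) - set(shared)
    if dropped:
        logger.info(
            "%s/%s: doses %s present in one arm only, excluded",
            mono.cell_line, mono.compound_id, sorted(dropped),
        )
    if not shared:
        raise ValidationError(
            f"{mono.cell_line}/{mono.compound_id}: no dose shared between arms"
        )
    deltas = tuple(
        (d, mono.viability_at(d) - combo.viability_at(d)) for d in shared
    )
    score = max(delta for _, delta in deltas)
    # ties resolve to the lowest dose: sensitization at low dose is the point
    best_dose = min(d for d, delta in deltas if delta == score)
    qc_pass = mono.qc_pass and combo.qc_pass
    return ReprogrammingResult(
        cell_line=mono.cell_line,
        compound_id=mono.compound_id,
        score=score,
        best_dose=best_dose,
        per_dose_deltas=deltas,
        qc_pass=qc_pass,
        hit=(score > threshold) and qc_pass,
    )


@dataclass
class HitMatrix:
    """Compounds x cell lines summary of the screen (the hit-map view)."""

    compounds: tuple[str, ...]
    cell_lines: tuple[str, ...]
    entries: dict[tuple[str, str], ReprogrammingResult]  # (compound_id, cell_line)
    threshold: float
    hits_per_cell_line: dict[str, int] = field(default_factory=dict)
    hits_per_class: dict[str, int] = field(default_factory=dict)

    def is_tested(self, compound_id: str, cell_line: str) -> bool:
        return (compound_id, cell_line) in self.entries

    def hit_count(self) -> int:
        return sum(1 for r in self.entries.values() if r.hit)

    def to_frame(self):
        """Wide score table (compound x cell line); untested pairs left empty."""
        import pandas as pd

        data = {
            cl: [
                self.entries[(c, cl)].score if (c, cl) in self.entries else None
                for c in self.compounds
            ]
            for cl in self.cell_lines
        }
        return pd.DataFrame(data, index=list(self.compounds))


def call_hits(
    results: Iterable[ReprogrammingResult],
    threshold: float = DEFAULT_HIT_THRESHOLD,
    library: Sequence[CompoundRecord] | None = None,
) -> HitMatrix:
    """Apply the hit rule (score strictly above threshold AND QC pass) to all results.

    ``library`` adds per-target-class hit tallies when provided. Duplicate
    (compound, cell line) entries are an error.
    """
    entries: dict[tuple[str, str], ReprogrammingResult] = {}
    for r in results:
        key = (r.compound_id, r.cell_line)
        if key in entries:
            raise ValidationError(f"duplicate result for {key}")
        hit = (r.score > threshold) and r.qc_pass
        entries[key] = ReprogrammingResult(
            cell_line=r.cell_line,
            compound_id=r.compound_id,
            score=r.score,
            best_dose=r.best_dose,
            per_dose_deltas=r.per_dose_deltas,
            qc_pass=r.qc_pass,
            hit=hit,
        )
    compounds = tuple(sorted({c for c, _ in entries}))
    cell_lines = tuple(sorted({cl for _, cl in entries}))
    per_line = {
        cl: sum(1 for (c, l), r in entries.items() if l == cl and r.hit)
        for cl in cell_lines
    }
    per_class: dict[str, int] = {}
    if library is not None:
        class_of = {rec.compound_id: rec.target_class for rec in library}
        for (c, _), r in entries.items():
            if r.hit:
                cls = class_of.get(c, "OTHER")
                per_class[cls] = per_class.get(cls, 0) + 1
    return HitMatrix(
        compounds=compounds,
        cell_lines=cell_lines,
        entries=entries,
        threshold=threshold,
        hits_per_cell_line=per_line,
        hits_per_class=per_class,
    )


@dataclass(frozen=True)
class DoseComparison:
    """Whether the sensitizing dose sits below the compound's own cytotoxic IC50."""

    cell_line: str
    compound_id: str
    best_dose: float
    mono_ic50: float | None
    sensitizing_below_cytotoxic: bool | None  # None = indeterminate (no converged fit)
    ratio: float | None  # ic50 / best_dose


def sensitizing_vs_cytotoxic_dose(
    result: ReprogrammingResult, mono_fit: CurveFit
) -> DoseComparison:
    """Compare the best sensitizing dose against the mono-arm cytotoxic IC50.

    Returns an indeterminate record when the mono fit did not converge (e.g.
    the pretreatment alone never reached 50 % inhibition in range).
    """
    if not mono_fit.converged or mono_fit.ic50 is None:
        return DoseComparison(
            cell_line=result.cell_line,
            compound_id=result.compound_id,
            best_dose=result.best_dose,
            mono_ic50=None,
            sensitizing_below_cytotoxic=None,
            ratio=None,
        )
    return DoseComparison(
        cell_line=result.cell_line,
        compound_id=result.compound_id,
        best_dose=result.best_dose,
        mono_ic50=mono_fit.ic50,
        sensitizing_below_cytotoxic=result.best_dose < mono_fit.ic50,
        ratio=mono_fit.ic50 / result.best_dose,
    )
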