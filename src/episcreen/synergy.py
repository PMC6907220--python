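"""Dose-matrix synergy scoring under an independence null.

For a matrix crossing epigenetic-inhibitor doses with doxorubicin+rituximab
levels, the expected combined inhibition under Bliss independence is

    E[f_ab] = f_a + f_b - f_a * f_b

for single-agent inhibition fractions f_a, f_b taken from the zero-dose
margins of the same plate set. The excess (observed - expected) matrix
averages to a single summary score on a x100 scale: ~0 means the two killing
effects are independent, positive excess synergy, negative antagonism.
Replicate experiments are summarized by the median score. The independence
model is pluggable so highest-single-agent or other nulls can be swapped in.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

_EPS = 1e-9


def bliss_expected(fa, fb):
    """Expected combined inhibition fraction under Bliss independence.

    Accepts scalars or arrays in [0, 1]; values outside the unit interval
    (beyond numerical tolerance) are rejected.
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if np.any(fa < -_EPS) or np.any(fa > 1 + _EPS) or np.any(fb < -_EPS) or np.any(fb > 1 + _EPS):
        raise ValidationError("inhibition fractions must lie in [0, 1]")
    fa = np.clip(fa, 0.0, 1.0)
    fb = np.clip(fb, 0.0, 1.0)
    out = fa + fb - fa * fb
    return float(out) if out.ndim == 0 else out


def hsa_expected(fa, fb):
    """Highest-single-agent null: expected effect is the stronger mono effect."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    out = np.maximum(np.clip(fa, 0, 1), np.clip(fb, 0, 1))
    return float(out) if out.ndim == 0 else out


#: registered independence-null models, keyed by name
NULL_MODELS: dict[str, Callable] = {"bliss": bliss_expected, "hsa": hsa_expected}


def inhibition_fraction(viability_pct) -> np.ndarray:
    """Map percent viability (possibly clamped outside [0,100]) to inhibition in [0,1]."""
    v = np.asarray(viability_pct, dtype=float)
    return np.clip((100.0 - v) / 100.0, 0.0, 1.0)


class SynergyClass(str, Enum):
    SYNERGY = "SYNERGY"
    ADDITIVE = "ADDITIVE"
    ANTAGONISM = "ANTAGONISM"
    UNTESTED = "UNTESTED"


@dataclass(frozen=True)
class SynergyGrid:
    """One replicate's dose matrix: observed inhibition plus the mono margins."""

    cell_line: str
    compound_id: str
    epi_doses: tuple[float, ...]  # nM, rows
    combo_doses: tuple[float, ...]  # doxorubicin+rituximab levels, columns
    observed: np.ndarray  # inhibition fractions, shape (len(epi), len(combo))
    mono_epi: np.ndarray  # inhibition at each epi dose, combo absent
    mono_combo: np.ndarray  # inhibition at each combo level, epi absent
    expected: np.ndarray | None = None
    excess: np.ndarray | None = None
    summary_score: float | None = None  # 100 * mean(excess)

    def __post_init__(self):
        ne, nc = len(self.epi_doses), len(self.combo_doses)
        if self.observed.shape != (ne, nc):
            raise ValidationError(
                f"observed matrix shape {self.observed.shape} != ({ne}, {nc})"
            )
        if self.mono_epi.shape != (ne,) or self.mono_combo.shape != (nc,):
            raise ValidationError("mono margins must match the dose lists")
        for name, arr in (("observed", self.observed), ("mono_epi", self.mono_epi),
                          ("mono_combo", self.mono_combo)):
            if np.any(arr < -_EPS) or np.any(arr > 1 + _EPS):
                raise ValidationError(f"{name} inhibition fractions must lie in [0, 1]")


def excess_grid(grid: SynergyGrid, model: Callable = bliss_expected) -> SynergyGrid:
    """Fill expected/excess matrices and the summary score (100 x mean excess)."""
    expected = model(
        np.asarray(grid.mono_epi)[:, None], np.asarray(grid.mono_combo)[None, :]
    )
    excess = np.clip(grid.observed, 0.0, 1.0) - expected
    return replace(
        grid,
        expected=expected,
        excess=excess,
        summary_score=float(100.0 * excess.mean()),
    )


@dataclass(frozen=True)
class SynergySummary:
    cell_line: str
    compound_id: str
    replicate_scores: tuple[float, ...]
    median_score: float | None
    classification: SynergyClass


def summarize_replicates(
    grids: Sequence[SynergyGrid],
    synergy_cutoff: float = 5.0,
    antagonism_cutoff: float = -5.0,
    model: Callable = bliss_expected,
) -> SynergySummary:
    """Median of per-replicate summary scores, classified against the cutoffs.

    All replicates must share dose lists. An even replicate count takes the
    mean of the two middle scores. Classification is strict: the median must
    exceed ``synergy_cutoff`` (fall below ``antagonism_cutoff``) to leave the
    additive band.
    """
    if not grids:
        raise ValidationError("need at least one replicate grid")
    first = grids[0]
    scores = []
    for g in grids:
        if g.epi_doses != first.epi_doses or g.combo_doses != first.combo_doses:
            raise ValidationError("replicate grids must share dose lists")
        if (g.cell_line, g.compound_id) != (first.cell_line, first.compound_id):
            raise ValidationError("replicate grids must describe the same experiment")
        if g.summary_score is None:
            g = excess_grid(g, model=model)
        scores.append(g.summary_score)
    med = statistics.median(scores)
    if med > synergy_cutoff:
        cls = SynergyClass.SYNERGY
    elif med < antagonism_cutoff:
        cls = SynergyClass.ANTAGONISM
    else:
        cls = SynergyClass.ADDITIVE
    return SynergySummary(
        cell_line=first.cell_line,
        compound_id=first.compound_id,
        replicate_scores=tuple(scores),
        median_score=med,
        classification=cls,
    )


GRID_COLUMNS = [
    "compound_id", "cell_line", "replicate",
    "epi_dose_nM", "combo_dose_level", "observed_inhibition",
]


def grids_from_table(table) -> dict[tuple[str, str], list[SynergyGrid]]:
    """Build replicate grids from the long-format CSV schema.

    Rows with ``combo_dose_level == 0`` supply the epi-only margin and rows
    with ``epi_dose_nM == 0`` the combo-only margin; the (0, 0) corner is the
    untreated anchor and is not part of the scored matrix.
    """
    df = pd.read_csv(table) if not isinstance(table, pd.DataFrame) else table
    missing = set(GRID_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"grid table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], list[SynergyGrid]] = {}
    for (cid, cl), sub in df.groupby(["compound_id", "cell_line"], sort=True):
        grids = []
        for _, rep in sub.groupby("replicate", sort=True):
            epi = sorted(set(rep["epi_dose_nM"]) - {0.0})
            combo = sorted(set(rep["combo_dose_level"]) - {0.0})
            lut = {
                (r.epi_dose_nM, r.combo_dose_level): r.observed_inhibition
                for r in rep.itertuples(index=False)
            }
            try:
                observed = np.array([[lut[(e, c)] for c in combo] for e in epi])
                mono_epi = np.array([lut[(e, 0.0)] for e in epi])
                mono_combo = np.array([lut[(0.0, c)] for c in combo])
            except KeyError as exc:
                raise ValidationError(
                    f"{cid}/{cl}: incomplete dose matrix, missing {exc.args[0]}"
                ) from exc
            grids.append(
                SynergyGrid(
                    cell_line=cl,
                    compound_id=cid,
                    epi_doses=tuple(epi),
                    combo_doses=tuple(combo),
                    observed=observed,
                    mono_epi=mono_epi,
                    mono_combo=mono_combo,
                )
            )
        out[(cid, cl)] = grids
    return out


def summaries_to_frame(summaries: Iterable[SynergySummary]) -> pd.DataFrame:
    rows = [
        {
            "compound_id": s.compound_id,
            "cell_line": s.cell_line,
            "median_score": s.median_score,
            "classification": s.classification.value,
            "n_replicates": len(s.replicate_scores),
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows, columns=["compound_id", "cell_line", "median_score", "classification", "n_replicates"]
    )
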