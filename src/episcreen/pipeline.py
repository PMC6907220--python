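"""End-to-end convenience: raw plates -> normalized plates -> profiles -> hit matrix."""

from __future__ import annotations

from typing import Sequence

from .dose_response import aggregate_all_profiles
from .normalize_qc import NormalizedPlate, QCThresholds, normalize_plate
from .reprogramming import (
    DEFAULT_HIT_THRESHOLD,
    HitMatrix,
    ReprogrammingResult,
    call_hits,
    reprogramming_score,
)
from .screen_model import Arm, CompoundRecord, PlateLayout, RawPlate


def normalize_screen(
    raw_plates: Sequence[RawPlate],
    layouts: Sequence[PlateLayout],
    thresholds: QCThresholds = QCThresholds(),
) -> list[NormalizedPlate]:
    by_id = {l.plate_id: l for l in layouts}
    return [normalize_plate(raw, by_id[raw.plate_id], thresholds) for raw in raw_plates]


def analyze_screen(
    raw_plates: Sequence[RawPlate],
    layouts: Sequence[PlateLayout],
    threshold: float = DEFAULT_HIT_THRESHOLD,
    thresholds: QCThresholds = QCThresholds(),
    library: Sequence[CompoundRecord] | None = None,
) -> tuple[list[ReprogrammingResult], HitMatrix]:
    """Run the full analysis and return per-pair scores plus the hit matrix.

    Pairs whose two arms are not both present are skipped (they show up as
    untested in the matrix).
    """
    norm = normalize_screen(raw_plates, layouts, thresholds)
    profiles = aggregate_all_profiles(norm, layouts)
    results: list[ReprogrammingResult] = []
    pairs = sorted(
        {(cl, c) for (cl, c, arm) in profiles if arm is Arm.PRETREAT_ONLY}
    )
    for cell_line, compound_id in pairs:
        combo = profiles.get((cell_line, compound_id, Arm.PRETREAT_PLUS_COMBO))
        if combo is None:
            continue
        mono = profiles[(cell_line, compound_id, Arm.PRETREAT_ONLY)]
        results.append(reprogramming_score(mono, combo, threshold))
    return results, call_hits(results, threshold, library=library)
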