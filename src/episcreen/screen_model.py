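"""Domain model for the pretreatment screen: compounds, dose ladders, plates, and their CSV I/O.

The screen tests a library of epigenetic-enzyme inhibitors as 9-day
pretreatments on 384-well plates. Each compound occupies a serial-dilution
ladder (top dose followed by tenfold dilutions); every plate carries
randomized DMSO (negative, 100 % viability anchor) and benzethonium-chloride
(positive, 0 % anchor) control wells. Plates come in paired arms: pretreatment
followed by vehicle vs. pretreatment followed by doxorubicin + rituximab.

All file formats are plain delimited text with canonical column order and
sorted wells, so writes are byte-stable and round-trip with the loaders.
"""

from __future__ import annotations

import enum
import io
import logging
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import pandas as pd

from .errors import OrphanWellError, PlateFormatError, ValidationError

logger = logging.getLogger(__name__)

TARGET_CLASSES = ("DNMT", "HDAC", "HAT", "HMT", "HDM", "BRD", "OTHER")

#: rows x columns per supported plate format
PLATE_FORMATS: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24)}

_WELL_RE = re.compile(r"^([A-Za-z])0*([1-9]\d*)$")


class WellKind(str, enum.Enum):
    COMPOUND = "COMPOUND"
    NEG_CONTROL = "NEG_CONTROL"
    POS_CONTROL = "POS_CONTROL"
    EMPTY = "EMPTY"


class Arm(str, enum.Enum):
    """The two paired plate sets of the non-simultaneous combination design."""

    PRETREAT_ONLY = "PRETREAT_ONLY"
    PRETREAT_PLUS_COMBO = "PRETREAT_PLUS_COMBO"


def parse_well(well: str, plate_format: int = 384) -> tuple[int, int]:
    """Parse a letter+number well address into 0-based (row, column).

    Accepts lowercase letters and zero-padded columns ("a01" == "A1");
    rejects addresses outside the plate format.
    """
    m = _WELL_RE.match(well.strip())
    if m is None:
        raise PlateFormatError(f"malformed well address {well!r}")
    nrow, ncol = PLATE_FORMATS[plate_format]
    row = ord(m.group(1).upper()) - ord("A")
    col = int(m.group(2)) - 1
    if row >= nrow or col >= ncol:
        raise PlateFormatError(
            f"well {well!r} outside {plate_format}-well format "
            f"({chr(ord('A') + nrow - 1)}{ncol} max)"
        )
    return row, col


def format_well(row: int, col: int) -> str:
    """Inverse of :func:`parse_well`: 0-based (row, col) -> canonical address like 'B7'."""
    return f"{chr(ord('A') + row)}{col + 1}"


def canonical_well(well: str, plate_format: int = 384) -> str:
    return format_well(*parse_well(well, plate_format))


def well_sort_key(well: str) -> tuple[int, int]:
    return parse_well(well)


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry: identity, target class, and its dilution-ladder geometry."""

    compound_id: str
    name: str
    target_class: str
    top_dose: float  # nM
    n_doses: int = 5
    dilution_factor: float = 10.0

    def __post_init__(self):
        if not self.compound_id:
            raise ValidationError("compound_id must be a non-empty token")
        if self.target_class not in TARGET_CLASSES:
            raise ValidationError(
                f"target_class {self.target_class!r} not in {TARGET_CLASSES}"
            )
        if not (math.isfinite(self.top_dose) and self.top_dose > 0):
            raise ValidationError(f"top_dose must be finite and > 0, got {self.top_dose}")
        if self.n_doses < 1:
            raise ValidationError(f"n_doses must be >= 1, got {self.n_doses}")
        if not self.dilution_factor > 1:
            raise ValidationError(
                f"dilution_factor must be > 1, got {self.dilution_factor}"
            )

    @property
    def dose_series(self) -> "DoseSeries":
        return build_dose_series(self.top_dose, self.n_doses, self.dilution_factor)


@dataclass(frozen=True)
class DoseSeries:
    """A strictly decreasing geometric concentration ladder, in nM."""

    concentrations: tuple[float, ...]

    def __post_init__(self):
        c = self.concentrations
        if len(c) == 0:
            raise ValidationError("dose series must contain at least one concentration")
        if any(not (math.isfinite(x) and x > 0) for x in c):
            raise ValidationError("all concentrations must be finite and positive")
        if any(a <= b for a, b in zip(c, c[1:])):
            raise ValidationError("concentrations must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.concentrations)

    def __iter__(self):
        return iter(self.concentrations)

    @property
    def fold_range(self) -> float:
        """Ratio of top to bottom dose (e.g. 10,000 for a 5-point tenfold ladder)."""
        return self.concentrations[0] / self.concentrations[-1]


def build_dose_series(
    top_dose: float, n_doses: int = 5, dilution_factor: float = 10.0
) -> DoseSeries:
    """Build the serial-dilution ladder: top dose followed by ``n_doses - 1`` dilutions.

    The default (5 points, tenfold steps) spans a 10,000-fold concentration range.
    """
    if not (math.isfinite(top_dose) and top_dose > 0):
        raise ValidationError(f"top_dose must be finite and > 0, got {top_dose}")
    if n_doses < 1:
        raise ValidationError(f"n_doses must be >= 1, got {n_doses}")
    if not dilution_factor > 1:
        raise ValidationError(f"dilution_factor must be > 1, got {dilution_factor}")
    return DoseSeries(
        tuple(top_dose / dilution_factor**i for i in range(n_doses))
    )


@dataclass(frozen=True)
class WellAssignment:
    """What a single well holds: a compound at a dose, a control, or nothing."""

    kind: WellKind
    compound_id: str | None = None
    dose: float | None = None  # nM

    def __post_init__(self):
        if self.kind is WellKind.COMPOUND:
            if self.compound_id is None or self.dose is None:
                raise ValidationError("COMPOUND wells require compound_id and dose")
            if not (math.isfinite(self.dose) and self.dose > 0):
                raise ValidationError(f"dose must be finite and > 0, got {self.dose}")
        else:
            if self.compound_id is not None or self.dose is not None:
                raise ValidationError(
                    f"{self.kind.value} wells must not carry compound_id or dose"
                )


@dataclass
class PlateLayout:
    """Well-level assay design for one plate: what sits where, for which arm."""

    plate_id: str
    cell_line: str
    arm: Arm
    assignments: dict[str, WellAssignment]
    plate_format: int = 384
    min_controls: int = 8

    def __post_init__(self):
        if self.plate_format not in PLATE_FORMATS:
            raise ValidationError(f"unsupported plate format {self.plate_format}")
        self.arm = Arm(self.arm)
        canon: dict[str, WellAssignment] = {}
        for well, a in self.assignments.items():
            cw = canonical_well(well, self.plate_format)
            if cw in canon:
                raise ValidationError(f"duplicate assignment for well {cw}")
            canon[cw] = a
        self.assignments = canon
        n_neg = sum(1 for a in canon.values() if a.kind is WellKind.NEG_CONTROL)
        n_pos = sum(1 for a in canon.values() if a.kind is WellKind.POS_CONTROL)
        if n_neg < self.min_controls or n_pos < self.min_controls:
            raise ValidationError(
                f"plate {self.plate_id}: needs >= {self.min_controls} wells of each "
                f"control type, found {n_neg} negative / {n_pos} positive"
            )

    def wells_of_kind(self, kind: WellKind) -> list[str]:
        return sorted(
            (w for w, a in self.assignments.items() if a.kind is kind),
            key=well_sort_key,
        )

    def compound_wells(
        self, compound_id: str | None = None, dose: float | None = None
    ) -> list[str]:
        out = []
        for w, a in self.assignments.items():
            if a.kind is not WellKind.COMPOUND:
                continue
            if compound_id is not None and a.compound_id != compound_id:
                continue
            if dose is not None and a.dose != dose:
                continue
            out.append(w)
        return sorted(out, key=well_sort_key)


@dataclass
class RawPlate:
    """Raw plate-reader export: luminescence counts per well (CellTiter-Glo style)."""

    plate_id: str
    readings: dict[str, float]
    meta: str = ""

    def __post_init__(self):
        canon: dict[str, float] = {}
        for well, v in self.readings.items():
            cw = canonical_well(well)
            v = float(v)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(
                    f"plate {self.plate_id} well {cw}: counts must be finite "
                    f"and non-negative, got {v}"
                )
            canon[cw] = v
        self.readings = canon


def validate_plate_pair(layout: PlateLayout, raw: RawPlate) -> None:
    """Check that every reading addresses a well declared in the layout."""
    orphans = set(raw.readings) - set(layout.assignments)
    if orphans:
        raise OrphanWellError(orphans)


# ---------------------------------------------------------------------------
# CSV I/O. Canonical dialect: comma-separated, UTF-8, '.' decimal; a `sep`
# argument admits tab/semicolon variants. Floats are written with %.10g so
# repeated write/load cycles are byte-stable.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"

LIBRARY_COLUMNS = ["compound_id", "name", "target_class", "top_dose_nM", "n_doses", "dilution_factor"]
LAYOUT_COLUMNS = ["plate_id", "cell_line", "arm", "well", "kind", "compound_id", "dose_nM"]
READER_COLUMNS = ["plate_id", "well", "counts"]


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def load_compound_library(source, sep: str = ",") -> list[CompoundRecord]:
    """Read a compound-library table into validated records.

    Unknown target classes are coerced to OTHER with a warning; duplicate
    compound ids and unparseable doses are hard errors.
    """
    df = pd.read_csv(source, sep=sep, dtype=str).fillna("")
    required = {"compound_id", "name", "target_class", "top_dose_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"library table missing columns: {sorted(missing)}")
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        cid = str(row.compound_id).strip()
        if cid in seen:
            raise ValidationError(f"duplicate compound_id {cid!r} (row {i})")
        seen.add(cid)
        cls = str(row.target_class).strip().upper()
        if cls not in TARGET_CLASSES:
            logger.warning("row %d: unknown target class %r mapped to OTHER", i, cls)
            cls = "OTHER"
        try:
            top = float(row.top_dose_nM)
        except ValueError as exc:
            raise ValidationError(f"row {i}: unparseable top_dose_nM {row.top_dose_nM!r}") from exc
        n_doses = int(row.n_doses) if getattr(row, "n_doses", "") else 5
        factor = float(row.dilution_factor) if getattr(row, "dilution_factor", "") else 10.0
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=str(row.name).strip(),
                target_class=cls,
                top_dose=top,
                n_doses=n_doses,
                dilution_factor=factor,
            )
        )
    return records


def write_compound_library(records: Iterable[CompoundRecord], dest, sep: str = ",") -> None:
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "target_class": r.target_class,
                "top_dose_nM": _fmt(r.top_dose),
                "n_doses": r.n_doses,
                "dilution_factor": _fmt(r.dilution_factor),
            }
            for r in records
        ],
        columns=LIBRARY_COLUMNS,
    )
    df.to_csv(dest, sep=sep, index=False)


def default_library() -> list[CompoundRecord]:
    """The packaged 60-inhibitor library (7 DNMT / 21 HDAC / 1 HAT / 15 HMT / 3 HDM / 13 BRD).

    Per-compound supplier-advised top doses are not public; the fixture uses a
    uniform 10,000 nM top dose, preserving the 10,000-fold range of the ladder.
    """
    ref = resources.files("episcreen.data") / "library.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return load_compound_library(fh)


def library_summary(records: Iterable[CompoundRecord]) -> dict[str, int]:
    """Count compounds per target class over the closed class set (zeros included)."""
    counts = {cls: 0 for cls in TARGET_CLASSES}
    for r in records:
        counts[r.target_class] += 1
    return counts


def load_plate_layout(source, sep: str = ",", min_controls: int = 8) -> PlateLayout:
    df = pd.read_csv(source, sep=sep, dtype=str).fillna("")
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"layout table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValidationError("layout table has no wells")
    plate_ids = df["plate_id"].unique()
    if len(plate_ids) != 1:
        raise ValidationError(f"layout file must describe one plate, found {list(plate_ids)}")
    cell_lines = df["cell_line"].unique()
    arms = df["arm"].unique()
    if len(cell_lines) != 1 or len(arms) != 1:
        raise ValidationError("cell_line and arm must be constant within a plate")
    assignments: dict[str, WellAssignment] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        kind = WellKind(str(row.kind).strip())
        cid = str(row.compound_id).strip() or None
        dose = str(row.dose_nM).strip()
        try:
            dose_val = float(dose) if dose else None
        except ValueError as exc:
            raise ValidationError(f"row {i}: unparseable dose_nM {dose!r}") from exc
        assignments[str(row.well)] = WellAssignment(kind=kind, compound_id=cid, dose=dose_val)
    return PlateLayout(
        plate_id=str(plate_ids[0]),
        cell_line=str(cell_lines[0]),
        arm=Arm(str(arms[0])),
        assignments=assignments,
        min_controls=min_controls,
    )


def write_plate_layout(layout: PlateLayout, dest, sep: str = ",") -> None:
    rows = []
    for well in sorted(layout.assignments, key=well_sort_key):
        a = layout.assignments[well]
        rows.append(
            {
                "plate_id": layout.plate_id,
                "cell_line": layout.cell_line,
                "arm": layout.arm.value,
                "well": well,
                "kind": a.kind.value,
                "compound_id": a.compound_id or "",
                "dose_nM": _fmt(a.dose) if a.dose is not None else "",
            }
        )
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(dest, sep=sep, index=False)


def load_raw_plate(source, sep: str = ",") -> RawPlate:
    df = pd.read_csv(source, sep=sep, dtype=str).fillna("")
    missing = set(READER_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"reader table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValidationError("reader table has no wells")
    plate_ids = df["plate_id"].unique()
    if len(plate_ids) != 1:
        raise ValidationError(f"reader file must describe one plate, found {list(plate_ids)}")
    readings: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            readings[str(row.well)] = float(row.counts)
        except ValueError as exc:
            raise ValidationError(f"row {i}: unparseable counts {row.counts!r}") from exc
    return RawPlate(plate_id=str(plate_ids[0]), readings=readings)


def write_raw_plate(raw: RawPlate, dest, sep: str = ",") -> None:
    rows = [
        {"plate_id": raw.plate_id, "well": well, "counts": _fmt(raw.readings[well])}
        for well in sorted(raw.readings, key=well_sort_key)
    ]
    pd.DataFrame(rows, columns=READER_COLUMNS).to_csv(dest, sep=sep, index=False)


def layout_to_csv(layout: PlateLayout, sep: str = ",") -> str:
    buf = io.StringIO()
    write_plate_layout(layout, buf, sep=sep)
    return buf.getvalue()


def raw_to_csv(raw: RawPlate, sep: str = ",") -> str:
    buf = io.StringIO()
    write_raw_plate(raw, buf, sep=sep)
    return buf.getvalue()
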