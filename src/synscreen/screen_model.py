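"""Data model and I/O for the drug x shRNA viability screen.

A screen is a factorial design: a compound library (80 targeted agents in
the full-scale screen) crossed with a panel of engineered shRNA knockdown
cell lines (36 targeted lines plus one control-shRNA line), dosed at a
small set of concentrations (1, 5, 20 uM) and read out with two viability
dyes (vital Hoechst and PrestoBlue). Each 96-well plate carries one cell
line, eight DMSO negative-control wells and eight positive-control wells
(CX-4945 at 20 uM), with compounds in the remaining wells.

On-disk formats are plain TSV (compounds, lines, layouts, measurements)
plus a small YAML design config; see the ``read_*``/``write_*`` functions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .wells import canonical_well

CONTROL_GENE_SYMBOL = "CTL"

WELL_KINDS = ("compound", "neg_control", "pos_control", "empty")


class ScreenValidationError(ValueError):
    """A screen file or record violates the design contract."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """One library member: a targeted agent, possibly FDA-approved."""

    compound_id: str
    name: str
    target_annotation: str = ""
    fda_approved: bool = False

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ScreenValidationError("compound_id must be non-empty")


@dataclass(frozen=True)
class CellLineRecord:
    """One engineered shRNA cell line: a gene knockdown or the control."""

    line_id: str
    gene_symbol: str
    role: str  # "targeted" | "control"

    def __post_init__(self) -> None:
        if self.role not in ("targeted", "control"):
            raise ScreenValidationError(
                f"line {self.line_id!r}: role must be 'targeted' or 'control', got {self.role!r}"
            )
        if self.role == "targeted" and self.gene_symbol == CONTROL_GENE_SYMBOL:
            raise ScreenValidationError(
                f"targeted line {self.line_id!r} may not use the control gene symbol "
                f"{CONTROL_GENE_SYMBOL!r}"
            )


@dataclass
class ScreenDesign:
    """The compound x shRNA-line x concentration factorial plus control rules."""

    compounds: list[CompoundRecord]
    lines: list[CellLineRecord]
    concentrations: tuple[float, ...] = (1.0, 5.0, 20.0)
    readouts: tuple[str, ...] = ("hoechst", "prestoblue")
    n_neg_controls_per_plate: int = 8
    n_pos_controls_per_plate: int = 8
    pos_control_label: str = "CX-4945 20 uM"

    def __post_init__(self) -> None:
        self.concentrations = tuple(float(c) for c in self.concentrations)
        self.readouts = tuple(self.readouts)
        if not self.compounds:
            raise ScreenValidationError("compound manifest is empty")
        ids = [c.compound_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ScreenValidationError(f"duplicate compound_id(s): {dupes}")
        line_ids = [ln.line_id for ln in self.lines]
        if len(set(line_ids)) != len(line_ids):
            dupes = sorted({i for i in line_ids if line_ids.count(i) > 1})
            raise ScreenValidationError(f"duplicate line_id(s): {dupes}")
        n_control = sum(ln.role == "control" for ln in self.lines)
        if n_control != 1:
            raise ScreenValidationError(
                f"a screen needs exactly one control line, found {n_control}"
            )
        if not self.concentrations:
            raise ScreenValidationError("at least one concentration is required")
        if any(c <= 0 for c in self.concentrations):
            raise ScreenValidationError("concentrations must be strictly positive")
        if list(self.concentrations) != sorted(set(self.concentrations)):
            raise ScreenValidationError("concentrations must be strictly increasing")
        if not self.readouts:
            raise ScreenValidationError("at least one readout is required")
        if self.n_neg_controls_per_plate < 2 or self.n_pos_controls_per_plate < 2:
            raise ScreenValidationError(
                "control counts must be >= 2 (the Z'-factor needs a dispersion estimate)"
            )

    # -- convenience views ---------------------------------------------------

    @property
    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    @property
    def control_line(self) -> CellLineRecord:
        return next(ln for ln in self.lines if ln.role == "control")

    @property
    def targeted_lines(self) -> list[CellLineRecord]:
        return [ln for ln in self.lines if ln.role == "targeted"]

    def compound(self, compound_id: str) -> CompoundRecord:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)

    def line(self, line_id: str) -> CellLineRecord:
        for ln in self.lines:
            if ln.line_id == line_id:
                return ln
        raise KeyError(line_id)


@dataclass(frozen=True)
class WellContent:
    """What was dispensed into one well."""

    kind: str  # compound | neg_control | pos_control | empty
    compound_id: str | None = None
    concentration_uM: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in WELL_KINDS:
            raise ScreenValidationError(f"unknown well kind {self.kind!r}")
        if self.kind == "compound":
            if not self.compound_id or self.concentration_uM is None:
                raise ScreenValidationError(
                    "compound wells need both compound_id and concentration_uM"
                )
        else:
            if self.compound_id is not None or self.concentration_uM is not None:
                raise ScreenValidationError(
                    f"{self.kind} wells must not carry compound_id/concentration_uM"
                )


@dataclass
class PlateLayout:
    """Geometry of one 96-well plate carrying a single cell line."""

    plate_id: str
    line_id: str
    wells: dict[str, WellContent] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[str, WellContent] = {}
        for addr, content in self.wells.items():
            c = canonical_well(addr)
            if c in canon:
                raise ScreenValidationError(
                    f"plate {self.plate_id!r}: well {c} addressed twice"
                )
            canon[c] = content
        self.wells = dict(sorted(canon.items()))
        if len(self.wells) > 96:
            raise ScreenValidationError(
                f"plate {self.plate_id!r}: {len(self.wells)} wells addressed (max 96)"
            )

    def count_kind(self, kind: str) -> int:
        return sum(w.kind == kind for w in self.wells.values())

    def validate_against(self, design: ScreenDesign) -> None:
        """Check control counts and cross-references against the design."""
        if self.line_id not in {ln.line_id for ln in design.lines}:
            raise ScreenValidationError(
                f"plate {self.plate_id!r}: unknown line_id {self.line_id!r}"
            )
        n_neg = self.count_kind("neg_control")
        if n_neg != design.n_neg_controls_per_plate:
            raise ScreenValidationError(
                f"plate {self.plate_id!r}: {n_neg} negative-control wells, "
                f"design requires {design.n_neg_controls_per_plate}"
            )
        n_pos = self.count_kind("pos_control")
        if n_pos != design.n_pos_controls_per_plate:
            raise ScreenValidationError(
                f"plate {self.plate_id!r}: {n_pos} positive-control wells, "
                f"design requires {design.n_pos_controls_per_plate}"
            )
        known = set(design.compound_ids)
        known_conc = set(design.concentrations)
        for addr, w in self.wells.items():
            if w.kind != "compound":
                continue
            if w.compound_id not in known:
                raise ScreenValidationError(
                    f"plate {self.plate_id!r} well {addr}: compound "
                    f"{w.compound_id!r} not in the manifest"
                )
            if w.concentration_uM not in known_conc:
                raise ScreenValidationError(
                    f"plate {self.plate_id!r} well {addr}: concentration "
                    f"{w.concentration_uM} uM not in the design"
                )


@dataclass(frozen=True)
class WellMeasurement:
    """One raw fluorescence reading (arbitrary units) for one well and readout."""

    plate_id: str
    well: str
    readout: str
    raw_value: float


@dataclass
class Screen:
    """A fully cross-referenced screen: design + layouts + measurements."""

    design: ScreenDesign
    layouts: list[PlateLayout]
    measurements: pd.DataFrame  # columns: plate_id, well, readout, raw_value


# ---------------------------------------------------------------------------
# Factorial enumeration
# ---------------------------------------------------------------------------


def enumerate_pairs(design: ScreenDesign) -> list[tuple[str, str]]:
    """All (compound_id, gene_symbol) drug-gene pairs, in manifest order.

    The full-scale screen (80 compounds x 36 targeted knockdowns) yields
    2880 pairs.
    """
    return [
        (c.compound_id, ln.gene_symbol)
        for c in design.compounds
        for ln in design.targeted_lines
    ]


def enumerate_datapoints(design: ScreenDesign) -> int:
    """Number of (pair x concentration) data points; 8640 at full scale."""
    return len(enumerate_pairs(design)) * len(design.concentrations)


# ---------------------------------------------------------------------------
# TSV / YAML I/O
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ["plate_id", "well", "readout", "raw_value"]
LAYOUT_COLUMNS = ["plate_id", "well", "kind", "compound_id", "concentration_uM"]


def read_compounds(path: str | Path) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "name": str})
    _require_columns(df, ["compound_id", "name", "target_annotation", "fda_approved"], path)
    return [
        CompoundRecord(
            compound_id=r.compound_id,
            name=r.name,
            target_annotation="" if pd.isna(r.target_annotation) else str(r.target_annotation),
            fda_approved=bool(int(r.fda_approved)),
        )
        for r in df.itertuples()
    ]


def write_compounds(compounds: Sequence[CompoundRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (c.compound_id, c.name, c.target_annotation, int(c.fda_approved))
            for c in compounds
        ],
        columns=["compound_id", "name", "target_annotation", "fda_approved"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_lines(path: str | Path) -> list[CellLineRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["line_id", "gene_symbol", "role"], path)
    return [
        CellLineRecord(line_id=r.line_id, gene_symbol=r.gene_symbol, role=r.role)
        for r in df.itertuples()
    ]


def write_lines(lines: Sequence[CellLineRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(ln.line_id, ln.gene_symbol, ln.role) for ln in lines],
        columns=["line_id", "gene_symbol", "role"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_design(directory: str | Path) -> ScreenDesign:
    """Assemble a ScreenDesign from compounds.tsv, lines.tsv and design.yaml."""
    directory = Path(directory)
    compounds = read_compounds(directory / "compounds.tsv")
    lines = read_lines(directory / "lines.tsv")
    cfg_path = directory / "design.yaml"
    cfg = {}
    if cfg_path.exists():
        with open(cfg_path) as fh:
            cfg = yaml.safe_load(fh) or {}
    return ScreenDesign(
        compounds=compounds,
        lines=lines,
        concentrations=tuple(cfg.get("concentrations", (1.0, 5.0, 20.0))),
        readouts=tuple(cfg.get("readouts", ("hoechst", "prestoblue"))),
        n_neg_controls_per_plate=int(cfg.get("n_neg_controls_per_plate", 8)),
        n_pos_controls_per_plate=int(cfg.get("n_pos_controls_per_plate", 8)),
        pos_control_label=str(cfg.get("pos_control_label", "CX-4945 20 uM")),
    )


def write_design(design: ScreenDesign, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_compounds(design.compounds, directory / "compounds.tsv")
    write_lines(design.lines, directory / "lines.tsv")
    cfg = {
        "concentrations": [float(c) for c in design.concentrations],
        "readouts": list(design.readouts),
        "n_neg_controls_per_plate": design.n_neg_controls_per_plate,
        "n_pos_controls_per_plate": design.n_pos_controls_per_plate,
        "pos_control_label": design.pos_control_label,
    }
    with open(directory / "design.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_layouts(path: str | Path) -> list[PlateLayout]:
    """Read plate layouts from a TSV with one row per addressed well."""
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "well": str, "kind": str,
                                            "compound_id": str, "line_id": str})
    _require_columns(df, ["plate_id", "line_id"] + LAYOUT_COLUMNS[1:], path)
    layouts = []
    for (plate_id, line_id), grp in df.groupby(["plate_id", "line_id"], sort=True):
        wells: dict[str, WellContent] = {}
        for r in grp.itertuples():
            addr = canonical_well(r.well)
            if addr in wells:
                raise ScreenValidationError(
                    f"plate {plate_id!r}: well {addr} addressed twice in {path}"
                )
            if r.kind == "compound":
                content = WellContent("compound", r.compound_id, float(r.concentration_uM))
            else:
                content = WellContent(r.kind)
            wells[addr] = content
        layouts.append(PlateLayout(plate_id=plate_id, line_id=line_id, wells=wells))
    return layouts


def layouts_to_frame(layouts: Iterable[PlateLayout]) -> pd.DataFrame:
    """Flatten layouts to one row per addressed well (the TSV shape)."""
    rows = [
        (lay.plate_id, lay.line_id, addr, w.kind, w.compound_id, w.concentration_uM)
        for lay in layouts
        for addr, w in lay.wells.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["plate_id", "line_id", "well", "kind", "compound_id", "concentration_uM"],
    )


def write_layouts(layouts: Sequence[PlateLayout], path: str | Path) -> None:
    df = layouts_to_frame(layouts).sort_values(["plate_id", "well"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "well": str, "readout": str},
                     float_precision="round_trip")
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    df["well"] = [canonical_well(w) for w in df["well"]]
    if not pd.api.types.is_float_dtype(df["raw_value"]):
        df["raw_value"] = df["raw_value"].astype(float)
    if not df["raw_value"].map(lambda v: v == v and abs(v) != float("inf")).all():
        bad = df.loc[~df["raw_value"].map(lambda v: v == v and abs(v) != float("inf"))]
        raise ScreenValidationError(
            f"non-finite raw_value(s) in {path}: first offending row {bad.iloc[0].to_dict()}"
        )
    dup = df.duplicated(subset=["plate_id", "well", "readout"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ScreenValidationError(
            f"duplicate measurement for (plate {first.plate_id!r}, well {first.well}, "
            f"readout {first.readout!r}) in {path}"
        )
    return df[MEASUREMENT_COLUMNS].reset_index(drop=True)


def write_measurements(measurements: pd.DataFrame, path: str | Path) -> None:
    # str() float formatting is shortest-round-trip, so write -> read is exact
    df = measurements[MEASUREMENT_COLUMNS].sort_values(
        ["plate_id", "well", "readout"], kind="stable"
    )
    df.to_csv(path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ScreenValidationError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# Whole-screen loading with cross-reference validation
# ---------------------------------------------------------------------------


def validate_screen(design: ScreenDesign, layouts: Sequence[PlateLayout],
                    measurements: pd.DataFrame) -> None:
    """Full referential-integrity check across design, layouts, measurements.

    Every compound_id/line_id in a layout must exist in the design, every
    plate must carry the designed number of control wells, and every
    addressed non-empty well must have a measurement for every readout.
    """
    plate_ids = [lay.plate_id for lay in layouts]
    if len(set(plate_ids)) != len(plate_ids):
        dupes = sorted({p for p in plate_ids if plate_ids.count(p) > 1})
        raise ScreenValidationError(f"duplicate plate_id(s): {dupes}")
    for lay in layouts:
        lay.validate_against(design)

    have = {
        (r.plate_id, r.well, r.readout) for r in measurements.itertuples()
    }
    missing: list[tuple[str, str, str]] = []
    for lay in layouts:
        for addr, w in lay.wells.items():
            if w.kind == "empty":
                continue
            for readout in design.readouts:
                if (lay.plate_id, addr, readout) not in have:
                    missing.append((lay.plate_id, addr, readout))
    if missing:
        shown = ", ".join(f"(plate {p!r}, well {w}, readout {r!r})" for p, w, r in missing[:10])
        more = "" if len(missing) <= 10 else f" and {len(missing) - 10} more"
        raise ScreenValidationError(f"missing measurement(s): {shown}{more}")

    known_plates = set(plate_ids)
    stray = sorted(set(measurements["plate_id"]) - known_plates)
    if stray:
        raise ScreenValidationError(f"measurements reference unknown plate_id(s): {stray}")


def load_screen(directory: str | Path) -> Screen:
    """Load a screen directory (compounds/lines/design/layouts/measurements).

    Expected files: compounds.tsv, lines.tsv, design.yaml, layouts.tsv,
    measurements.tsv. Raises ScreenValidationError on any broken
    cross-reference, duplicate well, or missing measurement.
    """
    directory = Path(directory)
    design = read_design(directory)
    layouts = read_layouts(directory / "layouts.tsv")
    measurements = read_measurements(directory / "measurements.tsv")
    validate_screen(design, layouts, measurements)
    return Screen(design=design, layouts=layouts, measurements=measurements)


def write_screen(screen: Screen, directory: str | Path) -> None:
    """Write a screen to a directory in the package's TSV/YAML formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_design(screen.design, directory)
    write_layouts(screen.layouts, directory / "layouts.tsv")
    write_measurements(screen.measurements, directory / "measurements.tsv")
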