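"""Data model and CSV I/O for 384-well plate maps and Ct tables.

A screening plate is described by two files:

* a plate map (``well,kind,compound_id,concentration_uM``) assigning each
  well DMSO vehicle, a compound at a concentration, or nothing;
* a Ct table (``plate_id,well,gene,ct``) holding per-well, per-gene
  threshold-cycle measurements, where ``ct`` is numeric or the thermocycler
  token ``Undetermined``.

"Undetermined" reactions are censored at the cycle ceiling (55 by default)
rather than dropped, so a target transcript that never amplifies still
contributes a directional (very low expression) signal downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

ROW_LETTERS = "ABCDEFGHIJKLMNOP"
N_ROWS = 16
N_COLS = 24
WELLS_PER_PLATE = N_ROWS * N_COLS
DEFAULT_MAX_CYCLES = 55.0
UNDETERMINED = "Undetermined"

PLATE_MAP_COLUMNS = ("well", "kind", "compound_id", "concentration_uM")
CT_TABLE_COLUMNS = ("plate_id", "well", "gene", "ct")

KIND_DMSO = "dmso"
KIND_COMPOUND = "compound"
KIND_EMPTY = "empty"
WELL_KINDS = (KIND_DMSO, KIND_COMPOUND, KIND_EMPTY)


class PlateError(ValueError):
    """Malformed plate map / Ct table input or inconsistent plate data."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """A 384-well position: letter row A-P, 1-based column 1-24.

    The canonical string form is zero-padded (``A01`` .. ``P24``) and
    round-trips through :meth:`parse`.
    """

    row: str
    col: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise PlateError(f"well row {self.row!r} outside A-{ROW_LETTERS[-1]}")
        if not isinstance(self.col, int) or not 1 <= self.col <= N_COLS:
            raise PlateError(f"well column {self.col!r} outside 1-{N_COLS}")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        text = str(text).strip().upper()
        if len(text) < 2 or not text[1:].isdigit():
            raise PlateError(f"malformed well address {text!r}")
        return cls(text[0], int(text[1:]))

    def __str__(self) -> str:
        return f"{self.row}{self.col:02d}"


def all_wells() -> list[WellAddress]:
    """All 384 well addresses in row-major (A01..A24, B01..) order."""
    return [WellAddress(r, c) for r in ROW_LETTERS for c in range(1, N_COLS + 1)]


@dataclass(frozen=True)
class WellContent:
    """What a plate-map well holds: vehicle, a dosed compound, or nothing."""

    kind: str
    compound_id: str | None = None
    concentration_um: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in WELL_KINDS:
            raise PlateError(f"unknown well kind {self.kind!r}")
        if self.kind == KIND_COMPOUND:
            if not self.compound_id:
                raise PlateError("compound well missing compound_id")
            if self.concentration_um is None or not self.concentration_um > 0:
                raise PlateError(
                    f"compound well needs concentration > 0, got {self.concentration_um!r}"
                )
        else:
            if self.compound_id or self.concentration_um is not None:
                raise PlateError(f"{self.kind} well must not carry compound fields")


@dataclass
class PlateMap:
    """Assignment of every populated well on one plate."""

    plate_id: str
    wells: dict[WellAddress, WellContent] = field(default_factory=dict)

    def dmso_wells(self) -> list[WellAddress]:
        return sorted(w for w, c in self.wells.items() if c.kind == KIND_DMSO)

    def compound_wells(self) -> list[WellAddress]:
        return sorted(w for w, c in self.wells.items() if c.kind == KIND_COMPOUND)

    def populated_wells(self) -> list[WellAddress]:
        return sorted(w for w, c in self.wells.items() if c.kind != KIND_EMPTY)

    @property
    def n_dmso(self) -> int:
        return sum(1 for c in self.wells.values() if c.kind == KIND_DMSO)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "well": str(w),
                "kind": c.kind,
                "compound_id": c.compound_id or "",
                "concentration_uM": "" if c.concentration_um is None else format(c.concentration_um, ".10g"),
            }
            for w, c in sorted(self.wells.items())
        ]
        return pd.DataFrame(rows, columns=list(PLATE_MAP_COLUMNS))


def read_plate_map(path: str | Path, plate_id: str | None = None) -> PlateMap:
    """Parse a plate-map CSV.

    Raises :class:`PlateError` naming the offending row(s) for malformed
    well addresses, compound rows without a concentration, unknown kinds
    and duplicated wells.
    """
    path = Path(path)
    wells: dict[WellAddress, WellContent] = {}
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(PLATE_MAP_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise PlateError(f"{path.name}: missing plate map columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                well = WellAddress.parse(row["well"])
            except PlateError as exc:
                problems.append(f"row {lineno}: {exc}")
                continue
            if well in wells:
                problems.append(f"row {lineno}: duplicate well {well}")
                continue
            kind = (row["kind"] or "").strip().lower()
            cid = (row.get("compound_id") or "").strip() or None
            conc_raw = (row.get("concentration_uM") or "").strip()
            try:
                conc = float(conc_raw) if conc_raw else None
            except ValueError:
                problems.append(f"row {lineno}: bad concentration {conc_raw!r}")
                continue
            try:
                wells[well] = WellContent(kind, cid, conc)
            except PlateError as exc:
                problems.append(f"row {lineno}: {exc}")
    if problems:
        raise PlateError(f"{path.name}: " + "; ".join(problems))
    return PlateMap(plate_id or path.stem, wells)


def write_plate_map(plate_map: PlateMap, path: str | Path) -> None:
    plate_map.to_frame().to_csv(path, index=False)


@dataclass
class CtTable:
    """Per-well, per-gene threshold-cycle measurements for one plate.

    ``data`` columns: ``well`` (canonical string), ``gene``, ``ct`` (float
    cycles) and ``censored`` (True where the reaction never crossed
    threshold; such records carry ``ct == max_cycles``).
    """

    plate_id: str
    data: pd.DataFrame
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        d = self.data
        required = {"well", "gene", "ct", "censored"}
        if not required.issubset(d.columns):
            raise PlateError(f"Ct table missing columns {sorted(required - set(d.columns))}")
        if ((d["ct"] <= 0) | (d["ct"] > self.max_cycles)).any():
            raise PlateError(f"Ct values outside (0, {self.max_cycles}]")
        if (d.loc[d["censored"], "ct"] != self.max_cycles).any():
            raise PlateError("censored records must carry ct = max_cycles")
        if d.duplicated(["well", "gene"]).any():
            dups = d.loc[d.duplicated(["well", "gene"]), ["well", "gene"]]
            raise PlateError(f"duplicate (well, gene) records: {dups.values.tolist()}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def wells(self) -> list[str]:
        return sorted(self.data["well"].unique())

    def ct_pivot(self) -> pd.DataFrame:
        """wells x genes matrix of Ct values (NaN where unmeasured)."""
        return self.data.pivot(index="well", columns="gene", values="ct")

    def censored_pivot(self) -> pd.DataFrame:
        return self.data.pivot(index="well", columns="gene", values="censored")


def read_ct_table(path: str | Path, max_cycles: float = DEFAULT_MAX_CYCLES) -> CtTable:
    """Parse a Ct-table CSV; ``Undetermined`` becomes a censored record at
    ``max_cycles``.  A file must describe exactly one plate."""
    path = Path(path)
    records: list[dict] = []
    seen: set[tuple[str, str]] = set()
    plate_ids: set[str] = set()
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CT_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise PlateError(f"{path.name}: missing Ct table columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                well = str(WellAddress.parse(row["well"]))
            except PlateError as exc:
                problems.append(f"row {lineno}: {exc}")
                continue
            gene = (row["gene"] or "").strip()
            if not gene:
                problems.append(f"row {lineno}: empty gene")
                continue
            token = (row["ct"] or "").strip()
            if token == UNDETERMINED:
                ct, censored = float(max_cycles), True
            else:
                try:
                    ct = float(token)
                except ValueError:
                    problems.append(f"row {lineno}: unknown ct token {token!r}")
                    continue
                censored = False
                if not 0 < ct <= max_cycles:
                    problems.append(f"row {lineno}: ct {ct} outside (0, {max_cycles}]")
                    continue
            key = (well, gene)
            if key in seen:
                problems.append(f"row {lineno}: duplicate record for {well}/{gene}")
                continue
            seen.add(key)
            plate_ids.add((row["plate_id"] or "").strip())
            records.append({"well": well, "gene": gene, "ct": ct, "censored": censored})
    if problems:
        raise PlateError(f"{path.name}: " + "; ".join(problems))
    if len(plate_ids) != 1:
        raise PlateError(f"{path.name}: expected exactly one plate_id, found {sorted(plate_ids)}")
    data = pd.DataFrame(records, columns=["well", "gene", "ct", "censored"])
    return CtTable(plate_ids.pop(), data, max_cycles=float(max_cycles))


def write_ct_table(table: CtTable, path: str | Path) -> None:
    """Write the canonical CSV form (sorted by well then gene; censored
    records rendered as ``Undetermined``).  ``write(read(x))`` is a fixed
    point on canonical files."""
    d = table.data.sort_values(["well", "gene"], kind="stable")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CT_TABLE_COLUMNS)
        for rec in d.itertuples(index=False):
            token = UNDETERMINED if rec.censored else format(rec.ct, ".10g")
            writer.writerow([table.plate_id, rec.well, rec.gene, token])


@dataclass
class ValidationReport:
    """Outcome of pre-analysis plate validation.

    ``errors`` reject the whole plate; ``wells_excluded`` lists wells the
    downstream stages must skip, each with a reason.
    """

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    wells_excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def excluded_wells(self) -> frozenset[str]:
        return frozenset(w for w, _ in self.wells_excluded)

    def to_dict(self) -> dict:
        return {
            "errors": list(self.errors),
            "warnings": list(self.warnings),
            "wells_excluded": [{"well": w, "reason": r} for w, r in self.wells_excluded],
        }


def validate_plate(
    plate_map: PlateMap,
    ct_table: CtTable,
    required_genes: Iterable[str],
    min_dmso: int = 2,
    calibrator_gene: str | None = None,
) -> ValidationReport:
    """Check a plate before analysis.

    Errors: fewer DMSO wells than ``min_dmso``; a required gene absent from
    every well.  Exclusions (with warnings): a populated well missing a
    required gene; a well whose calibrator reaction is censored (the
    normalization denominator is then meaningless, while a censored target
    is retained as a strong low-expression signal).

    Raises :class:`PlateError` on mismatched plate ids.
    """
    if plate_map.plate_id != ct_table.plate_id:
        raise PlateError(
            f"plate id mismatch: map {plate_map.plate_id!r} vs Ct table {ct_table.plate_id!r}"
        )
    required = sorted(set(required_genes))
    report = ValidationReport()
    if plate_map.n_dmso < min_dmso:
        report.errors.append(
            f"insufficient vehicle wells: {plate_map.n_dmso} DMSO wells, need >= {min_dmso}"
        )
    present = set(ct_table.data["gene"].unique())
    for gene in required:
        if gene not in present:
            report.errors.append(f"required gene {gene!r} absent from every well")
    genes_by_well: dict[str, set[str]] = {}
    for rec in ct_table.data.itertuples(index=False):
        genes_by_well.setdefault(rec.well, set()).add(rec.gene)
    censored_cal: set[str] = set()
    if calibrator_gene is not None:
        mask = (ct_table.data["gene"] == calibrator_gene) & ct_table.data["censored"]
        censored_cal = set(ct_table.data.loc[mask, "well"])
    for well in plate_map.populated_wells():
        name = str(well)
        missing = [g for g in required if g not in genes_by_well.get(name, ())]
        if missing:
            reason = f"missing required gene(s): {', '.join(missing)}"
            report.wells_excluded.append((name, reason))
            report.warnings.append(f"well {name} excluded: {reason}")
        elif name in censored_cal:
            reason = f"censored calibrator ({calibrator_gene})"
            report.wells_excluded.append((name, reason))
            report.warnings.append(f"well {name} excluded: {reason}")
    return report
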