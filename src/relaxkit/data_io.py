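"""Tabular input/output and PDB B-factor annotation.

All tables share one dialect: tab-separated UTF-8 text, ``#`` comment lines,
missing values written as ``NA``, and a first column ``residue`` holding
labels such as ``G154`` (one-letter amino-acid code + construct sequence
number).  The dialect matches common peak-integration exports and diffs
cleanly.  Numeric values round-trip to at least six significant digits.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    DuplicateResidueError,
    PDBFormatError,
    TableFormatError,
)

AXIS_KINDS = ("delay_s", "cpmg_hz", "noe_pair", "temperature_K")
NUCLEI = ("H", "N", "C")

_ONE_LETTER = set("ACDEFGHIKLMNPQRSTVWYX")
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}

_FLOAT_FMT = "%.10g"  # > 6 significant digits, diff-friendly


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return _FLOAT_FMT % x


@dataclass(frozen=True, order=True)
class ResidueKey:
    """A residue identified by construct sequence number and amino-acid code.

    Numbering is treated as opaque user input (no remapping between
    construct and crystal numbering).  Ordering is by sequence number,
    ties broken by residue name.
    """

    sequence_number: int
    residue_name: str = "X"

    def __post_init__(self) -> None:
        if self.sequence_number < 1:
            raise ValueError(f"sequence_number must be >= 1, got {self.sequence_number}")
        name = self.residue_name.upper()
        if len(name) == 3:
            if name not in _THREE_TO_ONE:
                raise ValueError(f"unknown three-letter residue code {self.residue_name!r}")
            name = _THREE_TO_ONE[name]
        if name not in _ONE_LETTER:
            raise ValueError(f"unknown residue code {self.residue_name!r}")
        object.__setattr__(self, "residue_name", name)

    @classmethod
    def from_label(cls, label: str) -> "ResidueKey":
        m = re.fullmatch(r"([A-Za-z]{1,3})(\d+)", label.strip())
        if m is None:
            raise ValueError(f"cannot parse residue label {label!r}")
        return cls(int(m.group(2)), m.group(1))

    @property
    def label(self) -> str:
        return f"{self.residue_name}{self.sequence_number}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class IntensitySeries:
    """Per-residue peak intensities along one experimental axis.

    ``axis_kind`` is one of ``delay_s`` (relaxation delay), ``cpmg_hz``
    (CPMG refocusing frequency), ``noe_pair`` (saturated/reference flag
    encoded 0 = reference, 1 = saturated) or ``temperature_K``.
    ``noise_sigma`` is the spectral noise estimate on the same intensity
    scale.
    """

    residue: ResidueKey
    axis_kind: str
    axis_values: np.ndarray
    intensities: np.ndarray
    noise_sigma: float

    def __post_init__(self) -> None:
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"axis_kind must be one of {AXIS_KINDS}, got {self.axis_kind!r}")
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis_values.shape != self.intensities.shape:
            raise ValueError("axis_values and intensities must have equal length")
        if np.any(self.axis_values < 0):
            raise ValueError("axis values must be non-negative")
        if self.axis_kind != "noe_pair" and np.any(np.diff(self.axis_values) <= 0):
            raise ValueError(f"axis values must be strictly increasing for {self.axis_kind}")
        if not (self.noise_sigma > 0):
            raise ValueError("noise_sigma must be positive")

    def __len__(self) -> int:
        return len(self.axis_values)


@dataclass
class ShiftTable:
    """Chemical shifts (ppm) per residue for nuclei H, N and C' at one condition.

    ``shifts`` maps each residue to a ``{nucleus: ppm}`` dict; absent
    nuclei are simply missing from the inner dict.
    """

    condition_label: str
    shifts: dict[ResidueKey, dict[str, float]]
    temperature_K: float | None = None

    def __post_init__(self) -> None:
        for res, row in self.shifts.items():
            clean = {k: float(v) for k, v in row.items() if k in NUCLEI and np.isfinite(v)}
            if not clean:
                raise ValueError(f"residue {res} has no finite shift in any nucleus")
            self.shifts[res] = clean

    def residues(self) -> list[ResidueKey]:
        return sorted(self.shifts)

    def get(self, residue: ResidueKey) -> dict[str, float]:
        return self.shifts.get(residue, {})


class IntensityReadResult(NamedTuple):
    series: list[IntensitySeries]
    skipped: list[str]  # residue labels of rows dropped for non-numeric cells


def _read_table_lines(path: Path) -> tuple[list[str], list[list[str]]]:
    header: list[str] | None = None
    rows: list[list[str]] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
        else:
            rows.append(cells)
    if header is None:
        raise TableFormatError(f"{path}: empty table (no header)")
    return header, rows


def read_intensity_table(path: str | Path, axis_kind: str) -> IntensityReadResult:
    """Read one intensity table; header names the axis values.

    Expected columns: ``residue``, ``noise_sigma``, then one column per
    axis value.  Rows with any non-numeric intensity cell are reported in
    ``skipped`` and dropped rather than aborting the read.
    """
    path = Path(path)
    header, rows = _read_table_lines(path)
    if len(header) < 3 or header[0] != "residue" or header[1] != "noise_sigma":
        raise TableFormatError(
            f"{path}: header must be 'residue<TAB>noise_sigma<TAB><axis values...>', got {header[:3]}"
        )
    try:
        axis = np.array([float(h) for h in header[2:]])
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric axis value in header") from exc

    series: list[IntensitySeries] = []
    skipped: list[str] = []
    seen: set[ResidueKey] = set()
    for cells in rows:
        if len(cells) != len(header):
            raise TableFormatError(f"{path}: row with {len(cells)} cells, expected {len(header)}")
        res = ResidueKey.from_label(cells[0])
        if res in seen:
            raise DuplicateResidueError(f"{path}: duplicate residue {res.label}")
        seen.add(res)
        try:
            sigma = float(cells[1])
            values = np.array([float(c) for c in cells[2:]])
        except ValueError:
            skipped.append(res.label)
            continue
        if not np.all(np.isfinite(values)):
            skipped.append(res.label)
            continue
        series.append(IntensitySeries(res, axis_kind, axis, values, sigma))
    series.sort(key=lambda s: s.residue)
    return IntensityReadResult(series, skipped)


def write_intensity_table(series: Sequence[IntensitySeries], path: str | Path,
                          comments: Sequence[str] = ()) -> None:
    series = sorted(series, key=lambda s: s.residue)
    if series:
        axis = series[0].axis_values
        kind = series[0].axis_kind
        for s in series:
            if s.axis_kind != kind or not np.array_equal(s.axis_values, axis):
                raise ConsistencyError("all series in one table must share axis kind and values")
    else:
        axis, kind = np.array([]), "delay_s"
    lines = [f"# {c}" for c in comments]
    lines.append(f"# axis_kind: {kind}")
    lines.append("\t".join(["residue", "noise_sigma"] + [_fmt(v) for v in axis]))
    for s in series:
        lines.append("\t".join([s.residue.label, _fmt(s.noise_sigma)]
                               + [_fmt(v) for v in s.intensities]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_RATE_COLUMNS = ["residue", "value", "error", "field_MHz", "temperature_K", "flags"]


def write_rate_table(records: Sequence, path: str | Path,
                     comments: Sequence[str] = ()) -> None:
    """Write RateRecord-like objects (attributes residue, observable, value,
    error, field_MHz, temperature_K, flags) as one table.

    All records must share one observable kind; it is stamped in a comment
    so the table is self-describing.
    """
    records = sorted(records, key=lambda r: r.residue)
    kinds = {r.observable for r in records}
    if len(kinds) > 1:
        raise ConsistencyError(f"mixed observable kinds in one table: {sorted(kinds)}")
    observable = kinds.pop() if kinds else "NA"
    lines = [f"# {c}" for c in comments]
    lines.append(f"# observable: {observable}")
    lines.append("\t".join(_RATE_COLUMNS))
    for r in records:
        flags = ",".join(r.flags) if r.flags else "-"
        lines.append("\t".join([
            r.residue.label, _fmt(r.value), _fmt(r.error),
            _fmt(r.field_MHz), _fmt(r.temperature_K), flags,
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rate_table(path: str | Path) -> list:
    """Read a rate table written by :func:`write_rate_table`."""
    from .rate_fitting import RateRecord  # local import to avoid a cycle

    path = Path(path)
    observable = None
    for raw in path.read_text(encoding="utf-8").splitlines():
        m = re.fullmatch(r"#\s*observable:\s*(\S+)", raw.strip())
        if m:
            observable = m.group(1)
    header, rows = _read_table_lines(path)
    if header != _RATE_COLUMNS:
        raise TableFormatError(f"{path}: unexpected rate-table header {header}")
    if observable is None:
        raise TableFormatError(f"{path}: missing '# observable:' stamp")
    out = []
    for cells in rows:
        flags = () if cells[5] in ("-", "") else tuple(cells[5].split(","))
        out.append(RateRecord(
            residue=ResidueKey.from_label(cells[0]), observable=observable,
            value=float(cells[1]), error=float(cells[2]),
            field_MHz=float(cells[3]), temperature_K=float(cells[4]), flags=flags,
        ))
    return out


def write_shift_table(table: ShiftTable, path: str | Path,
                      comments: Sequence[str] = ()) -> None:
    lines = [f"# {c}" for c in comments]
    lines.append(f"# condition: {table.condition_label}")
    if table.temperature_K is not None:
        lines.append(f"# temperature_K: {_fmt(table.temperature_K)}")
    lines.append("\t".join(["residue", "H_ppm", "N_ppm", "C_ppm"]))
    for res in table.residues():
        row = table.shifts[res]
        lines.append("\t".join([res.label] + [_fmt(row.get(nuc, float("nan"))) for nuc in NUCLEI]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_shift_table(path: str | Path) -> ShiftTable:
    path = Path(path)
    condition, temperature = path.stem, None
    for raw in path.read_text(encoding="utf-8").splitlines():
        m = re.fullmatch(r"#\s*condition:\s*(.+)", raw.strip())
        if m:
            condition = m.group(1).strip()
        m = re.fullmatch(r"#\s*temperature_K:\s*(\S+)", raw.strip())
        if m:
            temperature = float(m.group(1))
    header, rows = _read_table_lines(path)
    if header != ["residue", "H_ppm", "N_ppm", "C_ppm"]:
        raise TableFormatError(f"{path}: unexpected shift-table header {header}")
    shifts: dict[ResidueKey, dict[str, float]] = {}
    for cells in rows:
        res = ResidueKey.from_label(cells[0])
        if res in shifts:
            raise DuplicateResidueError(f"{path}: duplicate residue {res.label}")
        row = {nuc: float(c) for nuc, c in zip(NUCLEI, cells[1:4]) if c != "NA"}
        if row:
            shifts[res] = row
    return ShiftTable(condition, shifts, temperature_K=temperature)


def write_population_table(table, path: str | Path, comments: Sequence[str] = ()) -> None:
    """Write a StatePopulationTable as TSV (n_closed, weight, fraction)."""
    lines = [f"# {c}" for c in comments]
    lines.append(f"# n_subunits: {table.n_subunits}")
    lines.append("\t".join(["n_closed", "weight", "fraction"]))
    for k, (w, f) in enumerate(zip(table.group_weights, table.fractions)):
        lines.append("\t".join([str(k), _fmt(float(w)), _fmt(f)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# PDB B-factor heatmap writer
# ---------------------------------------------------------------------------

def write_pdb_bfactor(pdb_in: str | Path, per_residue_values: Mapping[ResidueKey, float],
                      pdb_out: str | Path, missing_fill: float = 0.0) -> None:
    """Replace the B-factor column (61-66) with per-residue values.

    Everything outside the B-factor column is copied byte-for-byte, so
    coordinates are guaranteed unchanged.  Only the first MODEL is
    annotated; insertion codes are unsupported.  Residues are matched by
    sequence number alone (the heatmap is cosmetic; chain sets share
    numbering).  Map keys absent from the PDB produce a warning.
    """
    values_by_seq = {k.sequence_number: float(v) for k, v in per_residue_values.items()}
    for v in values_by_seq.values():
        if not np.isfinite(v):
            raise ValueError("per-residue values must be finite")
    seen: set[int] = set()
    out_lines: list[str] = []
    in_first_model = True
    for line in Path(pdb_in).read_text(encoding="utf-8").splitlines(keepends=True):
        rec = line[:6]
        if rec.strip() == "ENDMDL":
            in_first_model = False
        if in_first_model and rec in ("ATOM  ", "HETATM"):
            if len(line.rstrip("\n")) < 66:
                raise PDBFormatError(f"ATOM record shorter than 66 columns: {line!r}")
            if line[26] != " ":
                raise PDBFormatError(f"insertion codes are unsupported: {line.rstrip()!r}")
            try:
                seq = int(line[22:26])
            except ValueError as exc:
                raise PDBFormatError(f"unparseable residue number in {line.rstrip()!r}") from exc
            seen.add(seq)
            value = values_by_seq.get(seq, missing_fill)
            line = line[:60] + f"{value:6.2f}" + line[66:]
        out_lines.append(line)
    missing = sorted(set(values_by_seq) - seen)
    if missing:
        warnings.warn(f"residues not found in {pdb_in}: {missing}", stacklevel=2)
    Path(pdb_out).write_text("".join(out_lines), encoding="utf-8")
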