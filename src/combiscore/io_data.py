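"""Long-format screening table I/O, dose-response matrices and the
cross-design extraction anchored at each drug's IC50.

The canonical on-disk layout is the long CSV used by matrix-style
combination screens: one row per (block, dose pair, replicate) with
columns ``block_id, drug_row, drug_col, conc_r, conc_c, response,
cell_line, replicate``. ``response`` is percent inhibition unless the
format spec declares viability, in which case records are flagged for
conversion (``%inhibition = 100 - %viability``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, DesignError, IntegrityError, ParseError

VIABILITY = "viability"
INHIBITION = "inhibition"


@dataclass(frozen=True)
class ResponseRecord:
    """One measured well: a dose pair of a drug-pair block."""

    block_id: str
    drug_row: str
    drug_col: str
    conc_row: float
    conc_col: float
    response: float
    cell_line: str = ""
    replicate: int = 1
    response_kind: str = INHIBITION

    def __post_init__(self):
        if self.conc_row < 0 or self.conc_col < 0:
            raise ValueError("concentrations must be >= 0")
        if self.response_kind not in (VIABILITY, INHIBITION):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")


@dataclass(frozen=True)
class FormatSpec:
    """Column-name mapping for :func:`read_long_table`."""

    block_id: str = "block_id"
    drug_row: str = "drug_row"
    drug_col: str = "drug_col"
    conc_row: str = "conc_r"
    conc_col: str = "conc_c"
    response: str = "response"
    cell_line: str | None = "cell_line"
    replicate: str | None = "replicate"
    response_kind: str = INHIBITION

    def mandatory(self) -> dict[str, str]:
        return {
            "block_id": self.block_id,
            "drug_row": self.drug_row,
            "drug_col": self.drug_col,
            "conc_row": self.conc_row,
            "conc_col": self.conc_col,
            "response": self.response,
        }


def viability_to_inhibition(v):
    """Percent inhibition from percent viability: ``100 - v`` (no clipping)."""
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("viability must be finite")
    out = 100.0 - arr
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def ensure_inhibition(records) -> list[ResponseRecord]:
    """Convert any viability-flagged records to percent inhibition."""
    out = []
    for rec in records:
        if rec.response_kind == VIABILITY:
            rec = replace(rec, response=viability_to_inhibition(rec.response),
                          response_kind=INHIBITION)
        out.append(rec)
    return out


def read_long_table(path, format_spec: FormatSpec | None = None) -> list[ResponseRecord]:
    """Read a long-format CSV into :class:`ResponseRecord` objects.

    Raises :class:`ConfigError` for missing mandatory columns and
    :class:`ParseError` (naming 1-based file row numbers, header = row 1)
    for non-numeric concentrations/responses or negative concentrations.
    """
    spec = format_spec or FormatSpec()
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ConfigError(f"{path}: file is empty (no header)") from None

    missing = [col for col in spec.mandatory().values() if col not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory column(s) {missing}")

    if df.empty:
        return []

    numeric = {}
    bad_rows: set[int] = set()
    for name in (spec.conc_row, spec.conc_col, spec.response):
        vals = pd.to_numeric(df[name], errors="coerce")
        bad = df.index[vals.isna()]
        bad_rows.update(int(i) + 2 for i in bad)  # +2: header + 1-based
        numeric[name] = vals
    for name in (spec.conc_row, spec.conc_col):
        bad = df.index[numeric[name] < 0]
        bad_rows.update(int(i) + 2 for i in bad)
    if bad_rows:
        rows = sorted(bad_rows)
        raise ParseError(
            f"{path}: malformed concentration/response in row(s) {rows}", rows)

    if spec.replicate is not None and spec.replicate in df.columns:
        reps = pd.to_numeric(df[spec.replicate], errors="coerce")
        bad = df.index[reps.isna()]
        if len(bad):
            rows = sorted(int(i) + 2 for i in bad)
            raise ParseError(f"{path}: non-numeric replicate in row(s) {rows}", rows)
        reps = reps.astype(int)
    else:
        reps = pd.Series(1, index=df.index)

    if spec.cell_line is not None and spec.cell_line in df.columns:
        cells = df[spec.cell_line].fillna("")
    else:
        cells = pd.Series("", index=df.index)

    records = []
    for i in df.index:
        records.append(ResponseRecord(
            block_id=str(df.at[i, spec.block_id]),
            drug_row=str(df.at[i, spec.drug_row]),
            drug_col=str(df.at[i, spec.drug_col]),
            conc_row=float(numeric[spec.conc_row][i]),
            conc_col=float(numeric[spec.conc_col][i]),
            response=float(numeric[spec.response][i]),
            cell_line=str(cells[i]),
            replicate=int(reps[i]),
            response_kind=spec.response_kind,
        ))
    return records


def records_to_frame(records) -> pd.DataFrame:
    cols = ["block_id", "drug_row", "drug_col", "conc_r", "conc_c",
            "response", "cell_line", "replicate"]
    rows = [(r.block_id, r.drug_row, r.drug_col, r.conc_row, r.conc_col,
             r.response, r.cell_line, r.replicate) for r in records]
    return pd.DataFrame(rows, columns=cols)


def write_long_table(records, path) -> None:
    """Write records in the canonical long-CSV layout (inhibition scale)."""
    records_to_frame(ensure_inhibition(records)).to_csv(path, index=False)


def group_by_block(records) -> dict[str, list[ResponseRecord]]:
    out: dict[str, list[ResponseRecord]] = {}
    for rec in records:
        out.setdefault(rec.block_id, []).append(rec)
    return out


@dataclass(frozen=True)
class DoseResponseMatrix:
    """Replicate-averaged % inhibition grid for one drug-pair block.

    ``inhibition[i, j]`` is the mean response at
    ``(row_concs[i], col_concs[j])``; missing cells are NaN with
    ``n_replicates`` 0. Concentration 0 rows/columns hold the monotherapy
    margins of the *other* drug.
    """

    block_id: str
    drug_row: str
    drug_col: str
    row_concs: np.ndarray
    col_concs: np.ndarray
    inhibition: np.ndarray
    n_replicates: np.ndarray
    cell_line: str = ""

    @property
    def has_margins(self) -> bool:
        return 0.0 in self.row_concs and 0.0 in self.col_concs

    def monotherapy_points(self, drug: int) -> list[tuple[float, float]]:
        """(conc, %inhibition) monotherapy pairs for drug 1 (rows) or 2 (cols)."""
        if drug == 1:
            if 0.0 not in self.col_concs:
                return []
            j = int(np.where(self.col_concs == 0.0)[0][0])
            pairs = [(float(c), float(self.inhibition[i, j]))
                     for i, c in enumerate(self.row_concs) if c > 0]
        elif drug == 2:
            if 0.0 not in self.row_concs:
                return []
            i = int(np.where(self.row_concs == 0.0)[0][0])
            pairs = [(float(c), float(self.inhibition[i, j]))
                     for j, c in enumerate(self.col_concs) if c > 0]
        else:
            raise ValueError("drug must be 1 or 2")
        return [(c, y) for c, y in pairs if not math.isnan(y)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cr in enumerate(self.row_concs):
            for j, cc in enumerate(self.col_concs):
                if self.n_replicates[i, j] > 0:
                    rows.append((self.block_id, self.drug_row, self.drug_col,
                                 float(cr), float(cc),
                                 float(self.inhibition[i, j]),
                                 int(self.n_replicates[i, j]), self.cell_line))
        return pd.DataFrame(rows, columns=[
            "block_id", "drug_row", "drug_col", "conc_r", "conc_c",
            "mean_inhibition", "n_replicates", "cell_line"])


def build_matrix(records) -> DoseResponseMatrix:
    """Average replicates into a dose-response grid for a single block."""
    records = ensure_inhibition(list(records))
    if not records:
        raise DesignError("no records to build a matrix from")
    block_ids = {r.block_id for r in records}
    if len(block_ids) != 1:
        raise IntegrityError(f"records span multiple blocks: {sorted(block_ids)}")
    drugs_r = {r.drug_row for r in records}
    drugs_c = {r.drug_col for r in records}
    cells = {r.cell_line for r in records}
    if len(drugs_r) != 1 or len(drugs_c) != 1:
        raise IntegrityError(
            f"conflicting drug names within block {records[0].block_id}: "
            f"rows={sorted(drugs_r)}, cols={sorted(drugs_c)}")

    row_concs = np.array(sorted({r.conc_row for r in records}))
    col_concs = np.array(sorted({r.conc_col for r in records}))
    total = np.zeros((len(row_concs), len(col_concs)))
    count = np.zeros((len(row_concs), len(col_concs)), dtype=int)
    ri = {c: i for i, c in enumerate(row_concs)}
    ci = {c: j for j, c in enumerate(col_concs)}
    for r in records:
        i, j = ri[r.conc_row], ci[r.conc_col]
        total[i, j] += r.response
        count[i, j] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return DoseResponseMatrix(
        block_id=records[0].block_id,
        drug_row=records[0].drug_row,
        drug_col=records[0].drug_col,
        row_concs=row_concs,
        col_concs=col_concs,
        inhibition=mean,
        n_replicates=count,
        cell_line=sorted(cells)[0] if cells else "",
    )


@dataclass(frozen=True)
class CrossDesignRecord:
    """The two IC50-anchored dose-response vectors of a drug pair.

    ``curve1_points`` varies drug 2 with drug 1 (the background drug) fixed
    at ``background1_conc``; ``curve2_points`` is the mirror image. The two
    vectors intersect at ``(background1_conc, background2_conc)``.
    """

    block_id: str
    background1_conc: float
    curve1_points: tuple[tuple[float, float], ...]
    background2_conc: float
    curve2_points: tuple[tuple[float, float], ...]
    mono1_points: tuple[tuple[float, float], ...] = ()
    mono2_points: tuple[tuple[float, float], ...] = ()
    drug_row: str = ""
    drug_col: str = ""
    cell_line: str = ""

    def swapped(self) -> "CrossDesignRecord":
        """The same record with the drug-1/drug-2 roles exchanged."""
        return CrossDesignRecord(
            block_id=self.block_id,
            background1_conc=self.background2_conc,
            curve1_points=self.curve2_points,
            background2_conc=self.background1_conc,
            curve2_points=self.curve1_points,
            mono1_points=self.mono2_points,
            mono2_points=self.mono1_points,
            drug_row=self.drug_col,
            drug_col=self.drug_row,
            cell_line=self.cell_line,
        )

    def to_dict(self) -> dict:
        return {
            "block_id": self.block_id,
            "drug_row": self.drug_row,
            "drug_col": self.drug_col,
            "background1_conc": self.background1_conc,
            "background2_conc": self.background2_conc,
            "curve1_points": [list(p) for p in self.curve1_points],
            "curve2_points": [list(p) for p in self.curve2_points],
            "mono1_points": [list(p) for p in self.mono1_points],
            "mono2_points": [list(p) for p in self.mono2_points],
        }


def nearest_conc(concs, ic50: float) -> float:
    """Tested nonzero concentration closest to ``ic50`` on the log10 scale.

    Log-equidistant ties resolve to the lower concentration (with a warning).
    """
    if ic50 <= 0:
        raise DesignError("ic50 must be > 0")
    pos = np.array(sorted(c for c in np.asarray(concs, float) if c > 0))
    if pos.size == 0:
        raise DesignError("no nonzero concentrations to anchor at")
    dist = np.abs(np.log10(pos) - math.log10(ic50))
    best = dist.min()
    ties = pos[np.isclose(dist, best, rtol=0.0, atol=1e-12)]
    if ties.size > 1:
        warnings.warn(
            f"anchor tie at IC50={ic50}: {ties.tolist()}; choosing the lower")
    return float(ties[0])


def extract_cross(matrix: DoseResponseMatrix, ic50_1: float,
                  ic50_2: float) -> CrossDesignRecord:
    """Pick the row and column of the grid nearest each drug's IC50.

    Drug 1 is ``drug_row`` (anchored by ``ic50_1``), drug 2 is ``drug_col``.
    Zero-dose cells are excluded from the returned vectors; monotherapy
    margins are attached when present.
    """
    bg1 = nearest_conc(matrix.row_concs, ic50_1)
    bg2 = nearest_conc(matrix.col_concs, ic50_2)
    i = int(np.where(matrix.row_concs == bg1)[0][0])
    j = int(np.where(matrix.col_concs == bg2)[0][0])

    curve1 = tuple(
        (float(c), float(matrix.inhibition[i, jj]))
        for jj, c in enumerate(matrix.col_concs)
        if c > 0 and not math.isnan(matrix.inhibition[i, jj]))
    curve2 = tuple(
        (float(c), float(matrix.inhibition[ii, j]))
        for ii, c in enumerate(matrix.row_concs)
        if c > 0 and not math.isnan(matrix.inhibition[ii, j]))
    if len(curve1) < 2 or len(curve2) < 2:
        raise DesignError(
            f"block {matrix.block_id}: need >= 2 nonzero concentrations per drug")

    return CrossDesignRecord(
        block_id=matrix.block_id,
        background1_conc=bg1,
        curve1_points=curve1,
        background2_conc=bg2,
        curve2_points=curve2,
        mono1_points=tuple(matrix.monotherapy_points(1)),
        mono2_points=tuple(matrix.monotherapy_points(2)),
        drug_row=matrix.drug_row,
        drug_col=matrix.drug_col,
        cell_line=matrix.cell_line,
    )
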