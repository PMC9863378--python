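"""Descriptor schemas, compound data structures and CSV input/output.

The regression outcome is the clearance index (CI): the ex vivo placental
transfer rate of a bisphenol divided by the antipyrine transfer rate in the
same perfusion.  Predictors are molecular descriptors (computed in silico and
consumed here as a table) and chromatographic descriptors measured from peak
shapes on a panel of reversed-phase columns.

Descriptor codes follow the field convention ``<column><solvent><parameter>``
for chromatographic slots (e.g. ``T3A2`` = width at 5 % height on the HSS T3
column with acetonitrile) and short family prefixes (``LP``, ``MT``, ``DE``,
...) for molecular slots.

CSV dialect: comma separated, UTF-8, ``.`` decimal separator, first column
``compound_id``; missing values are empty cells.  Clearance tables are long
format with columns ``compound_id, replicate_id, ci``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    MissingValueError,
    ParseError,
    SchemaCollisionError,
    UnknownDescriptorError,
)

# The 13 analytical columns of the descriptor panel, coded as in the
# descriptor tables (BEH RP18 Shield -> RP, BEH Phenyl -> P).
CHROM_COLUMNS: tuple[str, ...] = (
    "RB", "RCB", "FB", "CC18", "C18", "RP", "C8", "P", "PH", "FP", "T3", "PFP", "CN",
)
SOLVENTS: tuple[str, ...] = ("A", "M")  # A = acetonitrile, M = methanol
#: peak-shape parameter digits: 2 width (5 %), 5 k' vs reference, 7 asymmetry,
#: 8 tailing factor
CHROM_PARAMETERS: tuple[int, ...] = (2, 5, 7, 8)

PARAMETER_NAMES = {
    2: "width_5pct",
    5: "kprime_vs_ref",
    7: "asymmetry",
    8: "tailing_factor",
}

FAMILIES = ("physicochemical", "topological", "thermo-electronic", "chromatographic")


@dataclass(frozen=True)
class DescriptorEntry:
    code: str
    family: str
    column_code: str | None = None
    solvent_code: str | None = None
    parameter_code: int | None = None


@dataclass(frozen=True)
class DescriptorSchema:
    """An ordered, duplicate-free collection of descriptor slots."""

    entries: tuple[DescriptorEntry, ...]

    def __post_init__(self):
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise SchemaCollisionError(f"duplicate descriptor codes: {dup}")
        for e in self.entries:
            if e.family not in FAMILIES:
                raise ValueError(f"unknown descriptor family {e.family!r}")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def entry(self, code: str) -> DescriptorEntry:
        for e in self.entries:
            if e.code == code:
                return e
        raise UnknownDescriptorError(code)

    def subset(self, codes: Sequence[str]) -> "DescriptorSchema":
        return DescriptorSchema(tuple(self.entry(c) for c in codes))


def build_chrom_schema(
    columns: Sequence[str] = CHROM_COLUMNS,
    solvents: Sequence[str] = SOLVENTS,
    parameters: Sequence[int] = CHROM_PARAMETERS,
) -> DescriptorSchema:
    """Cartesian product of column x solvent x peak parameter.

    Codes are ``column + solvent + parameter digit``; the canonical panel
    (13 columns, 2 solvents, 4 parameters) yields 104 slots.
    """
    for name, seq in (("columns", columns), ("solvents", solvents), ("parameters", parameters)):
        if len(seq) == 0:
            raise ValueError(f"{name} must be non-empty")
        if len(set(seq)) != len(seq):
            raise ValueError(f"{name} contains duplicates")
    entries = []
    for col in columns:
        for solv in solvents:
            for par in parameters:
                entries.append(
                    DescriptorEntry(
                        code=f"{col}{solv}{par}",
                        family="chromatographic",
                        column_code=col,
                        solvent_code=solv,
                        parameter_code=int(par),
                    )
                )
    return DescriptorSchema(tuple(entries))


def build_molecular_schema() -> DescriptorSchema:
    """The canonical 50-slot molecular schema (16/14/20 by family).

    Physicochemical: partition coefficients (LP*, CD*) and bulk properties
    (CPP*); topological: connectivity/shape indices (MT*) plus the Connolly
    surface/volume slots (CPS*); thermo-electronic: DE* (heat of formation,
    total energy, orbital energies, ...).
    """
    phys = [f"LP{i}" for i in range(1, 4)] + [f"CD{i}" for i in range(1, 4)] + [
        f"CPP{i}" for i in range(1, 11)
    ]
    topo = [f"MT{i}" for i in range(1, 13)] + ["CPS2", "CPS3"]
    thermo = [f"DE{i}" for i in range(1, 21)]
    entries = (
        [DescriptorEntry(c, "physicochemical") for c in phys]
        + [DescriptorEntry(c, "topological") for c in topo]
        + [DescriptorEntry(c, "thermo-electronic") for c in thermo]
    )
    return DescriptorSchema(tuple(entries))


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors value matrix aligned to a schema."""

    compound_ids: list[str]
    schema: DescriptorSchema
    values: np.ndarray
    missing_codes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.compound_ids):
            raise ValueError("row count does not match number of compounds")
        if p != len(self.schema):
            raise ValueError("column count does not match schema size")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicated compound ids")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.schema.codes))
        df.insert(0, "compound_id", self.compound_ids)
        return df

    def column(self, code: str) -> np.ndarray:
        try:
            j = self.schema.codes.index(code)
        except ValueError:
            raise UnknownDescriptorError(code) from None
        return self.values[:, j]

    def subset(self, codes: Sequence[str]) -> "DescriptorMatrix":
        idx = []
        for c in codes:
            if c not in self.schema:
                raise UnknownDescriptorError(c)
            idx.append(self.schema.codes.index(c))
        return DescriptorMatrix(
            compound_ids=list(self.compound_ids),
            schema=self.schema.subset(codes),
            values=self.values[:, idx],
            missing_codes=[c for c in self.missing_codes if c in codes],
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def concat_matrices(a: DescriptorMatrix, b: DescriptorMatrix) -> DescriptorMatrix:
    """Column-concatenate two matrices over identical compound lists."""
    if a.compound_ids != b.compound_ids:
        raise ValueError("compound lists differ")
    schema = DescriptorSchema(a.schema.entries + b.schema.entries)
    return DescriptorMatrix(
        compound_ids=list(a.compound_ids),
        schema=schema,
        values=np.hstack([a.values, b.values]),
        missing_codes=a.missing_codes + b.missing_codes,
    )


def load_descriptor_matrix(path: str | Path, schema: DescriptorSchema) -> DescriptorMatrix:
    """Read a wide descriptor CSV and align it to ``schema`` order.

    Unknown columns are reported through :class:`UserWarning`; schema columns
    absent from the file are filled with NaN and flagged in
    ``missing_codes``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise FormatError(f"{path}: no data rows / descriptor columns")
    first = df.columns[0]
    if first != "compound_id":
        raise FormatError(f"{path}: first column must be 'compound_id', got {first!r}")
    compound_ids = df[first].astype(str).tolist()

    unknown = [c for c in df.columns[1:] if c not in schema]
    if unknown:
        warnings.warn(f"{path.name}: unknown descriptor columns ignored: {unknown}")

    n = len(compound_ids)
    values = np.full((n, len(schema)), np.nan)
    missing = []
    for j, code in enumerate(schema.codes):
        if code not in df.columns:
            missing.append(code)
            continue
        raw = df[code]
        cleaned = raw.fillna("nan").str.strip().replace("", "nan")
        try:
            # correctly-rounded Python float parsing (pandas' fast-path
            # to_numeric parser is not)
            values[:, j] = cleaned.astype(float)
        except ValueError:
            col = pd.to_numeric(raw, errors="coerce")
            bad = col.isna() & raw.notna() & (raw.str.strip() != "")
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path.name}: non-numeric value {raw.iloc[i]!r} in column "
                f"{code!r}, row {i + 2} (compound {compound_ids[i]})"
            ) from None
    return DescriptorMatrix(compound_ids, schema, values, missing_codes=missing)


def import_descriptor_xlsx(
    path: str | Path, schema: DescriptorSchema, sheet: int | str = 0
) -> DescriptorMatrix:
    """Shim converting a supplementary Excel descriptor sheet to the CSV dialect."""
    df = pd.read_excel(path, sheet_name=sheet)
    df = df.rename(columns={df.columns[0]: "compound_id"})
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        df.to_csv(fh.name, index=False)
        return load_descriptor_matrix(fh.name, schema)


@dataclass
class ClearanceTable:
    """Long-format replicate clearance-index observations."""

    records: pd.DataFrame  # columns: compound_id, replicate_id, ci

    def __post_init__(self):
        req = ["compound_id", "replicate_id", "ci"]
        if list(self.records.columns[:3]) != req:
            raise FormatError(f"clearance table needs columns {req}")
        self.records = self.records.copy()
        self.records["compound_id"] = self.records["compound_id"].astype(str)
        self.records["ci"] = self.records["ci"].astype(float)
        if (self.records["ci"] <= 0).any():
            bad = self.records.loc[self.records["ci"] <= 0, "compound_id"].tolist()
            raise ValueError(f"CI must be > 0 (1/Y weighting); offending compounds: {bad}")
        dup = self.records.duplicated(subset=["compound_id", "replicate_id"])
        if dup.any():
            raise ValueError("replicate ids must be unique within compound")

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.records["compound_id"]))

    def __len__(self) -> int:
        return len(self.records)

    def for_compounds(self, compounds: Iterable[str]) -> "ClearanceTable":
        keep = set(compounds)
        sub = self.records[self.records["compound_id"].isin(keep)].reset_index(drop=True)
        return ClearanceTable(sub)

    def mean_by_compound(self) -> pd.Series:
        return self.records.groupby("compound_id", sort=False)["ci"].mean()

    def summarize(self, transfer_classes: dict[str, str] | None = None) -> "CISummary":
        g = self.records.groupby("compound_id", sort=False)["ci"]
        df = pd.DataFrame(
            {
                "compound_id": list(g.mean().index),
                "mean_ci": g.mean().to_numpy(),
                "sd_ci": g.std(ddof=1).fillna(0.0).to_numpy(),
                "n_replicates": g.count().to_numpy(),
            }
        )
        if transfer_classes:
            df["transfer_class"] = [transfer_classes.get(c, "") for c in df["compound_id"]]
        return CISummary(df)

    def save_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, float_format="%.17g")


def load_clearance_table(path: str | Path) -> ClearanceTable:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    return ClearanceTable(df)


@dataclass
class CISummary:
    """Per-compound mean +/- SD of the clearance index with transfer class."""

    table: pd.DataFrame  # compound_id, mean_ci, sd_ci, n_replicates[, transfer_class]

    def __post_init__(self):
        if (self.table["sd_ci"] < 0).any():
            raise ValueError("sd_ci must be >= 0")
        if (self.table["n_replicates"] < 1).any():
            raise ValueError("n_replicates must be >= 1")

    def mean_ci(self, compound: str) -> float:
        row = self.table[self.table["compound_id"] == compound]
        if row.empty:
            raise KeyError(compound)
        return float(row["mean_ci"].iloc[0])


@dataclass(frozen=True)
class PublishedModel:
    """A fixed multilinear model in scaled descriptor space.

    ``predict_scaled`` evaluates intercept + sum(beta_k * z_k) for z given in
    the model's own descriptor order.  The intercept is the predicted CI of a
    hypothetical compound sitting at the descriptor centroid (all z = 0).
    """

    name: str
    intercept: float
    coefficients: tuple[tuple[str, float], ...]
    weighting: str = "1/Y"

    def validate_against(self, schema: DescriptorSchema) -> None:
        for code, _ in self.coefficients:
            if code not in schema:
                raise UnknownDescriptorError(code)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.coefficients)

    def predict_scaled(self, z: Sequence[float] | np.ndarray) -> float:
        z = np.asarray(z, dtype=float)
        betas = np.array([b for _, b in self.coefficients])
        if z.shape != betas.shape:
            raise ValueError(f"expected {betas.shape[0]} scaled values, got {z.shape}")
        return float(self.intercept + z @ betas)

    def predict_matrix(self, X: DescriptorMatrix, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
        """Predict CI for each compound from raw descriptor values."""
        if X.has_missing:
            raise MissingValueError("descriptor matrix has missing values")
        Z = (np.column_stack([X.column(c) for c in self.codes]) - center) / scale
        betas = np.array([b for _, b in self.coefficients])
        return self.intercept + Z @ betas
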