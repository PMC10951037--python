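"""Data model and readers/writers for the BrainSpan expression dialect.

The BrainSpan "summarised to genes" distribution is a triplet of CSV
files: a header-less expression matrix whose first field is a row number,
a row (gene) metadata table, and a column (specimen x structure) metadata
table.  This module parses that triplet into :class:`ExpressionDataset`,
applies the specimen-inclusion rule (cerebellar sample plus a minimum
number of non-cerebellar regions), and serialises pipeline outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ages import AgePoint, parse_age

#: Structure acronyms treated as cerebellar: whole cerebellum (early
#: foetal donors) and cerebellar cortex.
DEFAULT_CEREBELLAR_LABELS = frozenset({"CB", "CBC"})


class BrainSpanLoadError(ValueError):
    """Raised when the expression triplet violates the dialect contract."""


@dataclass(frozen=True)
class StructureLabel:
    acronym: str
    is_cerebellar: bool


@dataclass(frozen=True)
class SpecimenRecord:
    """One donor: identifier, age, and the structures actually sampled."""

    donor_id: str
    age: AgePoint
    structures: tuple[StructureLabel, ...]

    @property
    def cerebellar_structure(self) -> StructureLabel | None:
        cb = [s for s in self.structures if s.is_cerebellar]
        if len(cb) > 1:
            raise ValueError(f"donor {self.donor_id} has {len(cb)} cerebellar structures")
        return cb[0] if cb else None

    @property
    def n_non_cerebellar(self) -> int:
        return sum(not s.is_cerebellar for s in self.structures)


@dataclass
class ExpressionDataset:
    """Genes x (donor, structure) RPKM matrix with specimen metadata.

    ``values`` holds non-negative RPKM with a two-level column index
    ``(donor_id, structure_acronym)``; structures a donor was never
    sampled for have no column at all, and sporadic absent measurements
    are NaN — never zero, since zeros are legitimate expression values.
    """

    values: pd.DataFrame
    specimens: list[SpecimenRecord]
    cerebellar_labels: frozenset[str] = DEFAULT_CEREBELLAR_LABELS

    def __post_init__(self) -> None:
        genes = self.values.index
        if genes.has_duplicates:
            dups = genes[genes.duplicated()].unique().tolist()
            raise BrainSpanLoadError(f"duplicate gene identifiers: {dups[:5]}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise BrainSpanLoadError("negative RPKM values present")
        seen: set[str] = set()
        for sp in self.specimens:
            if sp.donor_id in seen:
                raise BrainSpanLoadError(f"duplicate donor id: {sp.donor_id}")
            seen.add(sp.donor_id)
            sp.cerebellar_structure  # raises if more than one

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def donor_ids(self) -> list[str]:
        return [sp.donor_id for sp in self.specimens]

    def specimen(self, donor_id: str) -> SpecimenRecord:
        for sp in self.specimens:
            if sp.donor_id == donor_id:
                return sp
        raise KeyError(donor_id)

    def cerebellar_values(self, donor_id: str) -> pd.Series | None:
        """Per-gene RPKM of the donor's cerebellar sample, or None."""
        cb = self.specimen(donor_id).cerebellar_structure
        if cb is None:
            return None
        return self.values[(donor_id, cb.acronym)]

    def non_cerebellar_values(self, donor_id: str) -> pd.DataFrame:
        """Per-gene RPKM across the donor's non-cerebellar regions."""
        sp = self.specimen(donor_id)
        cols = [(sp.donor_id, s.acronym) for s in sp.structures if not s.is_cerebellar]
        return self.values[cols]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        return replace(self, values=self.values.loc[list(genes)])


@dataclass(frozen=True)
class ExclusionRecord:
    donor_id: str
    reason: str


REASON_NO_CEREBELLUM = "no cerebellar sample"
REASON_TOO_FEW_REGIONS = "too few non-cerebellar regions"


def _read_rows_metadata(path: Path) -> list[str]:
    df = pd.read_csv(path, dtype=str)
    for col in ("gene_symbol", "gene", "symbol"):
        if col in df.columns:
            return df[col].tolist()
    raise BrainSpanLoadError(
        f"{path}: no gene symbol column (expected one of gene_symbol/gene/symbol, "
        f"found {list(df.columns)})"
    )


def _read_columns_metadata(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = {"donor_id", "age", "structure_acronym"} - set(df.columns)
    if missing:
        raise BrainSpanLoadError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_brainspan(
    matrix_path: str | Path,
    rows_meta_path: str | Path,
    columns_meta_path: str | Path,
    cerebellar_labels: Iterable[str] = DEFAULT_CEREBELLAR_LABELS,
) -> ExpressionDataset:
    """Load a BrainSpan-dialect triplet into an :class:`ExpressionDataset`.

    The matrix file has no header and its first field is a row number;
    the remaining fields are RPKM values, one per row of the column
    metadata table.  Dimension mismatches, duplicate (donor, structure)
    columns and negative values raise :class:`BrainSpanLoadError` with
    file context.
    """
    matrix_path = Path(matrix_path)
    cerebellar_labels = frozenset(cerebellar_labels)
    genes = _read_rows_metadata(Path(rows_meta_path))
    cols = _read_columns_metadata(Path(columns_meta_path))

    mat = pd.read_csv(matrix_path, header=None)
    if mat.shape[1] - 1 != len(cols):
        raise BrainSpanLoadError(
            f"{matrix_path}: {mat.shape[1] - 1} data columns but column metadata "
            f"has {len(cols)} rows"
        )
    if mat.shape[0] != len(genes):
        raise BrainSpanLoadError(
            f"{matrix_path}: {mat.shape[0]} rows but row metadata has {len(genes)} rows"
        )
    values = mat.iloc[:, 1:].astype(float)
    with np.errstate(invalid="ignore"):
        if (values.to_numpy() < 0).any():
            r, c = np.argwhere(values.to_numpy() < 0)[0]
            raise BrainSpanLoadError(
                f"{matrix_path}: negative RPKM at matrix row {r + 1}, data column {c + 1}"
            )

    pairs = list(zip(cols["donor_id"], cols["structure_acronym"]))
    if len(set(pairs)) != len(pairs):
        dup = next(p for p in pairs if pairs.count(p) > 1)
        raise BrainSpanLoadError(
            f"{columns_meta_path}: duplicate (donor, structure) column {dup}"
        )
    values.index = pd.Index(genes, name="gene")
    values.columns = pd.MultiIndex.from_tuples(pairs, names=["donor_id", "structure"])

    specimens: list[SpecimenRecord] = []
    for donor_id, grp in cols.groupby("donor_id", sort=False):
        ages = grp["age"].unique()
        if len(ages) != 1:
            raise BrainSpanLoadError(
                f"{columns_meta_path}: donor {donor_id} has conflicting ages {list(ages)}"
            )
        structures = tuple(
            StructureLabel(acr, acr in cerebellar_labels)
            for acr in grp["structure_acronym"]
        )
        specimens.append(SpecimenRecord(str(donor_id), parse_age(ages[0]), structures))
    return ExpressionDataset(values, specimens, cerebellar_labels)


def select_specimens(
    ds: ExpressionDataset, min_other_regions: int = 4
) -> tuple[ExpressionDataset, list[ExclusionRecord]]:
    """Apply the inclusion rule: cerebellar sample plus >= ``min_other_regions``
    non-cerebellar regions.  Returns the included dataset and an exclusion
    report listing every dropped donor with its reason."""
    included: list[SpecimenRecord] = []
    excluded: list[ExclusionRecord] = []
    for sp in ds.specimens:
        if sp.cerebellar_structure is None:
            excluded.append(ExclusionRecord(sp.donor_id, REASON_NO_CEREBELLUM))
        elif sp.n_non_cerebellar < min_other_regions:
            excluded.append(ExclusionRecord(sp.donor_id, REASON_TOO_FEW_REGIONS))
        else:
            included.append(sp)
    keep_cols = [
        (sp.donor_id, s.acronym) for sp in included for s in sp.structures
    ]
    values = ds.values[keep_cols] if keep_cols else ds.values.iloc[:, :0]
    out = ExpressionDataset(values, included, ds.cerebellar_labels)
    return out, excluded


# ---------------------------------------------------------------------------
# serialisation


def write_brainspan(ds: ExpressionDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset back out as the three-file BrainSpan dialect.

    Values are rendered with ``repr`` so a read-back round-trips
    bit-exactly.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "expression_matrix.csv",
        "rows": out_dir / "rows_metadata.csv",
        "columns": out_dir / "columns_metadata.csv",
    }
    with open(paths["rows"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["row_num", "gene_symbol"])
        for i, g in enumerate(ds.genes, start=1):
            w.writerow([i, g])
    with open(paths["columns"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["column_num", "donor_id", "age", "structure_acronym"])
        for i, (donor, struct) in enumerate(ds.values.columns, start=1):
            w.writerow([i, donor, ds.specimen(donor).age.raw_label, struct])
    arr = ds.values.to_numpy()
    with open(paths["matrix"], "w", newline="") as fh:
        w = csv.writer(fh)
        for i in range(arr.shape[0]):
            w.writerow([i + 1] + [("" if np.isnan(v) else repr(float(v))) for v in arr[i]])
    return paths


def write_tidy(ds: ExpressionDataset, path: str | Path) -> None:
    """Long-format TSV (gene, donor, structure, rpkm) for downstream tools."""
    long = ds.values.stack(["donor_id", "structure"], future_stack=True).rename("rpkm")
    long = long.dropna().reset_index()
    long.to_csv(path, sep="\t", index=False)


def write_exclusion_report(excluded: list[ExclusionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(e.donor_id, e.reason) for e in excluded], columns=["donor_id", "reason"]
    ).to_csv(path, sep="\t", index=False)
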