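"""Shared data model, file I/O and preprocessing.

Containers are thin wrappers around pandas objects:

* :class:`MetaboliteMatrix` — samples x metabolites intensity table
  (non-negative, NaN = missing / below detection).
* :class:`SampleDesign` — one row per sample with the three design factors
  of the study: treatment (Ctrl vs aggressor-exposed AggE), stress regimen
  (5day vs 10day) and time point (acute = 24 h after the last defeat,
  chronic = 1.5 or 4 weeks of stress withdrawal).
* :class:`PathwayMap` — two-level metabolite annotation
  (superpathway -> subpathway), the unit of every pathway-level test.

All files are delimited text (tab by default, UTF-8); "NA" and empty cells
parse as missing.  Output helpers prepend a single ``#`` comment line that
records provenance (config hash, seed) so every table is self-describing.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("Ctrl", "AggE")
REGIMENS = ("5day", "10day")
TIMEPOINTS = ("acute", "chronic")

NA_VALUES = ["", "NA"]


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise DataValidationError(f"duplicate {what}: {', '.join(map(str, dups.index[:5]))}")


@dataclass
class MetaboliteMatrix:
    """Intensity table, rows = samples, columns = metabolites.

    Intensities are non-negative reals on the original (unlogged) scale;
    NaN marks a missing measurement.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "metabolite ids")
        vals = self.data.to_numpy(dtype=float)
        bad = ~np.isnan(vals) & (~np.isfinite(vals) | (vals < 0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DataValidationError(
                f"non-finite or negative intensity at sample "
                f"{self.data.index[r]!r}, metabolite {self.data.columns[c]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def log(self) -> pd.DataFrame:
        """Natural-log intensities (NaN propagates)."""
        with np.errstate(divide="ignore"):
            return np.log(self.data)


@dataclass
class SampleDesign:
    """Design table: sample_id -> (treatment, regimen, timepoint)."""

    table: pd.DataFrame  # index sample_id; columns treatment, regimen, timepoint

    def __post_init__(self) -> None:
        need = {"treatment", "regimen", "timepoint"}
        missing = need - set(self.table.columns)
        if missing:
            raise DataValidationError(f"design table missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "design sample ids")
        for col, allowed in (
            ("treatment", TREATMENTS),
            ("regimen", REGIMENS),
            ("timepoint", TIMEPOINTS),
        ):
            bad = set(self.table[col]) - set(allowed)
            if bad:
                raise DataValidationError(f"unknown {col} value(s): {sorted(bad)}")

    def cell(self, treatment: str, regimen: str, timepoint: str) -> list[str]:
        t = self.table
        mask = (
            (t["treatment"] == treatment)
            & (t["regimen"] == regimen)
            & (t["timepoint"] == timepoint)
        )
        return list(t.index[mask])

    def cells(self) -> dict[tuple[str, str, str], list[str]]:
        return {
            (tr, rg, tp): self.cell(tr, rg, tp)
            for tr in TREATMENTS
            for rg in REGIMENS
            for tp in TIMEPOINTS
        }

    def check_matches(self, matrix: MetaboliteMatrix) -> None:
        extra = set(matrix.sample_ids) - set(self.table.index)
        absent = set(self.table.index) - set(matrix.sample_ids)
        if extra or absent:
            raise DataValidationError(
                f"design/matrix sample mismatch: {sorted(extra)[:3]} not in design, "
                f"{sorted(absent)[:3]} not in matrix"
            )


@dataclass
class PathwayMap:
    """Two-level annotation: metabolite_id -> (superpathway, subpathway)."""

    table: pd.DataFrame  # index metabolite_id; columns superpathway, subpathway

    def __post_init__(self) -> None:
        need = {"superpathway", "subpathway"}
        if need - set(self.table.columns):
            raise DataValidationError("pathway table needs superpathway and subpathway columns")
        _check_unique(self.table.index, "annotated metabolite ids")
        supers_per_sub = self.table.groupby("subpathway")["superpathway"].nunique()
        conflict = supers_per_sub[supers_per_sub > 1]
        if len(conflict):
            raise DataValidationError(
                f"subpathway mapped to several superpathways: {list(conflict.index[:3])}"
            )

    def subpathway_members(self) -> dict[str, list[str]]:
        return {s: list(g.index) for s, g in self.table.groupby("subpathway")}

    def superpathway_members(self) -> dict[str, list[str]]:
        return {s: list(g.index) for s, g in self.table.groupby("superpathway")}

    def superpathway_of(self, subpathway: str) -> str:
        rows = self.table[self.table["subpathway"] == subpathway]
        if rows.empty:
            raise KeyError(subpathway)
        return rows["superpathway"].iloc[0]


@dataclass(frozen=True)
class ComparisonSpec:
    """One two-group comparison: A vs B lists of sample ids."""

    label: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise DataValidationError(f"comparison {self.label!r} has an empty group")
        if set(self.group_a) & set(self.group_b):
            raise DataValidationError(f"comparison {self.label!r} has overlapping groups")


# ---------------------------------------------------------------------------
# I/O


def _read_delim(path, **kw) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=kw.pop("sep", "\t"), comment="#", na_values=NA_VALUES,
        keep_default_na=False, index_col=0, **kw,
    )


def load_matrix(path, sep: str = "\t") -> MetaboliteMatrix:
    """Read an intensity table: first row metabolite ids, first column sample ids.

    Raises :class:`DataValidationError` for duplicate ids or non-numeric cells
    (naming the offending row/column).
    """
    with open(path, encoding="utf-8") as fh:
        header = next(line for line in fh if not line.startswith("#"))
    _check_unique(header.rstrip("\n").split(sep)[1:], "metabolite ids")
    raw = pd.read_csv(
        path, sep=sep, comment="#", na_values=NA_VALUES,
        keep_default_na=False, index_col=0, dtype=str,
    )
    _check_unique(raw.index, "sample ids")
    raw.index.name = None
    raw.columns.name = None
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"non-numeric cell at sample {raw.index[r]!r}, metabolite "
            f"{raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    return MetaboliteMatrix(num)


def write_matrix(matrix: MetaboliteMatrix, path, sep: str = "\t",
                 meta: Mapping[str, object] | None = None) -> None:
    write_table(matrix.data, path, sep=sep, meta=meta, index_label="sample_id")


def load_design(path, sep: str = "\t") -> SampleDesign:
    return SampleDesign(_read_delim(path, sep=sep))


def load_pathways(path, sep: str = "\t") -> PathwayMap:
    return PathwayMap(_read_delim(path, sep=sep))


def write_table(df: pd.DataFrame, path, sep: str = "\t",
                meta: Mapping[str, object] | None = None,
                index_label: str | None = None, index: bool = True) -> None:
    """Write a TSV with an optional leading ``#`` provenance comment line."""
    buf = io.StringIO()
    if meta:
        buf.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
    df.to_csv(buf, sep=sep, index=index, index_label=index_label)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Preprocessing


def scale_and_impute(matrix: MetaboliteMatrix,
                     mode: str = "median_scale_min_impute") -> MetaboliteMatrix:
    """Vendor-style rescaling: divide each metabolite by its observed median
    (median becomes 1), then fill missing entries with the metabolite's
    observed (scaled) minimum.

    Medians and minima use observed values only; all-missing or zero-median
    metabolites are dropped with a warning.  ``mode="none"`` returns the
    input unchanged.
    """
    if mode == "none":
        return matrix
    if mode != "median_scale_min_impute":
        raise ValueError(f"unknown mode {mode!r}")
    if matrix.data.size == 0:
        raise DataValidationError("empty matrix")
    df = matrix.data
    med = df.median(axis=0, skipna=True)
    drop = med.index[med.isna() | (med == 0)]
    if len(drop):
        logger.warning("dropping %d metabolite(s) with all-missing or zero-median values: %s",
                       len(drop), list(drop[:5]))
        df = df.drop(columns=drop)
        med = med.drop(drop)
    scaled = df / med
    return MetaboliteMatrix(scaled.fillna(scaled.min(axis=0)))


def canonical_comparisons(design: SampleDesign) -> list[ComparisonSpec]:
    """The study's eight simple comparisons, in deterministic order.

    Four treatment comparisons (AggE vs Ctrl, A = AggE) at
    5day/acute, 5day/chronic, 10day/acute, 10day/chronic; then four time
    comparisons (acute vs chronic, A = acute) within Ctrl/5day, Ctrl/10day,
    AggE/5day, AggE/10day.
    """
    cells = design.cells()
    empty = [k for k, v in cells.items() if not v]
    if empty:
        raise DataValidationError(
            "empty design cell(s): " + ", ".join("/".join(k) for k in empty)
        )
    specs: list[ComparisonSpec] = []
    for rg in REGIMENS:
        for tp in TIMEPOINTS:
            specs.append(ComparisonSpec(
                label=f"AggE_vs_Ctrl|{rg}|{tp}",
                group_a=tuple(cells[("AggE", rg, tp)]),
                group_b=tuple(cells[("Ctrl", rg, tp)]),
            ))
    for tr in TREATMENTS:
        for rg in REGIMENS:
            specs.append(ComparisonSpec(
                label=f"acute_vs_chronic|{tr}|{rg}",
                group_a=tuple(cells[(tr, rg, "acute")]),
                group_b=tuple(cells[(tr, rg, "chronic")]),
            ))
    return specs
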