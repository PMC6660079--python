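"""Expression-matrix and design I/O.

The canonical interchange format is plain TSV: an expression table whose
first column is ``probe_id`` and whose remaining columns are sample ids,
and a design table with columns ``sample_id``, ``treatment``
(VEH / T3 / CORT / T3CORT) and ``replicate``. A convenience importer
strips the metadata preamble of a GEO series-matrix file down to the
same shape.

Signals are floored at a small positive value before any ratio is
computed: fold change is a ratio of group means, and normalized
bead-array signals can be zero or negative after background
subtraction.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENTS: tuple[str, ...] = ("VEH", "T3", "CORT", "T3CORT")
HORMONE_TREATMENTS: tuple[str, ...] = ("T3", "CORT", "T3CORT")

DEFAULT_SIGNAL_FLOOR = 0.1


class DesignError(ValueError):
    """Raised when a design table violates the experimental contract."""


class MatrixError(ValueError):
    """Raised when an expression table cannot be validated."""


@dataclass(frozen=True)
class Design:
    """Sample-to-treatment map for the four-arm hormone experiment.

    Every treatment (vehicle, T3, CORT, T3+CORT) must be present with at
    least two replicates so a within-group variance is estimable; the
    study design is triplicate.
    """

    table: pd.DataFrame  # columns: sample_id, treatment, replicate

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "treatment", "replicate"}
        missing = required - set(t.columns)
        if missing:
            raise DesignError(f"design table lacks columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample ids in design: {dups}")
        bad = set(t["treatment"]) - set(TREATMENTS)
        if bad:
            raise DesignError(
                f"unknown treatments {sorted(bad)}; expected one of {TREATMENTS}"
            )
        absent = set(TREATMENTS) - set(t["treatment"])
        if absent:
            raise DesignError(f"treatments absent from design: {sorted(absent)}")
        if (t["replicate"] < 1).any():
            raise DesignError("replicate indices must be positive integers")
        pairs = t[["treatment", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise DesignError("(treatment, replicate) pairs must be unique")
        counts = t["treatment"].value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise DesignError(
                f"treatments with fewer than 2 replicates: {thin.to_dict()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def samples_for(self, treatment: str) -> list[str]:
        if treatment not in TREATMENTS:
            raise DesignError(f"unknown treatment {treatment!r}")
        sel = self.table["treatment"] == treatment
        return self.table.loc[sel, "sample_id"].tolist()

    def n_replicates(self, treatment: str) -> int:
        return len(self.samples_for(treatment))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Design":
        t = frame.copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["treatment"] = t["treatment"].astype(str)
        t["replicate"] = t["replicate"].astype(int)
        return cls(t.reset_index(drop=True))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Design":
        frame = pd.read_csv(path, sep="\t")
        return cls.from_frame(frame)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe x sample matrix of normalized hybridization intensities.

    ``signals`` is indexed by probe id with one column per design sample,
    floored at ``floor`` so fold-change ratios are always defined.
    """

    signals: pd.DataFrame
    floor: float = DEFAULT_SIGNAL_FLOOR

    def __post_init__(self) -> None:
        s = self.signals
        if s.index.duplicated().any():
            dups = s.index[s.index.duplicated()].tolist()
            raise MatrixError(f"duplicate probe ids: {dups}")
        if not np.isfinite(s.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(s.to_numpy()))
            r, c = bad[0]
            raise MatrixError(
                f"non-finite signal at probe {s.index[r]!r}, sample {s.columns[c]!r}"
            )
        if self.floor <= 0:
            raise MatrixError("signal floor must be positive")
        if (s.to_numpy() < self.floor).any():
            raise MatrixError("signals below the floor; construct via floored()")

    @classmethod
    def floored(
        cls, signals: pd.DataFrame, floor: float = DEFAULT_SIGNAL_FLOOR
    ) -> "ExpressionMatrix":
        """Validate numeric content and raise sub-floor values to ``floor``."""
        arr = signals.to_numpy(dtype=float, copy=True)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))
            r, c = bad[0]
            raise MatrixError(
                "non-numeric or missing cell at probe "
                f"{signals.index[r]!r}, sample {signals.columns[c]!r}"
            )
        arr = np.maximum(arr, floor)
        framed = pd.DataFrame(arr, index=signals.index.astype(str), columns=signals.columns)
        return cls(framed, floor=floor)

    @property
    def probe_ids(self) -> list[str]:
        return self.signals.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.signals.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.signals.shape

    def write_tsv(self, path: str | Path) -> None:
        out = self.signals.copy()
        out.insert(0, "probe_id", out.index)
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe-to-gene-symbol map; unannotated clones carry an empty symbol."""

    table: pd.DataFrame  # columns: probe_id, gene_symbol

    def __post_init__(self) -> None:
        t = self.table
        if {"probe_id", "gene_symbol"} - set(t.columns):
            raise MatrixError("annotation needs columns probe_id, gene_symbol")
        if t["probe_id"].duplicated().any():
            raise MatrixError("duplicate probe ids in annotation")

    def symbol_of(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_symbol"].fillna("").astype(str)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProbeAnnotation":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(frame)


def read_expression_table(
    path: str | Path,
    design_path: str | Path,
    floor: float = DEFAULT_SIGNAL_FLOOR,
) -> tuple[ExpressionMatrix, Design]:
    """Read and cross-validate an expression TSV against its design.

    Columns of the returned matrix are reordered to the design's sample
    order, so downstream statistics are invariant to the column order of
    the file on disk. Any sample present in one file but not the other
    is an error naming the sample.
    """
    design = Design.read_tsv(design_path)
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.columns[0] != "probe_id":
        raise MatrixError(
            f"first column must be 'probe_id', found {raw.columns[0]!r}"
        )
    raw = raw.set_index("probe_id")
    matrix_samples = set(raw.columns)
    design_samples = set(design.sample_ids)
    missing = design_samples - matrix_samples
    if missing:
        raise MatrixError(f"design samples absent from matrix: {sorted(missing)}")
    extra = matrix_samples - design_samples
    if extra:
        raise MatrixError(f"matrix samples absent from design: {sorted(extra)}")
    raw = raw[design.sample_ids]
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            probe = raw.index[bad.to_numpy().argmax()]
            raise MatrixError(
                f"non-numeric cell at probe {probe!r}, sample {col!r}: "
                f"{raw.loc[probe, col]!r}"
            )
        if coerced.isna().any():
            probe = coerced.index[coerced.isna().to_numpy().argmax()]
            raise MatrixError(f"missing cell at probe {probe!r}, sample {col!r}")
        raw[col] = coerced
    matrix = ExpressionMatrix.floored(raw, floor=floor)
    return matrix, design


def strip_series_matrix(path: str | Path) -> pd.DataFrame:
    """Extract the signal table from a GEO series-matrix text file.

    Keeps only the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` and renames the ID column to
    ``probe_id``. Values are returned un-floored; pass the result to
    :meth:`ExpressionMatrix.floored`.
    """
    lines: list[str] = []
    inside = False
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if inside:
                lines.append(line)
    if not lines:
        raise MatrixError("no series-matrix table block found")
    frame = pd.read_csv(_io.StringIO("".join(lines)), sep="\t", dtype={0: str})
    frame = frame.rename(columns={frame.columns[0]: "probe_id"})
    frame["probe_id"] = frame["probe_id"].str.strip('"')
    return frame.set_index("probe_id")
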