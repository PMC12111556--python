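"""Core data containers: expression matrices, group designs, gene sets and
gene annotations, plus their plain-text (TSV / one-id-per-line) serialisation.

All tabular files are UTF-8, tab-delimited, '.' decimal.  Expression matrices
are stored genes-in-rows with the gene identifier in the first column and
sample identifiers in the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: Valid platform tags for an expression matrix.
PLATFORMS = ("bulk_log", "fpkm")

#: Ordinal immunohistochemistry levels, lowest to highest.
IHC_LEVELS = ("not_detected", "low", "medium", "high")

#: Staining intensity categories for ICC marker readouts.
STAIN_LEVELS = ("negative", "low", "high")


@dataclass
class ExpressionMatrix:
    """A gene x sample numeric matrix with a platform tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene ids, columns by unique sample ids.
    platform : str
        ``"bulk_log"`` for log2-scale intensities, ``"fpkm"`` for
        non-negative normalised single-cell counts.
    """

    values: pd.DataFrame
    platform: str = "bulk_log"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise InputError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dup[:5]}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample ids: {dup[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InputError("expression matrix contains non-finite values")
        if self.platform == "fpkm" and (arr < 0).any():
            raise InputError("fpkm matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, platform: str = "bulk_log") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, platform=platform)


@dataclass
class GroupDesign:
    """Sample -> group-label assignment (e.g. BT tumor vs BNT adjacent)."""

    labels: pd.Series  # index sample_id, values group label

    def __post_init__(self) -> None:
        if not isinstance(self.labels, pd.Series):
            self.labels = pd.Series(dict(self.labels))
        if self.labels.index.has_duplicates:
            raise InputError("duplicate sample ids in design")

    @property
    def groups(self) -> list[str]:
        return sorted(self.labels.unique())

    def samples(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])

    def validate_against(self, matrix: ExpressionMatrix, min_per_group: int = 2) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.labels.index]
        if missing:
            raise InputError(f"design lacks labels for samples: {missing[:5]}")
        counts = self.labels.loc[matrix.sample_ids].value_counts()
        small = counts[counts < min_per_group]
        if len(small):
            raise InputError(
                f"groups with fewer than {min_per_group} samples: {dict(small)}"
            )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"sample_id": self.labels.index, "group": self.labels.values})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(pd.Series(df["group"].values, index=df["sample_id"].values))


@dataclass
class GeneSet:
    """A named set of gene identifiers, serialisable one id per line."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.genes = frozenset(str(g) for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))

    def intersection(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}&{other.name}", self.genes & other.genes)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{g}\n" for g in sorted(self.genes)), encoding="utf-8")

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        lines = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()]
        return cls(name or Path(path).stem, frozenset(ln for ln in lines if ln))


class GeneAnnotation:
    """Per-gene curation flags and ordinal IHC levels.

    Columns: boolean ``membrane_db1``/``membrane_db2`` (plasma-membrane
    localisation per two protein databases), ``immune_db1``/``immune_db2``
    (expressed by immune cells), ``go_plasma_membrane`` (GO cellular-component
    flag), and ``ihc_levels`` — a tuple of ordinal levels from
    :data:`IHC_LEVELS`, one per annotated tumor sample.

    Genes missing from the table are treated as all-flags-false with IHC
    ``not_detected`` (conservative fail-closed filtering).
    """

    BOOL_COLS = ("membrane_db1", "membrane_db2", "immune_db1", "immune_db2", "go_plasma_membrane")

    def __init__(self, table: pd.DataFrame):
        if table.index.has_duplicates:
            raise InputError("duplicate gene ids in annotation table")
        for col in self.BOOL_COLS:
            if col not in table.columns:
                raise InputError(f"annotation table missing column {col!r}")
            table[col] = table[col].astype(bool)
        if "ihc_levels" not in table.columns:
            raise InputError("annotation table missing column 'ihc_levels'")
        for gene, levels in table["ihc_levels"].items():
            for lv in levels:
                if lv not in IHC_LEVELS:
                    raise InputError(f"gene {gene}: unknown IHC level {lv!r}")
        self.table = table

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def flag(self, gene: str, col: str) -> bool:
        if gene not in self.table.index:
            return False
        return bool(self.table.at[gene, col])

    def ihc_levels(self, gene: str) -> tuple[str, ...]:
        if gene not in self.table.index:
            return ()
        return tuple(self.table.at[gene, "ihc_levels"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["ihc_levels"] = out["ihc_levels"].map(lambda lv: ",".join(lv))
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df["ihc_levels"] = df["ihc_levels"].map(
            lambda s: tuple(s.split(",")) if isinstance(s, str) and s else ()
        )
        return cls(df)

    @classmethod
    def from_records(
        cls,
        genes: Sequence[str],
        membrane_db1: Iterable[bool],
        membrane_db2: Iterable[bool],
        immune_db1: Iterable[bool],
        immune_db2: Iterable[bool],
        go_plasma_membrane: Iterable[bool],
        ihc_levels: Iterable[tuple[str, ...]],
    ) -> "GeneAnnotation":
        df = pd.DataFrame(
            {
                "membrane_db1": list(membrane_db1),
                "membrane_db2": list(membrane_db2),
                "immune_db1": list(immune_db1),
                "immune_db2": list(immune_db2),
                "go_plasma_membrane": list(go_plasma_membrane),
                "ihc_levels": list(ihc_levels),
            },
            index=pd.Index([str(g) for g in genes], name="gene_id"),
        )
        return cls(df)


# ---------------------------------------------------------------------------
# Per-cell records (isolated cells on ScreenCell isolation supports)
# ---------------------------------------------------------------------------

#: Columns of a cell table, in serialisation order.
CELL_COLUMNS = (
    "cell_id",
    "subject_id",
    "support_id",
    "cohort",
    "panel",
    "diameter",
    "nc_ratio",
    "nuclear_irregular",
    "cd45_intensity",
    "cd45_homogeneous",
    "marker_stains",
)


def format_stains(stains: Mapping[str, str]) -> str:
    """Serialise a marker->level map as ``M1=high;M2=negative``."""
    return ";".join(f"{m}={lv}" for m, lv in sorted(stains.items()))


def parse_stains(text: str) -> dict[str, str]:
    """Inverse of :func:`format_stains`."""
    if not isinstance(text, str) or not text:
        return {}
    out: dict[str, str] = {}
    for tok in text.split(";"):
        marker, _, level = tok.partition("=")
        if level not in STAIN_LEVELS:
            raise InputError(f"unknown stain level {level!r} for marker {marker!r}")
        out[marker] = level
    return out


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check a cell table's schema and value ranges; returns the table."""
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise InputError(f"cell table missing columns: {missing}")
    if (cells["diameter"] <= 0).any():
        raise InputError("cell diameters must be positive")
    nc = cells["nc_ratio"]
    if ((nc < 0) | (nc > 1)).any():
        raise InputError("nc_ratio must lie in [0, 1]")
    bad = ~cells["cd45_intensity"].isin(("negative", "weak", "intense"))
    if bad.any():
        raise InputError(
            f"unknown cd45_intensity values: {sorted(cells.loc[bad, 'cd45_intensity'].unique())}"
        )
    return cells


def cells_to_tsv(cells: pd.DataFrame, path: str | Path) -> None:
    cells.loc[:, list(CELL_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.6g")


def cells_from_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"cell_id": str, "subject_id": str, "support_id": str},
        keep_default_na=False,
        na_values=[],
    )
    df["nuclear_irregular"] = df["nuclear_irregular"].astype(str).str.lower().isin(("true", "1"))
    df["cd45_homogeneous"] = df["cd45_homogeneous"].astype(str).str.lower().isin(("true", "1"))
    df["diameter"] = df["diameter"].astype(float)
    df["nc_ratio"] = df["nc_ratio"].astype(float)
    return validate_cells(df)
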