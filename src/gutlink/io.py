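"""Readers, writers and run configuration.

All tables are tab-delimited UTF-8 with a header row. Matrices carry
row ids in the first column; readers validate uniqueness, rectangular
shape and numeric cells, and report the offending id/line in errors.
Every writer's output round-trips bit-identically through the matching
reader (floats use full-precision decimal repr).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from gutlink.errors import InputError

__all__ = [
    "RunConfig",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_table_tsv",
    "read_metadata",
    "read_taxonomy",
    "read_newick",
]

METADATA_COLUMNS = ("mouse_id", "colonization", "diet")


def read_matrix_tsv(path: str | Path, orientation: str = "rows") -> pd.DataFrame:
    """Read an id-indexed numeric matrix (genes/taxa × samples).

    ``orientation='columns'`` transposes after reading (for tables
    stored samples × features). Duplicate ids, ragged rows, NaN or
    non-numeric cells raise :class:`InputError` with context.
    """
    path = Path(path)
    try:
        # round_trip parsing keeps written float reprs exact
        df = pd.read_csv(
            path, sep="\t", index_col=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate row ids {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate column ids {dup}")
    try:
        num = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise InputError(f"{path}: non-numeric cell ({exc})") from exc
    if num.isna().any().any():
        ii, jj = num.isna().to_numpy().nonzero()
        where = ", ".join(
            f"(row {num.index[i]!r}, column {num.columns[j]!r})"
            for i, j in list(zip(ii, jj))[:5]
        )
        raise InputError(f"{path}: NaN cells at {where}")
    if orientation == "columns":
        num = num.T
    elif orientation != "rows":
        raise InputError(f"unknown orientation {orientation!r}")
    return num


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write an id-indexed matrix as TSV with full-precision floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=None)
    return path


def read_table_tsv(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing input file: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = read_table_tsv(path, required=METADATA_COLUMNS)
    if meta["mouse_id"].duplicated().any():
        dup = meta.loc[meta["mouse_id"].duplicated(), "mouse_id"].tolist()
        raise InputError(f"{path}: duplicate mouse ids {dup}")
    bad = set(meta["colonization"]) - {"GF", "FMT"}
    if bad:
        raise InputError(f"{path}: unknown colonization labels {sorted(bad)}")
    return meta


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    return read_table_tsv(path, required=("taxon_id", "family", "species"))


def read_newick(path: str | Path) -> str:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing tree file: {path}")
    text = path.read_text().strip()
    if not text.endswith(";"):
        raise InputError(f"{path}: not a newick tree (no terminating semicolon)")
    return text


@dataclass
class RunConfig:
    """Pipeline run configuration (file paths, diet order, thresholds)."""

    outdir: str = "gutlink_out"
    metadata: str = ""
    growth: str = ""
    expression: dict[str, str] = field(default_factory=dict)  # tissue -> path
    abundance: str = ""
    taxonomy: str = ""
    tree: str = ""
    diets: list[str] = field(default_factory=list)
    rank: str = "species"
    deg_p: float = 0.05
    gene_r: float = 0.70
    taxon_r: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deg_p", "gene_r", "taxon_r"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InputError(f"threshold {name}={v} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def validate_diets(self, observed: list[str], source: str) -> None:
        """Check a table's diet labels against the declared diet order."""
        if self.diets and set(observed) - set(self.diets):
            extra = sorted(set(observed) - set(self.diets))
            raise InputError(f"{source}: diets {extra} not in configured diet order")
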