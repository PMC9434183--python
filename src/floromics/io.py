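"""Readers and writers for stage-resolved abundance tables and networks.

Two CSV dialects are accepted for abundance tables.  The *long* dialect is
canonical: one row per (compound, sample) cell with columns
``compound, stage, replicate, value`` and optionally ``class, fw, istd``.
The *wide* dialect (compounds as rows, ``<stage>_<replicate>`` sample
columns) is accepted because metabolomics exports commonly use it; it
carries no fresh-weight or internal-standard metadata, which then default
to 1.  Missing cells stay missing — an empty cell is never silently read
as zero, because absence and zero mean different things in these tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .networks import CorrelationNetwork

__all__ = [
    "StageProfileTable",
    "read_profile_table",
    "write_profile_table",
    "write_network",
]

#: Compound classes recognised in the study design.
COMPOUND_CLASSES = (
    "amino acid",
    "organic acid",
    "carbohydrate",
    "shikimate",
    "flavonoid",
    "glucosinolate",
    "polyamine",
    "hydroxycinnamate",
    "apocarotenoid",
    "hormone",
    "other",
)


@dataclass
class StageProfileTable:
    """Compound x sample abundance table with stage metadata.

    Attributes
    ----------
    values
        DataFrame indexed by compound id, columns a MultiIndex
        (stage, replicate); non-negative abundances, NaN for missing.
    classes
        Compound id -> compound class (defaults to "other").
    fw_mg
        Per-sample fresh weight in mg (positive).
    istd
        Per-sample internal-standard response (positive).
    normalized
        True once values have been divided by fw * istd.
    """

    values: pd.DataFrame
    classes: pd.Series = None
    fw_mg: pd.Series = None
    istd: pd.Series = None
    normalized: bool = False

    def __post_init__(self) -> None:
        cols = self.values.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError("values columns must be a (stage, replicate) MultiIndex")
        self.values.columns = cols.set_names(["stage", "replicate"])
        self.values.index = self.values.index.rename("compound")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate compounds: {dupes}")
        if cols.duplicated().any():
            raise ValueError(f"duplicate samples: {cols[cols.duplicated()].tolist()}")
        if self.classes is None:
            self.classes = pd.Series("other", index=self.values.index)
        self.classes = self.classes.reindex(self.values.index).fillna("other")
        if self.fw_mg is None:
            self.fw_mg = pd.Series(1.0, index=cols)
        if self.istd is None:
            self.istd = pd.Series(1.0, index=cols)
        self.fw_mg = self.fw_mg.reindex(cols).astype(float)
        self.istd = self.istd.reindex(cols).astype(float)
        for name, s in (("fw", self.fw_mg), ("istd", self.istd)):
            if s.isna().any() or (s <= 0).any():
                bad = s.index[s.isna() | (s <= 0)].tolist()
                raise ValueError(f"{name} must be positive for every sample; bad: {bad}")
        vals = self.values.to_numpy(dtype=float)
        if np.nan_to_num(vals, nan=0.0).min() < 0:
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative abundance at compound {self.values.index[r]!r}, "
                f"sample {tuple(cols[c])}"
            )

    # ------------------------------------------------------------------
    @property
    def stages(self) -> list:
        """Stage labels in column order, without duplicates."""
        return list(dict.fromkeys(self.values.columns.get_level_values("stage")))

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_long(self) -> pd.DataFrame:
        """Canonical long form: one row per cell (missing cells kept as NaN)."""
        long = (
            self.values.stack(["stage", "replicate"], future_stack=True)
            .rename("value")
            .reset_index()
        )
        long["class"] = long["compound"].map(self.classes)
        key = pd.MultiIndex.from_frame(long[["stage", "replicate"]])
        long["fw"] = self.fw_mg.reindex(key).to_numpy()
        long["istd"] = self.istd.reindex(key).to_numpy()
        return long[["compound", "class", "stage", "replicate", "value", "fw", "istd"]]

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "StageProfileTable":
        required = {"compound", "stage", "replicate", "value"}
        missing = required - set(long.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        key = ["compound", "stage", "replicate"]
        if long.duplicated(key).any():
            rows = long.index[long.duplicated(key)].tolist()
            raise ValueError(f"duplicate (compound, sample) rows at index {rows}")
        values = long.pivot(index="compound", columns=["stage", "replicate"], values="value")
        values = values.reindex(pd.unique(long["compound"]))
        order = pd.MultiIndex.from_frame(
            long[["stage", "replicate"]].drop_duplicates(), names=["stage", "replicate"]
        )
        values = values.reindex(columns=order)
        classes = None
        if "class" in long.columns:
            classes = long.drop_duplicates("compound").set_index("compound")["class"]
        per_sample = long.drop_duplicates(["stage", "replicate"]).set_index(["stage", "replicate"])
        fw = per_sample["fw"] if "fw" in long.columns else None
        istd = per_sample["istd"] if "istd" in long.columns else None
        return cls(values, classes=classes, fw_mg=fw, istd=istd)


def _split_wide_column(name: str) -> tuple[str, str]:
    if "_" not in name:
        raise ValueError(
            f"wide sample column {name!r} is not of the form <stage>_<replicate>"
        )
    stage, rep = name.rsplit("_", 1)
    return stage, rep


def read_profile_table(path: str | Path, format: str = "long") -> StageProfileTable:
    """Read an abundance table from CSV/TSV.

    Parameters
    ----------
    path
        Input file; ``.tsv`` is read tab-separated.
    format
        ``"long"`` (canonical, with metadata columns) or ``"wide"``
        (compound rows x ``<stage>_<replicate>`` columns).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if format == "long":
        return StageProfileTable.from_long(df)
    if format == "wide":
        if "compound" not in df.columns:
            raise ValueError("wide table must have a 'compound' column")
        df = df.set_index("compound")
        classes = None
        if "class" in df.columns:
            classes = df.pop("class")
        pairs = [_split_wide_column(c) for c in df.columns]
        df.columns = pd.MultiIndex.from_tuples(pairs, names=["stage", "replicate"])
        return StageProfileTable(df.astype(float), classes=classes)
    raise ValueError(f"unknown format {format!r}; expected 'wide' or 'long'")


def write_profile_table(table: StageProfileTable, path: str | Path, format: str = "long") -> None:
    """Write a table in the long (canonical) or wide dialect."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if format == "long":
        table.to_long().to_csv(path, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL)
    elif format == "wide":
        wide = table.values.copy()
        wide.columns = [f"{s}_{r}" for s, r in wide.columns]
        wide.insert(0, "class", table.classes)
        wide.to_csv(path, sep=sep, index_label="compound")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_network(network: "CorrelationNetwork", path: str | Path, format: str = "graphml") -> None:
    """Export a correlation network as GraphML or an edge-list CSV.

    GraphML keeps typed node attributes (class, degree, betweenness) and the
    edge weight r; the edge CSV (columns source, target, r, p) is provided
    for spreadsheet use.
    """
    import networkx as nx

    path = Path(path)
    g = network.graph
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_csv":
        rows = [
            {"source": u, "target": v, "r": d.get("r"), "p": d.get("p")}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "r", "p"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'graphml' or 'edge_csv'")
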