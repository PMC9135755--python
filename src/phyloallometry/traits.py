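"""Trait tables: species- or individual-level observations of named traits.

A :class:`TraitTable` is a thin, validated wrapper around a pandas
DataFrame. Columns hold trait values (raw or log-transformed, tracked per
column), one column holds the species label, and the index is the
observation id. Log transformation happens on read so downstream models
always see the scale they expect; the log base is recorded because
intercepts (elevations) depend on it while slopes and test statistics do
not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TraitTable:
    data: pd.DataFrame
    species_col: str = "species"
    log_cols: tuple = ()
    log_base: float = 10.0

    def __post_init__(self):
        if self.species_col not in self.data.columns:
            raise KeyError(f"species column {self.species_col!r} not in table")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate observation ids: {dups}")
        self.log_cols = tuple(self.log_cols)
        for col in self.log_cols:
            vals = self.data[col].dropna()
            if not np.isfinite(vals).all():
                raise ValueError(f"non-finite value in log column {col!r}")

    # -- accessors -----------------------------------------------------

    @property
    def species(self) -> pd.Series:
        return self.data[self.species_col]

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def trait_columns(self) -> list:
        return [c for c in self.data.columns if c != self.species_col]

    def is_logged(self, col: str) -> bool:
        return col in self.log_cols

    def column(self, col: str) -> pd.Series:
        if col not in self.data.columns:
            raise KeyError(f"column {col!r} not in table "
                           f"(have {self.trait_columns()})")
        return self.data[col]

    def species_means(self, cols=None) -> pd.DataFrame:
        cols = list(cols) if cols is not None else self.trait_columns()
        return self.data.groupby(self.species_col)[cols].mean()

    # -- manipulation --------------------------------------------------

    def restrict_species(self, species) -> "TraitTable":
        keep = self.data[self.species_col].isin(set(species))
        return TraitTable(self.data.loc[keep].copy(), self.species_col,
                          self.log_cols, self.log_base)

    def complete_rows(self, cols) -> "TraitTable":
        """Drop rows missing any of ``cols`` (per-model exclusion)."""
        sub = self.data.dropna(subset=list(cols))
        n_dropped = len(self.data) - len(sub)
        if n_dropped:
            logger.info("dropped %d rows with missing values in %s",
                        n_dropped, list(cols))
        return TraitTable(sub.copy(), self.species_col, self.log_cols,
                          self.log_base)

    def with_column(self, name: str, values, logged: bool = False) -> "TraitTable":
        data = self.data.copy()
        data[name] = values
        log_cols = self.log_cols + (name,) if logged else self.log_cols
        return TraitTable(data, self.species_col, log_cols, self.log_base)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="observation_id")

    def __repr__(self) -> str:
        return (f"TraitTable(n_obs={self.n_obs}, "
                f"n_species={self.species.nunique()}, "
                f"traits={self.trait_columns()})")


def read_trait_table(path, species_col: str = "species", log_cols=(),
                     sep=None, log_base: float = 10.0) -> TraitTable:
    """Read a delimited trait table, log-transforming ``log_cols`` on read.

    Parameters
    ----------
    path : path-like
        CSV or TSV file with a header row.
    species_col : str
        Column holding species labels.
    log_cols : sequence of str
        Columns to log-transform (base ``log_base``). Values must be > 0;
        a non-positive value raises with the offending row and column named.
    sep : str, optional
        Field delimiter; inferred from the file when omitted.

    Rows with missing values are retained (models drop them per-fit).
    """
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    if species_col not in df.columns:
        raise KeyError(f"species column {species_col!r} not found in {path}")
    if "observation_id" in df.columns:
        df = df.set_index("observation_id")
    for col in log_cols:
        if col not in df.columns:
            raise KeyError(f"log column {col!r} not found in {path}")
        vals = df[col]
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-positive value in column {col!r} at row {row}; "
                "cannot log-transform")
        df[col] = np.log(vals) / math.log(log_base)
    return TraitTable(df, species_col=species_col, log_cols=tuple(log_cols),
                      log_base=log_base)


def align_taxa(tree, table: TraitTable):
    """Prune tree and table to their shared species set.

    Returns ``(tree, table, dropped)`` where ``dropped`` maps
    ``"tree"``/``"table"`` to the labels removed from each side. Raises if
    the intersection is empty. Idempotent.
    """
    tree_taxa = set(tree.tip_labels)
    table_taxa = set(table.species.dropna())
    shared = tree_taxa & table_taxa
    if not shared:
        raise ValueError("no species shared between tree and table")
    dropped = {"tree": sorted(tree_taxa - shared),
               "table": sorted(table_taxa - shared)}
    if dropped["tree"] or dropped["table"]:
        logger.warning("align_taxa dropped %d tree tips and %d table species",
                       len(dropped["tree"]), len(dropped["table"]))
    out_tree = tree.prune_to(shared) if dropped["tree"] else tree
    out_table = table.restrict_species(shared) if dropped["table"] else table
    return out_tree, out_table, dropped


def subset_clade(tree, table: TraitTable, tip_set):
    """Restrict analysis to the clade spanned by the MRCA of ``tip_set``."""
    sub_tree = tree.subset_clade(tip_set)
    sub_table = table.restrict_species(sub_tree.tip_labels)
    return sub_tree, sub_table
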