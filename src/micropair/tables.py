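"""Core data containers: relative-abundance tables and cohort metadata.

The central object is :class:`AbundanceTable`, a samples x taxa matrix of
relative abundances on the simplex, with taxa identified by pipe-delimited
taxonomy lineages (``k__Bacteria|...|s__Some_species``).  Cohort metadata
carries the case/control label, demographics, and a biomarker panel that
includes fecal calprotectin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "CohortMetadata", "RANKS", "RANK_PREFIXES"]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__")))

#: tolerance inside which a row counts as already normalized; rows within
#: this band are left untouched so that write->read->write is byte-stable.
ROW_SUM_TOL = 1e-6


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = sorted(seen[seen.duplicated()].unique())
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class AbundanceTable:
    """Samples x taxa relative-abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample ID, columns by taxonomy lineage string,
        values non-negative proportions.  Each row must sum to 1 within
        ``1e-6`` (use :meth:`normalized` to renormalize arbitrary
        non-negative data).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample identifiers")
        _check_unique(self.data.columns, "taxa identifiers")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative abundance at sample "
                f"{self.data.index[i]!r}, taxon {self.data.columns[j]!r}"
            )
        sums = values.sum(axis=1)
        zero = sums == 0
        if zero.any():
            bad = list(self.data.index[zero])
            raise ValueError(f"all-zero sample(s): {bad}")
        if np.max(np.abs(sums - 1.0)) > ROW_SUM_TOL:
            raise ValueError(
                "rows do not sum to 1 within tolerance; call "
                "AbundanceTable.normalized(data) to renormalize"
            )

    @classmethod
    def normalized(cls, data: pd.DataFrame) -> "AbundanceTable":
        """Build a table, renormalizing rows that are off the simplex.

        Rows already summing to 1 within ``1e-6`` are left bit-identical,
        which keeps file round-trips stable.
        """
        values = data.to_numpy(dtype=float)
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {data.index[i]!r}, "
                f"taxon {data.columns[j]!r}"
            )
        sums = values.sum(axis=1)
        if np.any(sums == 0):
            bad = list(data.index[sums == 0])
            raise ValueError(f"all-zero sample(s): {bad}")
        off = np.abs(sums - 1.0) > ROW_SUM_TOL
        if off.any():
            values = values.copy()
            values[off] = values[off] / sums[off, None]
            data = pd.DataFrame(values, index=data.index, columns=data.columns)
        return cls(data)

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[list(sample_ids)])

    def subset_taxa(self, taxa, renormalize: bool = False) -> "AbundanceTable":
        missing = [t for t in taxa if t not in self.data.columns]
        if missing:
            raise KeyError(f"taxa not in table: {missing}")
        sub = self.data[list(taxa)]
        if renormalize:
            return AbundanceTable.normalized(sub)
        return AbundanceTable(sub)


GROUP_LABELS = ("case", "control")

#: reserved biomarker column name for fecal calprotectin (µg/g)
CALPROTECTIN = "fecal_calprotectin"

_REQUIRED_META = ("sample_id", "group")
_DEMOGRAPHICS = ("age", "sex", "bmi")


@dataclass
class CohortMetadata:
    """Per-sample group label, demographics and biomarker panel.

    ``frame`` is indexed by sample ID and holds ``group`` (case/control),
    optional ``age``/``sex``/``bmi``, and any number of numeric biomarker
    columns.  Missing biomarker values stay as NaN — they are excluded
    pairwise by downstream association tests, never imputed.
    """

    frame: pd.DataFrame
    biomarker_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample identifiers")
        if "group" not in self.frame.columns:
            raise ValueError("metadata requires a 'group' column")
        bad = set(self.frame["group"].unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(
                f"unknown group label(s) {sorted(bad)}; expected {GROUP_LABELS}"
            )
        if not self.biomarker_columns:
            known = set(_DEMOGRAPHICS) | {"group"}
            self.biomarker_columns = [
                c for c in self.frame.columns
                if c not in known and pd.api.types.is_numeric_dtype(self.frame[c])
            ]
        if CALPROTECTIN in self.frame.columns:
            calpro = self.frame[CALPROTECTIN]
            if (calpro.dropna() < 0).any():
                raise ValueError("calprotectin values must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    @property
    def cases(self) -> list[str]:
        return list(self.frame.index[self.frame["group"] == "case"])

    @property
    def controls(self) -> list[str]:
        return list(self.frame.index[self.frame["group"] == "control"])

    def biomarker(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"biomarker {name!r} not in metadata")
        return self.frame[name]

    def check_alignment(self, table: AbundanceTable) -> None:
        """Every metadata sample must be present in the abundance table."""
        missing = [s for s in self.frame.index if s not in table.data.index]
        if missing:
            raise ValueError(f"metadata samples absent from table: {missing}")
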