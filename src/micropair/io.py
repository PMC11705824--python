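"""Readers and writers for taxonomic-profile and metadata TSV files.

Profile files follow the merged-MetaPhlAn convention: first column
``clade_name`` holds pipe-delimited taxonomy lineages, remaining columns
are sample IDs, cell values are relative abundances in percent (the
profiler's native unit) or proportions.  Floats are written with 10
significant digits so that read -> write -> read is the identity on
files this package produced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    CohortMetadata,
    GROUP_LABELS,
    RANK_PREFIXES,
)

__all__ = [
    "read_profile_table",
    "write_profile_table",
    "select_rank",
    "read_metadata",
    "write_metadata",
]

_FLOAT_FMT = "%.10g"


def _detect_scale(sample_sums: np.ndarray) -> float:
    """Return the divisor mapping values to proportions (auto mode).

    Median per-sample total in [50, 150] is treated as percent, in
    [0.5, 1.5] as proportion; anything else is refused loudly.
    """
    med = float(np.median(sample_sums))
    if 50.0 <= med <= 150.0:
        return 100.0
    if 0.5 <= med <= 1.5:
        return 1.0
    raise ValueError(
        f"cannot auto-detect value scale: median sample sum {med:.4g} is "
        "neither percent-like ([50, 150]) nor proportion-like ([0.5, 1.5])"
    )


def read_profile_table(path, value_scale: str = "auto") -> AbundanceTable:
    """Read a merged taxonomic-profile TSV into an :class:`AbundanceTable`.

    Parameters
    ----------
    path : path-like
        TSV with a ``clade_name`` (or first) column of taxonomy lineages
        and one numeric column per sample.
    value_scale : {"auto", "percent", "proportion"}
        How cell values relate to proportions.  ``auto`` detects percent
        vs proportion from the median per-sample total and errors when
        neither fits.

    Returns
    -------
    AbundanceTable
        Values as proportions; samples whose totals deviate from 1 by
        more than 1e-6 are renormalized.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.shape[1] < 1:
        raise ValueError(f"{path}: no sample columns found")
    raw.index = raw.index.astype(str)
    try:
        values = raw.to_numpy(dtype=float)
    except ValueError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"{path}: non-numeric abundance cell ({exc})") from exc
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value at taxon {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate taxa: {dups}")

    # file layout is taxa x samples; the in-memory layout is samples x taxa
    sums = values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        raise ValueError(f"{path}: all-zero sample(s): {list(raw.columns[zero])}")
    if value_scale == "auto":
        divisor = _detect_scale(sums)
    elif value_scale == "percent":
        divisor = 100.0
    elif value_scale == "proportion":
        divisor = 1.0
    else:
        raise ValueError(f"unknown value_scale {value_scale!r}")
    data = pd.DataFrame(
        values.T / divisor, index=raw.columns.astype(str), columns=raw.index
    )
    return AbundanceTable.normalized(data)


def write_profile_table(table: AbundanceTable, path) -> None:
    """Write a profile TSV (taxa rows, sample columns, proportions)."""
    out = table.data.T
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _lineage_depth_prefix(lineage: str) -> str:
    """Prefix (``k__`` .. ``s__``) of the deepest rank in a lineage."""
    last = lineage.rsplit("|", 1)[-1]
    return last[:3]


def select_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Keep only taxa whose deepest lineage rank equals ``rank``.

    Leaves are selected, not aggregated: a genus-level leaf is dropped
    when species are requested even if species below it exist elsewhere.
    Rows are renormalized over the surviving taxa.
    """
    if rank not in RANK_PREFIXES:
        raise ValueError(f"unknown rank {rank!r}; expected one of {list(RANK_PREFIXES)}")
    prefix = RANK_PREFIXES[rank]
    keep = [t for t in table.taxa if _lineage_depth_prefix(t) == prefix]
    if not keep:
        raise ValueError(f"no taxa terminate at rank {rank!r}")
    return table.subset_taxa(keep, renormalize=True)


_META_LEADING = ["group", "age", "sex", "bmi"]


def read_metadata(path) -> CohortMetadata:
    """Read a cohort metadata TSV.

    Requires ``sample_id`` and ``group`` columns; ``group`` must be
    ``case`` or ``control``.  Any numeric column beyond the demographics
    is kept in the biomarker panel; blank cells become NaN and are
    flagged missing rather than dropped.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group"):
        if col not in frame.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    frame = frame.set_index("sample_id")
    bad = set(frame["group"].dropna().unique()) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"{path}: unknown group label(s) {sorted(bad)}")
    return CohortMetadata(frame)


def write_metadata(meta: CohortMetadata, path) -> None:
    """Write metadata TSV with the canonical column order."""
    cols = [c for c in _META_LEADING if c in meta.frame.columns]
    cols += [c for c in meta.frame.columns if c not in cols]
    out = meta.frame[cols].copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
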