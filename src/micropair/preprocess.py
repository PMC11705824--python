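"""Rare-taxon filtering, compositional zero replacement, and the CLR.

Relative abundances are compositional: only ratios carry information, so
Euclidean methods (PCA, distance-based matching) operate on centered
log-ratio (CLR) coordinates.  Zeros must be replaced before taking logs;
we use deterministic multiplicative replacement, which preserves the
rank order of nonzero values within each sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AbundanceTable

__all__ = [
    "FilterRule",
    "ClrMatrix",
    "filter_rare_taxa",
    "replace_zeros",
    "clr_transform",
]


@dataclass(frozen=True)
class FilterRule:
    """Removal rule for rare, low-abundance taxa.

    A taxon is discarded iff it is observed in at most ``max_prevalence``
    donors AND its maximum relative abundance across samples is below
    ``min_abundance``.  Both clauses must hold (the conservative reading);
    either threshold is configurable.
    """

    max_prevalence: int = 3
    min_abundance: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_prevalence < 0:
            raise ValueError("max_prevalence must be >= 0")
        if not (0.0 < self.min_abundance < 1.0):
            raise ValueError("min_abundance must be in (0, 1)")


@dataclass
class ClrMatrix:
    """Samples x taxa matrix of centered log-ratio coordinates.

    Every row sums to zero (within 1e-9): the CLR maps the simplex onto
    the zero-sum hyperplane of R^K.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.to_numpy(dtype=float).sum(axis=1)
        if np.max(np.abs(sums)) > 1e-9:
            raise ValueError("CLR rows must sum to 0 within 1e-9")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def filter_report(table: AbundanceTable, rule: FilterRule) -> pd.DataFrame:
    """Per-taxon filter diagnostics: prevalence, max abundance, clauses."""
    values = table.values
    prevalence = (values > 0).sum(axis=0)
    max_abund = values.max(axis=0)
    rare = prevalence <= rule.max_prevalence
    low = max_abund < rule.min_abundance
    return pd.DataFrame(
        {
            "prevalence": prevalence,
            "max_abundance": max_abund,
            "rare_clause": rare,
            "low_abundance_clause": low,
            "removed": rare & low,
        },
        index=pd.Index(table.taxa, name="taxon"),
    )


def filter_rare_taxa(
    table: AbundanceTable, rule: FilterRule = FilterRule()
) -> tuple[AbundanceTable, list[str]]:
    """Drop taxa that are both rare and low-abundance.

    Returns the filtered (renormalized) table and the list of removed
    taxa for reporting.  Raises if the rule would remove every taxon.
    """
    report = filter_report(table, rule)
    removed = list(report.index[report["removed"]])
    if len(removed) == table.n_taxa:
        raise ValueError("filter rule removes every taxon")
    kept = [t for t in table.taxa if t not in set(removed)]
    return table.subset_taxa(kept, renormalize=True), removed


def replace_zeros(table: AbundanceTable, delta: float | str = "auto") -> AbundanceTable:
    """Multiplicative zero replacement on the simplex.

    Zeros become ``delta``; nonzero entries in a sample with ``z`` zeros
    are scaled by ``1 - z * delta`` so the row still sums to 1.  With
    ``delta="auto"`` the replacement value is 0.65 x the smallest nonzero
    proportion in the whole table, keeping imputed values strictly below
    every observed one.
    """
    values = table.values
    zeros = values == 0
    if not zeros.any():
        return table
    min_nonzero = values[values > 0].min()
    if delta == "auto":
        delta_val = 0.65 * float(min_nonzero)
    else:
        delta_val = float(delta)
        if delta_val >= min_nonzero:
            raise ValueError(
                f"delta {delta_val:g} must be below the smallest nonzero "
                f"proportion {min_nonzero:g}"
            )
    if delta_val <= 0:
        raise ValueError("delta must be positive")
    out = values.copy()
    n_zero = zeros.sum(axis=1)
    scale = 1.0 - n_zero * delta_val
    if np.any(scale <= 0):
        raise ValueError("delta too large: replacement mass exceeds 1 in a sample")
    out *= scale[:, None]
    out[zeros] = delta_val
    return AbundanceTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    )


def clr_transform(table: AbundanceTable) -> ClrMatrix:
    """Centered log-ratio transform: ln x_j minus the sample mean of ln x.

    Requires strictly positive values; run :func:`replace_zeros` first.
    Scale-invariant: clr(c * x) == clr(x) for any c > 0.
    """
    values = table.values
    if np.any(values <= 0):
        raise ValueError(
            "CLR requires strictly positive values; apply replace_zeros first"
        )
    logs = np.log(values)
    centered = logs - logs.mean(axis=1, keepdims=True)
    # re-center exactly so downstream zero-sum assertions hold at 1e-9
    centered -= centered.mean(axis=1, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(centered, index=table.data.index, columns=table.data.columns)
    )
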