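"""Case-control matching in PC space and paired differential abundance.

Gut microbiomes vary far more between individuals than between cases and
controls, so an unpaired test is underpowered.  Pairing each case with
its most similar control (nearest neighbor in the selected principal
component space) cancels the shared inter-individual background; a
Wilcoxon signed-rank test on within-pair abundance differences then
isolates disease-associated shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ClrMatrix
from .tables import AbundanceTable, CohortMetadata

__all__ = [
    "MatchedPairSet",
    "match_nearest_neighbor",
    "wilcoxon_signed_rank",
    "paired_da",
    "benjamini_hochberg",
]


@dataclass
class MatchedPairSet:
    """Injective case -> control pairing with matching distances.

    ``pairs`` lists (case_id, control_id, euclidean_distance) in the
    order pairs were formed (tightest first); ``unmatched_cases`` are
    cases left over when controls ran out.
    """

    pairs: list[tuple[str, str, float]]
    unmatched_cases: list[str]
    k_components: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def case_ids(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [p[1] for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["case_id", "control_id", "distance"]
        ).assign(rank_of_formation=lambda d: np.arange(1, len(d) + 1))


def match_nearest_neighbor(
    scores: pd.DataFrame, meta: CohortMetadata, k: int | None = None
) -> MatchedPairSet:
    """Greedy nearest-neighbor matching without replacement.

    Pairs are formed tightest-first: at each step the globally closest
    remaining (case, control) pair over the first ``k`` score dimensions
    is fixed, the control is retired, and the process repeats until a
    group is exhausted.  Ties break by case ID then control ID, so the
    result is deterministic for a fixed input.

    Parameters
    ----------
    scores : DataFrame
        Sample x component PC scores (rows indexed by sample ID).
    meta : CohortMetadata
        Supplies the case/control labels.
    k : int, optional
        Number of leading score columns to use; default all columns.
    """
    if k is None:
        k = scores.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > scores.shape[1]:
        raise ValueError(f"k={k} exceeds available components ({scores.shape[1]})")
    cases = [s for s in meta.cases if s in scores.index]
    controls = [s for s in meta.controls if s in scores.index]
    if not controls:
        raise ValueError("no controls available for matching")
    if not cases:
        raise ValueError("no cases available for matching")
    # sort IDs so lexicographic tie-breaking is independent of input order
    cases = sorted(cases)
    controls = sorted(controls)
    xc = scores.loc[cases].iloc[:, :k].to_numpy(dtype=float)
    xh = scores.loc[controls].iloc[:, :k].to_numpy(dtype=float)
    dist = np.sqrt(((xc[:, None, :] - xh[None, :, :]) ** 2).sum(axis=2))

    case_free = np.ones(len(cases), dtype=bool)
    ctrl_free = np.ones(len(controls), dtype=bool)
    pairs: list[tuple[str, str, float]] = []
    n_pairs = min(len(cases), len(controls))
    masked = dist.copy()
    for _ in range(n_pairs):
        sub = np.where(
            case_free[:, None] & ctrl_free[None, :], masked, np.inf
        )
        # argmin scans row-major: ties resolve to smallest case index,
        # then smallest control index (IDs are sorted above)
        flat = int(np.argmin(sub))
        i, j = divmod(flat, sub.shape[1])
        pairs.append((cases[i], controls[j], float(dist[i, j])))
        case_free[i] = False
        ctrl_free[j] = False
    unmatched = [c for c, free in zip(cases, case_free) if free]
    return MatchedPairSet(pairs=pairs, unmatched_cases=unmatched, k_components=k)


@dataclass
class SignedRankResult:
    w: float
    p: float
    n_used: int
    degenerate: bool = False


def wilcoxon_signed_rank(diffs) -> SignedRankResult:
    """Wilcoxon signed-rank test on per-pair differences, two-sided.

    Zero differences are dropped (the standard convention).  The p-value
    is exact (full sign-pattern enumeration) when at most 25 nonzero
    differences remain and their magnitudes are tie-free; otherwise the
    normal approximation with tie and continuity corrections is used.
    With no nonzero differences the result is flagged degenerate and the
    p-value is NaN (undefined, not 1).
    """
    diffs = np.asarray(diffs, dtype=float)
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return SignedRankResult(w=np.nan, p=np.nan, n_used=0, degenerate=True)
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        nz, alternative="two-sided", method=method, correction=(method == "approx")
    )
    # scipy reports min(W+, W-); convert to the sum of positive ranks
    ranks = stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    return SignedRankResult(w=w_pos, p=float(res.pvalue), n_used=int(nz.size))


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_da(
    table: AbundanceTable,
    pairs: MatchedPairSet,
    clr: ClrMatrix | None = None,
    report_p: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon paired differential abundance across matched pairs.

    For each taxon the within-pair differences abundance(case) -
    abundance(control) are tested with the Wilcoxon signed-rank test;
    q-values are Benjamini-Hochberg across all non-degenerate taxa.
    Passing ``clr`` switches the differences to CLR coordinates.

    Returns a DataFrame indexed by taxon with columns ``n_pairs_used``,
    ``n_case_greater``, ``W``, ``p``, ``q``, ``direction`` and
    ``degenerate``.  ``direction`` is set only for taxa with
    p <= ``report_p``.
    """
    source = clr.data if clr is not None else table.data
    missing = [
        s
        for s in set(pairs.case_ids) | set(pairs.control_ids)
        if s not in source.index
    ]
    if missing:
        raise ValueError(f"pair references samples missing from table: {sorted(missing)}")
    case_m = source.loc[pairs.case_ids].to_numpy(dtype=float)
    ctrl_m = source.loc[pairs.control_ids].to_numpy(dtype=float)
    diffs = case_m - ctrl_m

    rows = []
    for j, taxon in enumerate(source.columns):
        d = diffs[:, j]
        res = wilcoxon_signed_rank(d)
        rows.append(
            {
                "taxon": taxon,
                "n_pairs_used": res.n_used,
                "n_case_greater": int((d > 0).sum()),
                "W": res.w,
                "p": res.p,
                "degenerate": res.degenerate,
                "median_diff": float(np.median(d)),
            }
        )
    out = pd.DataFrame(rows).set_index("taxon")
    tested = ~out["degenerate"]
    q = np.full(len(out), np.nan)
    q[tested.to_numpy()] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    direction = np.where(out["median_diff"] > 0, "case-enriched", "control-enriched")
    # at the report threshold the median difference sign names the winner;
    # fall back to the pair-count sign when the median is exactly zero
    fallback = np.where(
        out["n_case_greater"] * 2 > out["n_pairs_used"],
        "case-enriched",
        "control-enriched",
    )
    direction = np.where(out["median_diff"] == 0, fallback, direction)
    out["direction"] = np.where(
        tested & (out["p"] <= report_p), direction, None
    )
    return out.drop(columns="median_diff")
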