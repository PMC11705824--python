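"""Alpha/beta diversity, group comparisons, and PCA of CLR coordinates.

Diversity runs on the unfiltered table (rare taxa contribute to Shannon
and Bray-Curtis); ordination runs on CLR coordinates of the filtered,
zero-replaced table.  Component selection at a cumulative
explained-variance target defines the Euclidean space in which matched
pairs are later formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .preprocess import ClrMatrix
from .tables import AbundanceTable, CohortMetadata

__all__ = [
    "DiversityResult",
    "Ordination",
    "shannon",
    "bray_curtis",
    "ks_two_sample",
    "compare_group_diversity",
    "pca",
    "select_components",
]


def shannon(table: AbundanceTable) -> pd.Series:
    """Shannon index H = -sum p ln p per sample, in nats (0 ln 0 = 0)."""
    values = table.values
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(values > 0, values * np.log(values), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.data.index, name="shannon")


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    dm = squareform(pdist(table.values, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.data.index, columns=table.data.index)


def _ks_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided KS for tie-free samples by lattice-path counting.

    Walk the pooled order as a path on the (m, n) grid; the statistic is
    max |i*n - j*m| / (m*n), an integer criterion, so the permutation
    p-value P(D >= d_obs) is the exact fraction of C(m+n, m) orderings
    whose path ever reaches that deviation (counted with big integers).
    """
    m, n = a.size, b.size
    order = np.argsort(np.concatenate([a, b]), kind="stable")
    is_a = order < m
    i = j = 0
    c_obs = 0
    for flag in is_a:
        if flag:
            i += 1
        else:
            j += 1
        c_obs = max(c_obs, abs(i * n - j * m))
    # count paths that always stay strictly below the observed deviation
    inside = [[0] * (n + 1) for _ in range(m + 1)]
    inside[0][0] = 1
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            if abs(i * n - j * m) >= c_obs:
                continue
            inside[i][j] = (inside[i - 1][j] if i else 0) + (
                inside[i][j - 1] if j else 0
            )
    total = math.comb(m + n, m)
    p = 1.0 - inside[m][n] / total
    return c_obs / (m * n), min(max(p, 0.0), 1.0)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Exact p (permutation distribution, lattice-path counting) when
    m*n <= 10^4 and the pooled sample has no ties; the asymptotic
    distribution otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size * b.size <= 10_000 and no_ties:
        return _ks_exact(a, b)
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class DiversityResult:
    """Per-sample Shannon H and the pairwise Bray-Curtis matrix."""

    shannon: pd.Series
    bray_curtis: pd.DataFrame


def diversity(table: AbundanceTable) -> DiversityResult:
    return DiversityResult(shannon=shannon(table), bray_curtis=bray_curtis(table))


def _within_group_dissimilarities(dm: pd.DataFrame, ids: list[str]) -> np.ndarray:
    sub = dm.loc[ids, ids].to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    return sub[iu]


def compare_group_diversity(div: DiversityResult, meta: CohortMetadata) -> dict:
    """KS comparison of diversity distributions between cases and controls.

    Alpha: KS on per-sample Shannon H.  Beta: KS on the distributions of
    within-case vs within-control Bray-Curtis dissimilarities (our
    operationalization of a distribution-level beta comparison).
    """
    cases, controls = meta.cases, meta.controls
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("each group needs at least 2 samples")
    h = div.shannon
    d_alpha, p_alpha = ks_two_sample(h.loc[cases], h.loc[controls])
    beta_case = _within_group_dissimilarities(div.bray_curtis, cases)
    beta_ctrl = _within_group_dissimilarities(div.bray_curtis, controls)
    d_beta, p_beta = ks_two_sample(beta_case, beta_ctrl)
    return {
        "alpha": {"D": d_alpha, "p": p_alpha, "test": "ks_two_sample"},
        "beta": {
            "D": d_beta,
            "p": p_beta,
            "test": "ks_two_sample_within_group_bray_curtis",
        },
    }


@dataclass
class Ordination:
    """PCA scores, loadings, and explained-variance ratios.

    ``scores`` is samples x components, ``loadings`` taxa x components;
    ``evr`` sums to 1.  ``k_selected``/``cum_evr_at_k`` are filled in by
    :func:`select_components`.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    evr: np.ndarray
    k_selected: int | None = None
    cum_evr_at_k: float | None = None

    def selected_scores(self) -> pd.DataFrame:
        if self.k_selected is None:
            raise ValueError("run select_components first")
        return self.scores.iloc[:, : self.k_selected]


def pca(clr: ClrMatrix) -> Ordination:
    """PCA by SVD of the column-centered CLR matrix.

    Signs are fixed so each component's largest-magnitude loading is
    positive, making scores (and hence matching distances) reproducible
    across platforms.
    """
    x = clr.values
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 taxa")
    centered = x - x.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("matrix has no variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    evr = s**2 / np.sum(s**2)
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return Ordination(
        scores=pd.DataFrame(scores, index=clr.data.index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=clr.data.columns, columns=comp_names),
        evr=evr,
    )


def select_components(ord_: Ordination, target_cum_evr: float = 0.70) -> int:
    """Smallest k whose cumulative explained variance reaches the target.

    k is capped at n_samples - 1 (the rank bound of centered data).  The
    selection is recorded on the Ordination and returned.
    """
    if not (0.0 < target_cum_evr <= 1.0):
        raise ValueError("target_cum_evr must be in (0, 1]")
    cum = np.cumsum(ord_.evr)
    k_max = min(len(cum), ord_.scores.shape[0] - 1)
    reached = np.nonzero(cum >= target_cum_evr - 1e-12)[0]
    k = int(reached[0]) + 1 if reached.size else len(cum)
    k = max(1, min(k, k_max))
    ord_.k_selected = k
    ord_.cum_evr_at_k = float(cum[k - 1])
    return k
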