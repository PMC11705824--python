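"""Host-biomarker association: calprotectin flags, per-taxon linear
models, Kendall correlations, and RDA-based taxon ranking.

Fecal calprotectin above 35 µg/g is treated as operationally elevated —
a threshold near the lower bound used to exclude inflammatory bowel
disease and within the upper range of healthy variation.  Candidate taxa
are related to biomarkers via MaAsLin-style linear models (total-sum
scaled, log-transformed abundances, BH-corrected at 10% FDR), tie-aware
Kendall correlations, and a single-constraint redundancy analysis that
ranks taxa by their contribution to biomarker-associated variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .matching import benjamini_hochberg
from .preprocess import ClrMatrix
from .tables import AbundanceTable, CohortMetadata, CALPROTECTIN

__all__ = [
    "BiomarkerPanel",
    "RdaRanking",
    "classify_calprotectin",
    "taxon_biomarker_glm",
    "kendall_matrix",
    "rda_rank",
    "screen_blood_biomarkers",
]

#: biomarkers that are strictly positive and right-skewed get a log
#: transform before standardization in the linear models
LOG_SKEWED_DEFAULT = (CALPROTECTIN,)


@dataclass
class BiomarkerPanel:
    """Per-sample biomarker measurements with the calprotectin threshold."""

    frame: pd.DataFrame  # samples x biomarkers, NaN = missing
    calprotectin_threshold: float = 35.0

    def __post_init__(self) -> None:
        if self.calprotectin_threshold <= 0:
            raise ValueError("calprotectin threshold must be positive")

    @classmethod
    def from_metadata(cls, meta: CohortMetadata, threshold: float = 35.0) -> "BiomarkerPanel":
        return cls(meta.frame[meta.biomarker_columns].copy(), threshold)

    @property
    def biomarkers(self) -> list[str]:
        return list(self.frame.columns)


def classify_calprotectin(panel: BiomarkerPanel) -> pd.Series:
    """Per-sample elevated flag: strictly above the threshold.

    Missing measurements yield NA (pandas nullable boolean), never a
    guess; exactly-threshold values are not elevated.
    """
    if CALPROTECTIN not in panel.frame.columns:
        raise KeyError(f"panel has no {CALPROTECTIN!r} column")
    values = panel.frame[CALPROTECTIN]
    if (values.dropna() < 0).any():
        raise ValueError("negative calprotectin value")
    flags = values > panel.calprotectin_threshold
    return flags.mask(values.isna()).astype("boolean").rename("calprotectin_elevated")


def _log_abundance(col: np.ndarray) -> np.ndarray | None:
    """log(p + half the taxon's smallest nonzero proportion); None if constant."""
    nonzero = col[col > 0]
    if nonzero.size == 0:
        return None
    shifted = np.log(col + 0.5 * nonzero.min())
    if np.allclose(shifted, shifted[0]):
        return None
    return shifted


def taxon_biomarker_glm(
    table: AbundanceTable,
    panel: BiomarkerPanel,
    meta: CohortMetadata,
    taxa_subset: list[str],
    biomarkers: list[str] | None = None,
    extra_covariates: list[str] | None = None,
    fdr: float = 0.10,
    log_skewed: tuple[str, ...] = LOG_SKEWED_DEFAULT,
) -> pd.DataFrame:
    """Per-(taxon, biomarker) linear-model association with BH FDR.

    The response is the log-transformed relative abundance (half-minimum
    pseudocount per taxon); the predictor is the standardized biomarker
    (log first for markers listed in ``log_skewed``), with group as a
    covariate.  Samples missing the biomarker are excluded pairwise.
    One BH family spans every test in the invocation; significance is
    q <= ``fdr``.
    """
    if not taxa_subset:
        raise ValueError("taxa_subset must be non-empty")
    biomarkers = list(biomarkers or panel.biomarkers)
    extra_covariates = list(extra_covariates or [])
    meta.check_alignment(table)
    samples = [s for s in meta.sample_ids if s in table.data.index]
    abund = table.data.loc[samples, taxa_subset]
    group = (meta.groups.loc[samples] == "case").astype(float)

    rows = []
    for marker in biomarkers:
        raw = panel.frame[marker].reindex(samples)
        if marker in log_skewed:
            raw = np.log(raw.where(raw > 0))
        ok = raw.notna()
        if int(ok.sum()) < 3:
            continue
        x = raw[ok]
        x_std = (x - x.mean()) / x.std(ddof=0) if x.std(ddof=0) > 0 else None
        for taxon in taxa_subset:
            if x_std is None:
                rows.append(
                    dict(taxon=taxon, biomarker=marker, coefficient=np.nan,
                         p=np.nan, skipped="constant biomarker")
                )
                continue
            y = _log_abundance(abund.loc[ok.index[ok], taxon].to_numpy())
            if y is None:
                rows.append(
                    dict(taxon=taxon, biomarker=marker, coefficient=np.nan,
                         p=np.nan, skipped="constant abundance")
                )
                continue
            design = pd.DataFrame({"biomarker": x_std, "group": group[ok]})
            for cov in extra_covariates:
                design[cov] = pd.to_numeric(meta.frame[cov]).loc[ok.index[ok]]
            fit = sm.OLS(y, sm.add_constant(design), missing="drop").fit()
            rows.append(
                dict(
                    taxon=taxon,
                    biomarker=marker,
                    coefficient=float(fit.params["biomarker"]),
                    p=float(fit.pvalues["biomarker"]),
                    skipped=None,
                )
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no (taxon, biomarker) test had >= 3 observations")
    tested = out["skipped"].isna() & out["p"].notna()
    q = np.full(len(out), np.nan)
    q[tested.to_numpy()] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["significant_at_10pct_fdr"] = tested & (out["q"] <= fdr)
    out["sign"] = np.where(out["coefficient"] >= 0, "positive", "negative")
    out.loc[~tested, "sign"] = None
    return out


def kendall_matrix(
    table: AbundanceTable, panel: BiomarkerPanel, taxa_subset: list[str] | None = None
) -> pd.DataFrame:
    """Kendall tau-b between candidate taxa and biomarkers.

    Pairwise-complete over missing biomarker values; cells with fewer
    than 3 paired observations or an all-tied vector are NaN.
    """
    taxa = list(taxa_subset or table.taxa)
    common = [s for s in table.data.index if s in panel.frame.index]
    abund = table.data.loc[common, taxa]
    out = pd.DataFrame(index=pd.Index(taxa, name="taxon"), columns=panel.biomarkers,
                       dtype=float)
    for marker in panel.biomarkers:
        y_all = panel.frame[marker].reindex(common)
        ok = y_all.notna().to_numpy()
        if ok.sum() < 3:
            continue
        y = y_all.to_numpy(dtype=float)[ok]
        for taxon in taxa:
            x = abund[taxon].to_numpy(dtype=float)[ok]
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            out.loc[taxon, marker] = stats.kendalltau(x, y).statistic
    return out


@dataclass
class RdaRanking:
    """Taxa ordered by constrained-axis loading magnitude."""

    ranking: pd.DataFrame  # index taxon, columns score, rank
    constrained_variance_fraction: float

    def top(self, n: int = 5) -> list[str]:
        return list(self.ranking.index[:n])


def rda_rank(clr: ClrMatrix, covariate: pd.Series) -> RdaRanking:
    """Redundancy analysis with a single numeric constraint.

    The centered CLR matrix is regressed on the centered covariate; the
    fitted (rank-1) matrix's singular vector gives one constrained axis,
    and each taxon's score is its loading magnitude on that axis.  The
    constrained variance fraction is ||Y_hat||^2 / ||Y_centered||^2.
    Invariant to affine rescaling of the covariate.
    """
    common = [s for s in clr.data.index if s in covariate.index]
    x = covariate.loc[common].to_numpy(dtype=float)
    if np.isnan(x).any():
        keep = ~np.isnan(x)
        common = [s for s, k in zip(common, keep) if k]
        x = x[keep]
    if len(common) < 3:
        raise ValueError("need >= 3 samples with covariate values")
    y = clr.data.loc[common].to_numpy(dtype=float)
    y = y - y.mean(axis=0, keepdims=True)
    x = x - x.mean()
    xtx = float(x @ x)
    if xtx == 0:
        raise ValueError("covariate is constant")
    beta = (x @ y) / xtx  # per-taxon slope
    y_hat = np.outer(x, beta)
    total = float((y**2).sum())
    fraction = float((y_hat**2).sum() / total) if total > 0 else 0.0
    # rank-1 fit: the constrained axis is beta normalized; loading
    # magnitude per taxon is |beta_j| up to a common factor
    score = np.abs(beta)
    ranking = (
        pd.DataFrame({"score": score}, index=pd.Index(clr.taxa, name="taxon"))
        .sort_values("score", ascending=False)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return RdaRanking(ranking=ranking, constrained_variance_fraction=fraction)


def screen_blood_biomarkers(
    panel: BiomarkerPanel, meta: CohortMetadata, alpha: float = 0.05
) -> pd.DataFrame:
    """Case-vs-control Wilcoxon rank-sum screen, one row per biomarker."""
    rows = []
    for marker in panel.biomarkers:
        values = panel.frame[marker]
        a = values.reindex(meta.cases).dropna()
        b = values.reindex(meta.controls).dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            dict(biomarker=marker, U=float(res.statistic), p=float(res.pvalue),
                 median_case=float(a.median()), median_control=float(b.median()))
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        out["selected"] = out["p"] <= alpha
    return out
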