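"""Seeded synthetic cohorts with the statistical structure the pipeline
assumes.

The generator emulates a ~100-donor shotgun-profiled case-control cohort
in which inter-individual variability dominates disease signal:

* log-abundances combine a heavy-tailed baseline rank profile, a latent
  "cluster" effect shared by one designed case-control pair (what makes
  matching informative), and per-subject residual noise;
* a small set of taxa is spiked multiplicatively in cases or controls;
* fecal calprotectin is elevated (> 35 µg/g) in a configured minority of
  cases (and rarely in controls) and log-linearly coupled to a subset of
  taxa;
* a block of rare taxa is constructed to satisfy BOTH clauses of the
  default rare-taxon filter exactly, so that filtering 424 taxa leaves
  precisely 249.

Everything flows from one integer seed through a named generator; the
ground truth (spiked taxa, coupled taxa, planted pairing, latent
clusters) is returned alongside the tables for use as a test oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .tables import AbundanceTable, CohortMetadata, CALPROTECTIN

__all__ = ["SyntheticConfig", "GroundTruth", "generate_cohort", "generate_matched_structure"]

_PHYLA = ("Bacillota", "Bacteroidota", "Actinomycetota", "Pseudomonadota", "Euryarchaeota")


def _lineage(i: int, phylum: str) -> str:
    return (
        f"k__Bacteria|p__{phylum}|c__Class_{i:03d}|o__Order_{i:03d}"
        f"|f__Family_{i:03d}|g__Genus_{i:03d}|s__Species_{i:04d}"
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 53 cases / 47 controls, 424 taxa
    of which 175 fall to the default rare-taxon filter, 7 case- and 7
    control-enriched species at fold 2.0, calprotectin elevated in 15/53
    cases and 1/47 controls and coupled (slope 0.5 log-abundance per SD
    of log calprotectin) to 4 of the case spikes plus 2 other taxa.
    ``pair_cluster_sd`` (shared by a designed case-control pair) versus
    ``subject_sd`` (residual) is the inter-individual-variability dial;
    the default 3:1 ratio makes between-pair variation dominate, and the
    total inter-individual log-SD (~0.95) comfortably exceeds the
    largest spiked effect (ln 2 ~ 0.69), so group differences stay
    buried in donor-to-donor variation as in real fecal cohorts.
    """

    n_cases: int = 53
    n_controls: int = 47
    n_taxa: int = 424
    n_rare_removable: int = 175
    n_spiked_case: int = 7
    n_spiked_control: int = 7
    spike_fold: float = 2.0
    subject_sd: float = 0.3
    pair_cluster_sd: float = 0.9
    base_profile_exponent: float = 1.5
    spike_min_rank: int = 20
    spike_max_rank: int = 150
    n_coupled_case_spiked: int = 4
    n_coupled_other: int = 2
    coupling_slope: float = 0.5
    frac_cases_elevated: float = 15 / 53
    frac_controls_elevated: float = 1 / 47
    calprotectin_threshold: float = 35.0
    sequencing_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n_abundant = self.n_taxa - self.n_rare_removable
        if n_abundant < self.n_spiked_case + self.n_spiked_control + self.n_coupled_other:
            raise ValueError("not enough abundant taxa for spikes and coupled taxa")
        if self.n_coupled_case_spiked > self.n_spiked_case:
            raise ValueError("coupled case-spiked taxa cannot exceed case spikes")
        if self.spike_fold <= 0:
            raise ValueError("spike_fold must be positive")
        for name in ("frac_cases_elevated", "frac_controls_elevated"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("both groups must be non-empty")

    @property
    def n_abundant(self) -> int:
        return self.n_taxa - self.n_rare_removable


@dataclass
class GroundTruth:
    """What the generator planted, for use as a test oracle."""

    case_spiked: list[str]
    control_spiked: list[str]
    coupled: list[str]  # calprotectin-coupled taxa (case-spiked first)
    planted_pairs: dict[str, str]  # case_id -> control_id sharing a cluster
    cluster_of: dict[str, int]
    calprotectin: dict[str, float]
    elevated: dict[str, bool]
    removable_taxa: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _sample_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    cases = [f"case_{i + 1:03d}" for i in range(config.n_cases)]
    controls = [f"ctrl_{i + 1:03d}" for i in range(config.n_controls)]
    return cases, controls


def generate_matched_structure(config: SyntheticConfig) -> dict[str, str]:
    """The planted case-control bijection for this config and seed.

    Each control shares a latent cluster with exactly one designated
    case; the returned mapping covers min(n_cases, n_controls) donors
    and is what nearest-neighbor matching should recover when the
    cluster effect dominates subject noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    cases, controls = _sample_ids(config)
    n_pairs = min(len(cases), len(controls))
    chosen_cases = sorted(rng.choice(len(cases), size=n_pairs, replace=False))
    perm = rng.permutation(n_pairs)
    return {cases[ci]: controls[int(perm[i])] for i, ci in enumerate(chosen_cases)}


def _calprotectin(config: SyntheticConfig, rng, cases, controls):
    """Draw calprotectin with the configured elevated fractions.

    Elevated donors sit above the threshold on a right-skewed tail
    (threshold x exp|N(0, 0.45)|); the rest sit below it on a log scale
    spanning roughly 3-35 µg/g.  Quantile targeting by construction: the
    number of elevated donors is exact, not a random fraction.
    """
    n_elev_cases = int(round(config.frac_cases_elevated * len(cases)))
    n_elev_ctrl = int(round(config.frac_controls_elevated * len(controls)))
    elev_cases = rng.choice(len(cases), size=n_elev_cases, replace=False)
    elev_ctrl = rng.choice(len(controls), size=n_elev_ctrl, replace=False)
    values, elevated = {}, {}
    thr = config.calprotectin_threshold
    for ids, elev_idx in ((cases, set(elev_cases)), (controls, set(elev_ctrl))):
        for i, sid in enumerate(ids):
            if i in elev_idx:
                v = thr * np.exp(abs(rng.normal(0.0, 0.45)) + 0.02)
            else:
                v = thr * np.exp(-0.1 - abs(rng.normal(0.8, 0.7)))
            values[sid] = float(v)
            elevated[sid] = i in elev_idx
    return values, elevated


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[AbundanceTable, CohortMetadata, GroundTruth]:
    """Generate one synthetic cohort (abundances, metadata, ground truth)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    cases, controls = _sample_ids(config)
    samples = cases + controls
    n_samples = len(samples)
    n_ab = config.n_abundant

    # --- taxa names: abundant block then the rare-removable block -------
    phyla = [_PHYLA[i % len(_PHYLA)] for i in range(config.n_taxa)]
    taxa = [_lineage(i + 1, phyla[i]) for i in range(config.n_taxa)]
    abundant_taxa = taxa[:n_ab]
    rare_taxa = taxa[n_ab:]

    # --- roles ----------------------------------------------------------
    # spiked and coupled taxa live in the mid-abundance range: fold-level
    # shifts in dominant taxa would move every other taxon through
    # compositional closure, which is not the structure being emulated
    lo = min(config.spike_min_rank - 1, n_ab - 1)
    hi = min(config.spike_max_rank, n_ab)
    eligible = np.arange(lo, hi)
    n_spiked = config.n_spiked_case + config.n_spiked_control
    if eligible.size < n_spiked + config.n_coupled_other:
        raise ValueError("spike rank range too narrow for requested spikes")
    spiked_idx = rng.choice(eligible, size=n_spiked, replace=False)
    case_idx = spiked_idx[: config.n_spiked_case]
    ctrl_idx = spiked_idx[config.n_spiked_case:]
    non_spiked = np.setdiff1d(eligible, spiked_idx)
    coupled_case_idx = rng.choice(case_idx, size=config.n_coupled_case_spiked,
                                  replace=False) if config.n_coupled_case_spiked else np.array([], int)
    coupled_other_idx = rng.choice(non_spiked, size=config.n_coupled_other,
                                   replace=False) if config.n_coupled_other else np.array([], int)
    coupled_idx = np.concatenate([coupled_case_idx, coupled_other_idx]).astype(int)

    # --- latent clusters (the matching signal) --------------------------
    planted = generate_matched_structure(config)
    cluster_of: dict[str, int] = {}
    next_cluster = 0
    for case_id, ctrl_id in planted.items():
        cluster_of[case_id] = next_cluster
        cluster_of[ctrl_id] = next_cluster
        next_cluster += 1
    for sid in samples:
        if sid not in cluster_of:
            cluster_of[sid] = next_cluster
            next_cluster += 1
    cluster_effects = rng.normal(0.0, config.pair_cluster_sd, size=(next_cluster, n_ab))

    # --- calprotectin and coupling --------------------------------------
    calpro, elevated = _calprotectin(config, rng, cases, controls)
    log_c = np.log([calpro[s] for s in samples])
    z_c = (log_c - log_c.mean()) / log_c.std()

    # --- log-abundance assembly -----------------------------------------
    base = -config.base_profile_exponent * np.log(np.arange(1, n_ab + 1))
    log_ab = np.tile(base, (n_samples, 1))
    log_ab += np.stack([cluster_effects[cluster_of[s]] for s in samples])
    log_ab += rng.normal(0.0, config.subject_sd, size=(n_samples, n_ab))
    log_fold = np.log(config.spike_fold)
    is_case = np.array([s in set(cases) for s in samples])
    log_ab[np.ix_(is_case, case_idx)] += log_fold
    log_ab[np.ix_(~is_case, ctrl_idx)] += log_fold
    if coupled_idx.size:
        log_ab[:, coupled_idx] += config.coupling_slope * z_c[:, None]

    # softmax to the simplex
    log_ab -= log_ab.max(axis=1, keepdims=True)
    abundant = np.exp(log_ab)
    abundant /= abundant.sum(axis=1, keepdims=True)

    # --- rare-removable block: prevalence <= 3 AND max abundance < 1e-4 -
    rare = np.zeros((n_samples, config.n_rare_removable))
    for j in range(config.n_rare_removable):
        k = int(rng.integers(1, 4))
        donors = rng.choice(n_samples, size=k, replace=False)
        rare[donors, j] = rng.uniform(1e-6, 9e-5, size=k)
    rare_mass = rare.sum(axis=1)
    values = np.concatenate([abundant * (1.0 - rare_mass)[:, None], rare], axis=1)

    if config.sequencing_depth is not None:
        counts = np.stack(
            [rng.multinomial(config.sequencing_depth, row) for row in values]
        )
        keep = counts.sum(axis=1) > 0
        values = counts / counts.sum(axis=1, keepdims=True)
        if not keep.all():  # pragma: no cover - depth >= 1 always keeps
            raise ValueError("sequencing_depth produced an empty sample")

    table = AbundanceTable.normalized(
        pd.DataFrame(values, index=pd.Index(samples, name="sample_id"), columns=taxa)
    )

    # --- metadata --------------------------------------------------------
    age = np.clip(rng.normal(42, 12, n_samples).round(0), 18, 75)
    bmi = np.clip(rng.normal(25.5, 4.0, n_samples).round(1), 16, 45)
    sex = rng.choice(["female", "male"], size=n_samples)
    frame = pd.DataFrame(
        {
            "group": ["case"] * len(cases) + ["control"] * len(controls),
            "age": age,
            "sex": sex,
            "bmi": bmi,
            CALPROTECTIN: [round(calpro[s], 2) for s in samples],
            "crp_mg_l": np.round(np.exp(rng.normal(0.5, 0.7, n_samples)), 2),
            "esr_mm_h": np.clip(rng.normal(10, 6, n_samples).round(0), 1, 60),
            "alt_u_l": np.round(np.exp(rng.normal(3.0, 0.4, n_samples)), 1),
            "ast_u_l": np.round(np.exp(rng.normal(3.0, 0.35, n_samples)), 1),
            "cholesterol_mmol_l": np.round(rng.normal(5.1, 1.0, n_samples), 2),
            "ldl_mmol_l": np.round(rng.normal(3.0, 0.8, n_samples).clip(0.5), 2),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    meta = CohortMetadata(frame)

    truth = GroundTruth(
        case_spiked=[abundant_taxa[i] for i in case_idx],
        control_spiked=[abundant_taxa[i] for i in ctrl_idx],
        coupled=[abundant_taxa[i] for i in coupled_idx],
        planted_pairs=planted,
        cluster_of=cluster_of,
        calprotectin={s: calpro[s] for s in samples},
        elevated=elevated,
        removable_taxa=rare_taxa,
    )
    return table, meta, truth
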