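#!/usr/bin/env python
"""Host-biomarker association for the paired-DA candidate taxa.

Classifies donors by the 35 µg/g calprotectin threshold, fits
MaAsLin-style linear models of candidate-taxon abundance on
standardized log calprotectin (group as covariate, 10% FDR), computes
Kendall tau-b correlations, and ranks all taxa by a calprotectin-
constrained redundancy analysis.  Ground truth says which taxa were
actually coupled to the covariate.
"""

import json
from pathlib import Path

import numpy as np

from micropair import (
    BiomarkerPanel,
    FilterRule,
    classify_calprotectin,
    clr_transform,
    filter_rare_taxa,
    kendall_matrix,
    rda_rank,
    read_metadata,
    read_profile_table,
    replace_zeros,
    screen_blood_biomarkers,
    taxon_biomarker_glm,
)
from micropair.tables import CALPROTECTIN

ROOT = Path(__file__).resolve().parent.parent / "results"


def _species(lineage: str) -> str:
    return lineage.rsplit("|", 1)[-1]


def main() -> None:
    table = read_profile_table(ROOT / "cohort" / "profile.tsv")
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")
    truth = json.loads((ROOT / "cohort" / "ground_truth.json").read_text())
    da = __import__("pandas").read_csv(
        ROOT / "matched_pairs" / "paired_da.tsv", sep="\t", index_col=0)
    out = ROOT / "biomarkers"
    out.mkdir(parents=True, exist_ok=True)

    panel = BiomarkerPanel.from_metadata(meta, threshold=35.0)
    flags = classify_calprotectin(panel)
    print(f"elevated calprotectin (> 35 µg/g): "
          f"{int(flags.reindex(meta.cases).sum())}/53 cases, "
          f"{int(flags.reindex(meta.controls).sum())}/47 controls")

    candidates = list(da[da["p"] <= 0.05].nsmallest(14, "p").index)
    assoc = taxon_biomarker_glm(table, panel, meta, candidates,
                                biomarkers=[CALPROTECTIN])
    assoc.to_csv(out / "calprotectin_glm.tsv", sep="\t", index=False,
                 float_format="%.10g")
    sig = assoc[assoc["significant_at_10pct_fdr"]]
    coupled_spiked = [t for t in truth["coupled"] if t in truth["case_spiked"]]
    print(f"linear models: {len(sig)} of {len(candidates)} candidate taxa "
          f"significantly associated with calprotectin at 10% FDR")
    found = set(sig.loc[sig['sign'] == 'positive', 'taxon']) & set(coupled_spiked)
    print(f"  truth check: {len(found)}/{len(coupled_spiked)} coupled "
          f"case-enriched taxa recovered as positive associations "
          f"({', '.join(sorted(_species(t) for t in found))})")

    kendall = kendall_matrix(table, panel, candidates)
    kendall.to_csv(out / "kendall_tau.tsv", sep="\t", float_format="%.10g")

    filtered, _ = filter_rare_taxa(table, FilterRule())
    mat = clr_transform(replace_zeros(filtered))
    rda = rda_rank(mat, np.log(meta.frame[CALPROTECTIN]))
    rda.ranking.to_csv(out / "rda_ranking.tsv", sep="\t", float_format="%.10g")
    top5 = rda.top(5)
    overlap = set(top5) & set(truth["coupled"])
    print(f"RDA: constrained axis explains "
          f"{rda.constrained_variance_fraction:.1%} of CLR variance; "
          f"top-5 species contain {len(overlap)}/{len(truth['coupled'])} "
          f"truly coupled taxa")

    screen = screen_blood_biomarkers(panel, meta)
    screen.to_csv(out / "blood_screen.tsv", sep="\t", index=False,
                  float_format="%.10g")
    n_sel = int(screen["selected"].sum()) if not screen.empty else 0
    calpro_p = float(screen.set_index("biomarker").loc[CALPROTECTIN, "p"])
    print(f"biomarker screen: {n_sel} of {len(screen)} markers differ "
          f"between groups at p <= 0.05; whole-distribution rank test for "
          f"calprotectin p = {calpro_p:.3f} (the group difference lives in "
          f"the elevated tail, not the bulk)")


if __name__ == "__main__":
    main()
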