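"""Associate the consensus variables with domain-level impairment.

Spearman correlation of each consensus variable against the seven binary
domain-impairment flags, reported at two significance tiers (per-cell
alpha = 0.05 and Bonferroni alpha/m with m = |consensus| x 7); also runs the
drug-use-style sensitivity contrasts on the VDT Error Score. Writes
results/associations/associations.csv.
"""

from pathlib import Path

import numpy as np

from vdtscreen import scoring, selection, stats, telemetry
from vdtscreen.cohort import generate_cohort
from vdtscreen.pipeline import analysis_config

OUT = Path("results/associations")


def main() -> None:
    cfg = analysis_config(seed=0)
    sessions, cnpa, _ = generate_cohort(cfg.cohort)
    fm = telemetry.summarize_variables(sessions, error_weights=cfg.error_weights)
    deficits = scoring.write_deficit_summaries(scoring.score_cohort(cnpa), None)
    labels = deficits["hand"].to_numpy().astype(int)
    flags = deficits[[f"impaired_{d}" for d in scoring.DOMAINS]].rename(
        columns=lambda c: c.removeprefix("impaired_")
    )

    trains = selection.stratified_training_sets(labels, cfg.selection)
    ranked = [selection.kw_rank(fm.values, labels, tr, split_id=s)
              for s, tr in enumerate(trains)]
    consensus = selection.form_consensus(ranked, cfg.selection.k)
    assoc = stats.spearman_domain_matrix(
        fm.values, consensus.variable_ids, flags, alpha=cfg.association_alpha
    )
    OUT.mkdir(parents=True, exist_ok=True)
    assoc.tidy().to_csv(OUT / "associations.csv", index=False)

    tidy = assoc.tidy()
    n_raw = int(tidy["significant_raw"].sum())
    n_bonf = int(tidy["significant_bonferroni"].sum())
    print(f"{len(consensus)} consensus variables x 7 domains = {assoc.n_comparisons} cells")
    print(f"significant at alpha={assoc.alpha}: {n_raw}; after Bonferroni "
          f"(threshold {assoc.bonferroni_threshold:.2e}): {n_bonf}")

    score = fm.values["vdt_error_score|score|global"].to_numpy()
    rng = np.random.default_rng(0)
    drug = rng.random(len(score)) < 23 / 62  # synthetic allowable-drug-use flag
    res = stats.drug_use_comparisons(score, drug, labels.astype(bool))
    print("sensitivity contrasts on a synthetic drug-use flag "
          f"(n positive = {int(drug.sum())}):")
    print(f"  error score rank-sum W = {res['rank_sum_w']:.0f}, p = {res['rank_sum_p']:.2f}")
    print(f"  HAND prevalence chi-square = {res['chi_square']:.2e}, "
          f"p = {res['chi_square_p']:.2f}")


if __name__ == "__main__":
    main()
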