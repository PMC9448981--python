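"""Score the cohort's CNPA profiles: deficit scores, GDS, HAND labels.

Reads results/cohort/cnpa.csv (regenerating the cohort if absent), converts
T-scores to 0–5 deficit scores, averages them into domain deficits and the
Global Deficit Score, applies the GDS >= 0.5 (HAND) and domain-deficit >= 1
(impairment) cutoffs, and writes the deficit summary plus the within-domain
prevalence table under results/scoring/.
"""

from pathlib import Path

from vdtscreen import scoring, stats
from vdtscreen.cohort import generate_cohort
from vdtscreen.pipeline import analysis_config

COHORT = Path("results/cohort")
OUT = Path("results/scoring")


def main() -> None:
    if (COHORT / "cnpa.csv").exists():
        cnpa = scoring.read_cnpa_csv(COHORT / "cnpa.csv")
    else:
        _, cnpa, _ = generate_cohort(analysis_config(seed=0).cohort)
    summaries = scoring.score_cohort(cnpa)
    OUT.mkdir(parents=True, exist_ok=True)
    df = scoring.write_deficit_summaries(summaries, OUT / "deficit_summary.csv")
    flags = df[[f"impaired_{d}" for d in scoring.DOMAINS]].rename(
        columns=lambda c: c.removeprefix("impaired_")
    )
    prevalence = stats.prevalence_table(flags, df["hand"].to_numpy())
    prevalence.round(4).to_csv(OUT / "prevalence.csv")
    n_pos = int(df["hand"].sum())
    print(f"HAND prevalence: {n_pos}/{len(df)} ({n_pos / len(df):.0%}) at GDS >= 0.5")
    print("within-domain impairment prevalence (%, by HAND status):")
    print(prevalence.round(1).to_string())


if __name__ == "__main__":
    main()
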