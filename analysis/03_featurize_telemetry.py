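"""Build the telemetry feature matrix.

Regenerates the cohort's replay sessions (deterministic at seed 0), derives
the kinematic channels, summarizes every channel with min/max/mean/median/SD
at global and zonal scope, adds error counts and the composite VDT Error
Score, removes zero-variance columns, and writes the matrix + metadata under
results/features/.
"""

from pathlib import Path

from vdtscreen import telemetry
from vdtscreen.cohort import generate_cohort
from vdtscreen.pipeline import analysis_config

OUT = Path("results/features")


def main() -> None:
    cfg = analysis_config(seed=0)
    sessions, _, _ = generate_cohort(cfg.cohort)
    fm = telemetry.summarize_variables(sessions, error_weights=cfg.error_weights)
    OUT.mkdir(parents=True, exist_ok=True)
    fm.write(OUT / "feature_matrix.csv", OUT / "variable_meta.json")
    n_computed = len(fm.variable_ids) + len(fm.removed)
    print(f"{len(sessions)} sessions -> {n_computed} variables computed, "
          f"{len(fm.removed)} zero-variance removed, {len(fm.variable_ids)} retained")
    by_scope = fm.meta["scope"].str.startswith("zone").map({True: "zonal", False: "global"})
    print(by_scope.value_counts().to_string())


if __name__ == "__main__":
    main()
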