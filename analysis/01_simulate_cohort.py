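"""Generate the worked synthetic cohort.

62 participants at 57% HAND prevalence on a fixed 5-zone route, with twenty
informative telemetry variables planted at a one-scale-unit location shift
and group-specific error-event rates. Writes the CNPA table, the ground-truth
sidecar and two example replay files under results/cohort/ (the full replay
set is regenerated on demand by the later stages — it is deterministic).
"""

from pathlib import Path

from vdtscreen.cohort import write_cohort
from vdtscreen.cohort import generate_cohort
from vdtscreen.pipeline import analysis_config
from vdtscreen.scoring import write_cnpa_csv
from vdtscreen.telemetry import write_replay

OUT = Path("results/cohort")


def main() -> None:
    cfg = analysis_config(seed=0)
    sessions, cnpa, truth = generate_cohort(cfg.cohort)
    OUT.mkdir(parents=True, exist_ok=True)
    write_cnpa_csv(cnpa, OUT / "cnpa.csv")
    truth.to_json(OUT / "ground_truth.json")
    (OUT / "example_replays").mkdir(exist_ok=True)
    for s in sessions[:2]:
        write_replay(s, OUT / "example_replays" / f"{s.session_id}.json")
    n_pos = int(truth.hand_labels.sum())
    print(f"cohort: {len(sessions)} participants, {n_pos} HAND-positive "
          f"({n_pos / len(sessions):.0%})")
    print(f"planted: {len(truth.informative_variable_ids)} informative variables "
          f"across {len(truth.informative_variable_ids) // 4} (channel, zone) cells")
    print(f"wrote {OUT}/cnpa.csv, ground_truth.json and 2 example replays")


if __name__ == "__main__":
    main()
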