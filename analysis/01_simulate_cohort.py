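#!/usr/bin/env python
"""Generate the synthetic cohort used by the downstream analyses.

A scaled version of the reference design (3 subjects, 3 concentration
levels, 20 min per level at 250 Hz; the full design in configs/cohort.yaml
is 5 subjects x 5 levels x 60 min at 1 kHz): two spectral states with peaks
near 6 Hz and 2 Hz over a 1/f background, 10-minute mean dwells at the
deepest level, faster switching at lighter levels, and the lightest level
restricted to the 2 Hz state. Writes HDF5 traces + ground-truth CSVs to
results/cohort/.
"""

from pathlib import Path

import numpy as np

from lfpstates.io import write_cohort
from lfpstates.synthgen import (
    CohortConfig,
    ConditionSpec,
    build_transition_matrix,
    default_state_models,
    simulate_cohort,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def scaled_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(
        n_subjects=3,
        conditions=(
            ConditionSpec("iso_1.75", 1.0, (), 1200.0),
            ConditionSpec("iso_1.25", 0.5, (), 1200.0),
            ConditionSpec("iso_0.75", 0.5, (1,), 1200.0),
        ),
        base_transition=build_transition_matrix(2, 60.0, 10.0),
        state_models=default_state_models(),
        sampling_rate_hz=250.0,
        noise_sd=0.1,
        seed=seed,
    )


def main() -> None:
    cfg = scaled_config()
    members = simulate_cohort(cfg)
    written = write_cohort(members, OUT)
    total_s = sum(m.trace.duration_s for m in members)
    n_switches = sum(m.truth.n_transitions() for m in members)
    print(f"cohort: {len(members)} cells, {total_s / 3600:.1f} h of signal")
    print(f"ground truth: {n_switches} state switches across the cohort")
    for cond in {m.truth.condition for m in members}:
        labs = np.concatenate(
            [m.truth.labels for m in members if m.truth.condition == cond]
        )
        occ = [float(np.mean(labs == s)) for s in (0, 1)]
        print(f"  {cond}: state occupancy {occ[0]:.2f} / {occ[1]:.2f}")
    print(f"wrote {len(written)} files to {OUT}")


if __name__ == "__main__":
    main()
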