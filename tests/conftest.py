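import numpy as np
import pytest

from lfpstates.synthgen import (
    build_transition_matrix,
    default_state_models,
    sample_state_sequence,
    synthesize_signal,
)


@pytest.fixture(scope="session")
def two_state_models():
    return default_state_models()


@pytest.fixture(scope="session")
def alternating_trace(two_state_models):
    """A 1200 s two-state trace at 250 Hz with 60 s dwells, plus its truth.

    Deterministic blocks (not Markov-sampled) so within-state window sets are
    known exactly: states alternate 0,1 every six 10-s windows.
    """
    labels = np.tile(np.repeat([0, 1], 6), 10)
    from lfpstates.types import StateSequence

    seq = StateSequence(labels, 10.0, "sA", "c1")
    trace = synthesize_signal(seq, two_state_models, 250.0, seed=11, noise_sd=0.1)
    return trace, seq


@pytest.fixture(scope="session")
def markov_sequences():
    """Five subjects' label sequences from a known 2-state chain (dwell 60)."""
    T = build_transition_matrix(2, 60.0)
    seqs = {}
    for s in range(5):
        seed = np.random.SeedSequence(42, spawn_key=(s,))
        seqs[f"s{s}"] = [
            sample_state_sequence(T, 3000, seed=seed, subject_id=f"s{s}", condition="c")
        ]
    return T, seqs
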