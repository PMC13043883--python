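import numpy as np
import pytest
from scipy.stats import kendalltau

from substage.sustain import EventSequence, expected_z_matrix, random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def event_positions(seq: EventSequence, reference: EventSequence) -> list[int]:
    """Position of each of ``reference``'s events inside ``seq``."""
    order = {ev: i for i, ev in enumerate(seq.events())}
    return [order[ev] for ev in reference.events()]


def sequence_kendall_tau(a: EventSequence, b: EventSequence) -> float:
    """Kendall tau between two orderings of the same event set."""
    return float(kendalltau(event_positions(a, a), event_positions(b, a)).statistic)


def reversed_sequence(seq: EventSequence) -> EventSequence:
    """The same events in reverse biomarker-slot order (re-canonicalised)."""
    from substage.sustain import canonical_sequence

    return canonical_sequence(seq.biomarker[::-1], np.unique(seq.threshold),
                              seq.n_biomarkers)


def block_pair(n_bm, thresholds):
    """Two maximally separated sequences: biomarker blocks in opposite order."""
    from substage.cohort import opposed_pair

    return opposed_pair(n_bm, np.asarray(thresholds, dtype=float))


def planted_cohort(n, n_bm=6, thresholds=(1.0, 2.0, 3.0), n_subtypes=2,
                   noise_sd=0.25, seed=0, z_max=5.0, sequences=None):
    """Z-scores drawn from planted sequences with uniform stages.

    Sequences default to independent random orderings; pass e.g.
    ``block_pair(...)`` for well-separated subtypes.
    Returns (Z, true_subtype, true_stage, sequences).
    """
    rng = np.random.default_rng(seed)
    if sequences is not None:
        seqs = sequences
        n_subtypes = len(seqs)
    else:
        seqs = [random_sequence(n_bm, thresholds, rng) for _ in range(n_subtypes)]
    n_events = seqs[0].n_events
    subtype = rng.integers(0, n_subtypes, n)
    stage = rng.integers(0, n_events + 1, n)
    E = [expected_z_matrix(s, z_max) for s in seqs]
    Z = np.array([E[c][k] for c, k in zip(subtype, stage)])
    Z += rng.normal(0.0, noise_sd, Z.shape)
    return Z, subtype, stage, seqs
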