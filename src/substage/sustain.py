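"""Z-score event-based subtype-and-stage model.

The model describes cross-sectional atrophy z-scores as snapshots of a
monotone disease cascade.  A *subtype* is an ordering (event sequence) of
biomarker events, where an event is a biomarker's z-score crossing a fixed
threshold (by default 1, 2 and 3 control SDs).  A subject at *stage* k has
passed the first k events of their subtype's sequence.  Between events a
biomarker's expected z-score is interpolated linearly; after its last
threshold it continues toward ``z_max``.

Fitting alternates expectation-maximisation over subtype memberships with a
greedy relocation hill-climb over event orderings, starting each new subtype
from a random bipartition of the most populated cluster.  The number of
subtypes is chosen by BIC, and subjects are assigned their
maximum-likelihood subtype and stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EventSequence",
    "SubtypeModel",
    "Assignment",
    "expected_z_at_stage",
    "expected_z_matrix",
    "subject_log_likelihood",
    "sequence_log_likelihood",
    "optimize_sequence",
    "enumerate_sequences",
    "fit_subtypes",
    "select_model",
    "bic",
    "assign_subjects",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class EventSequence:
    """An ordered list of (biomarker, z-threshold) events.

    ``biomarker[j]`` and ``threshold[j]`` describe the event at sequence
    position j (0-based); the event has *occurred* for subjects at stage
    >= j + 1.  Within a biomarker, thresholds must appear in increasing
    order along the sequence: a marker cannot reach z=2 before z=1.
    """

    biomarker: np.ndarray  # int, shape (N,)
    threshold: np.ndarray  # float, shape (N,)
    n_biomarkers: int

    def __post_init__(self):
        bm = np.asarray(self.biomarker, dtype=int)
        thr = np.asarray(self.threshold, dtype=float)
        object.__setattr__(self, "biomarker", bm)
        object.__setattr__(self, "threshold", thr)
        if bm.shape != thr.shape or bm.ndim != 1:
            raise ValueError("biomarker and threshold must be 1-D and aligned")
        pairs = set(zip(bm.tolist(), thr.tolist()))
        if len(pairs) != len(bm):
            raise ValueError("duplicate (biomarker, threshold) event")
        for i in range(self.n_biomarkers):
            t_i = thr[bm == i]
            if np.any(np.diff(t_i) <= 0):
                raise ValueError(
                    f"thresholds of biomarker {i} not increasing along sequence"
                )

    @property
    def n_events(self) -> int:
        return len(self.biomarker)

    def events(self) -> list[tuple[int, float]]:
        return list(zip(self.biomarker.tolist(), self.threshold.tolist()))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventSequence)
            and self.n_biomarkers == other.n_biomarkers
            and np.array_equal(self.biomarker, other.biomarker)
            and np.array_equal(self.threshold, other.threshold)
        )


def canonical_sequence(
    event_bm: np.ndarray, thresholds: np.ndarray, n_biomarkers: int
) -> EventSequence:
    """Build a valid sequence from an arbitrary ordering of biomarker slots.

    ``event_bm`` lists which biomarker occupies each position; each
    biomarker's thresholds are then assigned to its positions in increasing
    order, which is the unique valid arrangement for that position pattern.
    """
    event_bm = np.asarray(event_bm, dtype=int)
    thr = np.empty(len(event_bm), dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    for i in range(n_biomarkers):
        pos = np.flatnonzero(event_bm == i)
        thr[pos] = thresholds[: len(pos)]
    return EventSequence(event_bm, thr, n_biomarkers)


def random_sequence(
    n_biomarkers: int, thresholds, rng: np.random.Generator
) -> EventSequence:
    """Uniform draw over valid sequences (within-biomarker order respected)."""
    thresholds = np.asarray(thresholds, dtype=float)
    slots = np.repeat(np.arange(n_biomarkers), len(thresholds))
    rng.shuffle(slots)
    return canonical_sequence(slots, thresholds, n_biomarkers)


def enumerate_sequences(n_biomarkers: int, thresholds) -> list[EventSequence]:
    """All valid sequences, by enumerating multiset permutations of slots.

    Intended for tiny instances (oracle tests); the count is
    N! / prod(K_i!) and grows fast.
    """
    from itertools import permutations

    thresholds = np.asarray(thresholds, dtype=float)
    slots = tuple(np.repeat(np.arange(n_biomarkers), len(thresholds)).tolist())
    seen = set()
    out = []
    for perm in permutations(slots):
        if perm in seen:
            continue
        seen.add(perm)
        out.append(canonical_sequence(np.array(perm), thresholds, n_biomarkers))
    return out


# ---------------------------------------------------------------------------
# Expected trajectories and likelihood


def expected_z_matrix(seq: EventSequence, z_max) -> np.ndarray:
    """Expected z-score for every (stage, biomarker), shape (N+1, B).

    Piecewise-linear through (stage 0, z 0), each of the biomarker's event
    vertices (event position, its threshold), and — when the biomarker's last
    event is not the final event of the sequence — (stage N, z_max).
    """
    n = seq.n_events
    z_max = np.broadcast_to(np.asarray(z_max, dtype=float), (seq.n_biomarkers,))
    stages = np.arange(n + 1, dtype=float)
    out = np.zeros((n + 1, seq.n_biomarkers))
    for i in range(seq.n_biomarkers):
        pos = np.flatnonzero(seq.biomarker == i) + 1.0  # stage at which event holds
        xs = np.concatenate([[0.0], pos])
        ys = np.concatenate([[0.0], seq.threshold[seq.biomarker == i]])
        if len(pos) == 0 or pos[-1] < n:
            if z_max[i] <= (ys[-1] if len(ys) else 0.0):
                raise ValueError(f"z_max for biomarker {i} must exceed its top threshold")
            xs = np.concatenate([xs, [float(n)]])
            ys = np.concatenate([ys, [z_max[i]]])
        out[:, i] = np.interp(stages, xs, ys)
    return out


def expected_z_at_stage(
    seq: EventSequence, biomarker: int, stage: float, z_max
) -> float:
    """Expected z of one biomarker at one stage (0 <= stage <= N_events)."""
    if not 0 <= stage <= seq.n_events:
        raise ValueError(f"stage {stage} outside [0, {seq.n_events}]")
    E = expected_z_matrix(seq, z_max)
    k = int(np.floor(stage))
    if k == stage:
        return float(E[k, biomarker])
    frac = stage - k
    return float((1 - frac) * E[k, biomarker] + frac * E[k + 1, biomarker])


def _stage_log_density(Z: np.ndarray, E: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """log p(z_row | stage k) for all subjects and stages, shape (n, K+1).

    Expands the Gaussian quadratic form as ||z/s||^2 - 2 (z/s)(E/s)^T +
    ||E/s||^2 so the subject-by-stage term is a single matrix product.
    """
    Zs = Z / sigma
    Es = E / sigma
    z2 = np.einsum("nb,nb->n", Zs, Zs)
    e2 = np.einsum("kb,kb->k", Es, Es)
    const = -np.sum(np.log(sigma)) - Z.shape[1] * _LOG_SQRT_2PI
    return const - 0.5 * (z2[:, None] - 2.0 * Zs @ Es.T + e2[None, :])


def subject_log_likelihood(
    z_row: np.ndarray, seq: EventSequence, sigma, z_max
) -> tuple[float, np.ndarray]:
    """Stage-marginalised log-likelihood of one subject and their stage posterior.

    L = (1/(N+1)) sum_k prod_i Normal(z_i; E_i(k), sigma_i), computed in log
    space.  The posterior over stages 0..N sums to one.
    """
    z_row = np.asarray(z_row, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (seq.n_biomarkers,))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if not np.all(np.isfinite(z_row)):
        raise ValueError("z_row must be finite")
    E = expected_z_matrix(seq, z_max)
    logdens = _stage_log_density(z_row[None, :], E, sigma)[0]
    ll = logsumexp(logdens) - np.log(seq.n_events + 1)
    post = np.exp(logdens - logsumexp(logdens))
    return float(ll), post


def _marginal_loglik(Z: np.ndarray, seq: EventSequence, sigma, z_max) -> np.ndarray:
    """Per-subject stage-marginalised log-likelihood, shape (n,)."""
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (seq.n_biomarkers,))
    E = expected_z_matrix(seq, z_max)
    logdens = _stage_log_density(Z, E, sigma)
    return logsumexp(logdens, axis=1) - np.log(seq.n_events + 1)


def sequence_log_likelihood(
    Z: np.ndarray, seq: EventSequence, sigma, z_max, weights=None
) -> float:
    """Weighted total log-likelihood of a sequence (weights default to 1)."""
    ll = _marginal_loglik(np.asarray(Z, dtype=float), seq, sigma, z_max)
    if weights is None:
        return float(ll.sum())
    return float(np.dot(np.asarray(weights, dtype=float), ll))


# ---------------------------------------------------------------------------
# Sequence search


def _expected_z_from_slots(slots, thresholds, n_bm, z_max, n_events) -> np.ndarray:
    """expected_z_matrix on the raw biomarker-slot encoding (hot path)."""
    E = np.empty((n_events + 1, n_bm))
    stages = np.arange(n_events + 1, dtype=float)
    for i in range(n_bm):
        pos = np.flatnonzero(slots == i) + 1.0
        xs = np.concatenate([[0.0], pos])
        ys = np.concatenate([[0.0], thresholds[: len(pos)]])
        if len(pos) == 0 or pos[-1] < n_events:
            xs = np.concatenate([xs, [float(n_events)]])
            ys = np.concatenate([ys, [z_max[i]]])
        E[:, i] = np.interp(stages, xs, ys)
    return E


class _SequenceObjective:
    """Weighted stage-marginalised log-likelihood as a function of slot order.

    Precomputes the subject-side quadratic terms once per climb so that
    evaluating a candidate ordering costs one small matrix product.
    """

    def __init__(self, Z, weights, sigma, z_max, thresholds):
        n, n_bm = Z.shape
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n_bm,))
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        if weights is None:
            weights = np.ones(n)
        weights = np.asarray(weights, dtype=float)
        keep = weights > 0
        self.w = weights[keep]
        self.Zs = Z[keep] / sigma
        self.z2 = np.einsum("nb,nb->n", self.Zs, self.Zs)
        self.sigma = sigma
        self.z_max = np.broadcast_to(np.asarray(z_max, dtype=float), (n_bm,))
        self.thresholds = np.asarray(thresholds, dtype=float)
        self.n_bm = n_bm
        self.const = -np.sum(np.log(sigma)) - n_bm * _LOG_SQRT_2PI

    def __call__(self, slots: np.ndarray) -> float:
        n_events = len(slots)
        E = _expected_z_from_slots(slots, self.thresholds, self.n_bm,
                                   self.z_max, n_events)
        Es = E / self.sigma
        e2 = np.einsum("kb,kb->k", Es, Es)
        M = self.const - 0.5 * (self.z2[:, None] - 2.0 * self.Zs @ Es.T + e2[None, :])
        mx = M.max(axis=1)
        ll = mx + np.log(np.exp(M - mx[:, None]).sum(axis=1)) - np.log(n_events + 1)
        return float(self.w @ ll)


def _relocation_climb(
    Z, seq: EventSequence, weights, sigma, z_max, thresholds, rng,
    max_sweeps: int = 50,
) -> tuple[EventSequence, float]:
    """Greedy hill-climb: repeatedly move single events to their best position.

    Each sweep visits every event (in random order) and relocates it to the
    position that maximises the weighted log-likelihood, re-sorting that
    biomarker's thresholds to keep the sequence valid.  Stops when a full
    sweep makes no improvement.
    """
    n_bm = seq.n_biomarkers
    thresholds = np.asarray(thresholds, dtype=float)
    obj = _SequenceObjective(Z, weights, sigma, z_max, thresholds)
    slots = seq.biomarker.copy()
    best_ll = obj(slots)
    n = len(slots)
    for _ in range(max_sweeps):
        improved = False
        for pos in rng.permutation(n):
            bm = slots[pos]
            rest = np.delete(slots, pos)
            cand_ll = np.full(n, -np.inf)
            for q in range(n):
                if q == pos:
                    continue
                cand_ll[q] = obj(np.insert(rest, q, bm))
            q_best = int(np.argmax(cand_ll))
            if cand_ll[q_best] > best_ll + 1e-12:
                slots = np.insert(rest, q_best, bm)
                best_ll = cand_ll[q_best]
                improved = True
        if not improved:
            break
    return canonical_sequence(slots, thresholds, n_bm), best_ll


def optimize_sequence(
    Z: np.ndarray,
    weights=None,
    n_restarts: int = 25,
    seed: int = 0,
    sigma=1.0,
    z_max=5.0,
    thresholds=(1.0, 2.0, 3.0),
    init: EventSequence | None = None,
) -> tuple[EventSequence, float]:
    """Best event ordering by multi-start relocation hill-climbing.

    Parameters mirror the likelihood: ``Z`` is the patients x biomarkers
    z-score matrix, ``weights`` are per-patient responsibilities (all-ones
    when None).  ``init`` warm-starts the first climb (used by EM); the
    remaining ``n_restarts`` starts are random valid sequences.  Deterministic
    given ``seed``.
    """
    Z = np.asarray(Z, dtype=float)
    n_bm = Z.shape[1]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if not np.any(weights > 0):
            raise ValueError("all weights are zero")
    rng = np.random.default_rng(seed)
    starts: list[EventSequence] = []
    if init is not None:
        starts.append(init)
    starts += [random_sequence(n_bm, thresholds, rng) for _ in range(n_restarts)]
    if not starts:
        raise ValueError("need at least one start (n_restarts >= 1 or init)")
    best: tuple[EventSequence, float] | None = None
    for s in starts:
        seq, ll = _relocation_climb(Z, s, weights, sigma, z_max, thresholds, rng)
        if best is None or ll > best[1]:
            best = (seq, ll)
    return best


# ---------------------------------------------------------------------------
# Subtype mixture fitting


@dataclass
class SubtypeModel:
    """A fitted mixture of event sequences.

    ``sequences[c]`` is subtype c's event ordering, ``fractions[c]`` its
    mixture weight.  ``em_trace`` records the total log-likelihood after
    every EM iteration (monotone non-decreasing by construction).
    """

    sequences: list[EventSequence]
    fractions: np.ndarray
    sigma: np.ndarray
    z_max: np.ndarray
    log_likelihood: float
    n_patients: int
    em_trace: list[float] = field(default_factory=list)
    degenerate: bool = False

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    @property
    def n_events(self) -> int:
        return self.sequences[0].n_events

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")

    def to_dict(self) -> dict:
        return {
            "sequences": [s.events() for s in self.sequences],
            "fractions": self.fractions.tolist(),
            "sigma": np.asarray(self.sigma).tolist(),
            "z_max": np.asarray(self.z_max).tolist(),
            "log_likelihood": self.log_likelihood,
            "n_patients": self.n_patients,
        }

    @classmethod
    def from_dict(cls, d: dict, n_biomarkers: int) -> "SubtypeModel":
        seqs = [
            EventSequence(
                np.array([e[0] for e in ev]), np.array([e[1] for e in ev]), n_biomarkers
            )
            for ev in d["sequences"]
        ]
        return cls(
            sequences=seqs,
            fractions=np.array(d["fractions"]),
            sigma=np.array(d["sigma"]),
            z_max=np.array(d["z_max"]),
            log_likelihood=float(d["log_likelihood"]),
            n_patients=int(d["n_patients"]),
        )


def _mixture_loglik(Z, sequences, fractions, sigma, z_max):
    """Return (total ll, responsibilities (n,C), per-subtype ll (n,C))."""
    per = np.column_stack([_marginal_loglik(Z, s, sigma, z_max) for s in sequences])
    logw = per + np.log(fractions)[None, :]
    tot = logsumexp(logw, axis=1)
    resp = np.exp(logw - tot[:, None])
    return float(tot.sum()), resp, per


def _run_em(Z, sequences, fractions, sigma, z_max, thresholds, rng,
            em_iters, tol) -> tuple[list[EventSequence], np.ndarray, float, list[float]]:
    sequences = list(sequences)
    fractions = np.asarray(fractions, dtype=float)
    ll, resp, _ = _mixture_loglik(Z, sequences, fractions, sigma, z_max)
    trace = [ll]
    for _ in range(em_iters):
        # M-step: re-optimise each sequence under its responsibilities,
        # warm-started from the current ordering (no random restarts).
        new_seqs = []
        for c, seq in enumerate(sequences):
            if resp[:, c].sum() <= 0:
                new_seqs.append(seq)
                continue
            s, _ = _relocation_climb(
                Z, seq, resp[:, c], sigma, z_max, thresholds, rng
            )
            new_seqs.append(s)
        fractions = resp.mean(axis=0)
        fractions = fractions / fractions.sum()
        sequences = new_seqs
        new_ll, resp, _ = _mixture_loglik(Z, sequences, fractions, sigma, z_max)
        trace.append(new_ll)
        if new_ll - ll < tol:
            ll = max(ll, new_ll)
            break
        ll = new_ll
    return sequences, fractions, ll, trace


def fit_subtypes(
    Z: np.ndarray,
    max_subtypes: int = 2,
    n_restarts: int = 25,
    em_iters: int = 30,
    seed: int = 0,
    sigma=1.0,
    z_max=5.0,
    thresholds=(1.0, 2.0, 3.0),
    split_restarts: int | None = None,
    tol: float = 1e-6,
) -> list[SubtypeModel]:
    """Fit mixture models with C = 1..max_subtypes subtypes hierarchically.

    C=1 is a direct multi-start sequence optimisation.  Each larger model is
    initialised by splitting the currently most populated subtype with
    ``split_restarts`` random bipartitions (default: ``n_restarts``), running
    EM from each, and keeping the best final log-likelihood.
    """
    Z = np.asarray(Z, dtype=float)
    n, n_bm = Z.shape
    if max_subtypes < 1:
        raise ValueError("max_subtypes must be >= 1")
    if n < 2 * max_subtypes:
        raise ValueError(
            f"{n} patients cannot support {max_subtypes} subtypes (need >= {2 * max_subtypes})"
        )
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n_bm,)).copy()
    z_max_arr = np.broadcast_to(np.asarray(z_max, dtype=float), (n_bm,)).copy()
    if split_restarts is None:
        split_restarts = n_restarts
    rng = np.random.default_rng(seed)

    models: list[SubtypeModel] = []
    seq1, ll1 = optimize_sequence(
        Z, None, n_restarts, int(rng.integers(2**31)), sigma, z_max_arr, thresholds
    )
    degenerate = _is_degenerate(Z, seq1, sigma, z_max_arr)
    models.append(
        SubtypeModel([seq1], np.array([1.0]), sigma, z_max_arr, ll1, n,
                     em_trace=[ll1], degenerate=degenerate)
    )
    for C in range(2, max_subtypes + 1):
        prev = models[-1]
        _, resp, _ = _mixture_loglik(Z, prev.sequences, prev.fractions, sigma, z_max_arr)
        hard = np.argmax(resp, axis=1)
        c_split = int(np.argmax(resp.sum(axis=0)))
        members = np.flatnonzero(hard == c_split)
        best = None
        for _ in range(max(1, split_restarts)):
            mask = rng.random(len(members)) < 0.5
            if mask.all() or (~mask).all():
                mask[rng.integers(len(mask))] = ~mask[rng.integers(len(mask))]
            groups = [members[mask], members[~mask]]
            init_seqs = [s for i, s in enumerate(prev.sequences) if i != c_split]
            init_fracs = [f for i, f in enumerate(prev.fractions) if i != c_split]
            for g in groups:
                w = np.zeros(n)
                w[g] = 1.0
                s, _ = optimize_sequence(
                    Z, w, 1, int(rng.integers(2**31)), sigma, z_max_arr, thresholds
                )
                init_seqs.append(s)
                init_fracs.append(prev.fractions[c_split] * len(g) / max(1, len(members)))
            fr = np.maximum(np.asarray(init_fracs, dtype=float), 1e-6)
            fr = fr / fr.sum()
            seqs, fracs, ll, trace = _run_em(
                Z, init_seqs, fr, sigma, z_max_arr, thresholds, rng, em_iters, tol
            )
            if best is None or ll > best[2]:
                best = (seqs, fracs, ll, trace)
        seqs, fracs, ll, trace = best
        models.append(
            SubtypeModel(list(seqs), fracs, sigma, z_max_arr, ll, n, em_trace=trace)
        )
    return models


def _is_degenerate(Z, seq, sigma, z_max) -> bool:
    """True when the likelihood is flat across orderings (e.g. all-zero Z)."""
    rng = np.random.default_rng(0)
    ll0 = sequence_log_likelihood(Z, seq, sigma, z_max)
    alt = random_sequence(seq.n_biomarkers, np.unique(seq.threshold), rng)
    return abs(ll0 - sequence_log_likelihood(Z, alt, sigma, z_max)) < 1e-9


# ---------------------------------------------------------------------------
# Model selection and assignment


def bic(model: SubtypeModel, n_patients: int | None = None,
        param_count: str = "events+fractions") -> float:
    """BIC = -2 logL + P log n with P = C*N_events + (C-1) by default."""
    n = model.n_patients if n_patients is None else n_patients
    C = model.n_subtypes
    if param_count == "events+fractions":
        P = C * model.n_events + (C - 1)
    elif param_count == "fractions":
        P = C - 1
    else:
        raise ValueError(f"unknown parameter-count convention {param_count!r}")
    return -2.0 * model.log_likelihood + P * np.log(n)


def select_model(models: list[SubtypeModel], n_patients: int | None = None,
                 param_count: str = "events+fractions") -> int:
    """Number of subtypes minimising BIC; ties go to the smaller model."""
    if not models:
        raise ValueError("empty model list")
    bics = [bic(m, n_patients, param_count) for m in models]
    return models[int(np.argmin(bics))].n_subtypes


@dataclass
class Assignment:
    """Maximum-likelihood subtype and stage for each subject."""

    subtype: np.ndarray          # int (n,)
    stage: np.ndarray            # int (n,), in [0, N_events]
    subtype_posterior: np.ndarray  # float (n,), P(assigned subtype | data)
    stage_posterior: np.ndarray    # float (n, N_events+1), assigned subtype's
    tied: np.ndarray             # bool (n,), ML stage or subtype was tied

    def __len__(self) -> int:
        return len(self.subtype)


def assign_subjects(Z: np.ndarray, model: SubtypeModel) -> Assignment:
    """Assign each subject the ML subtype, then the ML stage within it.

    Ties are broken toward the lower subtype index / lower stage and
    flagged.  The stage posterior of the assigned subtype is retained.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != model.sequences[0].n_biomarkers:
        raise ValueError(
            f"Z has {Z.shape[1]} biomarkers, model expects "
            f"{model.sequences[0].n_biomarkers}"
        )
    _, resp, _ = _mixture_loglik(Z, model.sequences, model.fractions,
                                 model.sigma, model.z_max)
    subtype = np.argmax(resp, axis=1)
    sub_post = resp[np.arange(len(Z)), subtype]
    n_stage = model.n_events + 1
    stage = np.zeros(len(Z), dtype=int)
    stage_post = np.zeros((len(Z), n_stage))
    tied = np.zeros(len(Z), dtype=bool)
    per_subtype_dens = {}
    for c in range(model.n_subtypes):
        E = expected_z_matrix(model.sequences[c], model.z_max)
        per_subtype_dens[c] = _stage_log_density(Z, E, model.sigma)
    for j in range(len(Z)):
        ld = per_subtype_dens[subtype[j]][j]
        post = np.exp(ld - logsumexp(ld))
        stage_post[j] = post
        stage[j] = int(np.argmax(post))
        if np.sum(np.abs(post - post.max()) < 1e-12) > 1:
            tied[j] = True
        if np.sum(np.abs(resp[j] - resp[j].max()) < 1e-12) > 1:
            tied[j] = True
    return Assignment(subtype, stage, sub_post, stage_post, tied)
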