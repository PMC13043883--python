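"""Synthetic cohort generation.

Builds seeded cohorts with the statistical structure the analysis chain
assumes: control regional volumes linear in age, sex and total intracranial
volume (TIV) with Gaussian residuals; patient volumes displaced downward
along a subtype-specific z-score event sequence; per-subject functional
connectivity matrices (Fisher-z units) with optional edges whose values
track disease stage at a requested Spearman correlation; and clinical
scores with per-subtype linear stage slopes.

Every generator takes an explicit integer seed and is bitwise reproducible.
A :class:`GroundTruth` manifest records the planted sequences, subtypes,
stages and effects so recovery can be measured downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sustain import (
    EventSequence,
    canonical_sequence,
    expected_z_matrix,
    random_sequence,
)

__all__ = [
    "DemographicsParams",
    "GroundTruth",
    "PlantedEdge",
    "ConnectivityStack",
    "BiomarkerRegistry",
    "default_registry",
    "generate_demographics",
    "generate_truth",
    "opposed_pair",
    "generate_volumes",
    "generate_connectivity",
    "generate_clinical",
    "apply_exclusions",
    "validate_subjects",
]

SUBJECT_COLUMNS = ("subject_id", "group", "age", "sex", "handedness", "scanner", "tiv")


@dataclass
class DemographicsParams:
    """Sampling distributions for the demographic covariates.

    Defaults follow the schizophrenia-cohort margins the package emulates:
    controls aged 34.5 +/- 12.8 years and 60.7% male, patients 39.8 +/- 10.4
    and 51.8% male, ~96%/93% right-handed, scanner A used for 29%/54% of
    controls/patients.  TIV is drawn per sex (mm^3).
    """

    control_age_mean: float = 34.5
    control_age_sd: float = 12.8
    patient_age_mean: float = 39.8
    patient_age_sd: float = 10.4
    age_range: tuple[float, float] = (18.0, 75.0)
    control_male_frac: float = 0.607
    patient_male_frac: float = 0.518
    control_right_frac: float = 0.96
    patient_right_frac: float = 0.929
    control_scanner_a_frac: float = 0.29
    patient_scanner_a_frac: float = 0.541
    tiv_mean_male: float = 1_550_000.0
    tiv_mean_female: float = 1_370_000.0
    tiv_sd: float = 100_000.0


def generate_demographics(
    n_controls: int,
    n_patients: int,
    params: DemographicsParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a subject table of ``n_controls`` controls then ``n_patients`` patients."""
    if n_controls < 1 or n_patients < 1:
        raise ValueError("group sizes must be >= 1")
    p = params or DemographicsParams()
    rng = np.random.default_rng(seed)
    rows = []
    specs = [
        ("control", n_controls, p.control_age_mean, p.control_age_sd,
         p.control_male_frac, p.control_right_frac, p.control_scanner_a_frac),
        ("patient", n_patients, p.patient_age_mean, p.patient_age_sd,
         p.patient_male_frac, p.patient_right_frac, p.patient_scanner_a_frac),
    ]
    idx = 0
    for group, n, age_mu, age_sd, male, right, scan_a in specs:
        age = np.clip(rng.normal(age_mu, age_sd, n), *p.age_range)
        sex = np.where(rng.random(n) < male, "male", "female")
        hand = np.where(rng.random(n) < right, "right", "left")
        scanner = np.where(rng.random(n) < scan_a, "A", "B")
        tiv_mu = np.where(sex == "male", p.tiv_mean_male, p.tiv_mean_female)
        tiv = np.maximum(rng.normal(tiv_mu, p.tiv_sd), 900_000.0)
        for i in range(n):
            rows.append(
                dict(subject_id=f"sub-{idx:04d}", group=group, age=age[i],
                     sex=sex[i], handedness=hand[i], scanner=scanner[i], tiv=tiv[i])
            )
            idx += 1
    return pd.DataFrame(rows)


def validate_subjects(subjects: pd.DataFrame) -> None:
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise ValueError(f"subject table missing columns: {missing}")
    if subjects["subject_id"].duplicated().any():
        dup = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    if (subjects["age"] <= 0).any() or (subjects["tiv"] <= 0).any():
        raise ValueError("age and tiv must be positive")
    bad = set(subjects["group"]) - {"control", "patient"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Ground truth


@dataclass(frozen=True)
class PlantedEdge:
    """A connectivity edge whose value tracks stage within one subtype."""

    i: int
    j: int
    rho: float
    subtype: int = 0


@dataclass
class GroundTruth:
    """Planted progression model and per-patient latent state."""

    sequences: list[EventSequence]
    fractions: np.ndarray
    subtype: np.ndarray          # int (n_patients,)
    stage: np.ndarray            # int (n_patients,)
    biomarkers: list[str]
    thresholds: np.ndarray
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    clinical_slopes: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return self.sequences[0].n_events

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.subtype = np.asarray(self.subtype, dtype=int)
        self.stage = np.asarray(self.stage, dtype=int)
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("subtype fractions must sum to 1")
        n_ev = self.n_events
        if self.stage.min(initial=0) < 0 or self.stage.max(initial=0) > n_ev:
            raise ValueError(f"stages must lie in [0, {n_ev}]")

    def to_dict(self) -> dict:
        return {
            "biomarkers": list(self.biomarkers),
            "thresholds": self.thresholds.tolist(),
            "sequences": [s.events() for s in self.sequences],
            "fractions": self.fractions.tolist(),
            "subtype": self.subtype.tolist(),
            "stage": self.stage.tolist(),
            "planted_edges": [
                {"i": e.i, "j": e.j, "rho": e.rho, "subtype": e.subtype}
                for e in self.planted_edges
            ],
            "clinical_slopes": {k: list(v) for k, v in self.clinical_slopes.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        n_bm = len(d["biomarkers"])
        seqs = [
            EventSequence(np.array([e[0] for e in ev]),
                          np.array([e[1] for e in ev]), n_bm)
            for ev in d["sequences"]
        ]
        return cls(
            sequences=seqs,
            fractions=np.array(d["fractions"]),
            subtype=np.array(d["subtype"]),
            stage=np.array(d["stage"]),
            biomarkers=list(d["biomarkers"]),
            thresholds=np.array(d["thresholds"]),
            planted_edges=[PlantedEdge(**e) for e in d.get("planted_edges", [])],
            clinical_slopes={k: list(v) for k, v in d.get("clinical_slopes", {}).items()},
        )


def generate_truth(
    n_patients: int,
    n_subtypes: int,
    biomarkers: list[str],
    z_thresholds=(1.0, 2.0, 3.0),
    fractions=None,
    seed: int = 0,
    sequences: list[EventSequence] | None = None,
) -> GroundTruth:
    """Draw subtype sequences, memberships and stages.

    Sequences are uniform random valid orderings unless given explicitly;
    subtypes are drawn from ``fractions`` (uniform by default) and stages
    uniformly on 0..N_events, matching the model's uniform stage prior.
    """
    thr = np.asarray(z_thresholds, dtype=float)
    if np.any(np.diff(thr) <= 0):
        raise ValueError("z thresholds must be strictly increasing")
    if fractions is None:
        fractions = np.full(n_subtypes, 1.0 / n_subtypes)
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != n_subtypes:
        raise ValueError("fractions length must equal n_subtypes")
    rng = np.random.default_rng(seed)
    n_bm = len(biomarkers)
    if sequences is None:
        sequences = [random_sequence(n_bm, thr, rng) for _ in range(n_subtypes)]
    elif len(sequences) != n_subtypes:
        raise ValueError("need one sequence per subtype")
    n_events = sequences[0].n_events
    subtype = rng.choice(n_subtypes, size=n_patients, p=fractions / fractions.sum())
    stage = rng.integers(0, n_events + 1, size=n_patients)
    return GroundTruth(sequences, fractions, subtype, stage,
                       list(biomarkers), thr)


def opposed_pair(n_biomarkers: int, thresholds) -> list[EventSequence]:
    """Two maximally separated sequences: biomarker blocks in opposite order.

    Subtype 0 completes biomarker 0 first and the last biomarker last;
    subtype 1 progresses in the reverse biomarker order.  Useful for
    well-separated recovery benchmarks.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    fwd = np.repeat(np.arange(n_biomarkers), len(thresholds))
    return [canonical_sequence(fwd, thresholds, n_biomarkers),
            canonical_sequence(fwd[::-1], thresholds, n_biomarkers)]


def apply_exclusions(
    subjects: pd.DataFrame, exclude_ids
) -> tuple[pd.DataFrame, dict]:
    """Drop excluded subjects and return per-group before/after counts."""
    exclude = set(exclude_ids)
    unknown = exclude - set(subjects["subject_id"])
    if unknown:
        raise ValueError(f"unknown subject ids in exclusion list: {sorted(unknown)[:5]}")
    kept = subjects[~subjects["subject_id"].isin(exclude)].reset_index(drop=True)
    summary = {}
    for grp in ("control", "patient"):
        before = int((subjects["group"] == grp).sum())
        after = int((kept["group"] == grp).sum())
        summary[grp] = {"enrolled": before, "excluded": before - after, "analyzed": after}
    return kept, summary


# ---------------------------------------------------------------------------
# Biomarker registry and volumes


@dataclass
class BiomarkerRegistry:
    """Names the modelled biomarkers and how raw volume columns map to them.

    ``bilateral_pairs`` maps a bilateral biomarker to its (left, right) raw
    columns; cortical biomarkers keep hemispheres separate.  ``base_volume``
    (mm^3) anchors default control-model coefficients.
    """

    biomarkers: list[str]
    bilateral_pairs: dict[str, tuple[str, str]]
    base_volume: dict[str, float]

    @property
    def raw_columns(self) -> list[str]:
        cols = []
        for b in self.biomarkers:
            if b in self.bilateral_pairs:
                cols.extend(self.bilateral_pairs[b])
            else:
                cols.append(b)
        return cols

    def default_betas(self) -> pd.DataFrame:
        """Plausible control-model coefficients per biomarker.

        Volumes shrink ~0.2%/year, scale with TIV, and carry a small sex
        offset beyond TIV; the intercept centres the prediction at the
        reference subject (age 35, male, TIV 1.45e6 mm^3).
        """
        rows = {}
        for b in self.biomarkers:
            base = self.base_volume[b]
            b_age = -0.002 * base
            b_female = -0.01 * base
            b_tiv = 0.6 * base / 1_450_000.0
            intercept = base - b_age * 35.0 - b_tiv * 1_450_000.0
            rows[b] = dict(intercept=intercept, age=b_age, female=b_female, tiv=b_tiv)
        return pd.DataFrame(rows).T[["intercept", "age", "female", "tiv"]]

    def default_resid_sd(self) -> pd.Series:
        return pd.Series({b: 0.03 * self.base_volume[b] for b in self.biomarkers})


def default_registry() -> BiomarkerRegistry:
    """13 biomarkers: 4 cortical lobes x 2 hemispheres + 5 bilateral subcortical."""
    cortical = {
        "frontal": 180_000.0, "temporal": 110_000.0,
        "parietal": 120_000.0, "occipital": 70_000.0,
    }
    subcortical = {
        "limbic": 18_000.0, "insula": 14_000.0, "amygdala": 3_200.0,
        "basal_ganglia": 22_000.0, "thalamus": 15_000.0,
    }
    biomarkers, base, pairs = [], {}, {}
    for name, vol in cortical.items():
        for hemi in ("left", "right"):
            col = f"{name}_{hemi}"
            biomarkers.append(col)
            base[col] = vol / 2.0
    for name, vol in subcortical.items():
        biomarkers.append(name)
        base[name] = vol
        pairs[name] = (f"{name}_left", f"{name}_right")
    return BiomarkerRegistry(biomarkers, pairs, base)


def _design(subjects: pd.DataFrame) -> np.ndarray:
    """Control-model design: intercept, age, female indicator, TIV."""
    female = (subjects["sex"] == "female").astype(float).to_numpy()
    return np.column_stack([
        np.ones(len(subjects)), subjects["age"].to_numpy(),
        female, subjects["tiv"].to_numpy(),
    ])


def generate_volumes(
    subjects: pd.DataFrame,
    truth: GroundTruth,
    control_betas: pd.DataFrame | None = None,
    resid_sd: pd.Series | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    registry: BiomarkerRegistry | None = None,
    split_bilateral: bool = False,
    asymmetry_sd: float = 0.0,
) -> pd.DataFrame:
    """Regional volumes (mm^3) for every subject, indexed by subject_id.

    Controls follow the linear covariate model plus Gaussian(0, resid_sd)
    residuals.  Patient volumes are displaced by their subtype sequence's
    expected z at their true stage (plus Gaussian(0, noise_sd) in z units),
    scaled by the residual SD, so more atrophy means smaller volume.

    With ``split_bilateral`` the registry's bilateral biomarkers are emitted
    as left/right columns straddling the bilateral value symmetrically
    (offset SD ``asymmetry_sd`` in mm^3), so averaging recovers it exactly.
    """
    validate_subjects(subjects)
    reg = registry or default_registry()
    betas = reg.default_betas() if control_betas is None else control_betas
    sd = reg.default_resid_sd() if resid_sd is None else resid_sd
    missing = [b for b in truth.biomarkers if b not in betas.index]
    if missing:
        raise ValueError(f"control betas missing regions: {missing}")
    rng = np.random.default_rng(seed)
    X = _design(subjects)
    is_pat = (subjects["group"] == "patient").to_numpy()
    n = len(subjects)
    B = len(truth.biomarkers)
    pred = X @ betas.loc[truth.biomarkers].to_numpy().T  # (n, B)
    z_true = np.zeros((n, B))
    E_by_subtype = [expected_z_matrix(s, 5.0) for s in truth.sequences]
    pat_rows = np.flatnonzero(is_pat)
    for row, c, k in zip(pat_rows, truth.subtype, truth.stage):
        z_true[row] = E_by_subtype[c][k]
    sd_vec = sd.loc[truth.biomarkers].to_numpy()
    z_noise = np.zeros((n, B))
    z_noise[~is_pat] = rng.normal(0.0, 1.0, size=(int((~is_pat).sum()), B))
    z_noise[is_pat] = rng.normal(0.0, noise_sd, size=(len(pat_rows), B))
    vols = pred - (z_true + z_noise) * sd_vec[None, :]
    out = pd.DataFrame(vols, columns=truth.biomarkers,
                       index=pd.Index(subjects["subject_id"], name="subject_id"))
    if split_bilateral:
        for b, (lcol, rcol) in reg.bilateral_pairs.items():
            if b not in out.columns:
                continue
            delta = rng.normal(0.0, asymmetry_sd, size=n)
            out[lcol] = out[b] + delta
            out[rcol] = out[b] - delta
            out = out.drop(columns=[b])
    if (out.to_numpy() <= 0).any():
        raise ValueError("generated a non-positive volume; lower noise or z range")
    return out


# ---------------------------------------------------------------------------
# Connectivity


@dataclass
class ConnectivityStack:
    """Per-subject symmetric region x region matrices of Fisher-z correlations."""

    data: np.ndarray            # (n_subjects, R, R)
    regions: list[str]
    subject_ids: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n, r1, r2 = self.data.shape
        if r1 != r2 or r1 != len(self.regions) or n != len(self.subject_ids):
            raise ValueError("connectivity stack dimensions inconsistent")
        self.validate()

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def validate(self, tol: float = 1e-8) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite connectivity values")
        asym = np.abs(self.data - np.transpose(self.data, (0, 2, 1)))
        if asym.max() > tol:
            s, i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"asymmetry {asym.max():.2e} at subject {self.subject_ids[s]}, "
                f"pair ({self.regions[i]}, {self.regions[j]})"
            )
        diag = np.abs(np.diagonal(self.data, axis1=1, axis2=2))
        if diag.max() > 0:
            raise ValueError("connectivity diagonal must be exactly zero")

    def edge_values(self, i: int, j: int) -> np.ndarray:
        return self.data[:, i, j]

    def edge_matrix(self) -> tuple[np.ndarray, list[tuple[int, int]]]:
        """Flatten to (n_subjects, n_edges) over all i<j pairs, row-major."""
        r = self.n_regions
        iu = np.triu_indices(r, k=1)
        return self.data[:, iu[0], iu[1]], list(zip(iu[0].tolist(), iu[1].tolist()))


def _spearman_to_pearson(rho: float) -> float:
    """Bivariate-normal inversion: the Pearson r giving Spearman rho."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def generate_connectivity(
    subjects: pd.DataFrame,
    truth: GroundTruth,
    n_regions: int = 96,
    planted: list[PlantedEdge] | None = None,
    edge_noise_sd: float = 0.15,
    baseline_mean: float = 0.3,
    baseline_sd: float = 0.1,
    seed: int = 0,
    region_names: list[str] | None = None,
) -> ConnectivityStack:
    """Fisher-z connectivity matrices with optional stage-coupled edges.

    Unplanted edges are subject-independent baselines plus Gaussian noise.
    A planted edge adds, for patients of its subtype, a linear-in-stage-rank
    shift whose slope is calibrated so the edge's Spearman correlation with
    true stage approximates ``rho`` at the given noise (closed-form
    rank-correlation inversion; verified by simulation in the test-suite).
    """
    validate_subjects(subjects)
    planted = planted or []
    for e in planted:
        if e.i == e.j:
            raise ValueError(f"planted self-edge ({e.i}, {e.i})")
        if not (0 <= e.i < n_regions and 0 <= e.j < n_regions):
            raise ValueError(f"planted edge ({e.i}, {e.j}) outside {n_regions} regions")
    rng = np.random.default_rng(seed)
    n = len(subjects)
    iu = np.triu_indices(n_regions, k=1)
    n_edges = len(iu[0])
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_edges)
    vals = baseline[None, :] + rng.normal(0.0, edge_noise_sd, size=(n, n_edges))

    is_pat = (subjects["group"] == "patient").to_numpy()
    pat_rows = np.flatnonzero(is_pat)
    edge_index = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(iu[0], iu[1]))}
    from scipy.stats import rankdata

    for e in planted:
        key = (min(e.i, e.j), max(e.i, e.j))
        k = edge_index[key]
        members = pat_rows[truth.subtype == e.subtype]
        if len(members) < 3:
            continue
        u = rankdata(truth.stage[truth.subtype == e.subtype])
        u = (u - u.mean()) / max(u.std(), 1e-12)
        r = _spearman_to_pearson(e.rho)
        slope = r * edge_noise_sd / np.sqrt(max(1.0 - r**2, 1e-12))
        vals[members, k] += slope * u

    data = np.zeros((n, n_regions, n_regions))
    data[:, iu[0], iu[1]] = vals
    data[:, iu[1], iu[0]] = vals
    regions = region_names or [f"roi_{i:03d}" for i in range(n_regions)]
    return ConnectivityStack(data, regions, subjects["subject_id"].tolist())


# ---------------------------------------------------------------------------
# Clinical scores


def generate_clinical(
    subjects: pd.DataFrame,
    truth: GroundTruth,
    slopes: dict[str, list[float]] | None = None,
    score_noise_sd: float = 2.0,
    baselines: dict[str, float] | None = None,
    patient_missing_rate: float = 0.04,
    controls: str = "missing",
    seed: int = 0,
) -> pd.DataFrame:
    """Append clinical score columns to a copy of the subject table.

    Patient scores follow ``baseline + slope[subtype] * true_stage`` plus
    Gaussian noise, with a Bernoulli missingness mask; controls are missing
    (default) or drawn at the baseline ("norm" mode).  Default slopes plant
    a positive hostility-stage slope in subtype 0 and a negative social
    withdrawal slope in subtype 1, echoing stage-linked symptom gradients.
    """
    validate_subjects(subjects)
    n_sub = len(truth.fractions)
    if slopes is None:
        slopes = {
            "hostility": [0.735] + [0.0] * (n_sub - 1),
            "social_withdrawal": [0.0] * (n_sub - 1) + [-1.052],
        }
    if baselines is None:
        baselines = {k: 10.0 for k in slopes}
    for score, sl in slopes.items():
        if len(sl) != n_sub:
            raise ValueError(
                f"score {score!r} has {len(sl)} slopes for {n_sub} subtypes"
            )
    rng = np.random.default_rng(seed)
    out = subjects.copy()
    is_pat = (out["group"] == "patient").to_numpy()
    pat_rows = np.flatnonzero(is_pat)
    for score, sl in slopes.items():
        col = np.full(len(out), np.nan)
        sl = np.asarray(sl, dtype=float)
        vals = (baselines[score] + sl[truth.subtype] * truth.stage
                + rng.normal(0.0, score_noise_sd, size=len(pat_rows)))
        mask = rng.random(len(pat_rows)) < patient_missing_rate
        vals[mask] = np.nan
        col[pat_rows] = vals
        if controls == "norm":
            col[~is_pat] = baselines[score] + rng.normal(
                0.0, score_noise_sd, size=int((~is_pat).sum())
            )
        out[score] = col
    return out
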