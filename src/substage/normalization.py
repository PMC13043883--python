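"""Control-referenced volume normalisation.

Regional volumes are adjusted for age, sex and total intracranial volume
(TIV) by ordinary least squares fitted on the control group only, and every
subject's residual is scaled by the control residual SD.  The sign is
flipped so that *atrophy is positive*:

    z = (predicted - observed) / residual SD

which is the orientation the monotone-increase event model requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import validate_subjects

__all__ = [
    "ControlModel",
    "compute_tiv",
    "average_bilateral",
    "fit_control_model",
    "compute_zscores",
]

COVARIATES = ("intercept", "age", "female", "tiv")


def compute_tiv(gm: float, wm: float, csf: float) -> float:
    """Total intracranial volume: grey + white matter + CSF (mm^3)."""
    for name, v in (("gm", gm), ("wm", wm), ("csf", csf)):
        if v < 0:
            raise ValueError(f"{name} volume must be non-negative, got {v}")
    return gm + wm + csf


def average_bilateral(
    volumes: pd.DataFrame, pairing: dict[str, tuple[str, str]]
) -> pd.DataFrame:
    """Replace left/right column pairs by their arithmetic mean.

    ``pairing`` maps the bilateral output name to its (left, right) input
    columns.  Unpaired columns pass through unchanged; column order is
    preserved with the bilateral column taking the left member's slot.
    """
    for name, (lcol, rcol) in pairing.items():
        missing = [c for c in (lcol, rcol) if c not in volumes.columns]
        if missing:
            raise ValueError(f"pair {name!r} missing member(s): {missing}")
    out = volumes.copy()
    for name, (lcol, rcol) in pairing.items():
        mean = (out[lcol] + out[rcol]) / 2.0
        pos = out.columns.get_loc(lcol)
        out = out.drop(columns=[lcol, rcol])
        out.insert(min(pos, len(out.columns)), name, mean)
    return out


@dataclass
class ControlModel:
    """Per-region control covariate model and residual scale.

    ``coefficients`` is a regions x (intercept, age, female, tiv) frame;
    ``resid_sd`` the per-region residual SD with an n - p denominator
    (p = 4), fitted on controls only.
    """

    coefficients: pd.DataFrame
    resid_sd: pd.Series
    n_controls: int

    def __post_init__(self):
        if (self.resid_sd <= 0).any():
            bad = self.resid_sd.index[self.resid_sd <= 0].tolist()
            raise ValueError(f"non-positive residual SD for regions {bad}")

    @property
    def regions(self) -> list[str]:
        return self.coefficients.index.tolist()

    def predict(self, subjects: pd.DataFrame) -> pd.DataFrame:
        X = _design_matrix(subjects)
        pred = X @ self.coefficients.to_numpy().T
        return pd.DataFrame(pred, columns=self.regions,
                            index=pd.Index(subjects["subject_id"], name="subject_id"))

    def to_dict(self) -> dict:
        return {
            "covariates": list(COVARIATES),
            "coefficients": {r: self.coefficients.loc[r].tolist() for r in self.regions},
            "resid_sd": {r: float(self.resid_sd[r]) for r in self.regions},
            "n_controls": self.n_controls,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControlModel":
        coef = pd.DataFrame.from_dict(d["coefficients"], orient="index",
                                      columns=list(d["covariates"]))
        return cls(coef, pd.Series(d["resid_sd"]), int(d["n_controls"]))


def _design_matrix(subjects: pd.DataFrame) -> np.ndarray:
    female = (subjects["sex"] == "female").astype(float).to_numpy()
    return np.column_stack([
        np.ones(len(subjects)),
        subjects["age"].to_numpy(dtype=float),
        female,
        subjects["tiv"].to_numpy(dtype=float),
    ])


def fit_control_model(
    volumes: pd.DataFrame, subjects: pd.DataFrame, min_controls: int = 10
) -> ControlModel:
    """OLS of each region's volume on (age, sex, TIV) over control rows only."""
    validate_subjects(subjects)
    controls = subjects[subjects["group"] == "control"]
    if len(controls) < min_controls:
        raise ValueError(f"need >= {min_controls} controls, got {len(controls)}")
    X = _design_matrix(controls)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        sds = X.std(axis=0)
        degenerate = [COVARIATES[i] for i in range(1, X.shape[1]) if sds[i] == 0]
        raise ValueError(
            f"control design is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"constant column(s): {degenerate or 'collinear covariates'}"
        )
    Y = volumes.loc[controls["subject_id"]]
    coefs, sds = {}, {}
    for region in Y.columns:
        fit = sm.OLS(Y[region].to_numpy(dtype=float), X).fit()
        coefs[region] = fit.params
        sds[region] = float(np.sqrt(fit.mse_resid))  # SSR / (n - p)
    coef = pd.DataFrame.from_dict(coefs, orient="index", columns=list(COVARIATES))
    return ControlModel(coef, pd.Series(sds), len(controls))


def compute_zscores(
    volumes: pd.DataFrame, subjects: pd.DataFrame, model: ControlModel
) -> pd.DataFrame:
    """Atrophy-positive z-scores for all subjects under the control model.

    z = (predicted - observed) / control residual SD, so a volume deficit
    of one control SD scores +1.  Columns follow the model's region order.
    """
    unseen = [c for c in volumes.columns if c not in model.regions]
    if unseen:
        raise ValueError(f"regions absent from control model: {unseen}")
    regions = [r for r in model.regions if r in volumes.columns]
    pred = model.predict(subjects)[regions]
    obs = volumes.loc[pred.index, regions]
    z = (pred - obs) / model.resid_sd[regions]
    if not np.all(np.isfinite(z.to_numpy())):
        raise ValueError("non-finite z-scores produced")
    return z
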