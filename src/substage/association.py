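"""Stage-association scanning.

Within a subtype, the inferred disease stage is tested against every
candidate variable (regional volumes, or all unique connectivity edges)
with a *partial Spearman* correlation: both sides are first residualised
on nuisance covariates by OLS, then rank-correlated.  Significance comes
from permutations of the residualised stage vector — one shared stream of
permutations across all units, which both keeps per-unit p-values exact
and lets the maximum statistic over units control the family-wise error
rate under arbitrary dependence.  Benjamini–Hochberg FDR q-values are
computed over the same family.
"""

from __future__ import annotations

from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "residualize",
    "partial_spearman",
    "permutation_scan",
    "permutation_pvalue",
    "bh_fdr",
    "edge_enumeration",
    "design_from_subjects",
]


def design_from_subjects(subjects: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Intercept + encoded covariate columns from a subject table.

    Categorical covariates are encoded as single indicators: sex (female=1),
    handedness (left=1), scanner (B=1).  ``age`` and ``tiv`` pass through.
    """
    cols = [np.ones(len(subjects))]
    for name in covariates:
        if name == "sex":
            cols.append((subjects["sex"] == "female").astype(float).to_numpy())
        elif name == "handedness":
            cols.append((subjects["handedness"] == "left").astype(float).to_numpy())
        elif name == "scanner":
            cols.append((subjects["scanner"] == "B").astype(float).to_numpy())
        elif name in subjects.columns:
            cols.append(subjects[name].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return np.column_stack(cols)


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of y on a full-rank design (intercept included by caller)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ValueError("y and covariates are not row-aligned")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"covariate design rank-deficient (rank {rank} < {X.shape[1]})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _rank_normalize(y: np.ndarray) -> np.ndarray | None:
    """Centred unit-norm average ranks; None when ranks are constant."""
    r = rankdata(y)
    r = r - r.mean()
    norm = np.linalg.norm(r)
    if norm == 0:
        return None
    return r / norm


def partial_spearman(x, y, covariates=None) -> float:
    """Spearman correlation of the covariate-residualised x and y.

    With ``covariates`` None, an intercept-only design is used (plain
    Spearman).  Average ranks handle ties.  Returns NaN when either residual
    vector has constant ranks (undefined correlation, not a numeric error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need aligned vectors with n >= 4")
    if covariates is None:
        covariates = np.ones((len(x), 1))
    rx = _rank_normalize(residualize(x, covariates))
    ry = _rank_normalize(residualize(y, covariates))
    if rx is None or ry is None:
        return float("nan")
    return float(rx @ ry)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values over one family of tests."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    finite = np.isfinite(p)
    if np.any((p[finite] <= 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def edge_enumeration(n_regions: int) -> list[tuple[int, int]]:
    """All unordered region pairs (i < j) in row-major order; n(n-1)/2 of them."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    iu = np.triu_indices(n_regions, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def permutation_scan(
    stage: np.ndarray,
    targets: np.ndarray | pd.DataFrame,
    covariates: np.ndarray | None = None,
    B: int = 20_000,
    seed: int = 0,
    unit_names: list[str] | None = None,
    exhaustive: bool = False,
    smoothing: str = "add-one",
    chunk: int = 2_000,
) -> pd.DataFrame:
    """Partial-Spearman scan of stage against every target column.

    For each of B permutations the residualised stage vector is shuffled
    once and correlated against every unit's fixed residual ranks (shared
    permutations), giving per-unit two-sided p-values on |rho|, BH-FDR
    q-values over the family, and max-statistic FWER-adjusted p-values.
    ``exhaustive`` enumerates all n! permutations (n <= 8) and reports exact
    proportions.  Deterministic given ``seed``.

    Returns a DataFrame (unit, rho, p_perm, q_fdr, p_fwer) in unit order,
    with B, n, and the smoothing mode in ``.attrs``.
    """
    stage = np.asarray(stage, dtype=float)
    if isinstance(targets, pd.DataFrame):
        unit_names = unit_names or [str(c) for c in targets.columns]
        targets = targets.to_numpy(dtype=float)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    n, m = targets.shape
    if len(stage) != n:
        raise ValueError("stage and targets are not row-aligned")
    if covariates is None:
        covariates = np.ones((n, 1))
    covariates = np.asarray(covariates, dtype=float)
    if n < covariates.shape[1] + 2:
        raise ValueError(
            f"{n} subjects cannot support {covariates.shape[1]} covariate columns"
        )
    if not exhaustive and B < 100:
        raise ValueError("need B >= 100 permutations")
    if unit_names is None:
        unit_names = [f"unit_{k}" for k in range(m)]

    s = _rank_normalize(residualize(stage, covariates))
    if s is None:
        raise ValueError("stage residual ranks are constant; association undefined")
    R = np.empty((n, m))
    valid = np.ones(m, dtype=bool)
    for k in range(m):
        rk = _rank_normalize(residualize(targets[:, k], covariates))
        if rk is None:
            valid[k] = False
            R[:, k] = 0.0
        else:
            R[:, k] = rk
    rho_obs = s @ R
    abs_obs = np.abs(rho_obs)

    count = np.zeros(m)
    count_max = np.zeros(m)
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive mode limited to n <= 8")
        perms = np.array(list(_iter_permutations(range(n))))
        B_eff = len(perms)
        S = s[perms]  # (n!, n)
        A = np.abs(S @ R)
        A[:, ~valid] = -np.inf
        count = (A >= abs_obs[None, :] - 1e-12).sum(axis=0).astype(float)
        mx = A[:, valid].max(axis=1) if valid.any() else np.full(len(A), -np.inf)
        count_max = (mx[:, None] >= abs_obs[None, :] - 1e-12).sum(axis=0).astype(float)
        p = count / B_eff
        p_fwer = count_max / B_eff
    else:
        rng = np.random.default_rng(seed)
        done = 0
        while done < B:
            nb = min(chunk, B - done)
            S = np.empty((nb, n))
            for b in range(nb):
                S[b] = s[rng.permutation(n)]
            A = np.abs(S @ R)
            A[:, ~valid] = -np.inf
            count += (A >= abs_obs[None, :] - 1e-12).sum(axis=0)
            mx = A[:, valid].max(axis=1) if valid.any() else np.full(nb, -np.inf)
            count_max += (mx[:, None] >= abs_obs[None, :] - 1e-12).sum(axis=0)
            done += nb
        if smoothing == "add-one":
            p = (1.0 + count) / (B + 1.0)
            p_fwer = (1.0 + count_max) / (B + 1.0)
        elif smoothing == "none":
            p = count / B
            p_fwer = count_max / B
        else:
            raise ValueError(f"unknown smoothing mode {smoothing!r}")
        B_eff = B
    p = np.where(valid, p, np.nan)
    p_fwer = np.where(valid, p_fwer, np.nan)
    rho_out = np.where(valid, rho_obs, np.nan)
    q = bh_fdr(p) if valid.any() else np.full(m, np.nan)
    out = pd.DataFrame({
        "unit": unit_names,
        "rho": rho_out,
        "p_perm": p,
        "q_fdr": q,
        "p_fwer": p_fwer,
    })
    out.attrs.update({"B": int(B_eff), "n": int(n), "smoothing": smoothing,
                      "exhaustive": bool(exhaustive)})
    return out


def permutation_pvalue(
    stage, y, covariates=None, B: int = 20_000, seed: int = 0, **kwargs
) -> tuple[float, float]:
    """(rho, permutation p) for a single unit; same stream contract as the scan."""
    res = permutation_scan(stage, np.asarray(y, dtype=float)[:, None],
                           covariates, B=B, seed=seed, **kwargs)
    return float(res["rho"][0]), float(res["p_perm"][0])
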