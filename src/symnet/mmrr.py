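"""Multiple matrix regression with randomization (MMRR).

Regresses an unfolded dependent distance/similarity matrix on one or more
predictor matrices.  All unfolded vectors are z-scored so coefficients are
standardized and comparable across predictors.  Significance comes from
permuting the *dependent* matrix's species labels simultaneously on rows
and columns (the Mantel-family convention for matrix regression), re-
fitting, and comparing |t| (and F) against the permutation distribution
with the +1 small-sample correction; ties count as exceedances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-9


def unfold(M) -> np.ndarray:
    """Strictly-lower-triangle entries of a square symmetric matrix.

    Fixed (row-major, i > j) order; length n(n-1)/2.  Raises on asymmetry
    beyond 1e-9.
    """
    A = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if np.abs(A - A.T).max() > SYMMETRY_TOL:
        raise ValueError("matrix asymmetric beyond 1e-9")
    i, j = np.tril_indices(A.shape[0], k=-1)
    return A[i, j]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant unfolded vector")
    return (v - v.mean()) / sd


@dataclass
class MMRRResult:
    """Standardized coefficients and permutation inference for one model."""

    predictor_names: list[str]
    beta: list[float]
    t: list[float]
    p_perm: list[float]
    r2: float
    F: float
    F_p_perm: float
    nperm: int
    seed: int | None
    n_species: int
    n_pairs: int
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "t": self.t, "p_perm": self.p_perm},
            index=self.predictor_names,
        )


def _check_labels(Y, Xs) -> None:
    if not isinstance(Y, pd.DataFrame):
        return
    for X in Xs:
        if isinstance(X, pd.DataFrame):
            if list(X.index) != list(Y.index):
                bad = next(
                    (a for a, b in zip(X.index, Y.index) if a != b),
                    "length mismatch",
                )
                raise ValueError(f"label mismatch between matrices at {bad!r}")


def mmrr(
    Y,
    Xs,
    names: list[str] | None = None,
    nperm: int = 9999,
    seed: int | None = None,
) -> MMRRResult:
    """Fit Y ~ X1 + ... + Xp on unfolded z-scored matrices with permutation p.

    Parameters
    ----------
    Y
        Square symmetric dependent matrix (similarity or distance).
    Xs
        Predictor matrices sharing Y's labels and order.
    names
        Predictor names for reporting; defaults to X1..Xp or DataFrame-
        derived names when available.
    nperm
        Number of random species-label permutations (>= 99).  Each
        permutes rows and columns of Y simultaneously, re-unfolds and
        re-fits; p = (#{|t_perm| >= |t_obs|} + 1) / (nperm + 1).
    seed
        Seed for the permutation stream; same seed, same result.
    """
    if nperm < 99:
        raise ValueError("nperm must be >= 99")
    _check_labels(Y, Xs)
    Ym = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, dtype=float)
    n = Ym.shape[0]
    if names is None:
        names = [f"X{k + 1}" for k in range(len(Xs))]
    y = _zscore(unfold(Ym))
    Xcols = [_zscore(unfold(X)) for X in Xs]
    npairs = len(y)
    X = np.column_stack([np.ones(npairs)] + Xcols)
    p = len(Xcols)
    dof = npairs - p - 1

    XtX_inv = np.linalg.inv(X.T @ X)
    A = XtX_inv @ X.T  # maps y -> beta
    diag = np.diag(XtX_inv)

    def fit(yv: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
        beta = A @ yv
        resid = yv - X @ beta
        rss = float(resid @ resid)
        tss = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss
        sigma2 = rss / dof
        t = beta / np.sqrt(sigma2 * diag)
        F = (r2 / p) / ((1.0 - r2) / dof) if r2 < 1 else np.inf
        return beta, t, r2, F

    beta_obs, t_obs, r2_obs, F_obs = fit(y)

    # vectorised permutation null: gather permuted-Y pairs for all perms at once
    rng = np.random.default_rng(seed)
    iu, ju = np.tril_indices(n, k=-1)
    perms = np.array([rng.permutation(n) for _ in range(nperm)])
    Yp = Ym[perms[:, iu], perms[:, ju]]  # (nperm, npairs)
    Yp = (Yp - Yp.mean(axis=1, keepdims=True)) / Yp.std(axis=1, ddof=1, keepdims=True)
    B = Yp @ A.T  # (nperm, p+1)
    resid = Yp - B @ X.T
    rss = (resid**2).sum(axis=1)
    tss = (Yp**2).sum(axis=1) - npairs * Yp.mean(axis=1) ** 2
    r2_perm = 1.0 - rss / tss
    sigma2 = rss / dof
    t_perm = B / np.sqrt(sigma2[:, None] * diag[None, :])
    with np.errstate(divide="ignore"):
        F_perm = (r2_perm / p) / ((1.0 - r2_perm) / dof)

    p_perm = (
        (np.abs(t_perm[:, 1:]) >= np.abs(t_obs[1:])[None, :]).sum(axis=0) + 1
    ) / (nperm + 1)
    F_p = float(((F_perm >= F_obs).sum() + 1) / (nperm + 1))

    return MMRRResult(
        predictor_names=list(names),
        beta=[float(b) for b in beta_obs[1:]],
        t=[float(t) for t in t_obs[1:]],
        p_perm=[float(v) for v in p_perm],
        r2=float(r2_obs),
        F=float(F_obs),
        F_p_perm=F_p,
        nperm=nperm,
        seed=seed,
        n_species=n,
        n_pairs=npairs,
    )
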