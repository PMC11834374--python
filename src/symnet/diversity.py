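"""Per-species diversity indices, rarefaction, and the diversity screen.

Richness, Shannon entropy (nats) and Gini-Simpson (1 - sum p^2) summarise
each aphid species' partner community.  Because sampling effort differs
wildly across species, indices are also computed on repeated random
subsamples of a fixed depth (rarefaction, without replacement); species
with fewer samples than the depth are excluded rather than resampled with
replacement.  A one-predictor OLS screen relates symbiont strain
diversity to parasitoid or plant diversity across species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .observations import CommunityMatrix


@dataclass
class LinearFit:
    """One-predictor ordinary least squares fit summary."""

    slope: float
    intercept: float
    r2_adjusted: float
    F: float
    p: float
    n: int


def diversity_indices(counts) -> tuple[int, float, float]:
    """(richness, Shannon in nats, Gini-Simpson) of one count vector."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    richness = int((c > 0).sum())
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    return richness, shannon, simpson


def rarefy_indices(
    counts,
    depth: int = 7,
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float] | None:
    """Mean (richness, Shannon, Simpson) over subsamples of ``depth``.

    Each replicate draws ``depth`` individuals without replacement from
    the community (multivariate hypergeometric).  Returns ``None`` when
    the community holds fewer than ``depth`` individuals — an exclusion
    signal for the caller to log, not an exception.
    """
    c = np.asarray(counts, dtype=int)
    total = int(c.sum())
    if total < depth:
        return None
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(c, depth, size=reps)
    rich = np.empty(reps)
    shan = np.empty(reps)
    simp = np.empty(reps)
    for k, d in enumerate(draws):
        rich[k], shan[k], simp[k] = diversity_indices(d)
    return float(rich.mean()), float(shan.mean()), float(simp.mean())


def expected_rarefied_richness(counts, depth: int) -> float:
    """Closed-form expectation of rarefied richness.

    E[S_d] = sum_i 1 - C(N - N_i, d)/C(N, d) under sampling without
    replacement; used as an analytic check on the Monte-Carlo mean.
    """
    from scipy.special import gammaln

    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    N = c.sum()

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = 0.0
    for ni in c:
        if N - ni < depth:
            out += 1.0
        else:
            out += 1.0 - np.exp(log_comb(N - ni, depth) - log_comb(N, depth))
    return float(out)


def fit_diversity_model(x, y) -> LinearFit:
    """OLS of y on x with intercept; F test on the single slope.

    The reported R^2 is adjusted, 1 - (1-R^2)(n-1)/(n-2), which can go
    negative for uninformative predictors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched x, y with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    if np.ptp(y) == 0:
        # constant response: no fit to test
        return LinearFit(0.0, float(y[0]), 0.0, 0.0, 1.0, len(x))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2_adjusted=float(res.rsquared_adj),
        F=float(res.fvalue) if np.isfinite(res.fvalue) else 0.0,
        p=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0,
        n=len(x),
    )


def diversity_table(
    matrices: dict[str, CommunityMatrix],
    depth: int = 7,
    reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-species diversity indices for each community matrix.

    One row per (aphid species, partner kind, variant) where variant is
    ``full`` or ``rarefied``; species below the rarefaction depth carry
    NaN in the rarefied rows and are flagged excluded.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for kind, M in matrices.items():
        for sp in M.focal_labels:
            c = M.counts.loc[sp].to_numpy()
            if c.sum() == 0:
                continue
            r, h, s = diversity_indices(c)
            rows.append(
                dict(species=sp, partner_kind=kind, variant="full",
                     n_samples=int(c.sum()), richness=r, shannon=h, simpson=s,
                     excluded=False)
            )
            rar = rarefy_indices(c, depth=depth, reps=reps, seed=rng)
            if rar is None:
                rows.append(
                    dict(species=sp, partner_kind=kind, variant=f"rarefied_{depth}",
                         n_samples=int(c.sum()), richness=np.nan, shannon=np.nan,
                         simpson=np.nan, excluded=True)
                )
            else:
                rows.append(
                    dict(species=sp, partner_kind=kind, variant=f"rarefied_{depth}",
                         n_samples=int(c.sum()), richness=rar[0], shannon=rar[1],
                         simpson=rar[2], excluded=False)
                )
    return pd.DataFrame(rows)
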