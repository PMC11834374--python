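"""Bipartite network specialisation and sharing statistics.

The network-level specialisation index H2' rescales the two-dimensional
Shannon entropy of an interaction count table between the minimum and
maximum entropies achievable by integer tables with the same row and
column totals: 0 means interactions follow the marginal expectation
(perfect generality), 1 means maximal partner specialisation.  Observed
H2' is compared against fixed-marginal (Patefield) null tables to give a
standardised effect size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import random_table

from .observations import CommunityMatrix


def _entropy(T: np.ndarray) -> float:
    p = T[T > 0].astype(float)
    p = p / T.sum()
    return float(-(p * np.log(p)).sum())


def _delta(T, i1, i2, j1, j2, k, m) -> float:
    """Entropy change from moving k units along the 2x2 cycle
    (i1,j1)+k, (i1,j2)-k, (i2,j1)-k, (i2,j2)+k (marginals preserved)."""
    def h(v):
        return 0.0 if v <= 0 else -v / m * np.log(v / m)

    a, b, c, d = T[i1, j1], T[i1, j2], T[i2, j1], T[i2, j2]
    return (
        h(a + k) + h(b - k) + h(c - k) + h(d + k)
        - h(a) - h(b) - h(c) - h(d)
    )


def _refine(T: np.ndarray, maximize: bool, max_sweeps: int = 200) -> np.ndarray:
    """Coordinate ascent/descent over 2x2 unit-transfer cycles.

    Along each cycle the entropy is concave in the transfer amount, so the
    maximising step jumps straight to the concave optimum and the
    minimising step to the better endpoint.  Sweeps repeat until no move
    improves the entropy.
    """
    T = T.copy()
    n, p = T.shape
    m = T.sum()
    tol = 1e-12
    for _ in range(max_sweeps):
        improved = False
        for i1 in range(n):
            for i2 in range(i1 + 1, n):
                for j1 in range(p):
                    for j2 in range(j1 + 1, p):
                        lo = -int(min(T[i1, j1], T[i2, j2]))
                        hi = int(min(T[i1, j2], T[i2, j1]))
                        if hi - lo == 0:
                            continue

                        def f(k):
                            return _delta(T, i1, i2, j1, j2, k, m)

                        best_k = 0
                        if maximize:
                            # f is concave with f(0)=0, so f(k) <= k*f(1)
                            # (resp. |k|*f(-1)); reject unless a unit step
                            # improves, else binary-search the argmax.
                            up = hi >= 1 and f(1) > tol
                            dn = lo <= -1 and f(-1) > tol
                            if up or dn:
                                a, b = (1, hi) if up else (lo, -1)
                                while b - a > 1:
                                    mid = (a + b) // 2
                                    if f(mid + 1) > f(mid):
                                        a = mid + 1
                                    else:
                                        b = mid
                                best_k = a if f(a) >= f(b) else b
                        else:
                            # concave => the minimum lies at an endpoint
                            cand = [(f(lo), lo), (f(hi), hi)]
                            d, k = min(cand)
                            if d < -tol:
                                best_k = k
                        if best_k != 0:
                            T[i1, j1] += best_k
                            T[i1, j2] -= best_k
                            T[i2, j1] -= best_k
                            T[i2, j2] += best_k
                            improved = True
        if not improved:
            break
    return T


def _canonical(fn):
    """Sort marginals descending before building an extreme table, then
    undo the permutation, so the bound does not depend on input order."""

    def wrapped(r: np.ndarray, c: np.ndarray) -> np.ndarray:
        ri = np.argsort(-r, kind="stable")
        ci = np.argsort(-c, kind="stable")
        T = fn(r[ri], c[ci])
        out = np.empty_like(T)
        out[np.ix_(ri, ci)] = T
        return out

    return wrapped


@_canonical
def _max_entropy_table(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Most even integer table with the given marginals.

    Small webs are solved exactly by enumeration; larger webs seed from
    largest-remainder rounding of the independence expectation r_i c_j / m
    (extra units go to admissible cells by remainder, ties row-major) and
    refine with 2x2 cycle moves, which lands on or very near the integer
    optimum once totals are large.
    """
    if len(r) * len(c) <= 16 and r.sum() <= 16:
        return _enumerate_extreme(r, c, maximize=True)
    m = r.sum()
    E = np.outer(r, c) / m
    T = np.floor(E).astype(np.int64)
    rem = E - T
    row_def = r - T.sum(axis=1)
    col_def = c - T.sum(axis=0)
    while row_def.sum() > 0:
        mask = (row_def[:, None] > 0) & (col_def[None, :] > 0)
        masked = np.where(mask, rem, -1.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        T[i, j] += 1
        row_def[i] -= 1
        col_def[j] -= 1
    return _refine(T, maximize=True)


def _greedy_concentrate(r: np.ndarray, c: np.ndarray, exact_first: bool) -> np.ndarray:
    """Greedy concentration: repeatedly place min(remaining row, remaining
    col) in the cell where that allocation is largest (ties row-major).
    With ``exact_first`` an allocation that exhausts a row and a column
    simultaneously takes precedence, which concentrates harder."""
    r = r.astype(np.int64).copy()
    c = c.astype(np.int64).copy()
    T = np.zeros((len(r), len(c)), dtype=np.int64)
    while r.sum() > 0:
        alloc = np.minimum(r[:, None], c[None, :])
        key = alloc.astype(float)
        if exact_first:
            exact = (r[:, None] == c[None, :]) & (alloc > 0)
            key = key + exact * (r.sum() + 1.0)
        i, j = np.unravel_index(np.argmax(key), key.shape)
        T[i, j] += alloc[i, j]
        r[i] -= alloc[i, j]
        c[j] -= alloc[i, j]
    return T


def _enumerate_extreme(r: np.ndarray, c: np.ndarray, maximize: bool) -> np.ndarray:
    """Exact extreme-entropy table by enumerating all tables with the
    given marginals; feasible only for small webs."""
    n, p = len(r), len(c)
    sign = -1.0 if maximize else 1.0
    best = {"H": np.inf, "T": None}

    def fill_row(i: int, cols_left: tuple, rows: list) -> None:
        if i == n - 1:
            T = np.array(rows + [list(cols_left)], dtype=np.int64)
            H = sign * _entropy(T)
            if H < best["H"] - 1e-15:
                best["H"], best["T"] = H, T
            return

        def comps(j: int, rem: int, row: list) -> None:
            if j == p - 1:
                if rem <= cols_left[j]:
                    left = tuple(
                        cl - v for cl, v in zip(cols_left, row + [rem])
                    )
                    fill_row(i + 1, left, rows + [row + [rem]])
                return
            for v in range(min(rem, cols_left[j]) + 1):
                comps(j + 1, rem - v, row + [v])

        comps(0, int(r[i]), [])

    fill_row(0, tuple(int(x) for x in c), [])
    return best["T"]


@_canonical
def _min_entropy_table(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Most concentrated integer table with the given marginals.

    The minimum of the (concave) entropy over the transportation polytope
    sits at a vertex, which greedy allocation does not always reach; for
    small webs the minimum is found exactly by enumeration, for larger
    ones two greedy concentration variants are refined with 2x2 cycle
    moves and the lower-entropy result kept.
    """
    if len(r) * len(c) <= 16 and r.sum() <= 16:
        return _enumerate_extreme(r, c, maximize=False)
    cands = [
        _refine(_greedy_concentrate(r, c, exact_first=ef), maximize=False)
        for ef in (False, True)
    ]
    return min(cands, key=_entropy)


def h2_components(M) -> tuple[float, float, float, float]:
    """(H2, H2min, H2max, H2') of an interaction count matrix.

    H2 is the Shannon entropy of the cell proportions; H2min/H2max are
    entropies of heuristic extreme tables sharing the observed marginals;
    H2' = (H2max - H2)/(H2max - H2min) clamped to [0, 1].  Returns H2'=0
    with a warning when the marginals admit no entropy range.
    """
    A = M.values if isinstance(M, CommunityMatrix) else np.asarray(M)
    A = np.asarray(A, dtype=np.int64)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("H2' needs at least 2 rows and 2 columns")
    if A.sum() < 2:
        raise ValueError("H2' needs at least 2 interactions")
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    H2 = _entropy(A)
    H2min = _entropy(_min_entropy_table(r, c))
    H2max = _entropy(_max_entropy_table(r, c))
    if H2max - H2min <= 1e-12:
        warnings.warn("degenerate marginals: H2max == H2min; H2' set to 0")
        return H2, H2min, H2max, 0.0
    h2p = (H2max - H2) / (H2max - H2min)
    return H2, H2min, H2max, float(np.clip(h2p, 0.0, 1.0))


def patefield_sample(
    row_sums, col_sums, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """One random contingency table with exactly the given marginals.

    Uniform-hypergeometric null (equivalent to shuffling row-labelled
    against column-labelled interaction tokens and tallying).
    """
    r = np.asarray(row_sums, dtype=np.int64)
    c = np.asarray(col_sums, dtype=np.int64)
    if r.sum() != c.sum() or r.sum() == 0:
        raise ValueError("row and column sums must match and be positive")
    rng = np.random.default_rng(seed)
    if len(r) == 1:
        return c.reshape(1, -1).copy()
    if len(c) == 1:
        return r.reshape(-1, 1).copy()
    return random_table(r, c).rvs(random_state=rng).astype(np.int64)


@dataclass
class H2Result:
    """Observed H2' with its fixed-marginal null distribution summary."""

    H2: float
    H2min: float
    H2max: float
    h2prime: float
    null_mean: float
    null_sd: float
    ses: float | None
    n_null: int
    seed: int | None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def h2_ses(
    M, n_null: int = 1000, seed: int | None = None
) -> H2Result:
    """H2' standardised effect size against the Patefield null.

    Draws ``n_null`` fixed-marginal tables, scores each with H2' (the
    entropy bounds depend only on the marginals, so they are computed
    once), and reports ses = (observed - null mean) / null sd with the
    sample (n-1) standard deviation.  ses is None with a warning when the
    null distribution is degenerate.
    """
    A = M.values if isinstance(M, CommunityMatrix) else np.asarray(M)
    A = np.asarray(A, dtype=np.int64)
    H2, H2min, H2max, h2p = h2_components(A)
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    rng = np.random.default_rng(seed)
    span = H2max - H2min
    dist = random_table(r, c)
    nulls = np.empty(n_null)
    draws = dist.rvs(size=n_null, random_state=rng)
    for k in range(n_null):
        if span <= 1e-12:
            nulls[k] = 0.0
        else:
            nulls[k] = np.clip((H2max - _entropy(draws[k])) / span, 0.0, 1.0)
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd == 0:
        warnings.warn("null H2' distribution degenerate; SES undefined")
        ses = None
    else:
        ses = float((h2p - mean) / sd)
    return H2Result(H2, H2min, H2max, h2p, mean, sd, ses, n_null, seed)


def project_parasitoid_symbiont(
    A: CommunityMatrix | pd.DataFrame, S: CommunityMatrix | pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Project symbiont strains onto parasitoids via shared aphid hosts.

    Each aphid species' strain counts are assigned to the parasitoids
    attacking it, proportionally to attack frequency:
    ``B[p, s] = sum_a S[a, s] * A[a, p] / sum_p' A[a, p']``.  Aphids with
    no parasitoid records (or absent from either matrix) are dropped and
    reported.  Fractional weights are retained, and the projection
    conserves the total strain count over retained aphids.

    Returns ``(parasitoid x strain weighted matrix, dropped aphids)``.
    """
    Ad = A.counts if isinstance(A, CommunityMatrix) else A
    Sd = S.counts if isinstance(S, CommunityMatrix) else S
    shared = sorted(set(Ad.index) & set(Sd.index))
    dropped = sorted(set(Ad.index) ^ set(Sd.index))
    Ad = Ad.loc[shared]
    Sd = Sd.loc[shared]
    attack_tot = Ad.sum(axis=1)
    zero = attack_tot[attack_tot == 0].index.tolist()
    dropped += zero
    keep = attack_tot[attack_tot > 0].index
    if len(keep) == 0:
        raise ValueError("no aphid species with both parasitoid and strain records")
    W = Ad.loc[keep].div(attack_tot[keep], axis=0)  # aphid x parasitoid weights
    B = W.T @ Sd.loc[keep]  # parasitoid x strain
    return B, sorted(dropped)


@dataclass
class PairSummary:
    """Pairwise sharing structure between strain and partner communities."""

    pairs: pd.DataFrame  # one row per unordered species pair
    n_pairs: int
    n_strain_sharing: int
    n_strain_and_partner_sharing: int
    pct_partner_among_strain_sharing: float
    n_species_sharing_strains: int
    n_species_linked_by_partner: int
    pct_species_linked: float
    strains_in_multiple_species: int | None = None
    n_strains: int | None = None

    def to_csv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, index=False)


def shared_pair_summary(
    sim_strain: pd.DataFrame,
    sim_partner: pd.DataFrame,
    threshold: float = 0.0,
    strain_matrix: CommunityMatrix | pd.DataFrame | None = None,
) -> PairSummary:
    """Count species pairs sharing symbiont strains and ecological partners.

    A pair shares strains when its strain-community similarity exceeds 0;
    among those, partner sharing requires partner similarity above
    ``threshold`` (default 0, i.e., any overlap).  Species-level linkage
    asks, for each species sharing strains with any other, whether it also
    shares at least one partner taxon with at least one of its
    strain-sharing counterparts.  If the aphid x strain count matrix is
    supplied, strain-level spread (strains found in more than one species)
    is reported as well.
    """
    if list(sim_strain.index) != list(sim_partner.index):
        raise ValueError("label mismatch between similarity matrices")
    labels = list(sim_strain.index)
    n = len(labels)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            ss = float(sim_strain.iloc[i, j])
            sp = float(sim_partner.iloc[i, j])
            rows.append(
                dict(
                    species_a=labels[i],
                    species_b=labels[j],
                    strain_similarity=ss,
                    partner_similarity=sp,
                    shares_strain=ss > 0,
                    shares_partner=sp > threshold,
                )
            )
    pairs = pd.DataFrame(rows)
    sharing = pairs[pairs.shares_strain]
    n_share = len(sharing)
    n_both = int((sharing.shares_partner).sum())
    pct_both = 100.0 * n_both / n_share if n_share else 0.0

    linked_species = set()
    sharing_species = set(sharing.species_a) | set(sharing.species_b)
    for _, row in sharing.iterrows():
        if row.shares_partner:
            linked_species.add(row.species_a)
            linked_species.add(row.species_b)
    n_sharing_sp = len(sharing_species)
    n_linked = len(linked_species)

    spread = None
    n_strains = None
    if strain_matrix is not None:
        Sd = (
            strain_matrix.counts
            if isinstance(strain_matrix, CommunityMatrix)
            else strain_matrix
        )
        per_strain = (Sd > 0).sum(axis=0)
        n_strains = int((per_strain > 0).sum())
        spread = int((per_strain > 1).sum())

    return PairSummary(
        pairs=pairs,
        n_pairs=len(pairs),
        n_strain_sharing=n_share,
        n_strain_and_partner_sharing=n_both,
        pct_partner_among_strain_sharing=pct_both,
        n_species_sharing_strains=n_sharing_sp,
        n_species_linked_by_partner=n_linked,
        pct_species_linked=100.0 * n_linked / n_sharing_sp if n_sharing_sp else 0.0,
        strains_in_multiple_species=spread,
        n_strains=n_strains,
    )


def write_edge_list(B: pd.DataFrame, path: str | Path) -> None:
    """Write a weighted bipartite matrix as a (source, target, weight) CSV."""
    rows = [
        {"source": i, "target": j, "weight": float(B.at[i, j])}
        for i in B.index
        for j in B.columns
        if B.at[i, j] > 0
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
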