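"""Community similarity and gene-distance matrices over aphid species.

Community similarity is 1 - Bray-Curtis dissimilarity on the rows of a
community count matrix (1 = identical partner communities, 0 = disjoint).
Phylogenetic "relatedness" between species is summarised by the pairwise
count of differing alignment positions between one representative marker
sequence per species; note that this raw site-difference count *grows*
with unrelatedness, so a transform is provided and the mode used is
always recorded.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform

from .observations import CommunityMatrix
from .otu import SequenceSet

SYMMETRY_TOL = 1e-9


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative counts")
    if x.sum() + y.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(braycurtis(x, y))


def community_similarity(
    M: CommunityMatrix | pd.DataFrame, normalize: bool = False
) -> pd.DataFrame:
    """Pairwise 1 - Bray-Curtis similarity between focal-species rows.

    With ``normalize`` each row is first scaled to relative abundances
    (row sum 1), removing differences in sampling effort; the default
    operates on raw counts.
    """
    counts = M.counts if isinstance(M, CommunityMatrix) else M
    vals = counts.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 focal species")
    zero = counts.index[vals.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"all-zero rows for species: {zero}")
    if normalize:
        vals = vals / vals.sum(axis=1, keepdims=True)
    sim = 1.0 - squareform(pdist(vals, metric="braycurtis"))
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=counts.index, columns=counts.index)


def community_dissimilarity(
    M: CommunityMatrix | pd.DataFrame, normalize: bool = False
) -> pd.DataFrame:
    """Bray-Curtis dissimilarity counterpart of :func:`community_similarity`."""
    sim = community_similarity(M, normalize=normalize)
    out = 1.0 - sim
    np.fill_diagonal(out.values, 0.0)
    return out


def gene_distance_matrix(
    seqs: SequenceSet,
    one_per_species: Mapping[str, str],
    gap_mode: str = "pairwise_deletion",
) -> pd.DataFrame:
    """Pairwise count of differing sites between species representatives.

    ``one_per_species`` maps species name -> sequence id in ``seqs``.
    Positions where either sequence carries a gap or N are excluded under
    ``pairwise_deletion`` (default) or counted as differences under
    ``count_gaps``.  The result is an integer-valued labelled distance
    matrix (diagonal 0); it is a plain site count, not an evolutionary
    model distance, and need not satisfy the triangle inequality.
    """
    lookup = seqs.as_dict()
    species = sorted(one_per_species)
    missing = [s for s in species if one_per_species[s] not in lookup]
    if missing:
        raise ValueError(f"species without representative sequence: {missing}")
    arrs = {
        s: np.frombuffer(lookup[one_per_species[s]].encode(), dtype="S1")
        for s in species
    }
    n = len(species)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[species[i]], arrs[species[j]]
            if len(a) != len(b):
                raise ValueError("representatives are not aligned to equal length")
            if gap_mode == "pairwise_deletion":
                ok = ~np.isin(a, [b"-", b"N"]) & ~np.isin(b, [b"-", b"N"])
                d = int((a[ok] != b[ok]).sum())
            else:
                d = int((a != b).sum())
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=species, columns=species)


def relatedness_transform(D: pd.DataFrame, mode: str = "raw_distance") -> pd.DataFrame:
    """Re-express a gene-distance matrix for use as a relatedness predictor.

    Modes
    -----
    raw_distance
        Identity pass-through; a positive regression coefficient then
        refers to *distance* (unrelatedness).
    one_minus_scaled
        ``1 - D/max(D)``: 1 for identical species, 0 for the most distant
        pair.  All-zero D yields an all-ones matrix with a warning.
    negated_z
        ``-(D - mean)/sd`` over off-diagonal entries, so larger means more
        related and the off-diagonal entries have mean 0, sd 1.
    """
    vals = D.to_numpy(dtype=float)
    if mode == "raw_distance":
        out = vals.copy()
    elif mode == "one_minus_scaled":
        mx = vals.max()
        if mx == 0:
            import warnings

            warnings.warn("all distances zero; relatedness set to 1 everywhere")
            out = np.ones_like(vals)
        else:
            out = 1.0 - vals / mx
    elif mode == "negated_z":
        off = vals[~np.eye(len(vals), dtype=bool)]
        out = -(vals - off.mean()) / off.std(ddof=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = pd.DataFrame(out, index=D.index, columns=D.columns)
    res.attrs["relatedness_mode"] = mode
    return res


def read_square_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled square matrix from CSV, validating symmetry."""
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column labels differ")
    v = df.to_numpy(dtype=float)
    if np.abs(v - v.T).max() > SYMMETRY_TOL:
        raise ValueError("matrix is asymmetric beyond 1e-9")
    return df
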