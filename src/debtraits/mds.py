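"""Trait-space comparison by classical multidimensional scaling.

Species are compared through a bounded-loss distance: each trait
contributes a symmetric, scale-free loss (x_i - x_j)^2 / (x_i^2 + x_j^2)
in [0, 1], and the distance is the root mean of the per-trait losses, so
the full matrix is invariant to per-trait unit changes.  Classical
(Torgerson) scaling of the squared-distance matrix then yields embedding
coordinates, and each trait is correlated with the retained axes to read
off which traits organize the cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import MDS_TRAITS

__all__ = [
    "DistanceMatrix",
    "MDSResult",
    "pair_distance",
    "distance_matrix",
    "classical_mds",
    "trait_axis_correlations",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric bounded-loss distances between species."""

    matrix: np.ndarray          #: (n, n) symmetric, zero diagonal, entries in [0, 1]
    species: list[str]          #: row/column order
    traits: list[str]           #: traits the distances were computed from
    n_dropped: int = 0          #: species dropped for missing trait values


@dataclass(frozen=True)
class MDSResult:
    """Classical MDS embedding of a distance matrix."""

    coordinates: np.ndarray     #: (n, n_axes), axes ordered by eigenvalue
    eigenvalues: np.ndarray     #: all eigenvalues, nonincreasing
    species: list[str]
    n_axes: int


def pair_distance(x_i, x_j) -> float:
    """Bounded-loss distance between two trait vectors.

    d = sqrt( (1/K) sum_k (x_ik - x_jk)^2 / (x_ik^2 + x_jk^2) ), with 0/0
    terms counted as zero.  Lies in [0, 1]; symmetric; invariant to
    multiplying any trait by a positive constant in both rows.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.size == 0:
        raise ValueError("pair_distance needs at least one trait")
    num = (x_i - x_j) ** 2
    den = x_i**2 + x_j**2
    loss = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(np.sqrt(loss.mean()))


def distance_matrix(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    on_missing: str = "drop",
) -> DistanceMatrix:
    """Pairwise bounded-loss distance matrix over a trait table.

    Parameters
    ----------
    table
        Trait table with a ``species_id`` column.
    traits
        Trait columns to use; defaults to the twelve comparison traits.
    on_missing
        ``"drop"`` removes species with any missing selected trait
        (count reported); ``"error"`` raises instead.
    """
    traits = list(MDS_TRAITS if traits is None else traits)
    X = table[traits].to_numpy(dtype=float)
    complete = np.isfinite(X).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped and on_missing == "error":
        bad = table.loc[~complete, "species_id"].tolist()
        raise ValueError(f"missing trait values for species: {bad}")
    X = X[complete]
    species = table.loc[complete, "species_id"].tolist()
    n = len(species)
    if n < 2:
        raise ValueError("distance_matrix needs at least 2 complete species")

    # vectorized bounded loss over all pairs, one trait at a time
    D2 = np.zeros((n, n))
    for k in range(X.shape[1]):
        col = X[:, k]
        num = (col[:, None] - col[None, :]) ** 2
        den = col[:, None] ** 2 + col[None, :] ** 2
        D2 += np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    D = np.sqrt(D2 / X.shape[1])
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # enforce exact symmetry against rounding
    return DistanceMatrix(matrix=D, species=species, traits=traits,
                          n_dropped=n_dropped)


def classical_mds(D: DistanceMatrix, n_axes: int = 2) -> MDSResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers the squared distances, B = -1/2 J D^2 J, and
    eigendecomposes B; coordinates are eigenvectors scaled by the square
    roots of the positive eigenvalues.  Negative eigenvalues (the
    distances need not be Euclidean) are reported but never embedded; if
    fewer positive eigenvalues exist than requested axes the embedding is
    truncated with a warning.  Axis signs are fixed by making the
    largest-magnitude coordinate on each axis positive.
    """
    M = D.matrix
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M**2) @ J
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]

    n_pos = int((eigval > max(eigval[0], 0.0) * 1e-12).sum())
    if n_axes > n_pos:
        import warnings

        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; "
            "truncating", stacklevel=2)
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    # deterministic sign: largest |coordinate| per axis is positive
    for j in range(n_axes):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return MDSResult(coordinates=coords, eigenvalues=eigval,
                     species=list(D.species), n_axes=n_axes)


def trait_axis_correlations(
    table: pd.DataFrame,
    result: MDSResult,
    traits: list[str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of each trait with each retained MDS axis.

    Traits spanning orders of magnitude are log10-transformed by default
    (only strictly positive traits can be; others fall back to raw scale).
    A constant trait has no defined correlation and is reported as
    missing.  Returns a frame (trait x axis) of correlations.
    """
    traits = list(MDS_TRAITS if traits is None else traits)
    sub = table.set_index("species_id").loc[result.species, traits]
    out = pd.DataFrame(
        index=traits,
        columns=[f"axis_{j + 1}" for j in range(result.n_axes)],
        dtype=float,
    )
    for t in traits:
        x = sub[t].to_numpy(dtype=float)
        if log_transform and (x > 0).all():
            x = np.log10(x)
        if np.ptp(x) == 0:
            continue  # constant trait: correlation undefined, stays NaN
        for j in range(result.n_axes):
            y = result.coordinates[:, j]
            out.loc[t, f"axis_{j + 1}"] = float(np.corrcoef(x, y)[0, 1])
    return out
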