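"""Jensen-Shannon distances and principal coordinates analysis.

Samples (taxon compositions or SCFA profiles expressed as proportions) are
compared with the square root of the Jensen-Shannon divergence computed with
base-2 entropies, which is a metric bounded by [0, 1].  Ordination uses
classical metric scaling (PCoA): double-centre -1/2 D^2, eigendecompose, and
keep the positive axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.special import xlogy

logger = logging.getLogger(__name__)


def normalize_profile(raw, pseudocount: float = 0.0) -> np.ndarray:
    """Turn a non-negative feature vector into a probability vector.

    A pseudocount is added to every entry before renormalising, so profiles
    with structural zeros stay inside the simplex interior for JSD.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if np.any(raw < 0) or not np.all(np.isfinite(raw)):
        raise ValueError("entries must be finite and non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = raw + pseudocount
    total = shifted.sum()
    if total <= 0:
        raise ValueError("all-zero profile cannot be normalised without a pseudocount")
    return shifted / total


def jsd(p, q, base: float = 2.0) -> float:
    """Square-root Jensen-Shannon divergence between two probability vectors.

    Entropies use the given base (default 2, for which the value lies in
    [0, 1]); 0*log(0) is taken as 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch between profiles")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-9 or np.any(v < 0):
            raise ValueError(f"{name} is not a probability vector")
    return float(jensenshannon(p, q, base=base))


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over labelled samples."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        self.values = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self):
        return len(self.labels)


def _entropy2(P: np.ndarray) -> np.ndarray:
    return -xlogy(P, P).sum(axis=-1) / np.log(2.0)


def distance_matrix(profiles, labels=None, chunk: int = 128) -> DistanceMatrix:
    """Pairwise sqrt-JSD (base 2) over rows of ``profiles``.

    Vectorised via H(m) - (H(p)+H(q))/2 on the mixture m = (p+q)/2, computed
    in row chunks to bound memory on large cohorts.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D array (samples x features)")
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9) or np.any(P < 0):
        raise ValueError("every profile row must be a probability vector")
    n = P.shape[0]
    if labels is None:
        labels = list(range(n))
    H = _entropy2(P)
    D2 = np.empty((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        M = (P[start:stop, None, :] + P[None, :, :]) / 2.0
        D2[start:stop] = _entropy2(M) - (H[start:stop, None] + H[None, :]) / 2.0
    np.clip(D2, 0.0, None, out=D2)
    D = np.sqrt((D2 + D2.T) / 2.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=list(labels), values=D)


@dataclass
class Ordination:
    """PCoA result: sample coordinates on positive axes, in eigenvalue order."""

    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # descending, all > 0
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix) -> Ordination:
    """Classical metric scaling of a distance matrix.

    Double-centres -1/2 D^2, eigendecomposes, and returns coordinates
    eigenvector * sqrt(eigenvalue) on the positive axes.  Negative eigenvalues
    (non-Euclidean distances) are dropped with a logged warning.
    """
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, abs(eigval[0]) * 1e-12) if n else 1e-12
    keep = eigval > tol
    n_neg = int(np.sum(eigval < -tol))
    if n_neg:
        logger.warning(
            "dropping %d negative eigenvalue(s) (non-Euclidean distances); "
            "most negative %.3g",
            n_neg,
            float(eigval.min()),
        )
    lam = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(lam)
    total = lam.sum() if lam.size else 1.0
    return Ordination(
        coordinates=coords,
        eigenvalues=lam,
        proportion_explained=lam / total if lam.size else lam,
    )
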