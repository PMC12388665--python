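"""Alpha diversity, Bray–Curtis dissimilarity, PCoA and non-metric
multidimensional scaling (Kruskal stress-1)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats import ordination
from sklearn.base import BaseEstimator
from sklearn.manifold import smacof

from .errors import InsufficientDataError, ParameterError, ValidationError
from .io_tables import CountTable

__all__ = [
    "richness",
    "shannon",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "NMDS",
    "nmds",
]


def richness(counts) -> int:
    """Number of taxa with count > 0."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    return int(np.count_nonzero(counts))


def shannon(counts) -> float:
    """Shannon entropy H = -sum q ln q in nats (0 <= H <= ln richness)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("Shannon index undefined for a zero-sum sample")
    q = counts[counts > 0] / total
    return float(-(q * np.log(q)).sum())


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample richness and Shannon index."""
    rows = []
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows.append({"sample_id": sample, "richness": richness(col), "shannon": shannon(col)})
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity BC(j,k) = sum|x-y| / sum(x+y) between
    samples."""
    if table.n_samples < 2:
        raise InsufficientDataError("need >= 2 samples for a distance matrix")
    if np.any(table.sample_sums() == 0):
        raise ValidationError("Bray–Curtis undefined when a sample has zero total")
    condensed = pdist(table.counts.T.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.sample_ids))


def pcoa(D: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -D**2/2, eigendecomposes, truncates negative eigenvalues
    and returns the first ``k`` coordinate columns.  For a genuinely
    Euclidean D the embedded distances reproduce D.
    """
    n = D.shape[0]
    if k >= n:
        raise ParameterError(f"k={k} must be < number of samples ({n})")
    res = ordination.pcoa(D, method="eigh", number_of_dimensions=n - 1)
    coords = res.samples.to_numpy()
    if coords.shape[1] < k:  # degenerate D: pad with zero coordinates
        coords = np.hstack([coords, np.zeros((n, k - coords.shape[1]))])
    return coords[:, :k]


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Runs SMACOF with isotonic (monotone) regression of configuration
    distances on dissimilarity ranks, once from a PCoA initialization and
    ``n_restarts - 1`` times from seeded random starts, keeping the best
    configuration.  Stress-1 = sqrt(sum (d - dhat)^2 / sum d^2); values below
    0.2 are conventionally read as a fair representation and below 0.1 as a
    good one.

    Attributes
    ----------
    embedding_ : ndarray (n_samples, n_components), column-centered
    stress_ : float, Kruskal stress-1 of the best configuration
    n_iter_ : int
    converged_ : bool, False when the best run hit max_iter
    """

    def __init__(self, n_components: int = 2, seed: int = 0, max_iter: int = 300,
                 tol: float = 1e-6, n_restarts: int = 4):
        self.n_components = n_components
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts

    def fit(self, D, y=None):
        D = D if isinstance(D, DistanceMatrix) else DistanceMatrix(np.asarray(D, dtype=float))
        n = D.shape[0]
        if n < 4:
            raise InsufficientDataError("NMDS needs >= 4 samples")
        mat = D.data
        inits = [pcoa(D, self.n_components)]
        for r in range(1, self.n_restarts):
            rng = np.random.default_rng(self.seed + r)
            inits.append(rng.standard_normal((n, self.n_components)))
        best = None
        for init in inits:
            pos, stress, n_iter = smacof(
                mat, metric=False, n_components=self.n_components, init=init,
                n_init=1, max_iter=self.max_iter, eps=self.tol,
                normalized_stress=True, return_n_iter=True,
            )
            if best is None or stress < best[1]:
                best = (pos, stress, n_iter)
        pos, stress, n_iter = best
        self.embedding_ = pos - pos.mean(axis=0)
        self.stress_ = float(stress)
        self.n_iter_ = int(n_iter)
        self.converged_ = n_iter < self.max_iter
        self.sample_ids_ = list(D.ids)
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_


def nmds(D, k: int = 2, seed: int = 0, max_iter: int = 300, tol: float = 1e-6,
         n_restarts: int = 4) -> NMDS:
    """Fit NMDS to a distance matrix; returns the fitted estimator."""
    return NMDS(n_components=k, seed=seed, max_iter=max_iter, tol=tol,
                n_restarts=n_restarts).fit(D)
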