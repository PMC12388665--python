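"""Mantel / partial Mantel tests, environmental distances, Pearson panels,
and one-way ANOVA with LSD post hoc + compact letter display.

The Mantel permutation null is computed with an explicit seeded generator and
the one-tailed convention p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), rows
and columns of the second matrix permuted jointly.  Spearman variants rank
the off-diagonal dissimilarities once and reuse the Pearson machinery (a
joint permutation of a matrix permutes its off-diagonal entries, so ranks
commute with the null).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import InsufficientDataError, ParameterError, ValidationError
from .io_tables import SampleMetadata

__all__ = [
    "MantelResult",
    "ANOVAResult",
    "mantel",
    "partial_mantel",
    "env_distance",
    "pearson_matrix",
    "anova_lsd_cld",
    "significance_band",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str
    seed: int | None


@dataclass(frozen=True)
class ANOVAResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    mse: float
    group_means: dict


def _as_matrix(D, name: str) -> tuple[np.ndarray, tuple | None]:
    if isinstance(D, DistanceMatrix):
        return D.data.astype(float), tuple(D.ids)
    mat = np.asarray(D, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError(f"{name} must be a square distance matrix")
    return mat, None


def _align(mats_ids):
    """Check that all labelled matrices carry identical sample ids."""
    labelled = [ids for _, ids in mats_ids if ids is not None]
    for ids in labelled[1:]:
        if ids != labelled[0]:
            raise ValidationError("distance matrices have mismatched sample ids")


def _rank_matrix(mat: np.ndarray) -> np.ndarray:
    """Replace off-diagonal entries by their ranks (ties averaged),
    symmetrically."""
    iu = np.triu_indices_from(mat, k=1)
    ranks = stats.rankdata(mat[iu])
    out = np.zeros_like(mat)
    out[iu] = ranks
    return out + out.T

def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with vector y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    return (Xc @ yc) / denom


def _permuted_condensed(mat: np.ndarray, perms: np.ndarray, iu) -> np.ndarray:
    """Off-diagonal vectors of mat under joint row/column permutations.

    perms has shape (n_perm, n); returns (n_perm, n*(n-1)/2)."""
    permuted = mat[perms[:, :, None], perms[:, None, :]]
    return permuted[:, iu[0], iu[1]]


def mantel(Dx, Dy, n_perm: int = 999, seed: int | None = None,
           method: str = "pearson", alternative: str = "greater") -> MantelResult:
    """Mantel test of matrix correlation with a permutation null.

    r is the correlation of the n(n-1)/2 upper-triangle pairs; the null
    permutes rows and columns of Dy jointly.  One-tailed ("greater") by
    default, the vegan convention.
    """
    x, ids_x = _as_matrix(Dx, "Dx")
    y, ids_y = _as_matrix(Dy, "Dy")
    if x.shape != y.shape:
        raise ValidationError("distance matrices differ in size")
    _align([(x, ids_x), (y, ids_y)])
    n = x.shape[0]
    if n < 4:
        raise InsufficientDataError("Mantel test needs >= 4 samples")
    if method == "spearman":
        x, y = _rank_matrix(x), _rank_matrix(y)
    elif method != "pearson":
        raise ParameterError(f"unknown method {method!r}")
    iu = np.triu_indices(n, k=1)
    vx, vy = x[iu], y[iu]
    r_obs = float(stats.pearsonr(vx, vy)[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    r_null = _pearson_rows(_permuted_condensed(y, perms, iu), vx)
    if alternative == "greater":
        extreme = np.sum(r_null >= r_obs)
    elif alternative == "two-sided":
        extreme = np.sum(np.abs(r_null) >= abs(r_obs))
    else:
        raise ParameterError(f"unknown alternative {alternative!r}")
    p = (1 + int(extreme)) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm, method=method, seed=seed)


def mantel_exhaustive(Dx, Dy, method: str = "pearson") -> MantelResult:
    """Exact Mantel p over all n! joint permutations (small n only)."""
    x, _ = _as_matrix(Dx, "Dx")
    y, _ = _as_matrix(Dy, "Dy")
    n = x.shape[0]
    if n > 8:
        raise ParameterError("exhaustive enumeration limited to n <= 8")
    if method == "spearman":
        x, y = _rank_matrix(x), _rank_matrix(y)
    iu = np.triu_indices(n, k=1)
    vx = x[iu]
    r_obs = float(stats.pearsonr(vx, y[iu])[0])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        perm = np.array(perm)
        r = float(stats.pearsonr(vx, y[perm][:, perm][iu])[0])
        count += r >= r_obs - 1e-12
        total += 1
    return MantelResult(r=r_obs, p_value=count / total, n_permutations=total,
                        method=method, seed=None)


def partial_mantel(Dx, Dy, Dz, n_perm: int = 999, seed: int | None = None,
                   method: str = "pearson") -> MantelResult:
    """Partial Mantel r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz²)(1-r_yz²)),
    permutation null permuting Dy."""
    x, ids_x = _as_matrix(Dx, "Dx")
    y, ids_y = _as_matrix(Dy, "Dy")
    z, ids_z = _as_matrix(Dz, "Dz")
    _align([(x, ids_x), (y, ids_y), (z, ids_z)])
    if method == "spearman":
        x, y, z = _rank_matrix(x), _rank_matrix(y), _rank_matrix(z)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    vx, vy, vz = x[iu], y[iu], z[iu]

    def partial_r(r_xy, r_xz, r_yz):
        denom = (1 - r_xz**2) * (1 - r_yz**2)
        return (r_xy - r_xz * r_yz) / np.sqrt(np.clip(denom, 1e-300, None))

    r_xz = float(stats.pearsonr(vx, vz)[0])
    r_yz = float(stats.pearsonr(vy, vz)[0])
    if 1 - r_xz**2 <= 1e-12:
        raise ValidationError("control matrix perfectly correlated with x")
    if 1 - r_yz**2 <= 1e-12:
        # control collinear with y: partialling it out leaves no signal
        r_obs = 0.0
    else:
        r_obs = partial_r(float(stats.pearsonr(vx, vy)[0]), r_xz, r_yz)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    y_perm = _permuted_condensed(y, perms, iu)
    r_null = partial_r(_pearson_rows(y_perm, vx), r_xz, _pearson_rows(y_perm, vz))
    p = (1 + int(np.sum(r_null >= r_obs))) / (1 + n_perm)
    return MantelResult(r=float(r_obs), p_value=p, n_permutations=n_perm,
                        method=method, seed=seed)


def env_distance(metadata: SampleMetadata | pd.DataFrame, variables) -> DistanceMatrix:
    """Euclidean distance on z-score-standardized variables (sd with n-1).

    Zero-variance variables are dropped with a warning.
    """
    frame = metadata.env_frame(variables) if isinstance(metadata, SampleMetadata) else (
        metadata[list(variables)].astype(float)
    )
    if frame.shape[1] < 1:
        raise ParameterError("need at least one variable")
    sd = frame.std(ddof=1)
    dead = list(sd.index[sd == 0])
    if dead:
        warnings.warn(f"dropping zero-variance variable(s): {dead}", stacklevel=2)
        frame = frame.drop(columns=dead)
        if frame.shape[1] == 0:
            raise ParameterError("all variables have zero variance")
        sd = sd.drop(dead)
    z = (frame - frame.mean()) / sd
    condensed = pdist(z.to_numpy(), metric="euclidean")
    return DistanceMatrix(squareform(condensed), ids=list(frame.index.astype(str)))


def pearson_matrix(metadata: SampleMetadata | pd.DataFrame, variables=None) -> pd.DataFrame:
    """Pearson correlation matrix of metadata variables; zero-variance
    columns yield NaN entries (flagged by a warning)."""
    frame = metadata.env_frame(variables) if isinstance(metadata, SampleMetadata) else (
        metadata if variables is None else metadata[list(variables)]
    ).astype(float)
    if frame.shape[0] < 3:
        raise InsufficientDataError("Pearson matrix needs >= 3 samples")
    if (frame.std(ddof=1) == 0).any():
        warnings.warn("zero-variance variable(s): correlations undefined (NaN)", stacklevel=2)
    return frame.corr(method="pearson")


def significance_band(p: float) -> str:
    """Banding convention for Mantel panels: p<0.01 / 0.01–0.05 / >=0.05."""
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "0.01<=p<0.05"
    return "p>=0.05"


# ---------------------------------------------------------------------------
# one-way ANOVA + LSD + compact letter display


def anova_lsd_cld(values, groups, alpha: float = 0.05):
    """One-way ANOVA, LSD (pooled-MSE pairwise t) tests and a compact letter
    display.

    Two groups sharing a letter are not significantly different at ``alpha``
    (unprotected LSD; no family-wise correction, by design).  Returns
    (ANOVAResult, {group: letters}).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise InsufficientDataError("need >= 2 groups")
    by_group = {g: values[groups == g] for g in labels}
    for g, v in by_group.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 observations")
    k = len(labels)
    n_total = values.size
    means = {g: float(v.mean()) for g, v in by_group.items()}
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in by_group.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    F = (ss_between / df_b) / mse if mse > 0 else np.inf
    p_anova = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    result = ANOVAResult(F=float(F), df_between=df_b, df_within=df_w,
                         p_value=p_anova, mse=float(mse), group_means=means)

    # pairwise LSD t tests with the pooled error
    sig = {}
    for g1, g2 in itertools.combinations(labels, 2):
        v1, v2 = by_group[g1], by_group[g2]
        se = np.sqrt(mse * (1 / v1.size + 1 / v2.size))
        t = abs(v1.mean() - v2.mean()) / se if se > 0 else np.inf
        p = 2 * stats.t.sf(t, df_w) if np.isfinite(t) else 0.0
        sig[(g1, g2)] = p < alpha
    letters = _compact_letter_display(labels, means, sig)
    return result, letters


def _compact_letter_display(labels, means, sig) -> dict:
    """Insert-and-absorb algorithm: produce letter sets such that two groups
    share a letter iff their pairwise comparison is non-significant."""
    order = sorted(labels, key=lambda g: -means[g])
    letter_sets = [set(order)]
    for g1, g2 in sorted(sig, key=lambda pair: (order.index(pair[0]), order.index(pair[1]))):
        if not sig[(g1, g2)]:
            continue
        for s in list(letter_sets):
            if g1 in s and g2 in s:
                letter_sets.remove(s)
                a, b = s - {g2}, s - {g1}
                for new in (a, b):
                    if not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
        # absorb subsets
        letter_sets = [s for s in letter_sets
                       if not any(s < other for other in letter_sets)]
    # order letters by the highest group mean they contain
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for ch, s in zip(alphabet, letter_sets):
        for g in order:
            if g in s:
                out[g] += ch
    return out
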