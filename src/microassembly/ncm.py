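"""Sloan neutral community model: occupancy–abundance fit and taxon
partitioning.

The model predicts the occurrence frequency of a taxon across local
communities from its metacommunity mean relative abundance ``p``.  Under
neutral drift with immigration, the local relative abundance of a taxon is
Beta(Nm*p, Nm*(1-p)) at stationarity, where ``N`` is the community size and
``m`` the immigration probability.  A taxon is detected when its local
abundance exceeds the detection fraction ``x = d/N`` (``d`` reads by
default 1), so its predicted occurrence frequency is the upper tail

    f_pred(p) = 1 - I_x(Nm*p, Nm*(1-p))

with ``I`` the regularized incomplete beta function.  ``m`` is the single
free parameter, fitted by least squares of observed on predicted
frequencies; the goodness of fit R² = 1 - SSR/SST summarizes how much of the
occupancy–abundance relationship neutral processes explain.  Taxa whose
observed frequency falls outside a 95% Wilson band around ``f_pred`` are
flagged as above-/below-prediction (candidate deterministically selected
members); the rest are consistent with neutrality.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import FitError, InsufficientDataError, ParameterError
from .io_tables import CountTable

__all__ = [
    "SloanNCM",
    "fit_ncm",
    "fit_occupancy",
    "occurrence_stats",
    "predicted_frequency",
    "wilson_interval",
    "classify_taxa",
]


def occurrence_stats(table: CountTable, detection_count: int = 1) -> pd.DataFrame:
    """Per-taxon mean relative abundance ``p`` and occurrence frequency
    ``f_obs`` (fraction of samples with count >= detection_count).

    Taxa never detected are excluded.  Requires >= 2 samples and positive
    sample sums.
    """
    if table.n_samples < 2:
        raise InsufficientDataError("occurrence statistics need >= 2 samples")
    sums = table.sample_sums()
    if np.any(sums == 0):
        raise InsufficientDataError("zero-sum sample; rarefy or drop it first")
    rel = table.counts / sums
    p = rel.mean(axis=1)
    f_obs = (table.counts >= detection_count).mean(axis=1)
    keep = f_obs > 0
    return pd.DataFrame(
        {"taxon_id": np.asarray(table.taxon_ids)[keep], "p": p[keep], "f_obs": f_obs[keep]}
    ).reset_index(drop=True)


def predicted_frequency(p, Nm: float, detection_fraction: float):
    """Model-predicted occurrence frequency 1 - I_x(Nm*p, Nm*(1-p)).

    ``p`` may be a scalar or array in (0, 1); ``detection_fraction`` is the
    detection limit expressed as a fraction of community size (d/N).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ParameterError("p must lie strictly in (0, 1)")
    if Nm <= 0:
        raise ParameterError("Nm must be > 0")
    if not 0 < detection_fraction < 1:
        raise ParameterError("detection_fraction must lie in (0, 1)")
    out = stats.beta.sf(detection_fraction, Nm * p, Nm * (1.0 - p))
    return float(out) if out.ndim == 0 else out


def wilson_interval(fraction, n_trials: int, confidence: float = 0.95):
    """Closed-form Wilson score interval for a proportion.

    Accepts scalar or array ``fraction``; the Hmisc/binconf convention with
    z = Phi^-1(1 - alpha/2).
    """
    f = np.asarray(fraction, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ParameterError("fraction must lie in [0, 1]")
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    denom = 1.0 + z * z / n_trials
    center = (f + z * z / (2 * n_trials)) / denom
    half = (z / denom) * np.sqrt(f * (1 - f) / n_trials + z * z / (4 * n_trials**2))
    low = np.where(f == 0, 0.0, np.clip(center - half, 0.0, 1.0))
    high = np.where(f == 1, 1.0, np.clip(center + half, 0.0, 1.0))
    if f.ndim == 0:
        return float(low), float(high)
    return low, high


def fit_occupancy(p, f_obs, N: int, detection_count: int = 1,
                  m_bounds: tuple = (1e-6, 1.0)):
    """Fit the migration parameter to an explicit occupancy–abundance cloud.

    Least squares of ``f_obs`` on ``predicted_frequency(p, N*m, d/N)`` by
    bounded scalar minimization on log m (one parameter, guaranteed
    bracketing).  Returns a dict with m, Nm, r_squared and f_pred.
    """
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    f_obs = np.asarray(f_obs, dtype=float)
    x_det = detection_count / N

    def sse(log_m: float) -> float:
        f_pred = predicted_frequency(p, N * np.exp(log_m), x_det)
        return float(np.sum((f_obs - f_pred) ** 2))

    lo, hi = m_bounds
    res = optimize.minimize_scalar(
        sse, bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise FitError(f"migration-parameter fit did not converge: {res.message}")
    m = float(np.exp(res.x))
    f_pred = predicted_frequency(p, N * m, x_det)
    sst = float(np.sum((f_obs - f_obs.mean()) ** 2))
    if sst == 0:
        raise FitError("all observed frequencies equal; R² undefined")
    r2 = 1.0 - float(np.sum((f_obs - f_pred) ** 2)) / sst
    return {"m": m, "Nm": N * m, "r_squared": r2, "f_pred": f_pred}


class SloanNCM(BaseEstimator):
    """Sloan neutral community model fitted to a count table.

    Parameters
    ----------
    detection_count : int, default=1
        Reads required to call a taxon present; enters the model as the
        fraction detection_count / N.
    confidence : float, default=0.95
        Level of the Wilson prediction band used to partition taxa.
    m_bounds : tuple, default=(1e-6, 1.0)
        Search interval for the migration parameter m.
    min_taxa : int, default=10
        Below this many detected taxa the fit proceeds with a warning.

    Attributes
    ----------
    m_ : float
        Fitted migration probability.
    N_ : int
        Community size: mean sample sum, rounded to the nearest integer.
    Nm_ : float
        Migration–dispersal magnitude, N_ * m_.
    r_squared_ : float
        1 - SSR/SST of observed vs predicted occurrence frequencies.
    detection_limit_ : int
        The detection count used.
    n_taxa_ : int
        Taxa entering the fit.
    records_ : pandas.DataFrame
        Per-taxon taxon_id, p, f_obs, f_pred, ci_low, ci_high, partition.
    partition_counts_ : dict
        {"above": ..., "neutral": ..., "below": ...}; sums to n_taxa_.
    """

    def __init__(self, detection_count: int = 1, confidence: float = 0.95,
                 m_bounds: tuple = (1e-6, 1.0), min_taxa: int = 10):
        self.detection_count = detection_count
        self.confidence = confidence
        self.m_bounds = m_bounds
        self.min_taxa = min_taxa

    def fit(self, X, y=None):
        """Fit m by bounded least squares on the occupancy–abundance cloud.

        ``X`` is a CountTable or a taxa x samples integer array.
        """
        table = X if isinstance(X, CountTable) else CountTable(
            np.asarray(X), [f"t{i}" for i in range(np.asarray(X).shape[0])],
            [f"s{j}" for j in range(np.asarray(X).shape[1])],
        )
        stats_df = occurrence_stats(table, self.detection_count)
        if len(stats_df) < self.min_taxa:
            warnings.warn(
                f"only {len(stats_df)} taxa after detection filtering; "
                "the one-parameter fit may be unstable", stacklevel=2,
            )
        N = int(round(table.sample_sums().mean()))
        f_obs = stats_df["f_obs"].to_numpy()
        fit = fit_occupancy(
            stats_df["p"].to_numpy(), f_obs, N,
            detection_count=self.detection_count, m_bounds=self.m_bounds,
        )
        m, f_pred, r2 = fit["m"], fit["f_pred"], fit["r_squared"]

        ci_low, ci_high = wilson_interval(f_pred, table.n_samples, self.confidence)
        partition = np.where(f_obs > ci_high, "above", np.where(f_obs < ci_low, "below", "neutral"))

        self.m_ = m
        self.N_ = N
        self.Nm_ = N * m
        self.r_squared_ = r2
        self.detection_limit_ = self.detection_count
        self.n_taxa_ = len(stats_df)
        self.records_ = stats_df.assign(
            f_pred=f_pred, ci_low=ci_low, ci_high=ci_high, partition=partition
        )
        self.partition_counts_ = {
            k: int(np.sum(partition == k)) for k in ("above", "neutral", "below")
        }
        return self

    def predict(self, p):
        """Predicted occurrence frequency for metacommunity abundance(s) p."""
        if not hasattr(self, "Nm_"):
            raise FitError("SloanNCM instance is not fitted yet")
        return predicted_frequency(p, self.Nm_, self.detection_count / self.N_)

    def summary(self) -> dict:
        return {
            "m": self.m_,
            "N": self.N_,
            "Nm": self.Nm_,
            "r_squared": self.r_squared_,
            "detection_limit": self.detection_limit_,
            "n_taxa": self.n_taxa_,
            "partition_counts": dict(self.partition_counts_),
        }


def fit_ncm(table: CountTable, detection_count: int = 1, **kwargs) -> SloanNCM:
    """Fit the neutral model to a count table; returns the fitted estimator."""
    return SloanNCM(detection_count=detection_count, **kwargs).fit(table)


def classify_taxa(f_obs, f_pred, n_samples: int, confidence: float = 0.95):
    """Partition taxa by position relative to the Wilson band around f_pred.

    Returns (partition array of {"above","neutral","below"}, counts dict).
    """
    f_obs = np.asarray(f_obs, dtype=float)
    ci_low, ci_high = wilson_interval(np.asarray(f_pred, dtype=float), n_samples, confidence)
    partition = np.where(f_obs > ci_high, "above", np.where(f_obs < ci_low, "below", "neutral"))
    counts = {k: int(np.sum(partition == k)) for k in ("above", "neutral", "below")}
    return partition, counts
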