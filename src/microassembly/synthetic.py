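"""Synthetic neutral and environmentally filtered communities.

The generators reproduce the statistical structure the neutral-model and
Mantel analyses assume:

* a lognormal metacommunity (regional pool) with relative abundances ``p``;
* neutral local communities whose composition follows Sloan's diffusion
  approximation — stationary ``Dirichlet(N*m*p)`` — from which reads are drawn
  multinomially, decoupling biological community size ``N`` from sequencing
  depth;
* an explicit Hubbell death–birth–immigration (Moran) simulation kept as an
  independent oracle for the stationary sampler;
* a Gaussian-niche environmental-filtering sampler in which taxon ``i`` has an
  optimum ``o_i`` on a sample gradient ``g_j`` and weight
  ``w_ij ∝ p_i * exp(-filter_strength * (o_i - g_j)**2)``;
* correlated physicochemical covariates shaped like the field-survey design
  (7 sites x 2 depth layers x 3 replicates).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_tables import ENV_VARIABLES, LAYERS, SITES, CountTable, SampleMetadata, TaxonomyMap


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the community generators.

    S: number of taxa in the pool; N: local community size (individuals);
    m: immigration probability per replaced individual; depth: reads per
    sample; meta_sigma: lognormal shape of the metacommunity; generations:
    burn-in length for the dynamic oracle (units of N replacement events);
    filter_strength: Gaussian-niche width parameter (0 = no filtering).
    """

    S: int = 300
    N: int = 10_000
    m: float = 0.2
    n_samples: int = 21
    depth: int = 10_000
    meta_sigma: float = 1.5
    seed: int = 0
    generations: int = 50
    filter_strength: float = 0.0

    def __post_init__(self):
        if self.S < 2:
            raise ParameterError("S must be >= 2")
        if self.N < 1:
            raise ParameterError("N must be >= 1")
        if not 0 < self.m <= 1:
            raise ParameterError("m must be in (0, 1]")
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.filter_strength < 0:
            raise ParameterError("filter_strength must be >= 0")


@dataclasses.dataclass(frozen=True)
class Metacommunity:
    """Regional pool relative abundances (sum to 1, all positive)."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ParameterError("metacommunity needs >= 2 taxa")
        if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ParameterError("metacommunity abundances must be positive and sum to 1")
        object.__setattr__(self, "p", p)

    @property
    def S(self) -> int:
        return self.p.size


def make_metacommunity(S: int, meta_sigma: float = 1.5, seed: int = 0) -> Metacommunity:
    """Lognormal species-abundance pool normalized to sum 1."""
    if S < 2:
        raise ParameterError("S must be >= 2")
    if meta_sigma <= 0:
        raise ParameterError("meta_sigma must be > 0")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=meta_sigma, size=S)
    p = raw / raw.sum()
    # renormalize defensively so the invariant holds to 1e-12
    return Metacommunity(p / p.sum())


def _taxon_ids(S: int):
    return [f"OTU{i:04d}" for i in range(1, S + 1)]


def _sample_ids(n: int, prefix: str = "S"):
    return [f"{prefix}{j:03d}" for j in range(1, n + 1)]


def simulate_neutral_samples(
    meta: Metacommunity,
    N: int,
    m: float,
    n_samples: int,
    depth: int,
    seed: int = 0,
) -> CountTable:
    """Stationary neutral sampler.

    Per sample, composition ~ Dirichlet(N*m*p) (Sloan's diffusion-limit
    stationary law of drift + immigration), then reads ~ multinomial(depth,
    composition).  Expected relative abundance of taxon i equals p_i; the
    among-sample dispersion shrinks as N*m grows.
    """
    SimulationConfig(S=meta.S, N=N, m=m, n_samples=n_samples, depth=depth)
    rng = np.random.default_rng(seed)
    alpha = N * m * meta.p
    counts = np.empty((meta.S, n_samples), dtype=np.int64)
    for j in range(n_samples):
        comp = rng.dirichlet(alpha)
        counts[:, j] = rng.multinomial(depth, comp)
    return CountTable(counts, _taxon_ids(meta.S), _sample_ids(n_samples))


def _moran_steps(slots: np.ndarray, p_cum: np.ndarray, m: float, n_steps: int, rng) -> None:
    """Advance the individual-based Moran process in place.

    ``slots`` holds the taxon label of each of the N individuals.  Each step
    one random individual dies and is replaced: with probability m by an
    immigrant drawn from the metacommunity, otherwise by the offspring of a
    random local individual.
    """
    N = slots.size
    death = rng.integers(0, N, size=n_steps)
    immigrate = rng.random(n_steps) < m
    immigrants = np.searchsorted(p_cum, rng.random(n_steps))
    local_parent = rng.integers(0, N, size=n_steps)
    for t in range(n_steps):
        if immigrate[t]:
            slots[death[t]] = immigrants[t]
        else:
            slots[death[t]] = slots[local_parent[t]]


def simulate_neutral_dynamic(
    meta: Metacommunity,
    N: int,
    m: float,
    generations: int,
    n_samples: int,
    depth: int,
    seed: int = 0,
    thin_generations: int = 5,
) -> CountTable:
    """Explicit Hubbell drift/immigration simulation (independent oracle).

    Runs a single Moran chain of ``N`` individuals for ``generations * N``
    burn-in replacement events, then takes ``n_samples`` snapshots thinned by
    ``thin_generations * N`` events; reads ~ multinomial(depth, snapshot
    composition).  The stationary law of a single taxon's frequency is
    Beta(N*m*p_i, N*m*(1-p_i)).  Burn-in below 50 generations raises a
    warning (the stationarity contract).
    """
    SimulationConfig(S=meta.S, N=N, m=m, n_samples=n_samples, depth=depth)
    if generations < 50:
        warnings.warn(
            f"burn-in of {generations} generations is below the 50-generation "
            "stationarity contract; snapshots may not be stationary",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    p_cum = np.cumsum(meta.p)
    p_cum[-1] = 1.0
    # initialize at the metacommunity to shorten transients
    slots = np.searchsorted(p_cum, rng.random(N)).astype(np.int64)
    _moran_steps(slots, p_cum, m, generations * N, rng)
    counts = np.empty((meta.S, n_samples), dtype=np.int64)
    for j in range(n_samples):
        comp = np.bincount(slots, minlength=meta.S) / N
        counts[:, j] = rng.multinomial(depth, comp)
        if j < n_samples - 1:
            _moran_steps(slots, p_cum, m, thin_generations * N, rng)
    return CountTable(counts, _taxon_ids(meta.S), _sample_ids(n_samples))


def moran_frequency_trace(
    meta: Metacommunity,
    N: int,
    m: float,
    burn_in_generations: int,
    n_snapshots: int,
    thin_generations: int = 5,
    seed: int = 0,
    taxon: int = 0,
) -> np.ndarray:
    """Post-burn-in relative-frequency trace of one taxon under the Moran
    process — used to test convergence to the Beta(N*m*p, N*m*(1-p))
    stationary law."""
    rng = np.random.default_rng(seed)
    p_cum = np.cumsum(meta.p)
    p_cum[-1] = 1.0
    slots = np.searchsorted(p_cum, rng.random(N)).astype(np.int64)
    _moran_steps(slots, p_cum, m, burn_in_generations * N, rng)
    freqs = np.empty(n_snapshots)
    for t in range(n_snapshots):
        freqs[t] = np.count_nonzero(slots == taxon) / N
        _moran_steps(slots, p_cum, m, thin_generations * N, rng)
    return freqs


def simulate_filtered_samples(
    meta: Metacommunity,
    gradient: np.ndarray,
    filter_strength: float,
    depth: int,
    seed: int = 0,
) -> tuple[CountTable, np.ndarray]:
    """Environmentally filtered (Gaussian niche) sampler.

    Taxon optima o_i ~ Uniform over the gradient range; the sampling weight of
    taxon i in sample j is p_i * exp(-filter_strength * (o_i - g_j)**2),
    renormalized per sample; reads ~ multinomial(depth, weights).  At
    filter_strength = 0 this is exactly multinomial(depth, p) for every
    sample.
    """
    if filter_strength < 0:
        raise ParameterError("filter_strength must be >= 0")
    gradient = np.asarray(gradient, dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = gradient.min(), gradient.max()
    if hi == lo:
        hi = lo + 1.0
    optima = rng.uniform(lo, hi, size=meta.S)
    n_samples = gradient.size
    counts = np.empty((meta.S, n_samples), dtype=np.int64)
    for j, g in enumerate(gradient):
        w = meta.p * np.exp(-filter_strength * (optima - g) ** 2)
        counts[:, j] = rng.multinomial(depth, w / w.sum())
    return CountTable(counts, _taxon_ids(meta.S), _sample_ids(n_samples)), gradient


# ---------------------------------------------------------------------------
# metadata and taxonomy


#: typical ranges of the physicochemical variables in lake-wetland sediments
_ENV_RANGES = {
    "pH": (7.0, 9.0),
    "WC": (20.0, 70.0),      # %
    "TC": (5.0, 40.0),       # g/kg
    "TSC": (50.0, 400.0),    # mg/kg
    "MBC": (100.0, 900.0),   # mg/kg
    "TN": (0.5, 4.0),        # g/kg
    "AN": (20.0, 200.0),     # mg/kg
    "TP": (0.3, 1.5),        # g/kg
    "AP": (5.0, 60.0),       # mg/kg
    "TK": (5.0, 25.0),       # g/kg
    "AK": (50.0, 300.0),     # mg/kg
}


def simulate_metadata(
    n_samples: int,
    env_corr: float = 0.5,
    seed: int = 0,
    sites=SITES,
    layer: str = LAYERS[0],
    gradient: np.ndarray | None = None,
) -> SampleMetadata:
    """Correlated physicochemical covariates on the study design.

    Latent standard-normal factors give every pair of variables Pearson
    correlation ``env_corr``; each variable is then mapped through its normal
    CDF into a field-realistic range, which keeps pH in (0, 14), WC in
    [0, 100] and concentrations positive.  If ``gradient`` is given the first
    latent factor is tied to it, so that community tables filtered along the
    same gradient correlate with the environment.
    """
    if not 0 <= env_corr < 1:
        raise ParameterError("env_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    k = len(ENV_VARIABLES)
    shared = rng.standard_normal(n_samples)
    if gradient is not None:
        g = np.asarray(gradient, dtype=float)
        sd = g.std()
        shared = (g - g.mean()) / (sd if sd > 0 else 1.0)
    z = np.sqrt(env_corr) * shared[:, None] + np.sqrt(1 - env_corr) * rng.standard_normal(
        (n_samples, k)
    )
    from scipy.stats import norm

    u = norm.cdf(z)
    data = {}
    for i, var in enumerate(ENV_VARIABLES):
        lo, hi = _ENV_RANGES[var]
        data[var] = lo + (hi - lo) * u[:, i]
    n_sites = len(sites)
    reps = int(np.ceil(n_samples / n_sites))
    site_col = [sites[j // reps] for j in range(n_samples)]
    rep_col = [j % reps + 1 for j in range(n_samples)]
    frame = pd.DataFrame(
        {"site": site_col, "layer": layer, "replicate": rep_col, **data},
        index=pd.Index(_sample_ids(n_samples), name="sample_id"),
    )
    return SampleMetadata(frame)


def make_taxonomy(taxon_ids, n_phyla: int = 8, seed: int = 0) -> TaxonomyMap:
    """Synthetic ranked lineages: taxa assigned to `n_phyla` phyla with
    lognormal phylum sizes (a few dominant phyla, a tail of rare ones)."""
    rng = np.random.default_rng(seed)
    w = rng.lognormal(0, 1.0, size=n_phyla)
    phyla = [f"Phylum{i + 1:02d}" for i in range(n_phyla)]
    assignment = rng.choice(n_phyla, size=len(taxon_ids), p=w / w.sum())
    lineages = {}
    for t, a in zip(taxon_ids, assignment):
        lineages[str(t)] = ("Archaea", phyla[a], None, None, None, None)
    return TaxonomyMap(lineages)
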