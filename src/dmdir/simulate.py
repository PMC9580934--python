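"""Directional simulator for cell-type-specific differential methylation.

Bulk DNA methylation measured on a heterogeneous tissue is a mixture: for
sample i and CpG j the observed beta-value-like signal is

    X_ij = sum_h W_ih * Z_ihj + e_ij,        e_ij ~ N(0, tau_j^2)

where W_ih is the proportion of cell type h in sample i and Z_ihj is the
(unobserved) methylation level of cell type h at CpG j in sample i, drawn
around a cell-type baseline:  Z_ihj ~ N(mu_hj, sigma_hj^2).

Phenotype effects can point in either direction:

* ``xgy`` (X|Y): the phenotype shifts latent methylation. At truth entries
  (j, h) the latent mean becomes mu_hj + beta * sigma_hj * y_i, i.e. effects
  are expressed in units of the latent cell-type standard deviation.
* ``ygx`` (Y|X): methylation drives the phenotype through a liability
  L_i = sum over truth entries of beta * (Z_ihj - mu_hj)/sigma_hj + noise,
  thresholded at its median so cases and controls are balanced.

Four scenarios control how many cell types carry an effect per affected CpG
and whether the signs agree: uni1c (one cell type), uni2c (two, same sign),
bi2c (two, opposite signs), bi3c (three, mixed signs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "SCENARIO_N_CELLTYPES",
    "ScenarioConfig",
    "EffectTruth",
    "SyntheticCohort",
    "simulate_proportions",
    "simulate_baseline",
    "assign_effects",
    "simulate_cohort",
    "simulate_cohort_xgy",
    "simulate_cohort_ygx",
]

#: affected cell types per affected CpG, by scenario
SCENARIO_N_CELLTYPES = {"uni1c": 1, "uni2c": 2, "bi2c": 2, "bi3c": 3}

_DIRECTIONS = ("xgy", "ygx")

#: blood-like Dirichlet concentration: one dominant cell type, minor subsets
DEFAULT_ALPHA = (7.0, 2.5, 2.0, 1.5, 1.0, 0.5)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one simulated cohort.

    Parameters
    ----------
    direction
        ``"xgy"`` (phenotype shifts methylation) or ``"ygx"`` (methylation
        drives the phenotype through a liability threshold).
    scenario
        One of ``uni1c``, ``uni2c``, ``bi2c``, ``bi3c``.
    effect_size
        Standardized effect magnitude, in units of the latent cell-type
        standard deviation (both directions).
    liability_sd
        Standard deviation of the Gaussian liability noise (ygx only).
    """

    direction: str
    scenario: str
    n: int = 500
    m: int = 1000
    m_true: int = 50
    k: int = 6
    effect_size: float = 1.0
    dirichlet_alpha: Tuple[float, ...] = DEFAULT_ALPHA
    mu_range: Tuple[float, float] = (0.1, 0.9)
    sigma_range: Tuple[float, float] = (0.02, 0.1)
    tau_range: Tuple[float, float] = (0.005, 0.02)
    liability_sd: float = 1.0
    clip: bool = False
    seed: int = 0
    #: when set, the truth assignment is drawn from this separate seed so
    #: independent cohorts (different ``seed``) can share ground truth
    truth_seed: Optional[int] = None

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ParameterError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )
        if self.scenario not in SCENARIO_N_CELLTYPES:
            raise ParameterError(
                f"scenario must be one of {tuple(SCENARIO_N_CELLTYPES)}, "
                f"got {self.scenario!r}"
            )
        for name in ("n", "m", "m_true", "k"):
            if int(getattr(self, name)) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.m_true > self.m:
            raise ParameterError(f"m_true ({self.m_true}) exceeds m ({self.m})")
        if len(self.dirichlet_alpha) != self.k:
            raise ParameterError(
                f"dirichlet_alpha has length {len(self.dirichlet_alpha)}, "
                f"expected k={self.k}"
            )
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ParameterError("dirichlet_alpha entries must be strictly positive")
        if SCENARIO_N_CELLTYPES[self.scenario] > self.k:
            raise ParameterError(
                f"scenario {self.scenario!r} needs "
                f"{SCENARIO_N_CELLTYPES[self.scenario]} cell types but k={self.k}"
            )
        for name in ("mu_range", "sigma_range", "tau_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ParameterError(f"{name} is inverted: ({lo}, {hi})")
        if self.sigma_range[0] < 0 or self.tau_range[0] < 0:
            raise ParameterError("standard-deviation ranges must be nonnegative")
        if self.liability_sd < 0:
            raise ParameterError("liability_sd must be nonnegative")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = {
            "direction": self.direction,
            "scenario": self.scenario,
            "n": self.n,
            "m": self.m,
            "m_true": self.m_true,
            "k": self.k,
            "effect_size": self.effect_size,
            "dirichlet_alpha": list(self.dirichlet_alpha),
            "mu_range": list(self.mu_range),
            "sigma_range": list(self.sigma_range),
            "tau_range": list(self.tau_range),
            "liability_sd": self.liability_sd,
            "clip": self.clip,
            "seed": self.seed,
            "truth_seed": self.truth_seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for name in ("dirichlet_alpha", "mu_range", "sigma_range", "tau_range"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


@dataclass
class EffectTruth:
    """Ground-truth answer key: which (CpG, cell type) pairs carry effects.

    ``beta`` holds signed standardized effect sizes (entries are
    ``+-effect_size`` or zero); generators rescale by sigma_hj where a value
    on the methylation scale is needed.
    """

    beta: np.ndarray  # (m, k) signed standardized effects
    affected_cpgs: np.ndarray  # sorted indices of CpGs with any effect
    affected_celltypes: Dict[int, Dict[int, float]]  # cpg -> {celltype: sign}

    @property
    def n_entries(self) -> int:
        return int(np.count_nonzero(self.beta))

    def pairs(self) -> set:
        """Set of (cpg index, cell type index) truth pairs."""
        jj, hh = np.nonzero(self.beta)
        return set(zip(jj.tolist(), hh.tolist()))


@dataclass
class SyntheticCohort:
    """One simulated bulk-methylation cohort with its full generative record.

    Everything the generator drew is retained (latent tensor Z, bulk noise)
    so every derived quantity — the mixture identity, the liability — can be
    recomputed exactly from the stored pieces.
    """

    X: np.ndarray  # (n, m) bulk methylation
    W: np.ndarray  # (n, k) cell-type proportions, rows on the simplex
    y: np.ndarray  # (n,) binary phenotype
    Z: np.ndarray  # (n, m, k) latent cell-type methylation
    noise: np.ndarray  # (n, m) bulk measurement noise actually added
    mu: np.ndarray  # (m, k) baseline latent means
    sigma: np.ndarray  # (m, k) latent standard deviations
    tau: np.ndarray  # (m,) bulk noise standard deviations
    truth: EffectTruth
    config: ScenarioConfig
    covariates: Optional[np.ndarray] = None
    liability: Optional[np.ndarray] = None  # (n,) ygx only
    cpg_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    celltype_ids: list = field(default_factory=list)

    def __post_init__(self):
        n, m = self.X.shape
        k = self.W.shape[1]
        if not self.cpg_ids:
            self.cpg_ids = [f"cpg{j:05d}" for j in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        if not self.celltype_ids:
            self.celltype_ids = [f"ct{h + 1}" for h in range(k)]


def simulate_proportions(n: int, dirichlet_alpha, seed=None) -> np.ndarray:
    """Draw an n x k matrix of cell-type proportions from Dirichlet(alpha).

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.ndim != 1 or alpha.size == 0:
        raise ParameterError("dirichlet_alpha must be a 1-d vector")
    if np.any(alpha <= 0):
        raise ParameterError("dirichlet_alpha entries must be strictly positive")
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(alpha, size=int(n))
    # guard against exact-zero rows from extreme concentrations
    W = W / W.sum(axis=1, keepdims=True)
    return W


def simulate_baseline(m: int, k: int, mu_range=(0.1, 0.9), sigma_range=(0.02, 0.1),
                      tau_range=(0.005, 0.02), seed=None):
    """Draw per-CpG, per-cell-type baselines.

    Returns ``(mu, sigma, tau)``: means in [0, 1] (m x k), latent standard
    deviations (m x k) and bulk-noise standard deviations (m,), each sampled
    uniformly from its range.
    """
    for name, (lo, hi) in (("mu_range", mu_range), ("sigma_range", sigma_range),
                           ("tau_range", tau_range)):
        if hi < lo:
            raise ParameterError(f"{name} is inverted: ({lo}, {hi})")
    if not (0.0 <= mu_range[0] and mu_range[1] <= 1.0):
        raise ParameterError("mu_range must lie within [0, 1]")
    if sigma_range[0] < 0 or tau_range[0] < 0:
        raise ParameterError("standard-deviation ranges must be nonnegative")
    rng = np.random.default_rng(seed)
    mu = rng.uniform(mu_range[0], mu_range[1], size=(m, k))
    sigma = rng.uniform(sigma_range[0], sigma_range[1], size=(m, k))
    tau = rng.uniform(tau_range[0], tau_range[1], size=m)
    return mu, sigma, tau


def assign_effects(config: ScenarioConfig, seed=None) -> EffectTruth:
    """Build the ground-truth effect matrix for a scenario.

    Exactly ``m_true`` CpGs carry effects; per affected CpG the scenario
    fixes how many cell types are hit (1/2/2/3) and whether signs agree
    (uni) or must mix (bi). Magnitudes all equal ``effect_size``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m, k = config.m, config.k
    c = SCENARIO_N_CELLTYPES[config.scenario]
    beta = np.zeros((m, k))
    if config.effect_size == 0:
        # null benchmark: no effects anywhere
        return EffectTruth(beta=beta, affected_cpgs=np.array([], dtype=int),
                           affected_celltypes={})
    affected = np.sort(rng.choice(m, size=config.m_true, replace=False))
    celltype_map: Dict[int, Dict[int, float]] = {}
    bidirectional = config.scenario.startswith("bi")
    for j in affected:
        hs = rng.choice(k, size=c, replace=False)
        if bidirectional:
            # both signs present within the CpG: alternate over a random order
            signs = np.array([1.0 if t % 2 == 0 else -1.0 for t in range(c)])
            rng.shuffle(signs)
            if np.all(signs == signs[0]):  # c >= 2 guard, cannot happen for 2/3
                signs[0] = -signs[0]
        else:
            signs = np.ones(c)
        beta[j, hs] = signs * config.effect_size
        celltype_map[int(j)] = {int(h): float(s) for h, s in zip(hs, signs)}
    return EffectTruth(beta=beta, affected_cpgs=affected,
                       affected_celltypes=celltype_map)


def _balanced_binary(n: int, rng: np.random.Generator) -> np.ndarray:
    y = np.zeros(n, dtype=int)
    y[: int(np.ceil(n / 2))] = 1
    rng.shuffle(y)
    return y


def _mix_bulk(W, Z, tau, rng):
    noise = rng.normal(0.0, tau[None, :], size=(W.shape[0], tau.size))
    X = np.einsum("ih,ijh->ij", W, Z) + noise
    return X, noise


def simulate_cohort_xgy(config: ScenarioConfig) -> SyntheticCohort:
    """Simulate a cohort in which the phenotype shifts latent methylation.

    The phenotype is drawn first (balanced cases/controls); at truth entries
    the latent cell-type mean is shifted by ``effect_size * sigma_hj`` in
    cases; bulk is the proportion-weighted mixture plus measurement noise.
    """
    if config.direction != "xgy":
        raise ParameterError("simulate_cohort_xgy requires direction='xgy'")
    rng = np.random.default_rng(config.seed)
    W = simulate_proportions(config.n, config.dirichlet_alpha, rng)
    mu, sigma, tau = simulate_baseline(
        config.m, config.k, config.mu_range, config.sigma_range,
        config.tau_range, rng)
    truth = assign_effects(config, config.truth_seed if config.truth_seed is not None else rng)
    y = _balanced_binary(config.n, rng)
    shift = truth.beta * sigma  # methylation-scale effects
    loc = mu[None, :, :] + y[:, None, None] * shift[None, :, :]
    Z = rng.normal(loc, sigma[None, :, :])
    X, noise = _mix_bulk(W, Z, tau, rng)
    if config.clip:
        X = np.clip(X, 0.0, 1.0)
    return SyntheticCohort(X=X, W=W, y=y, Z=Z, noise=noise, mu=mu, sigma=sigma,
                           tau=tau, truth=truth, config=config)


def simulate_cohort_ygx(config: ScenarioConfig) -> SyntheticCohort:
    """Simulate a cohort in which latent methylation drives the phenotype.

    The latent tensor carries no phenotype term; a liability aggregates the
    standardized latent components at truth entries plus Gaussian noise, and
    the top half of the liability distribution becomes the case group
    (ceil(n/2) cases, floor(n/2) controls).
    """
    if config.direction != "ygx":
        raise ParameterError("simulate_cohort_ygx requires direction='ygx'")
    rng = np.random.default_rng(config.seed)
    W = simulate_proportions(config.n, config.dirichlet_alpha, rng)
    mu, sigma, tau = simulate_baseline(
        config.m, config.k, config.mu_range, config.sigma_range,
        config.tau_range, rng)
    truth = assign_effects(config, config.truth_seed if config.truth_seed is not None else rng)
    Z = rng.normal(mu[None, :, :], sigma[None, :, :], size=(config.n, config.m, config.k))
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(sigma > 0, (Z - mu[None, :, :]) / sigma[None, :, :], 0.0)
    L = np.einsum("ijh,jh->i", std, truth.beta)
    L = L + rng.normal(0.0, config.liability_sd, size=config.n)
    n_cases = int(np.ceil(config.n / 2))
    order = np.argsort(L, kind="stable")
    y = np.zeros(config.n, dtype=int)
    y[order[-n_cases:]] = 1
    X, noise = _mix_bulk(W, Z, tau, rng)
    if config.clip:
        X = np.clip(X, 0.0, 1.0)
    return SyntheticCohort(X=X, W=W, y=y, Z=Z, noise=noise, mu=mu, sigma=sigma,
                           tau=tau, truth=truth, config=config, liability=L)


def simulate_cohort(config: ScenarioConfig) -> SyntheticCohort:
    """Dispatch to the generator matching ``config.direction``."""
    if config.direction == "xgy":
        return simulate_cohort_xgy(config)
    return simulate_cohort_ygx(config)
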