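"""Richness estimation: frequency counts, bias-corrected Chao1, ACE,
rarefaction curves, and log-normal fitting of OTU abundance distributions.

Estimators operate on an abundance vector (the list of cluster sizes from
one clustering of the full read set). The bias-corrected Chao1,

    S_chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1)),

remains finite when doubletons are absent; ACE splits OTUs into rare
(size <= 10 by default) and abundant classes and corrects the rare class by
an estimated sample coverage C_ACE = 1 - F1 / N_rare together with a
rare-class variation term gamma^2. Both estimators give singletons heavy
predictive weight, which is exactly why communities full of one-member
lineages drive them far above the true richness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

from .cluster import ClusterMap


@dataclass
class FrequencyCounts:
    """Histogram of cluster sizes: F[i] = number of clusters with exactly i
    members, plus the total reads N and observed clusters S_obs."""

    F: dict[int, int]
    n_reads: int
    s_obs: int

    def __post_init__(self) -> None:
        if sum(self.F.values()) != self.s_obs:
            raise ValueError("sum of F_i must equal S_obs")
        if sum(i * f for i, f in self.F.items()) != self.n_reads:
            raise ValueError("sum of i * F_i must equal N")


@dataclass
class RichnessEstimate:
    """Observed richness plus Chao1 and ACE at one sampling depth."""

    s_obs: int
    chao1: float
    ace: float
    depth: int


@dataclass
class RarefactionCurve:
    """Per-depth averages of observed/Chao1/ACE richness over repeated
    subsamples; the final depth is the full read count, where the averages
    coincide exactly with the full-data estimates."""

    depths: np.ndarray
    mean_obs: np.ndarray
    mean_chao1: np.ndarray
    mean_ace: np.ndarray
    iters: int

    def series(self, which: str) -> np.ndarray:
        try:
            return {"obs": self.mean_obs, "chao1": self.mean_chao1, "ace": self.mean_ace}[
                which
            ]
        except KeyError:
            raise ValueError(f"unknown series {which!r}; use obs, chao1 or ace") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "mean_obs": self.mean_obs,
                "mean_chao1": self.mean_chao1,
                "mean_ace": self.mean_ace,
            }
        )


@dataclass
class LogNormalFit:
    """Maximum-likelihood log-normal parameters of an abundance
    distribution, with asymptotic standard errors."""

    mu_hat: float
    sigma_hat: float
    sd_mu: float
    sd_sigma: float
    degenerate: bool = False


def _as_sizes(av) -> np.ndarray:
    sizes = np.asarray(av, dtype=int)
    if sizes.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if sizes.size and sizes.min() < 1:
        raise ValueError("cluster sizes must be >= 1")
    return sizes


def frequency_counts(av) -> FrequencyCounts:
    sizes = _as_sizes(av)
    counter = Counter(int(s) for s in sizes)
    return FrequencyCounts(dict(counter), int(sizes.sum()), int(sizes.size))


def chao1_corrected(av) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1)/(2(F2+1)). Always >= S_obs,
    with equality iff F1 <= 1."""
    sizes = _as_sizes(av)
    if sizes.size == 0:
        raise ValueError("abundance vector must be non-empty")
    f1 = int((sizes == 1).sum())
    f2 = int((sizes == 2).sum())
    return sizes.size + f1 * (f1 - 1) / (2 * (f2 + 1))


def ace(av, rare_cutoff: int = 10) -> float:
    """Abundance-based Coverage Estimator with the classic rare/abundant
    split at ``rare_cutoff``.

    Degenerate branches: with no rare clusters ACE is S_obs; when the
    coverage estimate C_ACE = 1 - F1/N_rare hits zero (every rare cluster a
    singleton) the estimate falls back to bias-corrected Chao1.
    """
    sizes = _as_sizes(av)
    if sizes.size == 0:
        raise ValueError("abundance vector must be non-empty")
    rare = sizes[sizes <= rare_cutoff]
    s_abund = int((sizes > rare_cutoff).sum())
    s_rare = int(rare.size)
    n_rare = int(rare.sum())
    if n_rare == 0:
        return float(sizes.size)
    f1 = int((rare == 1).sum())
    c_ace = 1 - f1 / n_rare
    if c_ace == 0:
        return chao1_corrected(av)
    ssum = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma_sq = 0.0
    if n_rare > 1:
        gamma_sq = max((s_rare / c_ace) * ssum / (n_rare * (n_rare - 1)) - 1, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma_sq


def estimate_richness(av, depth: int | None = None, rare_cutoff: int = 10) -> RichnessEstimate:
    sizes = _as_sizes(av)
    return RichnessEstimate(
        s_obs=int(sizes.size),
        chao1=chao1_corrected(sizes),
        ace=ace(sizes, rare_cutoff),
        depth=int(sizes.sum()) if depth is None else depth,
    )


def _labels(cm: ClusterMap) -> np.ndarray:
    return np.fromiter(cm.assignments.values(), dtype=int, count=len(cm.assignments))


def rarefy_counts(cm: ClusterMap, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Sizes of the non-empty clusters in one subsample of ``depth`` reads
    drawn without replacement from the full assignment."""
    labels = _labels(cm)
    if not 0 <= depth <= labels.size:
        raise ValueError(f"depth must be in [0, {labels.size}]")
    if depth == 0:
        return np.array([], dtype=int)
    sub = labels[rng.choice(labels.size, size=depth, replace=False)]
    counts = np.bincount(sub)
    return counts[counts > 0]


def rarefaction_curve(
    cm: ClusterMap,
    step: int = 100,
    iters: int = 10,
    rng: np.random.Generator | None = None,
    rare_cutoff: int = 10,
) -> RarefactionCurve:
    """Average observed/Chao1/ACE richness over ``iters`` independent
    subsamples at each depth in {step, 2*step, ..., N}; the final depth is
    always exactly N, where the subsample is the full data and the averages
    reproduce the full-data estimates."""
    if step < 1 or iters < 1:
        raise ValueError("step and iters must be >= 1")
    rng = rng or np.random.default_rng()
    labels = _labels(cm)
    n = labels.size
    if n == 0:
        raise ValueError("cannot rarefy an empty clustering")
    depths = list(range(step, n + 1, step))
    if not depths or depths[-1] != n:
        depths.append(n)
    mean_obs, mean_chao1, mean_ace = [], [], []
    for depth in depths:
        obs_acc = chao_acc = ace_acc = 0.0
        for _ in range(iters):
            sizes = rarefy_counts(cm, depth, rng)
            obs_acc += sizes.size
            chao_acc += chao1_corrected(sizes)
            ace_acc += ace(sizes, rare_cutoff)
        mean_obs.append(obs_acc / iters)
        mean_chao1.append(chao_acc / iters)
        mean_ace.append(ace_acc / iters)
    return RarefactionCurve(
        np.array(depths), np.array(mean_obs), np.array(mean_chao1), np.array(mean_ace), iters
    )


def expected_rarefied_richness(av, depth: int) -> float:
    """Closed-form expectation of observed richness in a without-replacement
    subsample: sum_j [1 - C(N - N_j, depth) / C(N, depth)] — the
    hypergeometric rarefaction formula, usable as an analytic oracle for
    the Monte-Carlo mean."""
    sizes = _as_sizes(av)
    n = int(sizes.sum())
    if not 0 <= depth <= n:
        raise ValueError(f"depth must be in [0, {n}]")
    total = math.comb(n, depth)
    return float(sum(1 - math.comb(n - int(nj), depth) / total for nj in sizes))


def last_k_average(curve: RarefactionCurve, k: int = 10, which: str = "chao1") -> float:
    """Arithmetic mean of the last ``k`` values of the chosen series — the
    end-of-curve summary used to judge whether an estimate has stabilised."""
    series = curve.series(which)
    if series.size < k:
        raise ValueError(f"curve has {series.size} points; need >= {k}")
    return float(series[-k:].mean())


def curve_slope(curve: RarefactionCurve, k: int = 10, which: str = "chao1") -> float:
    """Mean successive difference over the last ``k`` rarefaction steps of
    the chosen series, in units of richness per step (not per read)."""
    series = curve.series(which)
    if series.size < k + 1:
        raise ValueError(f"curve has {series.size} points; need >= {k + 1}")
    return float(np.diff(series[-(k + 1):]).mean())


def _discretized_nll(
    mu: float, sigma: float, sizes_u: np.ndarray, counts: np.ndarray
) -> float:
    """Negative log-likelihood of integer sizes under the discretized
    log-normal max(1, round(exp(Normal(mu, sigma)))): size 1 collects all
    mass below 1.5, size k >= 2 the mass in [k - 0.5, k + 0.5)."""
    from scipy.stats import norm

    hi = norm.cdf((np.log(sizes_u + 0.5) - mu) / sigma)
    lo = np.where(
        sizes_u == 1, 0.0, norm.cdf((np.log(np.maximum(sizes_u - 0.5, 0.5)) - mu) / sigma)
    )
    p = np.maximum(hi - lo, 1e-300)
    return float(-(counts * np.log(p)).sum())


def _fit_discretized(sizes: np.ndarray) -> LogNormalFit:
    from collections import Counter as _Counter

    from scipy.optimize import minimize

    hist = _Counter(int(s) for s in sizes)
    sizes_u = np.array(sorted(hist), dtype=float)
    counts = np.array([hist[int(k)] for k in sizes_u], dtype=float)
    logs = np.log(sizes)
    x0 = np.array([logs.mean(), math.log(max(logs.std(ddof=0), 0.1))])
    res = minimize(
        lambda x: _discretized_nll(x[0], math.exp(x[1]), sizes_u, counts),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    mu_hat, sigma_hat = float(res.x[0]), float(math.exp(res.x[1]))

    # asymptotic SEs from the observed information (central-difference Hessian)
    def nll(p: np.ndarray) -> float:
        return _discretized_nll(p[0], p[1], sizes_u, counts)

    h = 1e-4
    p0 = np.array([mu_hat, sigma_hat])
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei, ej = np.eye(2)[i] * h, np.eye(2)[j] * h
            hess[i, j] = (
                nll(p0 + ei + ej) - nll(p0 + ei - ej) - nll(p0 - ei + ej) + nll(p0 - ei - ej)
            ) / (4 * h * h)
    cov = np.linalg.inv(hess)
    return LogNormalFit(
        mu_hat=mu_hat,
        sigma_hat=sigma_hat,
        sd_mu=float(math.sqrt(max(cov[0, 0], 0.0))),
        sd_sigma=float(math.sqrt(max(cov[1, 1], 0.0))),
    )


def fit_lognormal(av, method: str = "moments") -> LogNormalFit:
    """Log-normal fit to cluster sizes.

    ``method="moments"`` (default) is the continuous ML estimator on log
    sizes — mu_hat the mean of log sizes, sigma_hat the ML standard
    deviation, with asymptotic standard errors sd_mu = sigma/sqrt(S) and
    sd_sigma = sigma/sqrt(2S). It describes the observed size distribution
    and is exactly shift-equivariant: doubling every size moves mu_hat by
    log 2 and leaves sigma_hat unchanged.

    ``method="discretized"`` is the ML fit of the discretized log-normal
    max(1, round(exp(Normal(mu, sigma)))) — the model a simulated abundance
    distribution is actually drawn from. Flooring at 1 pushes roughly a
    third of the mass onto singletons for realistic (mu, sigma), which
    biases the moment estimator upward in mu; the discretized fit inverts
    the floor-and-round and recovers the generating parameters. Standard
    errors come from the observed information.

    All-identical sizes yield sigma_hat = 0, flagged as degenerate (with
    either method).
    """
    sizes = _as_sizes(av)
    if sizes.size < 10:
        raise ValueError("need >= 10 cluster sizes to fit a log-normal")
    logs = np.log(sizes)
    mu_mom = float(logs.mean())
    sigma_mom = float(logs.std(ddof=0))
    s = sizes.size
    if np.all(sizes == sizes[0]):
        return LogNormalFit(mu_mom, 0.0, 0.0, 0.0, degenerate=True)
    if method == "moments":
        return LogNormalFit(
            mu_hat=mu_mom,
            sigma_hat=sigma_mom,
            sd_mu=sigma_mom / math.sqrt(s),
            sd_sigma=sigma_mom / math.sqrt(2 * s),
        )
    if method == "discretized":
        return _fit_discretized(sizes)
    raise ValueError(f"unknown method {method!r}; use 'moments' or 'discretized'")
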