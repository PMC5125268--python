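"""Housworth-Stahl interference-escape likelihood.

The model treats crossovers on a chromosome as the superposition of two
pathways.  The *interference* pathway lays down chiasmata as a stationary
gamma renewal process with shape ``nu`` and rate ``2*q*nu`` (q = 1 - p), of
which each chiasma is transmitted to a given chromatid with probability
1/2; the *escape* pathway is a homogeneous Poisson process with rate ``p``
per Morgan.  Total crossover intensity is therefore q + p = 1 per Morgan.

Thinning the gamma renewal by 1/2 gives the inter-crossover gap density

    f*(y) = sum_{k>=1} (1/2)^k Gamma(y; shape k*nu, rate 2*q*nu)

(the observed gap skips a Geometric(1/2) number of chiasma gaps), the
forward-recurrence density of the first crossover

    g*(y) = q * (1 - F*(y)),

and their cdfs F* and G*.  The per-meiosis likelihood sums over all 2^n
assignments of the n observed crossovers to the two pathways; both
pathways contribute proper censoring terms for the chromosome ends.

Series are truncated at K = 40 terms, where the remaining geometric
weight sum_{k>K} 2^-k < 1e-12 bounds the truncation error.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import gammainc, gammaln, logsumexp

from .core import HSParameters, IntervalData

_K_MAX = 40  # residual geometric weight 2^-40 ~ 9.1e-13
_LOG2 = np.log(2.0)
_NEG_SENTINEL = -1e300  # stands in for an impossible dataset (log L = -inf)
_MAX_CROSSOVERS = 12  # 2^n subset guard

__all__ = [
    "interference_gap_density",
    "first_gap_density",
    "chiasma_gap_cdf",
    "interference_gap_cdf",
    "first_gap_cdf",
    "meiosis_loglik",
    "dataset_loglik",
    "CompiledDataset",
]


def _check_interference_params(params: HSParameters) -> None:
    if params.q <= 0.0:
        raise ValueError(
            "interference-pathway densities are undefined at q = 1 - p = 0; "
            "callers must branch on p == 1"
        )


def _rate(params: HSParameters) -> float:
    return 2.0 * params.q * params.nu


def _log_gamma_pdf(y: np.ndarray, shape: np.ndarray, rate: float) -> np.ndarray:
    """Termwise log gamma pdf on a (K, n) broadcast; y must be > 0."""
    return (
        shape * np.log(rate)
        - gammaln(shape)
        + (shape - 1.0) * np.log(y)
        - rate * y
    )


def interference_gap_density(y, params: HSParameters) -> np.ndarray | float:
    """f*(y): density of gaps between adjacent interference-pathway crossovers."""
    _check_interference_params(params)
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y_arr < 0):
        raise ValueError("gap must be >= 0")
    out = np.zeros_like(y_arr)
    pos = y_arr > 0
    if pos.any():
        k = np.arange(1, _K_MAX + 1)[:, None]
        logterms = -k * _LOG2 + _log_gamma_pdf(
            y_arr[pos][None, :], k * params.nu, _rate(params)
        )
        out[pos] = np.exp(logsumexp(logterms, axis=0))
    if (~pos).any():
        # y = 0 limit: only the k=1 term can be nonzero, and only for nu <= 1
        if params.nu == 1.0:
            out[~pos] = params.q
        elif params.nu < 1.0:
            out[~pos] = np.inf
    return out if np.ndim(y) else float(out[0])


def _log_sf_interference(y_arr: np.ndarray, params: HSParameters) -> np.ndarray:
    """log(1 - F*(y)) by termwise upper gamma tails; y_arr >= 0."""
    k = np.arange(1, _K_MAX + 1)[:, None]
    shapes = k * params.nu
    tails = 1.0 - gammainc(shapes, _rate(params) * y_arr[None, :])
    sf = np.sum(0.5**k * tails, axis=0) + 0.5**_K_MAX
    with np.errstate(divide="ignore"):
        return np.log(sf)


def interference_gap_cdf(y, params: HSParameters) -> np.ndarray | float:
    """F*(y): cdf of f*."""
    _check_interference_params(params)
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y_arr < 0):
        raise ValueError("argument must be >= 0")
    out = 1.0 - np.exp(_log_sf_interference(y_arr, params))
    return out if np.ndim(y) else float(out[0])


def first_gap_density(y, params: HSParameters) -> np.ndarray | float:
    """g*(y) = q (1 - F*(y)): stationary density of the first crossover gap."""
    _check_interference_params(params)
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y_arr < 0):
        raise ValueError("gap must be >= 0")
    out = params.q * np.exp(_log_sf_interference(y_arr, params))
    return out if np.ndim(y) else float(out[0])


def chiasma_gap_cdf(x, params: HSParameters) -> np.ndarray | float:
    """F(x): gamma(nu, 2 q nu) cdf of latent chiasma gaps."""
    _check_interference_params(params)
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr < 0):
        raise ValueError("argument must be >= 0")
    out = gammainc(params.nu, _rate(params) * x_arr)
    return out if np.ndim(x) else float(out[0])


def first_gap_cdf(y, params: HSParameters) -> np.ndarray | float:
    """G*(y): cdf of g*, via the exact integral of termwise gamma cdfs.

    Uses int_0^y P(a, r u) du = y P(a, r y) - (a / r) P(a + 1, r y), so the
    truncation error inherits the same 2^-K geometric bound as F*.
    """
    _check_interference_params(params)
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y_arr < 0):
        raise ValueError("argument must be >= 0")
    r = _rate(params)
    k = np.arange(1, _K_MAX + 1)[:, None]
    shapes = k * params.nu
    ry = r * y_arr[None, :]
    integral_terms = y_arr[None, :] * gammainc(shapes, ry) - (
        shapes / r
    ) * gammainc(shapes + 1.0, ry)
    integral = np.sum(0.5**k * integral_terms, axis=0)
    out = np.clip(params.q * (y_arr - integral), 0.0, 1.0)
    return out if np.ndim(y) else float(out[0])


def _log_sf_first(y_arr: np.ndarray, params: HSParameters) -> np.ndarray:
    """log(1 - G*(y)) for the zero-crossover censoring term."""
    sf = 1.0 - np.asarray(first_gap_cdf(y_arr, params))
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(sf, 0.0))


def _log_g_star(y_arr: np.ndarray, params: HSParameters) -> np.ndarray:
    return np.log(params.q) + _log_sf_interference(y_arr, params)


def _log_f_star(y_arr: np.ndarray, params: HSParameters) -> np.ndarray:
    """log f*(y) on y_arr > 0 (vectorized)."""
    k = np.arange(1, _K_MAX + 1)[:, None]
    logterms = -k * _LOG2 + _log_gamma_pdf(
        y_arr[None, :], k * params.nu, _rate(params)
    )
    return logsumexp(logterms, axis=0)


class CompiledDataset:
    """A dataset of ``IntervalData`` flattened for fast repeated evaluation.

    Every per-meiosis term of the 2^n assignment sum is unrolled once into
    flat arrays; ``loglik`` then evaluates the full dataset log-likelihood
    with a handful of vectorized density calls.  Identical (positions, L)
    meioses (in practice the zero-crossover ones) are collapsed into
    multiplicity weights.
    """

    def __init__(self, dataset: Sequence[IntervalData]) -> None:
        if len(dataset) == 0:
            raise ValueError("dataset must contain at least one meiosis")
        counts: dict[tuple, float] = {}
        for d in dataset:
            if d.n > _MAX_CROSSOVERS:
                raise ValueError(
                    f"meiosis with {d.n} crossovers exceeds the "
                    f"{_MAX_CROSSOVERS}-crossover subset guard"
                )
            key = (round(d.length, 12), tuple(d.positions))
            counts[key] = counts.get(key, 0.0) + 1.0
        self.n_meioses = len(dataset)

        weights: list[float] = []
        term_starts: list[int] = []
        term_k: list[int] = []
        term_L: list[float] = []
        is_void: list[bool] = []
        g_args: list[float] = []
        tail_args: list[float] = []
        f_args: list[float] = []
        f_term: list[int] = []

        t = 0
        for (L, pos), w in counts.items():
            weights.append(w)
            term_starts.append(t)
            n = len(pos)
            idx = range(n)
            for m in range(n + 1):  # m = size of the interference subset
                for keep in combinations(idx, m):
                    u = [pos[i] for i in keep]
                    term_k.append(n - m)
                    term_L.append(L)
                    if m == 0:
                        is_void.append(True)
                        g_args.append(1.0)  # dummy
                        tail_args.append(1.0)
                    else:
                        is_void.append(False)
                        g_args.append(u[0])
                        tail_args.append(L - u[-1])
                        for j in range(1, m):
                            f_args.append(u[j] - u[j - 1])
                            f_term.append(t)
                    t += 1

        self._weights = np.asarray(weights)
        self._term_starts = np.asarray(term_starts, dtype=np.intp)
        self._term_counts = np.diff(np.append(self._term_starts, t))
        self._term_k = np.asarray(term_k, dtype=float)
        self._term_L = np.asarray(term_L)
        self._is_void = np.asarray(is_void)
        self._g_args = np.asarray(g_args)
        self._tail_args = np.asarray(tail_args)
        self._f_args = np.asarray(f_args)
        self._f_term = np.asarray(f_term, dtype=np.intp)
        self._n_terms = t
        # dedupe density arguments across the dataset; g* and the tail
        # survivor share one survival-function evaluation
        sf_args = np.concatenate([self._g_args, self._tail_args])
        self._sf_unique, sf_inv = np.unique(sf_args, return_inverse=True)
        self._g_inv = sf_inv[: self._n_terms]
        self._tail_inv = sf_inv[self._n_terms :]
        self._f_unique, self._f_inv = np.unique(self._f_args, return_inverse=True)
        self._L_unique, self._L_inv = np.unique(self._term_L, return_inverse=True)

    def loglik(self, params: HSParameters) -> float:
        """Total log-likelihood; -inf datasets return a large negative sentinel."""
        p, q = params.p, params.q
        term_log = np.zeros(self._n_terms)

        # escape-pathway factor p^k * exp(-p L)
        with np.errstate(divide="ignore", invalid="ignore"):
            esc = self._term_k * np.log(p) if p > 0 else np.where(
                self._term_k > 0, -np.inf, 0.0
            )
        term_log += esc - p * self._term_L

        chain = ~self._is_void
        if q > 0.0:
            sf = _log_sf_interference(self._sf_unique, params)
            lg = np.log(q) + sf[self._g_inv]
            lt = sf[self._tail_inv]
            term_log[chain] += lg[chain] + lt[chain]
            if self._f_args.size:
                lf = _log_f_star(self._f_unique, params)[self._f_inv]
                term_log += np.bincount(
                    self._f_term, weights=lf, minlength=self._n_terms
                )
            lvoid = _log_sf_first(self._L_unique, params)[self._L_inv]
            term_log[self._is_void] += lvoid[self._is_void]
        else:
            # p = 1: the interference pathway produces no crossovers, so
            # only the all-escape assignment contributes and 1 - G*(L) -> 1
            term_log[chain] = -np.inf

        # grouped log-sum-exp over each meiosis' contiguous terms
        starts = self._term_starts
        with np.errstate(invalid="ignore"):
            block_max = np.maximum.reduceat(term_log, starts)
        safe_max = np.where(np.isfinite(block_max), block_max, 0.0)
        shifted = np.exp(term_log - np.repeat(safe_max, self._term_counts))
        block_sum = np.add.reduceat(shifted, starts)
        with np.errstate(divide="ignore"):
            block_log = np.where(
                np.isfinite(block_max), safe_max + np.log(block_sum), -np.inf
            )
        if not np.all(np.isfinite(block_log)):
            return _NEG_SENTINEL
        return float(np.dot(self._weights, block_log))


def meiosis_loglik(data: IntervalData, params: HSParameters) -> float:
    """Log-likelihood of one chromosome of one meiosis.

    Sums the likelihood over all 2^n ways of assigning the n observed
    crossovers to the escape (Poisson, rate p) and interference (thinned
    gamma renewal) pathways, with censoring at both chromosome ends.
    """
    return CompiledDataset([data]).loglik(params)


def dataset_loglik(dataset: Sequence[IntervalData], params: HSParameters) -> float:
    """Sum of ``meiosis_loglik`` over all chromosome-meioses in the dataset."""
    return CompiledDataset(dataset).loglik(params)
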