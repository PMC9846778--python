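"""Nonnegative matrix factorisation by multiplicative updates.

Factorises a 96 x samples count matrix ``X ~ W H`` with ``W`` (96 x k) the
signature basis and ``H`` (k x samples) the exposures. The default objective
is the generalised Kullback-Leibler divergence

    D(X || WH) = sum_ij [ x_ij log(x_ij / (WH)_ij) - x_ij + (WH)_ij ],

the Poisson-likelihood loss appropriate for count catalogues and the loss
used by the SigProfiler lineage of extractors; the Frobenius norm is offered
as an option. Multiplicative updates make the objective non-increasing at
every iteration, which the implementation records in ``objective_path``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NMFResult", "multiplicative_nmf", "kl_divergence"]

_EPS = 1e-12


def kl_divergence(x: np.ndarray, y: np.ndarray) -> float:
    """Generalised KL divergence D(x || y), elementwise over matrices."""
    x = np.asarray(x, dtype=float)
    y = np.maximum(np.asarray(y, dtype=float), _EPS)
    xa = np.maximum(x, _EPS)
    return float(np.sum(np.where(x > 0, x * np.log(xa / y), 0.0) - x + y))


@dataclass
class NMFResult:
    w: np.ndarray  # features x k
    h: np.ndarray  # k x samples
    objective_path: np.ndarray
    converged: bool

    @property
    def objective(self) -> float:
        return float(self.objective_path[-1])


def _objective(x, w, h, loss):
    if loss == "kullback-leibler":
        return kl_divergence(x, w @ h)
    return 0.5 * float(np.sum((x - w @ h) ** 2))


def multiplicative_nmf(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    loss: str = "kullback-leibler",
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> NMFResult:
    """Run one seeded multiplicative-update NMF of rank *k* on ``x >= 0``.

    Initialisation is uniform-random scaled to the data mean; convergence is
    declared when the relative objective change over an iteration drops
    below *tol*. Results are bit-reproducible for a given generator state.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("input matrix must be nonnegative")
    if loss not in ("kullback-leibler", "frobenius"):
        raise ValueError(f"unknown NMF loss: {loss!r}")
    n, m = x.shape
    if not 1 <= k < min(n, m) + 1:
        raise ValueError(f"rank {k} invalid for a {n}x{m} matrix")
    scale = np.sqrt(max(x.mean(), _EPS) / k)
    w = rng.uniform(0.5, 1.5, size=(n, k)) * scale
    h = rng.uniform(0.5, 1.5, size=(k, m)) * scale

    objective = [_objective(x, w, h, loss)]
    converged = False
    for _ in range(max_iter):
        if loss == "kullback-leibler":
            wh = np.maximum(w @ h, _EPS)
            h *= (w.T @ (x / wh)) / np.maximum(w.sum(axis=0)[:, None], _EPS)
            wh = np.maximum(w @ h, _EPS)
            w *= ((x / wh) @ h.T) / np.maximum(h.sum(axis=1)[None, :], _EPS)
        else:
            h *= (w.T @ x) / np.maximum(w.T @ w @ h, _EPS)
            w *= (x @ h.T) / np.maximum(w @ h @ h.T, _EPS)
        objective.append(_objective(x, w, h, loss))
        prev, cur = objective[-2], objective[-1]
        if prev - cur <= tol * max(abs(prev), 1.0):
            converged = True
            break
    return NMFResult(w, h, np.asarray(objective), converged)
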