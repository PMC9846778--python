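"""Archetypal analysis (principal convex hull) of signature catalogues.

Given data rows ``x_i`` (here: signature profiles over the 96 contexts),
archetypal analysis finds ``r`` archetypes ``z_k`` minimising

    sum_i || x_i - sum_k alpha_ik z_k ||^2,   z_k = sum_j beta_kj x_j,

with both the ``alpha`` rows (reconstruction weights per data point) and the
``beta`` rows (composition weights per archetype) constrained to the
probability simplex. The constraints force every archetype onto the convex
hull of the data, so archetypes are extreme rather than average profiles,
and every data point is approximated by a convex mixture of extremes.

The solver alternates projected-gradient descent on ``alpha`` (with ``Z``
fixed) and on ``beta`` (with ``alpha`` fixed), using exact Euclidean
projection onto the simplex and a 1/L Lipschitz step, which keeps both
blocks exactly feasible and the residual sum of squares non-increasing.
Initialisation uses the furthest-sum heuristic; multiple restarts guard
against local optima.

Explained variance is ``1 - SSE/TSS``. By default TSS is the total squared
deviation of the data from its mean row ("centered"); the alternative about
zero ("uncentered") is available via ``variance_of``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin

from .catalogue_io import SignatureMatrix

__all__ = [
    "ArchetypalAnalysis",
    "ArchetypeModel",
    "ArchetypeReport",
    "project_to_simplex",
    "furthest_sum",
    "fit_archetypes",
    "explained_variance_curve",
    "select_num_archetypes",
    "reconstruction_report",
    "alpha_grouping",
    "alpha_similarity_consistency",
]


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Exact Euclidean projection of each row of *v* onto the probability
    simplex (Held/Duchi algorithm)."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, v.shape[1] + 1)
    cond = u - css / ind > 0
    rho = cond.sum(axis=1)
    theta = css[np.arange(v.shape[0]), rho - 1] / rho
    return np.maximum(v - theta[:, None], 0.0)


def furthest_sum(x: np.ndarray, r: int, rng: np.random.Generator) -> np.ndarray:
    """Furthest-sum candidate selection: r data-row indices spread out in
    Euclidean distance, grown greedily from a random start (which is then
    replaced by a furthest point, the standard refinement)."""
    p = x.shape[0]
    if r > p:
        raise ValueError("cannot select more candidates than data rows")
    sq = (x**2).sum(axis=1)

    def dists(j):
        return np.sqrt(np.maximum(sq + sq[j] - 2 * x @ x[j], 0.0))

    chosen = [int(rng.integers(p))]
    total = np.zeros(p)
    for _ in range(r):
        total += dists(chosen[-1])
        if len(chosen) == r:
            # drop the arbitrary seed point and replace it by a furthest one
            total -= dists(chosen[0])
            chosen = chosen[1:]
        masked = total.copy()
        masked[chosen] = -np.inf
        chosen.append(int(np.argmax(masked)))
    return np.asarray(chosen)


def _pg_step(grad_f, project, var, lipschitz, n_steps):
    """Monotone projected-gradient descent with fixed 1/L step."""
    step = 1.0 / max(lipschitz, 1e-300)
    for _ in range(n_steps):
        var = project(var - step * grad_f(var))
    return var


@dataclass
class ArchetypeModel:
    """A fitted archetypal decomposition of a data matrix."""

    r: int
    archetypes: np.ndarray  # r x q  (Z = beta @ X exactly)
    alpha: np.ndarray  # p x r, rows on the simplex
    beta: np.ndarray  # r x p, rows on the simplex
    sse: float
    explained_variance: float
    sse_path: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    seed: int | None = None


def _sse(x, alpha, z) -> float:
    return float(((x - alpha @ z) ** 2).sum())


def _total_ss(x: np.ndarray, variance_of: str) -> float:
    if variance_of == "centered":
        return float(((x - x.mean(axis=0)) ** 2).sum())
    if variance_of == "uncentered":
        return float((x**2).sum())
    raise ValueError(f"unknown variance convention: {variance_of!r}")


class ArchetypalAnalysis(BaseEstimator, TransformerMixin):
    """Archetypal analysis estimator (principal convex hull).

    Parameters
    ----------
    n_archetypes : int
        Number of archetypes ``r``.
    n_restarts : int
        Independent furthest-sum initialisations; the best-SSE fit is kept.
    max_iter : int
        Maximum alternating iterations per restart.
    tol : float
        Convergence threshold on the relative SSE change per iteration.
    inner_steps : int
        Projected-gradient steps per block update.
    variance_of : {"centered", "uncentered"}
        Total-sum-of-squares convention for explained variance.
    random_state : int or None
        Seed for initialisation.

    Attributes
    ----------
    archetypes_ : ndarray of shape (n_archetypes, n_features)
        The archetype profiles ``Z = beta_ @ X`` (exact identity).
    alpha_ : ndarray of shape (n_samples, n_archetypes)
        Simplex reconstruction weights per data row.
    beta_ : ndarray of shape (n_archetypes, n_samples)
        Simplex composition weights per archetype.
    sse_ : float
        Residual sum of squares.
    explained_variance_ : float
        ``1 - sse_ / TSS``.
    """

    def __init__(
        self,
        n_archetypes=3,
        n_restarts=5,
        max_iter=300,
        tol=1e-7,
        inner_steps=15,
        variance_of="centered",
        random_state=None,
    ):
        self.n_archetypes = n_archetypes
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.inner_steps = inner_steps
        self.variance_of = variance_of
        self.random_state = random_state

    def _fit_once(self, x: np.ndarray, rng: np.random.Generator):
        p, q = x.shape
        r = self.n_archetypes
        idx = furthest_sum(x, min(r, p), rng)
        if r > p:  # degenerate: duplicate archetypes allowed
            idx = np.concatenate([idx, rng.integers(p, size=r - p)])
        beta = np.zeros((r, p))
        beta[np.arange(r), idx] = 1.0
        z = beta @ x
        # nearest-archetype one-hot start for alpha
        d2 = ((x[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
        alpha = np.zeros((p, r))
        alpha[np.arange(p), np.argmin(d2, axis=1)] = 1.0

        xxt_norm = np.linalg.norm(x @ x.T, 2)
        path = [_sse(x, alpha, z)]
        converged = False
        for _ in range(self.max_iter):
            # alpha block: min ||X - alpha Z||^2, rows independent
            zzt = z @ z.T
            l_alpha = 2.0 * np.linalg.norm(zzt, 2)
            alpha = _pg_step(
                lambda a: 2.0 * (a @ zzt - x @ z.T),
                project_to_simplex,
                alpha,
                l_alpha,
                self.inner_steps,
            )
            # beta block: min ||X - alpha beta X||^2
            ata = alpha.T @ alpha
            l_beta = 2.0 * np.linalg.norm(ata, 2) * xxt_norm
            atx = alpha.T @ x

            def grad_beta(b):
                return 2.0 * ((ata @ b @ x - atx) @ x.T)

            beta = _pg_step(grad_beta, project_to_simplex, beta, l_beta, self.inner_steps)
            z = beta @ x
            path.append(_sse(x, alpha, z))
            prev, cur = path[-2], path[-1]
            # relative-change criterion, with an absolute floor for
            # (near-)exact fits where the relative change never settles
            if prev - cur <= self.tol * max(prev, 1e-300) or cur <= 1e-12 * (x**2).sum():
                converged = True
                break
        return alpha, beta, z, np.asarray(path), converged

    def fit(self, X, y=None):
        """Fit archetypes to a (n_samples, n_features) nonnegative matrix."""
        x = X.values if isinstance(X, SignatureMatrix) else np.asarray(X, dtype=float)
        if x.ndim != 2:
            raise ValueError("expected a 2-D data matrix")
        if not 1 <= self.n_archetypes:
            raise ValueError("n_archetypes must be >= 1")
        seed_seq = np.random.SeedSequence(self.random_state)
        best = None
        for child in seed_seq.spawn(max(1, self.n_restarts)):
            rng = np.random.default_rng(child)
            alpha, beta, z, path, conv = self._fit_once(x, rng)
            if best is None or path[-1] < best[3][-1]:
                best = (alpha, beta, z, path, conv)
        alpha, beta, z, path, conv = best
        if not conv:
            warnings.warn(
                "archetypal analysis did not converge within max_iter",
                UserWarning,
                stacklevel=2,
            )
        self.alpha_, self.beta_, self.archetypes_ = alpha, beta, z
        self.sse_ = float(path[-1])
        self.sse_path_ = path
        self.converged_ = conv
        tss = _total_ss(x, self.variance_of)
        self.explained_variance_ = 1.0 - self.sse_ / tss if tss > 0 else 1.0
        self.n_features_in_ = x.shape[1]
        return self

    def transform(self, X):
        """Simplex reconstruction weights of new rows against the fitted
        archetypes (projected-gradient solve, alpha-step only)."""
        x = X.values if isinstance(X, SignatureMatrix) else np.asarray(X, dtype=float)
        z = self.archetypes_
        zzt = z @ z.T
        l_alpha = 2.0 * np.linalg.norm(zzt, 2)
        alpha = np.full((x.shape[0], z.shape[0]), 1.0 / z.shape[0])
        for _ in range(50):
            alpha = _pg_step(
                lambda a: 2.0 * (a @ zzt - x @ z.T),
                project_to_simplex,
                alpha,
                l_alpha,
                self.inner_steps,
            )
        return alpha

    def inverse_transform(self, alpha):
        return np.asarray(alpha) @ self.archetypes_

    def to_model(self, seed=None) -> ArchetypeModel:
        return ArchetypeModel(
            r=self.archetypes_.shape[0],
            archetypes=self.archetypes_,
            alpha=self.alpha_,
            beta=self.beta_,
            sse=self.sse_,
            explained_variance=self.explained_variance_,
            sse_path=self.sse_path_,
            converged=self.converged_,
            seed=seed,
        )


def fit_archetypes(
    X,
    r: int,
    random_state=None,
    n_restarts: int = 5,
    tol: float = 1e-7,
    max_iter: int = 300,
    variance_of: str = "centered",
) -> ArchetypeModel:
    """Fit an :class:`ArchetypeModel` with *r* archetypes to *X*."""
    est = ArchetypalAnalysis(
        n_archetypes=r,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        variance_of=variance_of,
        random_state=random_state,
    ).fit(X)
    return est.to_model(seed=random_state)


def explained_variance_curve(
    X,
    r_range,
    n_restarts: int = 5,
    random_state=None,
    variance_of: str = "centered",
    **kwargs,
):
    """Best-of-restarts explained variance for each r in *r_range*.

    Returns ``(curve, models)`` with ``curve`` a list of ``(r, ev)`` pairs
    (nondecreasing in r up to optimisation noise) and ``models`` the fitted
    model per r.
    """
    r_range = list(r_range)
    if any(b <= a for a, b in zip(r_range, r_range[1:])):
        raise ValueError("r_range must be strictly increasing")
    curve, models = [], {}
    ss = np.random.SeedSequence(random_state)
    for r, child in zip(r_range, ss.spawn(len(r_range))):
        model = fit_archetypes(
            X,
            r,
            random_state=child.generate_state(1)[0] % (2**31),
            n_restarts=n_restarts,
            variance_of=variance_of,
            **kwargs,
        )
        curve.append((r, model.explained_variance))
        models[r] = model
    return curve, models


def select_num_archetypes(curve, threshold: float = 0.95) -> int:
    """Smallest r on *curve* with explained variance >= *threshold*;
    the largest r (with a warning) when none reaches it."""
    if not curve:
        raise ValueError("empty explained-variance curve")
    for r, ev in sorted(curve):
        if ev >= threshold:
            return r
    r_max = max(r for r, _ in curve)
    warnings.warn(
        f"no archetype count reached explained variance {threshold}; "
        f"returning the largest tried (r={r_max})",
        UserWarning,
        stacklevel=2,
    )
    return r_max


def _cosine_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    return (a @ b.T) / np.maximum(na * nb.T, 1e-300)


@dataclass
class ArchetypeReport:
    """Reconstruction quality and archetype-signature correspondence."""

    signature_cosines: dict[str, float]  # x_i vs alpha_i Z
    archetype_best_match: list[tuple[str, str, float]]  # (archetype, signature, cos)
    n_correspondent: int  # archetypes matching some signature >= threshold
    correspondence_threshold: float
    one_to_one_archetypes: int  # archetypes dominant for exactly one signature


def reconstruction_report(
    model: ArchetypeModel, X: SignatureMatrix, correspondence_threshold: float = 0.97
) -> ArchetypeReport:
    """Score how well archetypes reconstruct and correspond to signatures.

    Reports the cosine between each signature and its archetypal
    reconstruction, each archetype's best-matching signature, the number of
    archetypes whose best match reaches *correspondence_threshold*, and the
    number of archetypes that dominate exactly one signature's alpha row.
    """
    recon = model.alpha @ model.archetypes
    cos_recon = np.diag(_cosine_rows(X.values, recon))
    arch_names = [f"A{k + 1}" for k in range(model.r)]
    cos_arch = _cosine_rows(model.archetypes, X.values)
    best = []
    for k, name in enumerate(arch_names):
        j = int(np.argmax(cos_arch[k]))
        best.append((name, X.names[j], float(cos_arch[k, j])))
    n_corr = sum(1 for _, _, c in best if c >= correspondence_threshold)
    dominant = np.argmax(model.alpha, axis=1)
    counts = np.bincount(dominant, minlength=model.r)
    return ArchetypeReport(
        signature_cosines={n: float(c) for n, c in zip(X.names, cos_recon)},
        archetype_best_match=best,
        n_correspondent=n_corr,
        correspondence_threshold=correspondence_threshold,
        one_to_one_archetypes=int((counts == 1).sum()),
    )


def alpha_grouping(
    model: ArchetypeModel,
    X: SignatureMatrix,
    display_threshold: float = 0.2,
    cluster_threshold: float = 0.5,
    linkage: str = "average",
):
    """Group signatures by the similarity of their alpha rows.

    Signatures are hierarchically clustered on their full alpha rows
    (cosine distance, average linkage by default) and the tree is cut at
    *cluster_threshold*; each group reports its dominant archetype (largest
    mean alpha). The returned display table is reordered to the dendrogram
    leaf order and masks coefficients below *display_threshold* — the
    clustering itself always uses all coefficients.

    Returns ``(groups, table)``: a list of
    ``{"signatures": [...], "dominant_archetype": "Ak"}`` dicts and the
    masked, leaf-ordered coefficient DataFrame.
    """
    alpha = model.alpha
    if len(X.names) != alpha.shape[0]:
        raise ValueError("model was not fitted on this signature matrix")
    arch_names = [f"A{k + 1}" for k in range(model.r)]
    if alpha.shape[0] > 1:
        link = hierarchy.linkage(pdist(alpha, metric="cosine"), method=linkage)
        labels = hierarchy.fcluster(link, t=cluster_threshold, criterion="distance")
        order = list(hierarchy.leaves_list(link))
    else:
        labels = np.array([1])
        order = [0]
    groups = []
    for lab in sorted(set(labels)):
        members = [i for i, l in enumerate(labels) if l == lab]
        dominant = int(np.argmax(alpha[members].mean(axis=0)))
        groups.append(
            {
                "signatures": [X.names[i] for i in members],
                "dominant_archetype": arch_names[dominant],
            }
        )
    table = pd.DataFrame(alpha, index=X.names, columns=arch_names)
    table = table.iloc[order].mask(table.iloc[order] < display_threshold, 0.0)
    return groups, table


def alpha_similarity_consistency(model: ArchetypeModel, X: SignatureMatrix):
    """Pairwise profile cosines vs alpha-row cosines, with rank correlation.

    For every unordered signature pair, emits the cosine similarity of the
    original profiles and of the corresponding alpha rows; the attached
    Spearman correlation summarises whether more similar signatures are
    reconstructed from more similar archetype mixtures.
    """
    prof = _cosine_rows(X.values, X.values)
    ac = _cosine_rows(model.alpha, model.alpha)
    iu = np.triu_indices(X.n_signatures, k=1)
    profile_cos = prof[iu]
    alpha_cos = ac[iu]
    rho = spearmanr(profile_cos, alpha_cos).statistic if profile_cos.size > 1 else np.nan
    return {
        "profile_cosines": profile_cos,
        "alpha_cosines": alpha_cos,
        "spearman_rho": float(rho),
    }
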