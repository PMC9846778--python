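"""De novo signature extraction: repeated NMF, Hungarian consensus, stability.

The extractor mirrors the consensus strategy of SigProfiler-style tools in a
simplified, fully specified form. For a candidate rank ``k``:

1. ``n_runs`` independent NMF factorisations are computed (optionally on a
   Poisson bootstrap of the catalogue, replacing each count by a Poisson
   draw with that mean);
2. the ``n_runs * k`` run-signatures are partitioned into ``k`` clusters by
   iterated Hungarian matching: each run's signatures are optimally assigned
   to the current centroids under cosine distance, centroids are recomputed
   as normalised cluster means, and the loop repeats until assignments
   stabilise;
3. cluster compactness is scored by silhouette coefficients on cosine
   distance: per-signature ``c_ik``, per-cluster means ``C_k``, their average
   ``C_mean`` and minimum ``C_min``.

Rank selection keeps the largest rank whose minimum cluster stability
clears a threshold and whose reconstruction error still improves materially
over the previous rank; all per-rank diagnostics are exposed so users can
apply their own rule.

Evaluation metrics for simulated scenarios:

* ``F`` — fraction of replicate catalogues in which every generating
  signature is recovered (one-to-one optimal matching, all matched cosines
  above a threshold);
* ``MSE`` — mean squared difference between the simulated catalogue and its
  reconstruction from consensus signatures and NNLS-refit exposures, with
  denominator ``n_contexts * n_samples``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.base import BaseEstimator

from .catalogue_io import MutationalCatalogue, SignatureMatrix
from .contexts import N_CONTEXTS
from .nmf import multiplicative_nmf
from .synthetic import SimulatedCatalogue

__all__ = [
    "NMFRunSet",
    "ConsensusResult",
    "ExtractionEvaluation",
    "RefitResult",
    "SignatureExtractor",
    "run_nmf_once",
    "collect_nmf_runs",
    "consensus_partition",
    "select_rank",
    "match_to_truth",
    "evaluate_scenario",
    "success_frequency",
    "refit_exposures",
    "catalogue_mse",
    "silhouette_samples_cosine",
]


def run_nmf_once(
    cat: MutationalCatalogue,
    k: int,
    rng: np.random.Generator,
    resample: bool = False,
    loss: str = "kullback-leibler",
    max_iter: int = 1000,
    tol: float = 1e-6,
):
    """One seeded NMF factorisation of a catalogue at rank *k*.

    With ``resample=True`` the catalogue is first Poisson-perturbed (each
    count replaced by a Poisson draw with that mean), the bootstrap used to
    probe solution stability. Returned signatures are L1-normalised rows
    (k x 96) with the scale absorbed into the exposures (k x samples).
    """
    x = cat.counts.astype(float)
    if resample:
        x = rng.poisson(x).astype(float)
    res = multiplicative_nmf(x, k, rng, loss=loss, max_iter=max_iter, tol=tol)
    if not res.converged:
        warnings.warn(
            f"NMF at rank {k} did not converge within {max_iter} iterations",
            UserWarning,
            stacklevel=2,
        )
    scale = np.maximum(res.w.sum(axis=0), 1e-300)
    signatures = (res.w / scale).T  # k x 96
    exposures = res.h * scale[:, None]
    return signatures, exposures


@dataclass
class NMFRunSet:
    """Signatures and exposures from repeated NMF at one rank."""

    rank: int
    signatures: list[np.ndarray]  # each k x 96, rows summing to 1
    exposures: list[np.ndarray]  # each k x samples

    def __post_init__(self) -> None:
        if len(self.signatures) < 2:
            raise ValueError("need at least 2 NMF runs for a consensus")
        for s in self.signatures:
            if s.shape != (self.rank, N_CONTEXTS):
                raise ValueError("run signature shape mismatch")

    @property
    def n_runs(self) -> int:
        return len(self.signatures)


def collect_nmf_runs(
    cat: MutationalCatalogue,
    k: int,
    rng: np.random.Generator,
    n_runs: int = 30,
    resample: bool = True,
    loss: str = "kullback-leibler",
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> NMFRunSet:
    """Run *n_runs* independent (optionally bootstrapped) NMFs at rank *k*."""
    sigs, exps = [], []
    for _ in range(n_runs):
        s, e = run_nmf_once(
            cat, k, rng, resample=resample, loss=loss, max_iter=max_iter, tol=tol
        )
        sigs.append(s)
        exps.append(e)
    return NMFRunSet(k, sigs, exps)


def _cosine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    return (a @ b.T) / np.maximum(na * nb.T, 1e-300)


def silhouette_samples_cosine(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette coefficients under cosine distance.

    ``c_i = (b_i - a_i) / max(a_i, b_i)`` with ``a_i`` the mean intra-cluster
    distance and ``b_i`` the mean distance to the nearest other cluster.
    Members of singleton clusters, and points whose ``a`` and ``b`` both
    vanish (identical points), score 0.
    """
    dist = 1.0 - _cosine_matrix(points, points)
    np.fill_diagonal(dist, 0.0)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    out = np.zeros(len(labels))
    for i in range(len(labels)):
        same = labels == labels[i]
        n_same = same.sum()
        if n_same == 1:
            out[i] = 0.0
            continue
        a = dist[i, same].sum() / (n_same - 1)
        b = min(dist[i, labels == lab].mean() for lab in uniq if lab != labels[i])
        denom = max(a, b)
        out[i] = 0.0 if denom <= 0 else (b - a) / denom
    return out


@dataclass
class ConsensusResult:
    """Consensus signatures at one rank with cluster-stability scores."""

    rank: int
    consensus_signatures: np.ndarray  # k x 96, rows summing to 1
    labels: np.ndarray  # cluster label per run-signature (n_runs * k,)
    silhouettes: np.ndarray  # c_ik per run-signature
    cluster_stability: np.ndarray  # C_k per cluster
    stable_partition: bool = True

    @property
    def c_mean(self) -> float:
        return float(self.cluster_stability.mean())

    @property
    def c_min(self) -> float:
        return float(self.cluster_stability.min())


def consensus_partition(runs: NMFRunSet, max_iter: int = 100) -> ConsensusResult:
    """Partition run-signatures into rank-many clusters by Hungarian matching.

    Centroids start from the first run; each iteration optimally assigns
    every run's signatures to the centroids by minimum-cost bipartite
    matching under cosine distance, then recomputes centroids as normalised
    cluster means. Every cluster ends with exactly one member per run.
    """
    k, n_runs = runs.rank, runs.n_runs
    centroids = runs.signatures[0].copy()
    assign = np.tile(np.arange(k), (n_runs, 1))
    stable = False
    for _ in range(max_iter):
        new_assign = np.empty_like(assign)
        for r, s in enumerate(runs.signatures):
            cost = 1.0 - _cosine_matrix(s, centroids)
            rows, cols = linear_sum_assignment(cost)
            new_assign[r, rows] = cols
        if np.array_equal(new_assign, assign):
            stable = True
            break
        assign = new_assign
        for c in range(k):
            members = np.stack(
                [runs.signatures[r][np.where(assign[r] == c)[0][0]] for r in range(n_runs)]
            )
            mean = members.mean(axis=0)
            centroids[c] = mean / mean.sum()
    else:
        warnings.warn(
            "consensus partition did not stabilise; keeping last assignment",
            UserWarning,
            stacklevel=2,
        )
    points = np.vstack(runs.signatures)
    labels = assign.ravel()
    if k == 1:
        # a single cluster has no alternative; stability is trivially perfect
        sil = np.ones(points.shape[0])
    else:
        sil = silhouette_samples_cosine(points, labels)
    c_k = np.array([sil[labels == c].mean() for c in range(k)])
    return ConsensusResult(k, centroids, labels, sil, c_k, stable_partition=stable)


@dataclass
class RefitResult:
    """NNLS exposure refit of a catalogue against fixed signatures."""

    exposures: np.ndarray  # k x samples
    reconstruction: np.ndarray  # 96 x samples
    sample_cosines: np.ndarray
    sample_maes: np.ndarray

    @property
    def mean_cosine(self) -> float:
        return float(self.sample_cosines.mean())

    @property
    def mean_mae(self) -> float:
        return float(self.sample_maes.mean())


def refit_exposures(cat, sig: SignatureMatrix) -> RefitResult:
    """Per-sample nonnegative least-squares fit of counts to signatures.

    Solves ``min ||counts_j - S^T e_j||  s.t. e_j >= 0`` per sample and
    reports per-sample cosine similarity and mean absolute error between
    the observed and reconstructed count columns. *cat* may be a
    :class:`MutationalCatalogue` or a raw nonnegative 96 x samples array.
    """
    obs = (
        cat.counts.astype(float)
        if isinstance(cat, MutationalCatalogue)
        else np.asarray(cat, dtype=float)
    )
    if obs.ndim != 2 or obs.shape[0] != N_CONTEXTS:
        raise ValueError(f"catalogue must be ({N_CONTEXTS}, n_samples)")
    a = sig.values.T  # 96 x k
    n = obs.shape[1]
    exposures = np.empty((sig.n_signatures, n))
    for j in range(n):
        exposures[:, j], _ = nnls(a, obs[:, j])
    recon = a @ exposures
    cosines = np.empty(n)
    for j in range(n):
        num = float(obs[:, j] @ recon[:, j])
        den = np.linalg.norm(obs[:, j]) * np.linalg.norm(recon[:, j])
        cosines[j] = num / den if den > 0 else 0.0
    maes = np.abs(obs - recon).mean(axis=0)
    return RefitResult(exposures, recon, cosines, maes)


def catalogue_mse(observed: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean squared error between two catalogues: ``sum (x - xhat)^2 / (n m)``."""
    observed = np.asarray(observed, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if observed.shape != reconstructed.shape:
        raise ValueError("catalogue shapes differ")
    return float(((observed - reconstructed) ** 2).mean())


def _consensus_signature_matrix(res: ConsensusResult) -> SignatureMatrix:
    names = [f"DN{i + 1}" for i in range(res.rank)]
    return SignatureMatrix.from_profiles(names, res.consensus_signatures)


def select_rank(
    cat: MutationalCatalogue,
    k_range,
    rng: np.random.Generator,
    n_runs: int = 30,
    resample: bool = True,
    stability_threshold: float = 0.7,
    improvement_tol: float = 0.01,
    loss: str = "kullback-leibler",
    max_iter: int = 1000,
    tol: float = 1e-6,
):
    """Choose the number of latent signatures for a catalogue.

    Runs repeated NMF plus consensus partitioning at every rank in
    *k_range* and keeps the largest rank whose minimum cluster stability
    ``C_min`` is at least *stability_threshold* and whose reconstruction
    error improves on the previous rank by more than *improvement_tol*
    (relative). If no rank qualifies, the rank with the best ``C_min`` is
    returned flagged as an unstable selection.

    Returns ``(chosen_k, per_k, stable)`` where ``per_k`` maps each rank to
    a dict with the consensus result and its reconstruction MSE.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    per_k: dict[int, dict] = {}
    for k in k_range:
        runs = collect_nmf_runs(
            cat, k, rng, n_runs=n_runs, resample=resample, loss=loss,
            max_iter=max_iter, tol=tol,
        )
        res = consensus_partition(runs)
        refit = refit_exposures(cat, _consensus_signature_matrix(res))
        per_k[k] = {
            "consensus": res,
            "mse": catalogue_mse(cat.counts, refit.reconstruction),
            "c_mean": res.c_mean,
            "c_min": res.c_min,
        }
    candidates = []
    for i, k in enumerate(k_range):
        if per_k[k]["c_min"] < stability_threshold:
            continue
        if i > 0:
            prev = per_k[k_range[i - 1]]["mse"]
            if prev <= 0 or (prev - per_k[k]["mse"]) / prev < improvement_tol:
                continue
        candidates.append(k)
    if candidates:
        return max(candidates), per_k, True
    fallback = max(k_range, key=lambda k: per_k[k]["c_min"])
    warnings.warn(
        f"no rank in {k_range} met the stability criterion; "
        f"returning best-compromise rank {fallback}",
        UserWarning,
        stacklevel=2,
    )
    return fallback, per_k, False


@dataclass
class MatchResult:
    """Optimal one-to-one correspondence between extracted and true signatures."""

    pairs: list[tuple[str, str, float]]  # (true name, extracted name, cosine)
    success: bool
    threshold: float


def match_to_truth(
    extracted: SignatureMatrix, truth: SignatureMatrix, threshold: float = 0.8
) -> MatchResult:
    """Match extracted to true signatures by maximum total cosine similarity.

    The extraction counts as successful iff the number of extracted
    signatures equals the number of true ones and every matched pair has
    cosine similarity at least *threshold*.
    """
    cos = _cosine_matrix(truth.values, extracted.values)
    rows, cols = linear_sum_assignment(-cos)
    pairs = [
        (truth.names[i], extracted.names[j], float(cos[i, j]))
        for i, j in zip(rows, cols)
    ]
    success = extracted.n_signatures == truth.n_signatures and all(
        c >= threshold for _, _, c in pairs
    )
    return MatchResult(pairs, success, threshold)


@dataclass
class ExtractionEvaluation:
    """Scenario-level evaluation across replicate catalogues."""

    f_success: float
    mse_median: float
    mse_iqr: tuple[float, float]
    c_mean_median: float
    c_min_median: float
    per_replicate: list[dict] = field(repr=False, default_factory=list)


def success_frequency(flags) -> float:
    """Fraction of successful runs: ``F = n_successful / n_total``."""
    flags = list(flags)
    if not flags:
        raise ValueError("need at least one run")
    return sum(bool(f) for f in flags) / len(flags)


def _median_iqr(values) -> tuple[float, tuple[float, float]]:
    v = np.asarray(values, dtype=float)
    return float(np.median(v)), (
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def evaluate_scenario(
    replicates: list[SimulatedCatalogue],
    rng: np.random.Generator,
    k_range=None,
    match_threshold: float = 0.8,
    **extractor_kwargs,
) -> ExtractionEvaluation:
    """Run extraction on every replicate and score recovery of the truth.

    ``F`` is the fraction of replicates in which all generating signatures
    were recovered; the MSE between each simulated catalogue and its
    consensus reconstruction, and the stability scores of the chosen rank,
    are summarised as median and inter-quartile range.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    records = []
    for rep in replicates:
        truth = rep.true_signatures
        if k_range is None:
            ks = range(max(1, truth.n_signatures - 2), truth.n_signatures + 3)
        else:
            ks = k_range
        chosen, per_k, stable = select_rank(
            rep.catalogue, ks, rng, **extractor_kwargs
        )
        res: ConsensusResult = per_k[chosen]["consensus"]
        extracted = _consensus_signature_matrix(res)
        match = match_to_truth(extracted, truth, threshold=match_threshold)
        records.append(
            {
                "chosen_k": chosen,
                "stable_selection": stable,
                "success": match.success,
                "match": match,
                "mse": per_k[chosen]["mse"],
                "c_mean": res.c_mean,
                "c_min": res.c_min,
            }
        )
    f = success_frequency(r["success"] for r in records)
    mse_med, mse_iqr = _median_iqr([r["mse"] for r in records])
    c_mean_med, _ = _median_iqr([r["c_mean"] for r in records])
    c_min_med, _ = _median_iqr([r["c_min"] for r in records])
    return ExtractionEvaluation(f, mse_med, mse_iqr, c_mean_med, c_min_med, records)


class SignatureExtractor(BaseEstimator):
    """De novo mutational-signature extractor (repeated KL-NMF consensus).

    Scikit-learn style estimator. ``fit`` expects a catalogue oriented
    samples x 96 (one row per sample, one column per mutation context,
    nonnegative integer counts) and performs rank selection over
    ``k_range`` unless a fixed ``n_signatures`` is given.

    Parameters
    ----------
    n_signatures : int or None
        Fixed number of signatures to extract; if None, the rank is chosen
        from ``k_range`` by the stability/error rule.
    k_range : sequence of int
        Candidate ranks scanned when ``n_signatures`` is None.
    n_runs : int
        NMF repetitions per rank (default 30).
    resample : bool
        Poisson-bootstrap the catalogue before each repetition.
    loss : {"kullback-leibler", "frobenius"}
        NMF objective.
    stability_threshold, improvement_tol : float
        Rank-selection rule parameters: minimum acceptable ``C_min`` and the
        relative reconstruction-error improvement required over the previous
        rank.
    random_state : int or None
        Seed for all NMF initialisations and bootstraps.

    Attributes
    ----------
    rank_ : int
        Chosen number of signatures.
    signatures_ : ndarray of shape (rank_, 96)
        Consensus signature profiles (rows summing to 1).
    exposures_ : ndarray of shape (n_samples, rank_)
        NNLS-refit exposures of the training catalogue.
    stability_ : dict
        ``C_mean`` and ``C_min`` of the chosen rank.
    diagnostics_ : dict
        Per-rank consensus results, stability scores and reconstruction MSE.
    selection_stable_ : bool
        False when no rank met the selection rule and the best compromise
        was returned.
    """

    def __init__(
        self,
        n_signatures=None,
        k_range=(2, 3, 4, 5, 6, 7, 8),
        n_runs=30,
        resample=True,
        loss="kullback-leibler",
        stability_threshold=0.7,
        improvement_tol=0.01,
        max_iter=1000,
        tol=1e-6,
        random_state=None,
    ):
        self.n_signatures = n_signatures
        self.k_range = k_range
        self.n_runs = n_runs
        self.resample = resample
        self.loss = loss
        self.stability_threshold = stability_threshold
        self.improvement_tol = improvement_tol
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _validate(self, X) -> MutationalCatalogue:
        if isinstance(X, MutationalCatalogue):
            return X
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != N_CONTEXTS:
            raise ValueError(
                f"expected a (n_samples, {N_CONTEXTS}) catalogue; got {X.shape}"
            )
        return MutationalCatalogue(
            [f"S{i + 1}" for i in range(X.shape[0])], X.T
        )

    def fit(self, X, y=None):
        """Extract consensus signatures from a samples x 96 count matrix."""
        cat = self._validate(X)
        rng = np.random.default_rng(self.random_state)
        ks = [self.n_signatures] if self.n_signatures is not None else list(self.k_range)
        chosen, per_k, stable = select_rank(
            cat,
            ks,
            rng,
            n_runs=self.n_runs,
            resample=self.resample,
            stability_threshold=self.stability_threshold,
            improvement_tol=self.improvement_tol,
            loss=self.loss,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        res: ConsensusResult = per_k[chosen]["consensus"]
        self.rank_ = chosen
        self.signatures_ = res.consensus_signatures
        self.consensus_ = res
        self.diagnostics_ = {
            k: {kk: v[kk] for kk in ("mse", "c_mean", "c_min")}
            for k, v in per_k.items()
        }
        self.selection_stable_ = stable
        self.stability_ = {"c_mean": res.c_mean, "c_min": res.c_min}
        refit = refit_exposures(cat, self.signature_matrix_)
        self.exposures_ = refit.exposures.T
        self.reconstruction_mse_ = catalogue_mse(cat.counts, refit.reconstruction)
        return self

    @property
    def signature_matrix_(self) -> SignatureMatrix:
        return _consensus_signature_matrix(self.consensus_)

    def transform(self, X):
        """NNLS exposures (n_samples x rank_) of a catalogue against the
        fitted consensus signatures."""
        cat = self._validate(X)
        return refit_exposures(cat, self.signature_matrix_).exposures.T

    def fit_transform(self, X, y=None):
        return self.fit(X).exposures_
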