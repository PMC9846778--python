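"""Simulation of mutational catalogues and synthetic signature sets.

Catalogue simulation follows the SigsPack ``create_mut_catalogues``
procedure: per sample, one exposure weight per active signature is drawn
from Uniform(0, 1) and L1-normalised, the mixture profile is the
exposure-weighted combination of the signature profiles, and a fixed number
of mutations (default 5,000 per sample, the PCAWG median) is drawn from one
multinomial over the 96 contexts. Ten replicate catalogues per scenario
capture the statistical fluctuation of the draw.

``generate_synthetic_signatures`` provides a download-free stand-in for
reference signature sets: sparse random profiles mixed towards the uniform
profile, with the mixing weight tuned by bisection to hit a target flatness
and optional pairwise-similarity constraints enforced by bounded retries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalogue_io import MutationalCatalogue, SignatureMatrix
from .contexts import N_CONTEXTS
from .profile_metrics import flatness, pairwise_similarity, similarity_groups

__all__ = [
    "ScenarioConfig",
    "SimulatedCatalogue",
    "SCENARIO_PRESETS",
    "sample_exposures",
    "simulate_catalogue",
    "generate_scenario",
    "generate_synthetic_signatures",
    "resolve_scenario_signatures",
    "replicate_rng",
]


@dataclass
class ScenarioConfig:
    """Parameters of one simulated extraction scenario."""

    signature_names: list[str] | None = None
    n_samples: int = 200
    mutations_per_sample: int = 5000
    n_replicates: int = 10
    seed: int = 0
    exposure_distribution: str = "uniform_normalised"  # or "dirichlet"

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.mutations_per_sample < 1 or self.n_replicates < 1:
            raise ValueError("sample, mutation and replicate counts must be positive")
        if self.exposure_distribution not in ("uniform_normalised", "dirichlet"):
            raise ValueError(
                f"unknown exposure distribution: {self.exposure_distribution!r}"
            )


@dataclass
class SimulatedCatalogue:
    """A simulated catalogue with its generating signatures and exposures."""

    catalogue: MutationalCatalogue
    true_signatures: SignatureMatrix
    true_exposures: np.ndarray  # signatures x samples, columns on the simplex

    def __post_init__(self) -> None:
        self.true_exposures = np.asarray(self.true_exposures, dtype=float)
        k, n = self.true_exposures.shape
        if k != self.true_signatures.n_signatures or n != self.catalogue.n_samples:
            raise ValueError("exposure matrix shape mismatch")
        if np.any(self.true_exposures < 0) or not np.allclose(
            self.true_exposures.sum(axis=0), 1.0, atol=1e-9
        ):
            raise ValueError("exposure columns must lie on the simplex")


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator derived from (seed, replicate)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def sample_exposures(
    k: int, n: int, rng: np.random.Generator, distribution: str = "uniform_normalised"
) -> np.ndarray:
    """Draw a k x n exposure matrix with each column on the simplex.

    The default draws k independent Uniform(0,1) weights per sample and
    L1-normalises them (the SigsPack construction); ``"dirichlet"`` draws
    from the flat Dirichlet instead.
    """
    if k < 1 or n < 1:
        raise ValueError("k and n must be positive")
    if distribution == "uniform_normalised":
        raw = rng.uniform(size=(k, n))
        return raw / raw.sum(axis=0, keepdims=True)
    if distribution == "dirichlet":
        return rng.dirichlet(np.ones(k), size=n).T
    raise ValueError(f"unknown exposure distribution: {distribution!r}")


def simulate_catalogue(
    sig: SignatureMatrix,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedCatalogue:
    """Simulate one catalogue of ``cfg.n_samples`` samples from *sig*.

    Every sample receives exactly ``cfg.mutations_per_sample`` mutations,
    drawn from one multinomial over the mixture profile
    ``sum_k exposure_k * signature_k``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    active = sig if cfg.signature_names is None else sig.select(cfg.signature_names)
    exposures = sample_exposures(
        active.n_signatures, cfg.n_samples, rng, cfg.exposure_distribution
    )
    mixtures = active.values.T @ exposures  # 96 x n
    col_sums = mixtures.sum(axis=0)
    if np.any(col_sums <= 0):
        raise ValueError("degenerate all-zero mixture profile")
    mixtures = mixtures / col_sums
    counts = np.empty((N_CONTEXTS, cfg.n_samples), dtype=np.int64)
    for j in range(cfg.n_samples):
        counts[:, j] = rng.multinomial(cfg.mutations_per_sample, mixtures[:, j])
    catalogue = MutationalCatalogue(
        [f"S{j + 1}" for j in range(cfg.n_samples)], counts
    )
    return SimulatedCatalogue(catalogue, active, exposures)


def generate_scenario(
    sig: SignatureMatrix, cfg: ScenarioConfig
) -> list[SimulatedCatalogue]:
    """Simulate ``cfg.n_replicates`` independent catalogues.

    Replicate ``r`` uses a generator derived from ``(cfg.seed, r)``, so the
    whole scenario is bit-reproducible under a fixed seed while replicates
    stay mutually independent.
    """
    return [
        simulate_catalogue(sig, cfg, rng=replicate_rng(cfg.seed, r))
        for r in range(cfg.n_replicates)
    ]


_MIN_FLATNESS = 1.0 / np.sqrt(N_CONTEXTS)


def _sparse_profile(rng: np.random.Generator, support: np.ndarray) -> np.ndarray:
    base = np.zeros(N_CONTEXTS)
    base[support] = rng.uniform(0.2, 1.0, size=support.size)
    return base / base.sum()


def _mix_to_flatness(base: np.ndarray, target: float, tol: float = 1e-4) -> np.ndarray:
    """Bisection on the uniform-mixing weight w so that
    flatness((1-w) base + w uniform) hits *target*."""
    uniform = np.full(N_CONTEXTS, 1.0 / N_CONTEXTS)
    lo, hi = 0.0, 1.0
    for _ in range(200):
        w = 0.5 * (lo + hi)
        f = flatness((1 - w) * base + w * uniform)
        if abs(f - target) < tol:
            break
        if f < target:
            lo = w
        else:
            hi = w
    return (1 - w) * base + w * uniform


def generate_synthetic_signatures(
    k: int,
    target_flatness: float | list[float] = 0.3,
    rng: np.random.Generator | None = None,
    max_pairwise_sim: float | None = None,
    min_pairwise_sim: float | None = None,
    n_active_contexts: int = 6,
    max_retries: int = 50,
) -> SignatureMatrix:
    """Generate *k* synthetic SBS-96 profiles with controlled shape.

    Each profile is a sparse random profile (``n_active_contexts`` nonzero
    contexts) mixed with the uniform profile, the mixing weight tuned by
    bisection so the achieved flatness is within +-0.02 of its target.
    Pairwise-similarity bounds are enforced by regenerating the sparse
    supports up to *max_retries* times; low ``max_pairwise_sim`` is aided by
    drawing disjoint supports where the 96 contexts allow it.
    """
    if rng is None:
        rng = np.random.default_rng()
    targets = np.broadcast_to(np.asarray(target_flatness, dtype=float), (k,))
    if np.any(targets < _MIN_FLATNESS - 1e-9) or np.any(targets > 1.0 + 1e-9):
        raise ValueError(
            f"target flatness must lie in [{_MIN_FLATNESS:.4f}, 1]"
        )
    # the bisection can only move flatness upward from the sparse base, so
    # the support must be small enough that the base sits below the target:
    # n equal-weight active contexts give flatness ~ sqrt(n / 96)
    n_active = [
        max(1, min(n_active_contexts, int(N_CONTEXTS * t**2 * 0.8))) for t in targets
    ]
    best: tuple[float, np.ndarray] | None = None
    for _ in range(max_retries):
        if min_pairwise_sim is not None:
            # overlapping supports: share an anchor half so the sparse parts
            # of different profiles correlate
            anchor_n = max(1, min(n_active) // 2 + 1)
            anchor = rng.choice(N_CONTEXTS, size=anchor_n, replace=False)
            rest = np.setdiff1d(np.arange(N_CONTEXTS), anchor)
            supports = [
                np.concatenate(
                    [anchor[: min(anchor_n, n)],
                     rng.choice(rest, size=max(0, n - anchor_n), replace=False)]
                )
                for n in n_active
            ]
        elif sum(n_active) <= N_CONTEXTS:
            perm = rng.permutation(N_CONTEXTS)
            supports, start = [], 0
            for n in n_active:
                supports.append(perm[start : start + n])
                start += n
        else:
            supports = [
                rng.choice(N_CONTEXTS, size=n, replace=False) for n in n_active
            ]
        rows = np.stack(
            [
                _mix_to_flatness(_sparse_profile(rng, sup), t)
                for sup, t in zip(supports, targets)
            ]
        )
        sig = SignatureMatrix.from_profiles([f"SYN{i + 1}" for i in range(k)], rows)
        achieved = np.array([flatness(r) for r in sig.values])
        if np.any(np.abs(achieved - targets) > 0.02):
            continue
        if k == 1:
            return sig
        tri = pairwise_similarity(sig).upper_triangle()
        violation = 0.0
        if max_pairwise_sim is not None:
            violation = max(violation, float(tri.max() - max_pairwise_sim))
        if min_pairwise_sim is not None:
            violation = max(violation, float(min_pairwise_sim - tri.min()))
        if violation <= 0.0:
            return sig
        if best is None or violation < best[0]:
            best = (violation, tri)
    detail = "" if best is None else (
        f"; best attempt violated the similarity bound by {best[0]:.3f}"
        f" (pairwise range [{best[1].min():.3f}, {best[1].max():.3f}])"
    )
    raise ValueError(
        f"could not satisfy flatness/similarity constraints in {max_retries} tries{detail}"
    )


@dataclass
class ScenarioPreset:
    """One of the five catalogue-simulation scenarios.

    Named presets reference COSMIC signature identifiers and therefore need a
    user-supplied COSMIC signature file; rule-based presets select signatures
    from the supplied matrix by flatness and similarity-cluster structure.
    The scenario-1 member list is reconstructed from COSMIC annotations and
    the flat-cluster description, not taken verbatim from a published list.
    """

    n_signatures: int
    sample_sizes: tuple[int, ...]
    signature_names: tuple[str, ...] | None = None
    rule: str | None = None  # "low_flatness_similar_pairs"
    notes: str = ""


SCENARIO_PRESETS: dict[int, ScenarioPreset] = {
    1: ScenarioPreset(
        6,
        (200, 500),
        signature_names=("SBS3", "SBS5", "SBS25", "SBS40", "SBS89", "SBS92"),
        notes="flat six-signature cluster; membership reconstructed, not verbatim",
    ),
    2: ScenarioPreset(
        5,
        (200, 500),
        signature_names=("SBS10a", "SBS10c", "SBS10d", "SBS18", "SBS36"),
        notes="high-similarity low-flatness polymerase/ROS cluster",
    ),
    3: ScenarioPreset(
        11,
        (200, 500, 1000, 3000, 5000, 10000),
        signature_names=(
            "SBS3",
            "SBS5",
            "SBS25",
            "SBS40",
            "SBS89",
            "SBS92",
            "SBS10a",
            "SBS10c",
            "SBS10d",
            "SBS18",
            "SBS36",
        ),
        notes="scenarios 1 and 2 combined",
    ),
    4: ScenarioPreset(
        11,
        (200, 500, 1000, 3000, 5000),
        rule="low_flatness_similar_pairs",
        notes="11 low-flatness signatures, each with a >0.8-similarity partner",
    ),
    5: ScenarioPreset(
        20,
        (1000, 3000, 5000, 10000),
        rule="low_flatness_similar_pairs",
        notes="20 low-flatness signatures, each with a >0.8-similarity partner",
    ),
}


def resolve_scenario_signatures(
    preset: ScenarioPreset, sig: SignatureMatrix, similarity_cut: float = 0.8
) -> list[str]:
    """Resolve a preset to concrete signature names against matrix *sig*.

    Named presets validate that every referenced signature is present (a
    clear error tells the user to supply the reference file). Rule-based
    presets take the ``n_signatures`` lowest-flatness signatures among those
    belonging to a multi-member group at similarity > *similarity_cut*.
    """
    if preset.signature_names is not None:
        missing = [n for n in preset.signature_names if n not in sig.names]
        if missing:
            raise KeyError(
                f"scenario references signatures absent from the supplied matrix: "
                f"{missing}; provide the COSMIC signature file"
            )
        return list(preset.signature_names)
    if preset.rule != "low_flatness_similar_pairs":
        raise ValueError(f"unknown scenario rule: {preset.rule!r}")
    groups = similarity_groups(sig, similarity_cut)
    grouped = [n for g in groups if len(g) > 1 for n in g]
    if len(grouped) < preset.n_signatures:
        raise ValueError(
            f"matrix has only {len(grouped)} signatures with a "
            f">{similarity_cut} similarity partner; {preset.n_signatures} needed"
        )
    flat = {n: flatness(sig.values[sig.names.index(n)]) for n in grouped}
    return sorted(grouped, key=lambda n: (flat[n], n))[: preset.n_signatures]
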