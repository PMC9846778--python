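# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `sigarch`, in the spirit of the methods documentation of
packages like statsmodels or scanpy. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Signatures are stored *signatures × 96* with each row a probability profile
over the canonical SBS-96 context order (substitution class, then 5'
flank, then 3' flank, alphabetically — the COSMIC file order, defined once
in `sigarch.contexts`). Catalogues are stored *96 × samples* with integer
counts. Profiles are renormalised on read rather than rejected, because
published signature files vary between probabilities and percentages.
Orientation converters are explicit (`to_frame`, constructor arguments);
nothing transposes silently.

The default artefact-exclusion list (SBS27, SBS43, SBS45–SBS60, SBS95) is
reconstructed from the public COSMIC v3.3 "possible sequencing artefact"
annotations. It is a package default, always overridable; users working
with other catalogue versions should pass their own list.

## Similarity, flatness, cluster maps

Cosine similarity is the only profile metric used; distances are
`1 − similarity`. Flatness is the cosine of a profile against the uniform
96-vector: a closed-form minimum of `1/√96 ≈ 0.102` for a one-hot profile,
1 for a perfectly flat one, and invariant to positive rescaling. Cluster
maps use average-linkage agglomerative clustering (scipy) on the cosine
distance matrix. Scenario summaries take the median over the strict upper
triangle of the similarity matrix (each unordered pair once) — a
convention this package fixes explicitly because "median pairwise
similarity" is ambiguous otherwise; ties in the most-similar pair are
broken by lexicographic name order. Signature grouping for scenario
construction cuts the tree at cosine similarity 0.8 by default (exposed as
a parameter), the threshold conventionally used to call two signatures
"similar".

## Catalogue simulation

The generator emulates the SigsPack `create_mut_catalogues` procedure:

- **Exposures**: per sample, one Uniform(0,1) draw per active signature,
  L1-normalised. This is *not* the flat Dirichlet (the normalised-uniform
  construction concentrates less mass at the corners); Dirichlet(1,…,1) is
  available via `exposure_distribution="dirichlet"` for users who prefer
  the exchangeable-simplex model.
- **Counts**: one multinomial draw per sample from the exposure-weighted
  mixture profile, with a fixed total of 5,000 mutations per sample by
  default (the order of the PCAWG median per-sample burden). Drawing one
  multinomial is distributionally identical to sampling each mutation's
  context independently.
- **Replicates**: 10 per scenario by default, to average over sampling
  fluctuations. Replicate `r` uses a generator seeded from the pair
  `(seed, r)` via `numpy` `SeedSequence`, so scenarios are bit-reproducible
  while replicates remain mutually independent.

What this emulates — and what it does not: simulated samples share a
homogeneous exposure law and an exact per-sample mutation total. Real
cohorts have heavy-tailed burdens, cancer-type-specific exposure patterns,
and sequencing noise beyond multinomial sampling. Passing tests on these
catalogues therefore demonstrates correctness of the extraction machinery
under controlled conditions, not performance on realistic tumour cohorts.

Synthetic signature sets (`generate_synthetic_signatures`) mix a sparse
random profile with the uniform profile, tuning the mixing weight by
bisection until the achieved flatness is within ±0.02 of target. The
sparse support size adapts to the target (a support of `n` roughly equal
peaks has flatness `√(n/96)`, which lower-bounds what bisection can
reach). Pairwise-similarity bounds are enforced by bounded retries:
disjoint supports for upper bounds, partially shared ("anchor") supports
for lower bounds; infeasible combinations raise an error reporting the
best achieved values.

Scenario presets 1–5 mirror the published simulation grid (6/5/11/11/20
signatures; 200–10,000 samples). Presets 1–3 reference concrete COSMIC
signature names and therefore require a user-supplied COSMIC file; the
scenario-1 membership (SBS3, SBS5, SBS25, SBS40, SBS89, SBS92) is
reconstructed from the flat-cluster description and flatness annotations,
not copied from a published list, and is config-driven so users can
substitute the exact membership. Presets 4–5 are defined by rule (the
lowest-flatness signatures among those with a >0.8-similarity partner),
matching how those scenarios are described.

## De novo extraction

**NMF.** Multiplicative updates under generalised Kullback–Leibler loss,
the Poisson-likelihood objective appropriate for count data and the one
used by the SigProfiler lineage; Frobenius is available as an option. The
updates make the objective provably non-increasing, which the
implementation records per iteration and the tests assert. Initialisation
is uniform-random scaled to the data mean; convergence is a relative
objective change below `tol` (default 1e−6) within `max_iter` (default
1,000); non-convergence returns the factors with a warning rather than
failing. Implementing the updates in-package (rather than calling
scikit-learn) buys three contract properties the tests rely on:
per-iteration objective traces, bit-determinism under an injected
generator, and in-loop Poisson bootstrapping; scikit-learn's KL-NMF serves
as an independent cross-check in the test suite.

**Poisson bootstrap.** Each NMF repetition may first replace every count
by a Poisson draw with that mean (on by default, as in
SigProfiler-style extractors; off for deterministic tests). This probes
the stability of the factorisation under count noise.

**Consensus partitioning.** Run signatures are clustered under the
constraint that each cluster contains exactly one signature per run:
centroids start from the first run, each run's signatures are assigned to
centroids by minimum-cost bipartite matching (Hungarian algorithm, cosine
distance), centroids are recomputed as normalised cluster means, and the
loop repeats until assignments stabilise (oscillation past `max_iter`
keeps the last assignment with a warning). Consensus signatures are the
final centroids.

**Stability.** Silhouettes use cosine distance, `(b − a)/max(a, b)`, with
singleton clusters and exactly coincident points scoring 0 by convention.
With a single cluster (rank 1) no alternative cluster exists and stability
is reported as 1. Because every cluster has the same size (one member per
run), the mean over all run-signatures equals the mean of per-cluster
means, so `C_mean` is unambiguous.

**Rank selection.** The rule is a transparent surrogate for the black-box
heuristics of production extractors: keep the largest rank whose `C_min`
is at least 0.7 *and* whose reconstruction error improves on the previous
rank by more than 1% relative. If nothing qualifies, the rank with the
best `C_min` is returned flagged unstable. All per-rank diagnostics
(consensus, stability, MSE) are exposed so users can apply their own rule.

**Success criterion.** "All signatures correctly identified" is
formalised as: the extracted count equals the true count, and the optimal
one-to-one assignment (maximum total cosine) matches every true signature
at cosine ≥ 0.8. The 0.8 threshold follows the field's similarity
convention and is a parameter.

**Reconstruction MSE.** `X̂` is built from consensus signatures and NNLS
refit exposures on the raw count catalogue, with denominator `n·m`
(contexts × samples). Raw counts, not normalised profiles, are used —
consistent with MSE magnitudes in the tens for 5,000-mutation samples.

**Refitting.** Exposures are per-sample nonnegative least squares
(`scipy.optimize.nnls`); quality is reported as mean per-sample cosine and
mean absolute error on counts. On noiseless full-rank inputs NNLS recovers
exposures exactly (tested to 1e−6).

## Archetypal analysis

The principal-convex-hull problem is solved by alternating blockwise
projected-gradient descent: with archetypes fixed, each `α` row is an
independent simplex-constrained least-squares problem; with `α` fixed, `β`
is updated on the full objective `‖X − αβX‖²` (its rows are coupled
through `α`, so the block is treated jointly). Both blocks use exact
Euclidean projection onto the simplex (the sorting algorithm of Held et
al./Duchi et al.) and a `1/L` step with `L` the spectral-norm Lipschitz
constant of the block gradient, which guarantees exact feasibility after
every step and a monotonically non-increasing SSE — the two contract
properties asserted in the tests; the identity `Z = βX` holds exactly by
construction. Initialisation is furthest-sum candidate selection with
one-hot `β` rows and nearest-archetype one-hot `α` rows; 5 restarts by
default, best SSE kept. Convergence is a relative SSE change below `tol`
(default 1e−7), with an absolute floor of `1e−12·‖X‖²` so exact fits
(e.g. `r = p`) terminate. `r > p` is allowed and simply duplicates
candidates.

Explained variance is `1 − SSE/TSS`. TSS defaults to the total squared
deviation from the mean row ("centered", the R `archetypes`-style
convention); the alternative about zero is available via
`variance_of="uncentered"` because published analyses rarely state which
convention they used — on probability-normalised signature matrices the
centered convention is the more conservative (smaller TSS, lower EV) and
is what the 95% selection rule applies to here. Archetypes are row
vectors of `Z` throughout.

The α-coefficient grouping clusters signatures on their *full* α rows
(cosine distance, average linkage, tree cut at distance 0.5) and reports
each group's dominant archetype; the display table masks coefficients
below 0.2 purely for legibility, never for clustering. The
similarity-consistency check pairs every signature-pair profile cosine
with the corresponding α-row cosine and summarises with Spearman rank
correlation.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
reduced scale, chosen so the full analysis remains a desk-scale
computation: extraction checks use 2–4 latent signatures, 50–500 samples,
4–6 NMF repetitions and ranks up to 6; the archetype recovery experiment
compresses 20 synthetic signatures built from 6 latent extremes, scanning
r = 2…12 with 3 restarts; distributional checks use up to 10,000 samples
where the law of large numbers is the point. Reproducing published-scale
analyses (60 reference signatures, ranks to 25, 30 NMF repetitions,
archetype scans to r = 40) uses the same code paths with larger
parameters and a user-supplied COSMIC file.

## Known limitations

- The extractor is a transparent simplification, not a clone of production
  tools: no NNDSVD initialisation variants, no GPU path, no hierarchical
  re-extraction or COSMIC decomposition step. Published performance tables
  from such tools are comparable only in a loose, stochastic sense.
- Uniform-exposure simulation does not model realistic per-cancer-type
  exposure structure; conclusions transfer to the machinery, not to
  specific tumour cohorts.
- Archetypal analysis is non-convex; the furthest-sum + restarts strategy
  finds good local optima (grid-search-verified on tiny instances) but
  global optimality is not guaranteed at scale.
- Flatness compares only against the uniform profile; it does not
  distinguish different kinds of near-flat structure.
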