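# Methods

## The distance and its metric structure

All searching and clustering in this package runs on the optimal-superposition
RMSD: for two structures with matched atoms `i` and `j`,

    RMSD_opt(i, j) = min over proper rigid motions (R, T) of
                     sqrt( Σ_k ‖ r_ik − (R r_jk + T) ‖² / N )

The minimizing translation aligns centroids; the minimizing rotation is found
by Kabsch's SVD construction with the determinant sign corrected so that
det(R) = +1 — mirror images are never considered superposable.  The RMSD is
evaluated from the actual rotated residuals rather than from the
singular-value trace identity `(G_i + G_j − 2·tr)/N`: the trace form loses
roughly half the significant digits to cancellation for near-identical
structures, and tight-threshold searches live exactly in that regime (the
residual form keeps identical pairs at ~1e-15 Å instead of ~1e-8 Å).

`RMSD_opt` is a metric on rototranslation-equivalence classes of structures,
so the inverse triangle inequality holds:

    RMSD_opt(i, j) ≥ | RMSD_opt(r, i) − RMSD_opt(r, j) |

for any reference structure `r`.  This is the engine of the whole package: one
reference pass of N−1 RMSDs certifies every pair whose reference-distance gap
exceeds the search threshold as "no hit" at zero further cost.

## The pruned pair search

`search_pairs(ensemble, t)` returns exactly `{(i, j), i<j : RMSD_opt ≤ t}`.
The algorithm repeats until every structure is resolved:

1. **Reference pass.** The lowest-index unresolved structure becomes the
   reference; its RMSD to every other unresolved structure is computed
   (batched 3×3 SVDs over the pre-centered coordinate stack).
2. **Pruning walk.** The reference RMSD list is sorted ascending (stable, so
   ties keep input order).  Walking the sorted list, structure `j` is
   *retired* — declared fully resolved — after direct comparison against only
   those structures `k` above it with `d_k − d_j ≤ t + slack`; the inverse
   triangle inequality certifies every other pair.
3. **Adaptive stop.** The walk continues while the ratio
   (structures retired)/(comparisons spent this iteration) still improves;
   structures deep in the populated region of the distance distribution gain
   little from the bound, so at the first non-improving step the iteration
   ends and a fresh reference pass begins.  The first walk step always runs.

The output is exact, not approximate: the bound only ever *excludes* pairs it
proves are above threshold, and every reported hit carries a directly computed
RMSD.  Memory stays O(N) — only the current reference's RMSD list is held,
never a pairwise matrix.  The comparison count (but not the hit set) depends
on the input ordering of structures, since the reference at each iteration is
the lowest-index survivor; `SearchStats.per_iteration` records, for each
iteration, the reference, comparisons spent, structures retired and the
effective stop value `s` (the reference RMSD of the last retired structure).

Numerical choices: threshold comparison is inclusive (`rmsd ≤ t`); the
exclusion window uses `t + slack` with `slack = 1e-6 Å` by default, guarding
against floating-point loss of the mathematically exact bound at the boundary;
hits are canonicalized `i < j` and emitted sorted regardless of discovery
order.

The comparison count is *not* guaranteed monotone in `t`: a larger threshold
widens each retired structure's comparison window but also changes where the
adaptive stop triggers, and the two effects can trade against each other.  On
the broad single-scale ensembles used here the trend is monotone; on
heterogeneous real decoy sets occasional inversions between neighbouring
thresholds are expected behaviour of the stop rule, not an error.

## The iteration cost model

For one iteration at ensemble size N, threshold t and stop value s, with f(x)
the probability density the reference RMSD list is drawn from,

    N_cmp  = (N−1) + (N−1)(N−2) ∫₀ˢ f(x) [ ∫ₓ^{x+t} f(x′) dx′ ] dx
    N_done = 1 + (N−1) ∫₀ˢ f(x) dx

`predicted_cost` evaluates both by trapezoidal quadrature on a histogram
estimate of f (piecewise-constant density, 4000-point grid; a histogram whose
densities do not integrate to 1 within 1e-6 is rejected).  Two analytic
consequences worth noting:

* at `s = 0` the model collapses to `(N−1, 1)` — a bare reference pass;
* as `t` grows past the support width the inner integral saturates to
  `1 − F(x)`, so the nested term tends to ∫f(1−F) = 1/2, i.e. a full sweep
  counts each unordered pair once — not to 1.

**Which f to feed back.**  The model describes a *single* reference's
iteration, and different references see very different left tails: a structure
near the ensemble's conformational center has many more close neighbours than
the population average, so the ensemble-wide pairwise histogram can misstate
one reference's tail integrals several-fold.  The consistency check therefore
feeds back the empirical histogram of the first reference pass itself (its
N−1 RMSDs are a sample of the ensemble pairwise distribution); with that f the
quadrature tracks the observed discrete walk to a few percent at N = 2000
across unimodal and multi-basin ensembles and thresholds 0.2–1.0 Å.

## Weighted greedy clustering

Given the complete hit list at threshold t, every item receives a proximity
weight

    w_i = Σ_{j : RMSD_ij ≤ t}  w_j⁰ · cos( π · RMSD_ij / (2t) )

including the self term j = i (cos 0 · w_i⁰), so an isolated item keeps its
prior weight.  Priors w⁰ are 1 at the first level.  Clustering is greedy
leader selection: the unassigned item of largest weight (ties: lower index,
for determinism) becomes a representative and absorbs every unassigned item
within t of it; the result is a partition in which members sit within the
level threshold of their representative and representative weights are
non-increasing across clusters.

`cluster_iterative` repeats this at increasing thresholds (default: doubling
from 0.05 Å, stopping when a single cluster remains), re-running the pruned
search on survivors only.  A representative carries to the next level the
**sum of its cluster's prior weights**.  "Accumulated cluster weight" admits
two readings — the representative's own computed w, or the summed prior mass
of its members — and the summed-prior reading is used here because it
conserves total weight (Σ priors = original N at every level, a directly
testable invariant) and leaves a singleton's prior unchanged, which is the
behaviour multi-level weighting needs.

## Length-normalized redundancy filtering

Models of different residue content are compared on the residues common to
both (matched by chain and residue identifier, using the atoms of the chosen
selection present in both), and the resulting RMSD is normalized to the value
expected for a 100-residue alignment:

    RMSD100 = RMSD / (1 + 0.5 · ln(N/100))        (natural log)

The denominator crosses zero near N ≈ 13.5, so pairs with fewer than 14
common residues are assigned a cap distance (999.9 Å by default,
configurable) — maximally dissimilar, never causing a removal.

`filter_redundant` scans models in input order and removes a model whenever
its normalized distance to an *earlier kept* model is strictly below the
threshold (default 1.0 Å); ties at exactly the threshold keep both.  Because
the common-residue set varies pair by pair, RMSD100 is not guaranteed to be a
strict metric; the pruned search is therefore used only as a candidate
generator — the bound can only exclude pairs, and every removal rests on a
directly computed distance (prune-then-confirm).  In adversarial geometries a
bound-excluded pair could in principle violate the inequality, which would
make the filter keep a model it might have removed — never remove one it
should have kept.

## The synthetic-ensemble generator

`make_ensemble` emulates the shared geometry of decoy sets, MD snapshot
collections and fragment libraries: k center conformations are built from one
base CA trace (ideal α-helix parameters 2.3 Å radius / 1.5 Å rise / 100° per
residue; a 3.8 Å-step extended zigzag; or a 3.8 Å-step random walk) plus
center-specific Gaussian deformations scaled so two centers sit at roughly the
requested `separation` RMSD (per-coordinate std = separation/√6).  Each of
the n structures is a center plus per-atom Gaussian noise of std `sigma`
(members of one center then differ by ≈ sigma·√6 raw RMSD), followed by an
independent random rigid rototranslation so that optimal superposition is
always exercised.  A single seeded `numpy` Generator drives everything;
identical specs reproduce identical coordinates.

What it does **not** emulate: real protein stereochemistry (no side chains,
no excluded volume; large center deformations do not preserve chain-like
CA–CA spacing, so fragment-extraction experiments use independently grown
chains instead of far-separated centers), and the breadth of real decoy RMSD
distributions — isotropic Gaussian conformational noise concentrates the
pairwise RMSD distribution (relative spread ~1/√(6·n_atoms)), so synthetic
f(x) is narrower than the near-normal distributions seen in real decoy sets.
Passing tests therefore demonstrate exactness, accounting and trend behaviour
of the algorithms, not the absolute speed-up figures attainable on any
particular real dataset, where the threshold-to-spread ratio differs.

Study conditions used by the test suite and `scripts/acceptance.py` are
scaled-down analogues of the published experiment types, chosen once:
a 665-member decoy-like set searched at four thresholds; a 2000-member and a
4000-member five-basin ensemble (36 residues, 6 Å basin separation, 1 Å
within-basin noise) searched at 1.0 Å for the MD-snapshot and size-trend
experiments; 1680 five-residue fragments from thirty 60-residue random-walk
chains clustered at thresholds doubling from 0.05 Å; and a 150-model
filtering pool of 110 diverse conformations plus 40 injected near-duplicates
(0.05 Å perturbations) screened at RMSD100 < 1.0 Å.

## Known limitations

* Comparison counts are deterministic for a fixed input order but change
  under reordering; only the hit set is order-invariant.
* No RMSD cache is kept across iterations by design (O(N) memory); schemes
  remembering all computed RMSDs would prune slightly more at O(N²) memory.
* The search is efficient only when the threshold is well below the typical
  pairwise distance; as t approaches the distribution's bulk the ratio tends
  to 1 and the method degrades gracefully to all-vs-all.
* Fragment extraction treats residues with insertion codes as breaking
  contiguity (windows require consecutive integer numbering and CA–CA ≤
  4.5 Å by default); exact fragment counts on real data depend on this
  break policy.
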