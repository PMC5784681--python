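# Methods

## Model representation

A protein is a two-bead chain: one Cα per residue plus a virtual Cβ at
`cb_dist` = 1.53 Å from its Cα along a direction derived from the local
backbone frame (the bisector of the two adjacent virtual bonds tilted
toward the local normal, roughly tetrahedral). Glycine has no Cβ; its
Cβ row equals its Cα row so every Cβ–Cβ contact distance stays
evaluable, and contact restraints involving glycine are attached to Cα
explicitly. Chain ends copy their neighbour's frame; collinear frames
fall back to a deterministic perpendicular.

The Cβ is deliberately *not* a free particle inside the folding engine:
it is re-derived from the backbone after every move. Distance-only
restraints are blind to handedness — a mirror-image fold satisfies
every Cα distance exactly — but the frame construction is chiral, so a
mirrored backbone presents different Cβ–Cβ distances to the contact
energy. On the bundle fixture the mirror fold scores a contact energy
an order of magnitude worse than the native (55 vs 4.7), which is what
lets a purely distance-restrained optimizer avoid the classic mirror
degeneracy of contact-map reconstruction. With freely optimizable Cβ
offsets the two scores are identical and roughly half of all folds come
out mirror-handed.

## Energy

Total energy is `E_contact + E_ss + E_bond + E_clash`:

- `E_contact`, `E_ss`: soft-square restraints (below) on Cβ–Cβ (contacts)
  and Cα–Cα (secondary structure) distances.
- `E_bond = Σ k_b (|Cα_i − Cα_{i+1}| − b₀)²`, k_b = 10, b₀ = 3.8 Å.
- `E_clash = Σ k_c max(0, d_c − |Cα_i − Cα_j|)²` over |i − j| ≥ 2,
  k_c = 10, d_c = 4.0 Å.

The soft-square restraint has a flat well `[d − d₋, d + d₊]` (zero
energy and gradient), a square-error region above it, and a taper to the
bounded constant `a·min(ceil, w)` beyond `d + d₊ + r_sw`. The smoothing
constants solve value and slope continuity at Δ = r_sw:

    b = −(exp/softexp) · r_sw^(exp+softexp)
    a = (1 + exp/softexp) · r_sw^exp

Contact defaults: d = 3.6, d₋ = 0.1, d₊ = 4.4, r_sw = 1.8 (all Å),
exp = softexp = 2, ceil = 1000, w = 1, giving a zero-error well of
3.5–8.0 Å, switch point 9.8 Å, branch value 3.24 there, and asymptote
6.48. The taper applies only to upper-bound violations; the lower side
stays purely quadratic at all violations (the branch condition is on R,
not |Δ|). Contact confidence never scales w — it is used only for
ranking and subsetting.

Secondary-structure restraints are configuration, not physics: helix
runs (length ≥ 4) restrain Cα(i, i+4) to 6.2 ± 0.3 Å; strand runs
(length ≥ 3) restrain Cα(i, i+2) to 6.7 ± 0.4 Å; stage-2 beta pairing
restrains cross-strand Cα pairs found within 5.5 Å to 5.2 ± 0.5 Å. All
share the contact r_sw/exponents/weights.

## Folding protocol

Simulated annealing from a self-avoiding random walk (bond length 3.8 Å,
no nonbonded pair under 4.0 Å): single-residue Gaussian moves with
Metropolis acceptance, temperature geometric from `t_start` = 10 to
`t_end` = 0.05 over `n_blocks` = 40 blocks, one line-searched
gradient-descent sweep per block (`sweep_iters` iterations; Cβ forces
are applied to the parent Cα).

Two numerical choices matter:

1. **Continuation.** The tapered energy has vanishing long-range
   gradients (≈ 2·r_sw⁴/Δ³), so an extended chain feels almost no pull
   from distant contacts and plain descent on the true surface stalls
   (observed: zero contact-energy improvement from a random start). The
   first half of the schedule therefore optimizes the pure square-error
   surrogate — exactly the r_sw → ∞ limit of the same function — whose
   quadratic tails drive the collapse; the second half switches to the
   true tapered surface, which stops badly violated (likely wrong)
   restraints from distorting the final model. Both the Metropolis
   acceptance and the line search always use the surface that generated
   the proposal, so each phase is a coherent optimization.
2. **Best-state bookkeeping.** The best state seen, scored by the *true*
   energy and subject to the chain-feasibility window (all bonds within
   [3.0, 4.6] Å), is what is returned; the initial chain qualifies, so
   the final energy never exceeds the initial one.

`n_steps` defaults to 5000·L Metropolis moves (production scale).
Quality on the 48-residue fixture saturates near n_steps ≈ 2000 with 60
descent iterations per sweep (~2 s/fold); the test suite and acceptance
script use such short schedules and state so. Model k of subset s uses
seed `base + 1000·s + k`, so the whole 200-model ensemble is
reproducible from one integer.

Stage 2 drops contact restraints violated by more than
`stage2_violation_cutoff` = 2 Å in the stage-1 model, adds the beta
pairing restraints detected in it, and refolds from the stage-1
coordinates at reduced temperature with half the moves.

## Exploration and selection

Subset sizes are round-half-up of x·L, never below 1, capped at the
available contacts; subsets are nested by construction. Per-subset
selection keeps the 5 models with lowest contact energy *against that
subset's own restraints* (ties by seed index). Satisfaction is the
fraction of the top ⌈L/5⌉ long-range (|i−j| ≥ 24, the CASP convention)
contacts with model Cβ–Cβ ≤ 8 Å; ⌈L/2⌉ is available as an alternative
window for the baseline selector. Filtering keeps the 50
highest-satisfaction models (ties: lower contact energy, then pool
order); average-linkage hierarchical clustering on 1 − TM cut at five
clusters is deterministic and seed-free; the medoid (member maximizing
mean within-cluster TM) represents each cluster.

TM-score is computed on Cα with d0 = 1.24(L−15)^⅓ − 1.8 (floored at
0.5 Å), maximized by Kabsch superpositions seeded from contiguous
fragments (lengths L, L/2, L/4) and refined by iterating TM-weighted
(weights (1+(d/d0)²)⁻² ) whole-chain superposition to convergence. It is
symmetric by construction and invariant under rigid motions. Against an
independent anchor-based reference implementation it agrees to ≤ 0.006
on similar pairs (TM ≳ 0.5); on dissimilar pairs the reference's anchor
search undershoots the optimum (it is designed for homologs), so that
regime is validated against a multi-start global-search oracle instead,
where this implementation always scores ≥ the oracle within 0.012.

## Synthetic targets

`FixtureSpec` builds idealized topologies: α-helices as 2.3 Å-radius,
1.5 Å-rise, 100°-per-residue traces (Cα–Cα 3.8 Å, Cα(i,i+4) 6.2 Å),
strands as 3.3 Å-rise zigzags (Cα(i,i+2) 6.6 Å), segments packed
antiparallel at 8.2 Å lateral spacing — a realistic inter-helix
separation that yields ~70 true contacts (17 long-range) on the default
L = 48 bundle — joined by 3-residue linkers arcing over the segment
ends with analytically exact bond lengths. Sequences are random draws
over the 20 amino acids (seeded), so glycine code paths are exercised.
True contacts are all Cβ–Cβ pairs ≤ 8 Å at separation ≥ 6, with
confidence 1 − d/16 so ranking is distance-informative. Degraded sets
mix a chosen fraction of true contacts with uniform decoy pairs whose
confidences are drawn strictly below the true range, mimicking a ranked
predictor output whose head is precision-enriched.

What the fixtures do *not* emulate: real backbone dihedral statistics,
beta-sheet hydrogen-bond registry, sequence-dependent contact patterns,
and predictor-specific error correlations (decoys here are uniform
random pairs, while real false positives cluster near true contacts). A
green reconstruction test therefore establishes that the energy
function plus optimizer can recover an idealized topology from its own
contact map — not that any particular real predictor's output would
reach the same accuracy. The mixed helix/strand topology has few
long-range contacts (equal-residue segments differ 2× in spatial
extent) and is used for construction invariants only.

## Degenerate inputs and edge cases

Fewer contacts than x·L: subsets cap at the available list (the
pipeline logs and proceeds; with 3 contacts all 40 subsets coincide).
Pools smaller than the filter size pass through whole; fewer models
than clusters reduce k with a warning; no long-range contacts make the
satisfaction score 0 with a warning rather than an error. RR records
are normalized to i < j, duplicates keep the maximum confidence, and
sorting (confidence desc, then i, then j) is a total order, so shuffled
inputs give identical pipelines.

## Known limitations

Coarse-grained accuracy ceiling: with a perfect contact map the
48-residue bundle reconstructs to TM ≈ 0.4 on average (best-of-20
≈ 0.6–0.7); the wide zero-error well (3.5–8 Å) simply does not pin the
backbone tighter. No GDT-TS/lDDT, no per-residue error estimates, no
multi-domain splitting, single chain only.
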