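# Methods

## Similarity model

### Shape

Each atom (ligand atom or cavity pseudo-atom) is a spherical Gaussian
density ρ(r) = p·exp(−α|r − r₀|²) with amplitude p = 2.7 and width α fixed
so that the Gaussian's integral equals the hard-sphere volume (4/3)πR³ of
the atom's Bondi van der Waals radius: α = π(3p/(4πR³))^(2/3). The overlap
volume of two structures is the first-order pairwise sum

    O_AB = Σ_{i∈A, j∈B} p² (π/(α_i+α_j))^{3/2} exp(−α_i α_j d_ij² / (α_i+α_j)),

without inclusion–exclusion corrections for multi-atom intersections. The
shape score is the Hodgkin index 2·O_AB/(O_AA + O_BB): exactly 1 for
identical atom sets, positive everywhere, invariant under a common rigid
motion. Higher-order corrections change absolute overlaps but the method
only consumes the *ranking* of compounds, for which the first-order index is
a standard, fast and adequate signal. Radii: Bondi set (H 1.20, C 1.70,
N 1.55, O 1.52, S/P 1.80, halogens per Bondi), 1.70 Å for unknown symbols.
Coordinates are Å everywhere; no unit conversions exist in the package.

### Electrostatics

Partial charges are read from the MOL2 charge column, never computed. Both
charge sets are turned into softened Coulomb potentials

    V(x) = Σ_k q_k / sqrt(|x − r_k|² + ε²),   ε = 0.5 Å,

sampled at the union of both structures' atom centers, and compared with the
Hodgkin index h = 2ΣV_A V_B/(ΣV_A² + ΣV_B²) ∈ [−1, 1], reported as
(1 + h)/2 so shape and ESP share the [0, 1] scale (0.5 = uncorrelated; if
either field is identically zero the score is the neutral 0.5).

The Plummer softening, with *all* source terms included, was chosen over two
superficially natural alternatives that both fail a basic robustness
requirement — that a pose which is a slightly perturbed copy of the model
must score near 1:

* a clamped kernel q/max(d, ε) with self-terms excluded is asymmetric: at an
  observer on structure A, A's own charge is excluded while B's
  near-coincident partner charge saturates at q/ε, which makes a jittered
  copy *anti-correlate* with its template;
* a hard exclusion ball (ignore sources with d < ε) is symmetric but
  discontinuous at d = ε, so matched partner atoms at typical coordinate
  perturbations flicker in and out of the sum and the score becomes noisy.

The smooth symmetric kernel has neither problem, keeps identity → 1 and
charge negation → 0 exact, and at pseudo-atom resolution is dominated by
per-site charge agreement — the discriminative signal the blend needs.
Observer points at atom centers (rather than a molecular-surface mesh) keep
the score deterministic and mesh-free.

### Combination and aggregation

`combined = w·shape + (1−w)·esp` with w = 0.5 by default, or w = 1 (shape
only); w = 1 reproduces the shape score bit-exactly. A compound with several
docked poses is represented by the best combined score over its poses
(argmax, first pose on ties). Poses are used exactly where the docking
engine placed them — the package contains no superposition or pose
optimization of any kind.

## Enrichment metrics

Rankings sort scored compounds by descending combined score with a stable
sort (ties keep input order); compounds skipped by docking carry no score
and are appended at the bottom in a uniform random permutation drawn from a
recorded seed, emulating random picking so early-enrichment values stay
comparable.

* **AUC** — pair-counting probability that an active outranks a decoy;
  rankings are total orders so no tie correction is needed. The standard
  error uses the Hanley–McNeil/Wilcoxon formula with Q₁ = A/(2−A),
  Q₂ = 2A²/(1+A).
* **EFd(f)** — walk the ranking until ⌈f·n_decoys⌉ decoys have been seen and
  report 100·(actives seen strictly before that decoy)/n_actives. The decoy
  count uses the ceiling and actives are counted strictly above the
  threshold decoy — the conservative deterministic reading; no interpolation
  between integer decoy counts.
* **BEDROC(α)** — the Truchon–Bailey closed form
  RIE·Ra·sinh(α/2)/(cosh(α/2) − cosh(α/2 − α·Ra)) + 1/(1 − e^{α(1−Ra)}),
  clamped to [0, 1] against round-off at the boundaries. α = 20 weights
  roughly the top 8% of the ranking.

The exported ROC curve is the unit staircase of the ranking; its trapezoid
area equals the pair-counting AUC to machine precision, which the tests
assert.

## Greedy optimization (the search)

One *generation* evaluates every single-atom-removal variant of the current
model: score the training library, rank, compute the target metric (default
BEDROC(20); AUC and EFd(f) are selectable). The best variant is accepted iff
its metric **strictly** exceeds the current model's, with exact
floating-point comparison and ties broken by the lowest removed-atom index;
the loop ends at the first generation with no improvement, at an optional
generation cap, or at the minimum model size (default 3 atoms — below that,
shape similarity to a cavity is not meaningful). Strictness plus the indexed
tie-break make the search fully deterministic; variant evaluations are
independent and may run on several workers, but results are always collected
in index order so the outcome never depends on scheduling.

A run that shrinks n atoms to a₁ and terminates by no-improvement performs
exactly Σ_{k=a₁}^{n} k variant evaluations (each accepted generation at size
m tests m variants, and the terminating generation tests a₁); the exhaustive
alternative would test Σ_{k=a₁}^{n} C(n,k) subsets. Both counts are exposed
as exact integer formulas and verified against enumeration and instrumented
runs.

*Cut-and-go* accelerates the start: one pass measures every single-deletion
metric of the input model, removes all strictly improving atoms at once
(keeping the smallest improvements if the bulk removal would undershoot the
minimum size), then runs the standard loop on the pruned model.

Models from different sub-pockets of one cavity can be merged by
concatenation (shared coordinate frame is the caller's responsibility);
optionally, same-element atoms within 0.25 Å of an earlier atom collapse to
the first occurrence.

The training metric is computed on training compounds only; test or
validation evaluation is a separate post-hoc call on the held-out sets.
Being greedy, the search can stop in a local optimum — deliberately accepted
in exchange for determinism and tractable cost.

## Training/test splits

Actives and decoys are shuffled and divided independently (stratified) with
a seeded Mersenne Twister; the first round(n·fraction) of each class
(minimum 1) go to training. Class members are sorted before shuffling so a
split depends only on the IDs, the fraction and the seed. Bit-level parity
with any particular external implementation's shuffles is not a goal —
reproducibility within this package is.

## Synthetic benchmark

The generator emulates a rescoring benchmark with a known planted optimum.

* **Cavity model**: a compact *signal* cluster (radius 2 Å, minimum atom
  separation 1.2 Å) at the origin — the sub-pocket actives really occupy —
  plus a *noise* patch of the same construction centred `decoy_displacement`
  (default 6 Å, always ≥ 2 Å outside the active-pose envelope) away: the
  over-generated cavity volume a cavity-filling tool produces. Charges are
  balanced within each cluster (half the atoms charged, split evenly between
  +q and −q, default q = 0.3 e): real cavity images pair donor and acceptor
  points, and a net cluster monopole would otherwise dominate both fields'
  far tails and drown the local pattern the ESP score should measure.
* **Actives** (default 30): the complete signal cluster, re-jittered
  independently per pose (default 3 poses, σ = 0.3 Å per coordinate). Using
  the complete cluster makes every signal atom load-bearing for every
  active, so no signal deletion can look like an improvement.
* **Decoys** (default 300), two alternating flavors:
  *shape-mismatched* decoys mix noise and signal atoms (noise fraction drawn
  from [0.25, 1], each noise atom serving round-robin as a guaranteed
  anchor) with matching charges — under the full model every atom they carry
  is matched, so they score like actives and enrichment starts poor; each
  noise-atom removal demotes exactly the decoys leaning on it, which is the
  gradient the greedy search follows. *Charge-mismatched* decoys occupy the
  signal cluster with negated charges: good shape, anti-correlated ESP,
  exercising the electrostatic channel and the shape-only mode contrast.
* **Skipped compounds**: a fraction of compounds (default 0) are dropped
  from the pose file and listed as skipped, exercising the bottom-of-ranking
  policy.

All randomness flows from the single spec seed; identical specs produce
byte-identical files. Ground truth (signal vs noise atom indices, decoy
flavors) is recorded in `truth.json`.

What the generator does **not** emulate: real chemistry (bonds, valence,
conformers), property-matched decoy selection, docking-pose failure modes,
or score distributions of real screening libraries. Passing the recovery
tests therefore shows that the search machinery finds a planted, recoverable
optimum under controlled conditions — not that any particular real target
would enrich comparably.

## Problem sizes and numerical choices

The default study conditions (16-atom model, 30 actives + 300 decoys × 3
poses) give optimizer runs of about a hundred variant evaluations over ~990
pose scorings each — a few seconds on one core — which is the scale at which
the test suite and the acceptance script operate. Greedy acceptance uses
exact float comparison (no tolerance); the grid oracle for the shape engine
integrates on a 0.05 Å trapezoid grid in an 8 Å box and agrees with the
analytic overlaps to better than 1e−3 relative; rigid-motion invariance
holds to 1e−9. On some generator seeds the greedy search stops in a local
optimum with part of the noise patch still present — expected behaviour of a
greedy method, reported honestly by the acceptance script rather than
smoothed over.

## Interfaces

TRIPOS MOL2 for models (single record) and pose libraries (multi-record,
repeated molecule names = poses of one compound; ninth atom column =
partial charge); plain-text ID lists for labels; CSV score tables; JSON
metric reports and optimizer summaries; JSONL generation logs; two-column
TSV ROC curves. The CLI (`brnib generate|split|rescore|optimize|evaluate`)
is a thin layer over these library functions with exit codes 0 (success),
2 (usage error), 3 (data error).
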