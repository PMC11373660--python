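# Methods

## Developmental model

Development is a deterministic discrete-time dynamical system on the
expression vector x ∈ [0, 1/α]^n:

    x(0) = g,
    x(τ+1) = (1−α) x(τ) + f(B x(τ) + c δ(τ)),   τ = 0 … τl−1,

with f(u) = (1 + tanh u)/2.  Because f maps into (0, 1), the update keeps
every coordinate inside [0, 1/α] for arbitrary B and c; α is the per-step
decay of expression and 1/α the expression ceiling.

The sensor term δ(τ) equals s/α for τ < τc and 0 afterwards.  The relative
activation s is the single environmental coordinate: s = 1 (environment E1),
s = 0 (E2), and intermediate environments are realized by intermediate s.
The update for step τ uses δ evaluated at the source step, so the sensor
influences the states x(1) … x(τc); x(τc) is the "star" state shown in the
phase portraits — the point from which sensor-free relaxation toward an
attractor continues.  Whether the step *producing* x(τc) should carry the
sensor term is a genuine convention choice; we fix it as above and expose
τc so either reading can be emulated.

Lifetime fitness against the optimum X of an environment is the geometric
mean of per-step Gaussian fitness over the adult phase, inclusive of both
endpoints (τv … τl, 20 steps at the defaults):

    w = exp( − Σ_{τ=τv}^{τl} |x(τ) − X|² / (2 σ² (τl − τv + 1)) ).

It is accumulated as a single sum of exponents and exponentiated once;
this is algebraically identical to the product of per-step factors but
avoids intermediate floating-point underflow for badly adapted genotypes.
w = 1 exactly iff the adult trajectory sits on the optimum at every step.

Two distinct fitness evaluations exist and should not be confused:

* `evaluate_both`: w1 from the trajectory grown **in** E1 (s = 1) scored
  against X1, and w2 from the trajectory grown in E2 scored against X2.
  This is what selection and the acquisition monitor use.
* `fitness_at_level`: one trajectory grown at an arbitrary s, scored
  against both X1 and X2.  This is the reaction-norm/discreteness
  quantity.

## Evolutionary model

A haploid Wright–Fisher population of N genotypes evolves in discrete
generations.  Per generation: (1) (w1, w2) is computed for every member;
(2) selection weights are w1 during E1 epochs and w2 during E2 epochs
(epoch = ⌊T/IT⌋, alternating from `initial_env`, first switch at T = IT);
(3) N ordered parent pairs are drawn with replacement, each parent
fitness-proportional and independent (selfing allowed; all-zero weights
fall back to uniform); (4) each child inherits every scalar locus — each
g_i, B_ij, c_i — from either parent with probability 1/2 (free
recombination with no linkage); (5) each locus mutates independently
(probabilities μg, μb per element, μc) by a U(−γ, γ) increment, with g
clamped to [0, 1/α].  The event order selection → recombination → mutation
and the per-element reading of μb are the package's fixed conventions; a
per-row B-mutation variant (one trial per regulatory region, hitting one
uniformly chosen element) is available via `b_mutation="row"`.

All individuals start at g = 1/(2α)·1, B = 0, c = 0 — a fixed point of
development at the center of expression space, giving mean fitness
exp(−1) ≈ 0.368 in both environments at the defaults.

### Acquisition monitor

Both population means w̄1, w̄2 are recorded every generation regardless of
which environment is selecting.  Plasticity is considered acquired at the
earliest generation Tp such that min(w̄1, w̄2) > 0.95 at every generation
in [Tp, Tp + 10⁵]; any dip restarts the window.  The monitor is online
(run-length counter, O(1) memory), always sees full resolution even when
the recorded series is thinned, and terminates the run at Tp + window.
Runs are capped at T_max = 10⁷ generations by default.  Sp is the fraction
of replicates that verify acquisition before the cap.

### Engine implementation

Two interchangeable engines produce bit-identical output:

* the **reference** path: plain numpy, one python iteration per
  generation, built from the public operations (`select_parent_pairs`,
  `advance_generation`, …), with an optional exact fitness memo keyed on
  genotype bytes;
* the **fast** path (default): a compiled chunked kernel.  A child
  identical to one of its parents (the overwhelming majority at realistic
  mutation rates) inherits that parent's fitness; any other child is
  looked up in a hash table of genotypes evaluated this or the previous
  generation, every hit verified by full row comparison; only genuinely
  new genotypes are developed.  Because fitness is a deterministic
  function of the genotype, this caching is exactly transparent.

Both paths share one random draw protocol per generation (parent-pair
uniforms, recombination uniforms, mutation trials, mutation effects, in
that order, loci packed as [g | B row-major | c]) and the same compiled
per-row evaluator and alias-table sampler, which is what makes the
outputs identical rather than merely statistically equivalent.  Draw-order
identity is a within-package contract; bit-identity with other
implementations of the same model is not promised.  Parent sampling uses
a Walker/Vose alias table; slot and coin derive from a single uniform.
One `numpy.random.Generator` per run, seeded from (params, seed); sweep
replicate seeds are a pure function of (base_seed, cell index, replicate).

## Analyses

**Discreteness assay.**  Each distinct genotype (count-weighted, so the
result is invariant to how a population is split into duplicates) is grown
at `grid_size` = 101 evenly spaced sensor levels in [0, 1]; development is
deterministic, so one embryo per (genotype, level) suffices.  A pair is
*intermediate* iff both w1 < 0.95 and w2 < 0.95; the plasticity is
*discrete* iff the weighted intermediate fraction is below 5%.  Both
thresholds are configurable.  The default pools all (individual, level)
pairs; `pooling="individuals"` instead counts individuals that are
intermediate anywhere, a stricter per-individual reading.

**Phase portraits.**  Stable equilibria of the sensor-silent map
x → (1−α)x + f(Bx) are found by iterating from a lattice of starts
(21×21 over [0, 1/α]² for n = 2) until the sup-norm step falls below
tol = 1e−8 (max 10⁴ iterations), clustering endpoints within 1e−3, and
filtering by linear stability (spectral radius of
(1−α)I + diag(f′(Bx*)) B below 1).  The stability filter matters because
lattice starts lying exactly on a saddle's stable manifold — e.g. the
diagonal of a symmetric bistable network — do converge to the saddle
numerically.  Basins are reported as per-start labels, not as an analytic
boundary curve.  The tolerances sit far below the biological resolution of
the optima (spacing 5).

## Parameter presets

| preset | n | σ | μ (all) | X1 / X2 |
|---|---|---|---|---|
| `full_default` | 8 | 5 | 1e−5 | (0,0,5,5,5,5,0,0) / (0,0,5,5,0,0,5,5) |
| `simplified` | 2 | 5/2 | 1e−4 | (5,0) / (0,5) |
| `intermediate_optima` | 8 | 5 | 1e−5 | (1,1,4,4,4,4,1,1) / (1,1,4,4,1,1,4,4) |

Shared defaults: N = 1000, α = 0.2, τc = 10, τv = 21, τl = 40, γ = 0.1
for all three mutation classes, T_max = 10⁷.  The environment period IT
has no table default — it is the main experimental variable — and defaults
to 1 in the presets; set it per run.  The simplified preset compensates
its smaller gene count with stronger selection and faster mutation.

## Problem sizes used by the tests and the acceptance script

The full replicate surfaces (100 replicates per parameter set, up to 10⁷
generations each) are cluster-scale; the sweep harness supports them but
the shipped checks use desk-scale runs of the simplified model: single
runs to acquisition with caps of 10⁶ (IT = 1) and 2×10⁶ (IT = 10⁴)
generations and the full 10⁵-generation verification window, plus three
discreteness replicates at IT = 10⁴ with a reduced 2×10⁴ verification
window and a 10⁶ cap.  Structural properties (oracle agreement of
development, boundedness, sensor neutrality at c = 0, cache/seed
reproducibility, neutral fixation probability ≈ 1/N over 2000 replicates
at N = 100, recovery of known attractors) stand in for the sweeps.

## What the generator does and does not emulate

The simulator *is* the study system; there is no external data.  Within
the model, development is deterministic (no expression noise), the
population is haploid and panmictic with non-overlapping generations, the
environment alternates with a fixed period and is binary (intermediate
environments appear only in the assay, not during evolution), and
fitness effects are Gaussian around fixed optima.  Conclusions from
passing tests therefore concern this idealized system; real developmental
systems add stochastic expression, overlapping generations, structured
populations and irregular environments, any of which could shift Tp/Sp
and the degree of discreteness.

## Known limitations

* The fast engine supports only the default per-element B-mutation; the
  per-row variant runs on the reference engine (automatic fallback) and
  is correspondingly slower.
* Fitness can underflow to exactly 0 for pathologically bad genotypes
  under very strong selection (exponent below ≈ −745); selection then
  treats such genotypes as weight 0, and a population of all-zero weights
  falls back to uniform sampling.
* `find_equilibria` locates only attractors reachable from its start set;
  a sufficiently exotic B could hide an attractor between lattice points.
  Periodic or chaotic attractors of the map are reported as
  non-converged starts, not as objects of their own.
* Population snapshots record whole genotype matrices; snapshotting every
  few hundred generations of a 10⁶-generation run is memory-heavy — use
  `record_stride` for the fitness series and sparse `snapshot_every`.
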