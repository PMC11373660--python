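"""Haploid Wright-Fisher evolution of a population of network genotypes.

Each generation: the fitness of every individual is computed in both
environments (w1 and w2; only the one matching the current environment
enters selection), N parent pairs are drawn with probability proportional
to fitness (with replacement, pairs may coincide), each child inherits
every scalar locus (each g_i, B_ij, c_i) from either parent independently
with probability 1/2 (free recombination), and new mutations are applied
per locus.  The environment alternates between E1 and E2 every IT
generations.  Both population mean fitnesses are recorded every generation,
and an online monitor detects the acquisition of plasticity: the first
generation Tp from which min(mean_w1, mean_w2) stays above a threshold for
a full verification window.

Two engine paths produce bit-identical output for the same seed:

* ``engine="fast"`` (default in :func:`run`): a compiled chunked loop
  (:mod:`plastevo._kernels`) in which a child identical to one parent
  inherits its fitness and only genuinely new genotypes are evaluated.
* ``engine="reference"``: a plain numpy loop built from the public
  operations below, with an optional unique-genotype evaluation cache.

Random draw protocol per generation (both paths): parent-pair uniforms
``random(2N)`` (pair i uses draws i and N+i), then recombination uniforms
``random((N, L))`` (< 0.5 picks parent A), mutation trials ``random((N, L))``
and mutation effect uniforms ``random((N, L))``, with loci packed as
``[g | B row-major | c]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .genotype import Genotype
from .params import E1, E2, SimulationParams

logger = logging.getLogger("plastevo")

_LOG_EVERY = 10_000  # progress-line interval in generations


def environment_at(T: int, IT: int, initial_env: str = E1) -> str:
    """Environment at generation T: epochs of IT generations, alternating.

    Generation 0 starts in ``initial_env``; the first switch happens at
    T = IT.
    """
    if IT < 1:
        raise ValueError("IT must be >= 1")
    if initial_env not in (E1, E2):
        raise ValueError("initial_env must be 'E1' or 'E2'")
    other = E2 if initial_env == E1 else E1
    return initial_env if (T // IT) % 2 == 0 else other


@dataclass
class Population:
    """N genotypes stored as packed rows ``[g | B row-major | c]``."""

    rows: np.ndarray
    n: int
    generation: int = 0
    current_env: str = E1

    def __post_init__(self):
        self.rows = np.ascontiguousarray(self.rows, dtype=float)
        L = self.n + self.n * self.n + self.n
        if self.rows.ndim != 2 or self.rows.shape[1] != L:
            raise ValueError(f"rows must have shape (N, {L})")

    @property
    def size(self) -> int:
        return self.rows.shape[0]

    @property
    def members(self) -> list:
        """The population as a list of :class:`Genotype` (copy)."""
        return [Genotype.from_vector(r, self.n) for r in self.rows]

    @classmethod
    def from_members(cls, members, generation: int = 0,
                     current_env: str = E1) -> "Population":
        n = members[0].n
        rows = np.stack([m.to_vector() for m in members])
        return cls(rows=rows, n=n, generation=generation,
                   current_env=current_env)

    @classmethod
    def initial(cls, params: SimulationParams) -> "Population":
        """Monomorphic ancestral population: g = 1/(2 alpha), B = 0, c = 0."""
        rows = np.zeros((params.N, params.n_loci))
        rows[:, :params.n] = 0.5 / params.alpha
        return cls(rows=rows, n=params.n, generation=0,
                   current_env=params.initial_env)

    def unique_counts(self) -> list:
        """Distinct genotypes and their multiplicities, for assays."""
        uniq, counts = np.unique(self.rows, axis=0, return_counts=True)
        return [(Genotype.from_vector(u, self.n), int(c))
                for u, c in zip(uniq, counts)]

    def copy(self) -> "Population":
        return Population(self.rows.copy(), self.n, self.generation,
                          self.current_env)


class EvalCache:
    """Exact fitness memo for the reference engine, keyed on genotype bytes.

    Purely a performance device: enabling or disabling it never changes any
    result, because fitness is a deterministic function of the genotype row.
    """

    def __init__(self):
        self._d = {}

    def __len__(self):
        return len(self._d)

    def get(self, key):
        return self._d.get(key)

    def put(self, key, value):
        self._d[key] = value


def _eval_args(params: SimulationParams):
    denom = 2.0 * params.sigma ** 2 * params.adult_steps
    return (params.n, params.alpha, params.tau_c, params.tau_v, params.tau_l,
            denom, params.optimum(E1), params.optimum(E2))


def evaluate_rows(rows: np.ndarray, params: SimulationParams,
                  cache: EvalCache | None = None) -> np.ndarray:
    """(w1, w2) for every packed genotype row; shape (N, 2).

    With a cache, each distinct genotype is evaluated once and reused across
    generations; without one, every row is evaluated independently.  The
    results are identical either way.
    """
    rows = np.ascontiguousarray(rows, dtype=float)
    args = _eval_args(params)
    if cache is None:
        return K._eval_rows(rows, *args)
    uniq, inv = np.unique(rows, axis=0, return_inverse=True)
    out_u = np.empty((uniq.shape[0], 2))
    missing = []
    for i in range(uniq.shape[0]):
        hit = cache.get(uniq[i].tobytes())
        if hit is None:
            missing.append(i)
        else:
            out_u[i] = hit
    if missing:
        vals = K._eval_rows(np.ascontiguousarray(uniq[missing]), *args)
        for j, i in enumerate(missing):
            out_u[i] = vals[j]
            cache.put(uniq[i].tobytes(), vals[j].copy())
    return out_u[inv]


# ---------------------------------------------------------------------------
# public per-generation operations
# ---------------------------------------------------------------------------

def mutate(genotype: Genotype, params: SimulationParams,
           rng: np.random.Generator) -> Genotype:
    """Return a mutated copy of ``genotype``.

    Each g entry mutates independently with probability mu_g (increment
    U(-gamma_g, gamma_g), clamped to [0, 1/alpha]); each B entry with
    probability mu_b and each c entry with probability mu_c (unbounded).
    Draw order per block (g, then B, then c): one uniform array of trial
    probabilities, then one uniform array of effect sizes.  With
    ``b_mutation="row"`` the B block instead makes one trial per row, then
    draws the target column, then the effect.
    """
    g = genotype.g.copy()
    B = genotype.B.copy()
    c = genotype.c.copy()
    n = genotype.n

    hit = np.asarray(rng.random(n)) < params.mu_g
    eff = (2.0 * np.asarray(rng.random(n)) - 1.0) * params.gamma_g
    g = np.where(hit, np.clip(g + eff, 0.0, params.x_max), g)

    if params.b_mutation == "element":
        hit = np.asarray(rng.random((n, n))) < params.mu_b
        eff = (2.0 * np.asarray(rng.random((n, n))) - 1.0) * params.gamma_b
        B = np.where(hit, B + eff, B)
    else:
        hit = np.asarray(rng.random(n)) < params.mu_b
        col = np.asarray(rng.integers(0, n, size=n))
        eff = (2.0 * np.asarray(rng.random(n)) - 1.0) * params.gamma_b
        for i in np.nonzero(hit)[0]:
            B[i, col[i]] += eff[i]

    hit = np.asarray(rng.random(n)) < params.mu_c
    eff = (2.0 * np.asarray(rng.random(n)) - 1.0) * params.gamma_c
    c = np.where(hit, c + eff, c)
    return Genotype(g=g, B=B, c=c)


def recombine(parent_a: Genotype, parent_b: Genotype,
              rng: np.random.Generator) -> Genotype:
    """Free recombination: every scalar locus from either parent with
    probability 1/2, independently."""
    if parent_a.n != parent_b.n:
        raise ValueError("parents must have the same number of genes")
    va = parent_a.to_vector()
    vb = parent_b.to_vector()
    from_a = np.asarray(rng.random(va.shape[0])) < 0.5
    return Genotype.from_vector(np.where(from_a, va, vb), parent_a.n)


def select_parent_pairs(fitnesses, n_pairs: int,
                        rng: np.random.Generator) -> np.ndarray:
    """N independent ordered parent pairs, fitness-proportional with
    replacement (the two parents of a pair may coincide).

    Returns an (n_pairs, 2) integer array.  If every fitness is zero the
    draw falls back to uniform weights.
    """
    w = np.ascontiguousarray(fitnesses, dtype=float)
    if np.any(w < 0):
        raise ValueError("fitnesses must be non-negative")
    prob, alias = K._build_alias(w)
    S = rng.random(2 * n_pairs)
    ia = K._alias_sample(prob, alias, np.ascontiguousarray(S[:n_pairs]))
    ib = K._alias_sample(prob, alias, np.ascontiguousarray(S[n_pairs:]))
    return np.stack([ia, ib], axis=1)


def _advance(pop: Population, w: np.ndarray, params: SimulationParams,
             rng: np.random.Generator) -> Population:
    """Selection, recombination and mutation given precomputed fitness."""
    N, L = pop.rows.shape
    n = params.n
    wt = np.ascontiguousarray(w[:, 0] if pop.current_env == E1 else w[:, 1])
    pairs = select_parent_pairs(wt, N, rng)
    R = rng.random((N, L))
    child = np.where(R < 0.5, pop.rows[pairs[:, 0]], pop.rows[pairs[:, 1]])
    if params.b_mutation == "element":
        M = rng.random((N, L))
        D = rng.random((N, L))
        hit = M < params.mu_vector()
        child = child + np.where(hit, (2.0 * D - 1.0) * params.gamma_vector(),
                                 0.0)
        g_block = child[:, :n]
        child[:, :n] = np.where(hit[:, :n],
                                np.clip(g_block, 0.0, params.x_max), g_block)
    else:
        # g block
        Mg = rng.random((N, n))
        Dg = rng.random((N, n))
        hit = Mg < params.mu_g
        g_new = child[:, :n] + np.where(hit,
                                        (2.0 * Dg - 1.0) * params.gamma_g,
                                        0.0)
        child[:, :n] = np.where(hit, np.clip(g_new, 0.0, params.x_max),
                                child[:, :n])
        # B block: one trial per row, one target column per hit
        Mb = rng.random((N, n))
        col = rng.integers(0, n, size=(N, n))
        Db = rng.random((N, n))
        hits = np.nonzero(Mb < params.mu_b)
        for i, r in zip(*hits):
            j = n + r * n + col[i, r]
            child[i, j] += (2.0 * Db[i, r] - 1.0) * params.gamma_b
        # c block
        Mc = rng.random((N, n))
        Dc = rng.random((N, n))
        hit = Mc < params.mu_c
        child[:, n + n * n:] += np.where(hit, (2.0 * Dc - 1.0)
                                         * params.gamma_c, 0.0)
    T_next = pop.generation + 1
    return Population(rows=child, n=n, generation=T_next,
                      current_env=environment_at(T_next, params.IT,
                                                 params.initial_env))


def advance_generation(pop: Population, params: SimulationParams,
                       rng: np.random.Generator,
                       cache: EvalCache | None = None):
    """One Wright-Fisher generation.

    Evaluates (w1, w2) for every member, applies selection on the fitness
    matching ``pop.current_env``, recombination and mutation, and returns
    ``(new_population, mean_w1, mean_w2)`` where the means are measured on
    the pre-selection population.
    """
    if pop.size != params.N or pop.n != params.n:
        raise ValueError("population does not match params (N, n)")
    w = evaluate_rows(pop.rows, params, cache)
    m1 = float(K._mean(np.ascontiguousarray(w[:, 0])))
    m2 = float(K._mean(np.ascontiguousarray(w[:, 1])))
    return _advance(pop, w, params, rng), m1, m2


# ---------------------------------------------------------------------------
# whole-run driver
# ---------------------------------------------------------------------------

@dataclass
class RunRecord:
    """Result of one evolutionary run.

    ``generations``, ``mean_w1`` and ``mean_w2`` hold the per-generation
    population mean fitnesses, thinned to ``record_stride`` (the final
    generation is always included; the acquisition monitor itself always
    sees every generation).  ``acquisition_generation`` is Tp, the first
    generation from which min(mean_w1, mean_w2) exceeded ``threshold`` for
    ``window`` consecutive further generations; ``success`` marks whether
    that was verified before the generation cap.
    """

    params: SimulationParams
    seed: object
    threshold: float
    window: int
    record_stride: int
    generations: np.ndarray
    mean_w1: np.ndarray
    mean_w2: np.ndarray
    success: bool
    acquisition_generation: int | None
    final_generation: int
    final_population: Population
    snapshots: list = field(default_factory=list)

    @property
    def params_hash(self) -> str:
        return self.params.params_hash()


_CHUNK = 1024
_CACHE_ROWS = 2048   # genotype-cache capacity (rows kept per generation)
_CACHE_TABLE = 8192  # open-addressing table size (power of two)


def run(params: SimulationParams, *, seed=None, threshold: float = 0.95,
        window: int = 100_000, record_stride: int = 1,
        snapshot_every: int | None = None, engine: str = "fast",
        use_cache: bool = True) -> RunRecord:
    """Evolve from the ancestral state until plasticity is verified or the
    generation cap ``params.T_max`` is reached.

    All individuals start at g = 1/(2 alpha), B = 0, c = 0.  The run stops
    early at generation Tp + window once the acquisition monitor verifies
    that min(mean_w1, mean_w2) stayed above ``threshold`` from Tp on.  The
    same (params, seed) always reproduces the identical record; the engine
    choice ("fast" or "reference") and ``use_cache`` (reference path only)
    do not change any output.
    """
    if engine == "fast" and params.b_mutation != "element":
        engine = "reference"  # the compiled path supports per-element only
    if engine not in ("fast", "reference"):
        raise ValueError("engine must be 'fast' or 'reference'")
    if record_stride < 1:
        raise ValueError("record_stride must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    used_seed = params.seed if seed is None else seed

    pop0 = Population.initial(params)
    snapshots = []

    def snap(T, rows):
        snapshots.append((T, Population(
            rows.copy(), params.n, T,
            environment_at(T, params.IT, params.initial_env))))

    if snapshot_every:
        snap(0, pop0.rows)

    hist1, hist2 = [], []

    if engine == "fast":
        rows = pop0.rows
        w = evaluate_rows(rows, params, None)
        w1 = np.ascontiguousarray(w[:, 0])
        w2 = np.ascontiguousarray(w[:, 1])
        state = np.array([0, -1], dtype=np.int64)
        L = params.n_loci
        store_a = np.zeros((_CACHE_ROWS, L))
        store_b = np.zeros((_CACHE_ROWS, L))
        wa = np.zeros((_CACHE_ROWS, 2))
        wb = np.zeros((_CACHE_ROWS, 2))
        table_a = np.zeros(_CACHE_TABLE, dtype=np.int64)
        table_b = np.zeros(_CACHE_TABLE, dtype=np.int64)
        cache_meta = np.zeros(1, dtype=np.int64)
        m1_buf = np.empty(_CHUNK)
        m2_buf = np.empty(_CHUNK)
        args = _eval_args(params)
        T = 0
        while True:
            max_gens = _CHUNK
            if snapshot_every:
                next_snap = (T // snapshot_every + 1) * snapshot_every
                max_gens = min(max_gens, next_snap - T)
            g_done, status = K._wf_chunk(
                rows, w1, w2, T, max_gens, params.T_max, params.IT,
                params.initial_env == E1, *args,
                params.mu_vector(), params.gamma_vector(),
                threshold, window, state, store_a, wa, table_a,
                store_b, wb, table_b, cache_meta, rng, m1_buf, m2_buf)
            hist1.append(m1_buf[:g_done].copy())
            hist2.append(m2_buf[:g_done].copy())
            if (logger.isEnabledFor(logging.INFO)
                    and (T + g_done) // _LOG_EVERY > T // _LOG_EVERY):
                n_unique = np.unique(rows, axis=0).shape[0]
                logger.info(
                    "generation %d: mean_w1=%.4f mean_w2=%.4f unique=%d",
                    T + g_done - 1, m1_buf[g_done - 1], m2_buf[g_done - 1],
                    n_unique)
            if status == K.CONT:
                T += g_done
                if snapshot_every and T % snapshot_every == 0:
                    snap(T, rows)
            else:
                T = T + g_done - 1
                break
        success = status == K.DONE
        Tp = int(state[1]) if success else None
        final_rows = rows
    else:
        pop = pop0
        cache = EvalCache() if use_cache else None
        streak = 0
        cand = -1
        success = False
        Tp = None
        while True:
            w = evaluate_rows(pop.rows, params, cache)
            m1 = float(K._mean(np.ascontiguousarray(w[:, 0])))
            m2 = float(K._mean(np.ascontiguousarray(w[:, 1])))
            hist1.append(np.array([m1]))
            hist2.append(np.array([m2]))
            if (logger.isEnabledFor(logging.INFO)
                    and pop.generation % _LOG_EVERY == 0):
                logger.info(
                    "generation %d: mean_w1=%.4f mean_w2=%.4f unique=%d",
                    pop.generation, m1, m2,
                    np.unique(pop.rows, axis=0).shape[0])
            if min(m1, m2) > threshold:
                if streak == 0:
                    cand = pop.generation
                streak += 1
                if streak >= window + 1:
                    success = True
                    Tp = cand
                    break
            else:
                streak = 0
            if pop.generation >= params.T_max:
                break
            pop = _advance(pop, w, params, rng)
            if snapshot_every and pop.generation % snapshot_every == 0:
                snap(pop.generation, pop.rows)
        T = pop.generation
        final_rows = pop.rows

    m1_all = np.concatenate(hist1) if hist1 else np.empty(0)
    m2_all = np.concatenate(hist2) if hist2 else np.empty(0)
    gens_all = np.arange(m1_all.shape[0])
    if record_stride > 1:
        keep = gens_all % record_stride == 0
        keep[-1] = True  # always include the final generation
        gens, m1_rec, m2_rec = gens_all[keep], m1_all[keep], m2_all[keep]
    else:
        gens, m1_rec, m2_rec = gens_all, m1_all, m2_all

    final_pop = Population(final_rows.copy(), params.n, T,
                           environment_at(T, params.IT, params.initial_env))
    return RunRecord(
        params=params, seed=used_seed, threshold=threshold, window=window,
        record_stride=record_stride,
        generations=gens, mean_w1=m1_rec, mean_w2=m2_rec,
        success=success, acquisition_generation=Tp, final_generation=T,
        final_population=final_pop, snapshots=snapshots)
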