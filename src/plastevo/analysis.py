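"""Derived statistics: plasticity acquisition, reaction-norm discreteness,
and fixed-point/basin structure of the developmental map.

*Acquisition.*  A population has acquired plasticity at generation Tp if the
population mean fitness in both environments stays above a threshold
(default 0.95) for a full verification window (default 1e5 generations)
starting at Tp.  Sp is the fraction of replicate runs that verify this
before the generation cap.

*Discreteness.*  Grown along a gradient of sensor activation levels
s in [0, 1], a phenotype is "intermediate" when it fits neither optimum
well (both w1 < 0.95 and w2 < 0.95).  Plasticity is discrete when
intermediate phenotypes make up less than 5% of all (individual, level)
pairs: the reaction norm then jumps between the two adapted phenotypes
almost everywhere along the gradient.

*Phase portraits.*  With the sensor silent, development iterates the map
x -> (1 - alpha) x + f(Bx).  Plasticity rests on this map having two stable
equilibria (the memorized adult phenotypes); the sensor's role during the
sensitive period is to push the state across the basin boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import Genotype
from .model import activation, develop, fitness_at_level
from .params import SimulationParams


@dataclass
class PlasticitySummary:
    """Acquisition verdict of one run: Tp (or None) and success."""

    acquisition_generation: int | None
    success: bool

    @property
    def Tp(self):
        return self.acquisition_generation


def detect_acquisition(stream, threshold: float = 0.95,
                       window: int = 100_000) -> PlasticitySummary:
    """Online scan of a (generation, mean_w1, mean_w2) stream.

    Tp is the earliest generation t with min(mean_w1, mean_w2) > threshold
    at every observed generation in [t, t + window]; any dip restarts the
    verification window.  Single pass, O(1) memory.  ``success`` requires
    the full window to fall inside the stream.
    """
    cand = None
    for gen, m1, m2 in stream:
        if min(m1, m2) > threshold:
            if cand is None:
                cand = gen
            if gen - cand >= window:
                return PlasticitySummary(int(cand), True)
        else:
            cand = None
    return PlasticitySummary(None, False)


def success_proportion(summaries) -> float:
    """Sp: the fraction of replicate runs that acquired plasticity."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one summary")
    return sum(1 for s in summaries if s.success) / len(summaries)


@dataclass
class DiscretenessResult:
    """Reaction norms along the sensor gradient plus the verdict.

    ``fitness_curves`` has shape (n_genotypes, n_levels, 2) with the last
    axis holding (w1, w2) for the phenotype grown at each level; ``counts``
    are the genotype multiplicities used for weighting.
    """

    levels: np.ndarray
    fitness_curves: np.ndarray
    counts: np.ndarray
    intermediate_fraction: float
    is_discrete: bool
    threshold: float = 0.95
    cutoff: float = 0.05


def discreteness_assay(genotypes, params: SimulationParams,
                       grid_size: int = 101, threshold: float = 0.95,
                       cutoff: float = 0.05,
                       pooling: str = "pairs") -> DiscretenessResult:
    """Grow every genotype along a sensor-level gradient and classify.

    ``genotypes`` is a list of (Genotype, count) pairs (e.g. from
    ``Population.unique_counts()``), a Population, or a single Genotype.
    Development is deterministic, so one embryo per (genotype, level)
    suffices.  A (genotype, level) pair is intermediate iff both w1 and w2
    fall below ``threshold``; the count-weighted fraction of intermediate
    pairs decides discreteness (< ``cutoff``).

    ``pooling="pairs"`` (default) pools all (individual, level) pairs;
    ``pooling="individuals"`` instead counts an individual as intermediate
    if it is intermediate at any level, a stricter per-individual reading.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if pooling not in ("pairs", "individuals"):
        raise ValueError("pooling must be 'pairs' or 'individuals'")
    if isinstance(genotypes, Genotype):
        pairs = [(genotypes, 1)]
    elif hasattr(genotypes, "unique_counts"):
        pairs = genotypes.unique_counts()
    else:
        pairs = list(genotypes)
    # merge duplicates so the result is invariant to count splitting
    merged: dict = {}
    for gt, cnt in pairs:
        key = gt.to_vector().tobytes()
        if key in merged:
            merged[key] = (merged[key][0], merged[key][1] + cnt)
        else:
            merged[key] = (gt, cnt)
    pairs = list(merged.values())

    levels = np.linspace(0.0, 1.0, grid_size)
    curves = np.empty((len(pairs), grid_size, 2))
    counts = np.array([cnt for _, cnt in pairs], dtype=float)
    for k, (gt, _) in enumerate(pairs):
        for li, s in enumerate(levels):
            fp = fitness_at_level(gt, float(s), params)
            curves[k, li, 0] = fp.w1
            curves[k, li, 1] = fp.w2
    inter = (curves[:, :, 0] < threshold) & (curves[:, :, 1] < threshold)
    if pooling == "pairs":
        frac = float((inter.sum(axis=1) * counts).sum()
                     / (grid_size * counts.sum()))
    else:
        frac = float((inter.any(axis=1) * counts).sum() / counts.sum())
    return DiscretenessResult(
        levels=levels, fitness_curves=curves, counts=counts,
        intermediate_fraction=frac, is_discrete=frac < cutoff,
        threshold=threshold, cutoff=cutoff)


@dataclass
class PhasePortrait:
    """Stable equilibria of the sensor-silent developmental map.

    ``equilibria`` lists the distinct stable fixed points found by
    iteration; ``basin_labels`` maps each start to the index of the
    equilibrium it converged to (-1 for non-converged), shaped as the start
    grid for n = 2; ``star_state`` is x(tau_c) under full sensor activation
    (the state from which post-sensor development continues in E1).
    """

    equilibria: list
    basin_labels: np.ndarray | None
    star_state: np.ndarray
    starts: np.ndarray
    labels: np.ndarray = field(default=None)


def _no_sensor_map(x, B, alpha):
    return (1.0 - alpha) * x + activation(x @ B.T)


def _is_stable(x_star, B, alpha):
    """Linear stability of a fixed point of the sensor-silent map.

    The Jacobian is (1 - alpha) I + diag(f'(B x*)) B with
    f'(u) = (1 - tanh^2 u)/2; the point is stable iff the spectral radius
    is below 1.  Starts lying exactly on a saddle's stable manifold (e.g. a
    symmetric diagonal) do converge there numerically, so saddles must be
    filtered out explicitly.
    """
    u = B @ x_star
    J = (1.0 - alpha) * np.eye(len(x_star)) + (
        0.5 * (1.0 - np.tanh(u) ** 2))[:, None] * B
    return np.max(np.abs(np.linalg.eigvals(J))) < 1.0


def find_equilibria(genotype: Genotype, params: SimulationParams,
                    starts: np.ndarray | None = None,
                    max_iter: int = 10_000, tol: float = 1e-8,
                    cluster_radius: float = 1e-3,
                    grid_size: int = 21) -> PhasePortrait:
    """Locate stable fixed points of x -> (1 - alpha) x + f(Bx).

    The map is iterated from each start until successive iterates differ by
    less than ``tol`` in sup norm (or ``max_iter`` is hit); converged
    endpoints within ``cluster_radius`` of each other are merged into one
    equilibrium.  Only stable equilibria can be found this way: iteration
    escapes sources and saddles from almost every start.  For n = 2 the
    default starts form a ``grid_size`` x ``grid_size`` lattice over
    [0, 1/alpha]^2 and ``basin_labels`` is returned in grid shape.
    """
    n = params.n
    hi = params.x_max
    grid_shape = None
    if starts is None:
        if n == 2:
            axis = np.linspace(0.0, hi, grid_size)
            xx, yy = np.meshgrid(axis, axis, indexing="ij")
            starts = np.stack([xx.ravel(), yy.ravel()], axis=1)
            grid_shape = (grid_size, grid_size)
        else:
            corners = np.array(
                np.meshgrid(*([[0.0, hi]] * min(n, 8)), indexing="ij")
            ).reshape(min(n, 8), -1).T
            if n > 8:  # cap the lattice; pad with center coordinates
                corners = np.hstack([
                    corners, np.full((corners.shape[0], n - 8), hi / 2)])
            starts = np.vstack([corners, np.full((1, n), hi / 2),
                                genotype.g[None, :]])
    starts = np.asarray(starts, dtype=float)
    if starts.ndim != 2 or starts.shape[1] != n:
        raise ValueError("starts must have shape (m, n)")
    if np.any(starts < 0) or np.any(starts > hi):
        raise ValueError("starts must lie in [0, 1/alpha]^n")
    if genotype.n != n:
        raise ValueError("genotype dimension does not match params")

    B, alpha = genotype.B, params.alpha
    x = starts.copy()
    converged = np.zeros(starts.shape[0], dtype=bool)
    for _ in range(max_iter):
        x_new = _no_sensor_map(x, B, alpha)
        step = np.max(np.abs(x_new - x), axis=1)
        x = x_new
        converged |= step < tol
        if converged.all():
            break

    equilibria: list = []
    labels = np.full(starts.shape[0], -1, dtype=int)
    rejected: list = []  # saddles reached from their stable manifolds
    for i in range(starts.shape[0]):
        if not converged[i]:
            continue
        for eq in rejected:
            if np.max(np.abs(x[i] - eq)) < cluster_radius:
                break
        else:
            for k, eq in enumerate(equilibria):
                if np.max(np.abs(x[i] - eq)) < cluster_radius:
                    labels[i] = k
                    break
            else:
                if _is_stable(x[i], B, params.alpha):
                    equilibria.append(x[i].copy())
                    labels[i] = len(equilibria) - 1
                else:
                    rejected.append(x[i].copy())

    star = develop(genotype, 1.0, params).x[params.tau_c].copy()
    basin = labels.reshape(grid_shape) if grid_shape is not None else None
    return PhasePortrait(equilibria=equilibria, basin_labels=basin,
                         star_state=star, starts=starts, labels=labels)
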