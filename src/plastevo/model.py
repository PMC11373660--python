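"""Deterministic developmental dynamics and lifetime fitness.

Development iterates, for tau = 0 .. tau_l - 1,

    x_i(tau+1) = (1 - alpha) x_i(tau) + f( sum_j B_ij x_j(tau) + c_i d(tau) )

with the sigmoid f(u) = (1 + tanh u)/2, the initial condition x(0) = g, and
the sensor input d(tau) = s/alpha for tau < tau_c and 0 afterwards, where
s in [0, 1] is the relative sensor activation (s = 1 in environment E1,
s = 0 in E2; intermediate environments scale the sensor linearly).  Since f
maps into (0, 1), every expression level stays within [0, 1/alpha].

Lifetime fitness in environment Ei is the geometric mean over the adult
phase tau_v .. tau_l of the per-step Gaussian fitness
exp(-|x(tau) - X_i|^2 / (2 sigma^2)); it is accumulated in log space and
exponentiated once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype import Genotype
from .params import SimulationParams


def activation(u):
    """Sigmoid activation f(u) = (1 + tanh u) / 2, strictly in (0, 1).

    Accepts scalars or arrays; raises on non-finite input.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("activation input must be finite")
    out = 0.5 * (1.0 + np.tanh(u))
    return float(out) if out.ndim == 0 else out


def sensor_expression(step: int, sensor_level: float,
                      params: SimulationParams) -> float:
    """Sensor-gene expression d(tau) at developmental step ``step``.

    The sensor expresses only during the sensitive period (steps
    0 .. tau_c - 1) at level ``sensor_level / alpha``; full activation
    (s = 1) gives the maximum expression 1/alpha, as in environment E1, and
    s = 0 silences it, as in E2.
    """
    if not 0.0 <= sensor_level <= 1.0:
        raise ValueError("sensor_level must lie in [0, 1]")
    if not 0 <= step <= params.tau_l:
        raise ValueError("step must lie in [0, tau_l]")
    return sensor_level / params.alpha if step < params.tau_c else 0.0


@dataclass
class Trajectory:
    """Expression time series of one individual in one environment.

    ``x`` has shape (tau_l + 1, n): row tau is the expression vector at
    developmental step tau, with x[0] equal to the genotype's g.
    """

    x: np.ndarray
    sensor_level: float


@dataclass(frozen=True)
class FitnessPair:
    """Lifetime fitness of one genotype in each environment."""

    w1: float
    w2: float

    def min(self) -> float:
        return min(self.w1, self.w2)


def develop(genotype: Genotype, sensor_level: float,
            params: SimulationParams) -> Trajectory:
    """Run the developmental recurrence for one genotype.

    Deterministic: identical inputs always give identical trajectories.
    """
    if genotype.n != params.n:
        raise ValueError(
            f"genotype has {genotype.n} genes but params.n = {params.n}")
    genotype.validate_bounds(params.x_max)
    n, tau_l = params.n, params.tau_l
    one_minus_a = 1.0 - params.alpha
    x = np.empty((tau_l + 1, n))
    x[0] = genotype.g
    B, c = genotype.B, genotype.c
    for tau in range(tau_l):
        d = sensor_expression(tau, sensor_level, params)
        x[tau + 1] = one_minus_a * x[tau] + activation(B @ x[tau] + c * d)
    return Trajectory(x=x, sensor_level=float(sensor_level))


def lifetime_fitness(traj: Trajectory, optimum: np.ndarray,
                     params: SimulationParams) -> float:
    """Geometric-mean fitness over the adult phase against ``optimum``.

    Equals 1 exactly when the adult-phase expression matches the optimum at
    every step; always positive.
    """
    optimum = np.asarray(optimum, dtype=float)
    if optimum.shape != (params.n,):
        raise ValueError("optimum must have length n")
    adult = traj.x[params.tau_v:params.tau_l + 1]
    denom = 2.0 * params.sigma ** 2 * params.adult_steps
    log_w = -np.sum((adult - optimum) ** 2) / denom
    return float(np.exp(log_w))


def evaluate_both(genotype: Genotype, params: SimulationParams) -> FitnessPair:
    """Fitness the genotype would have if grown in E1 and if grown in E2.

    w1 is measured on the trajectory developed under full sensor activation
    (E1) against X1; w2 on the sensor-silent trajectory (E2) against X2.
    """
    w1 = lifetime_fitness(develop(genotype, 1.0, params),
                          params.optimum("E1"), params)
    w2 = lifetime_fitness(develop(genotype, 0.0, params),
                          params.optimum("E2"), params)
    return FitnessPair(w1=w1, w2=w2)


def fitness_at_level(genotype: Genotype, sensor_level: float,
                     params: SimulationParams) -> FitnessPair:
    """Reaction-norm point: grow at a (possibly intermediate) sensor level
    and score the one resulting phenotype against both optima.

    Unlike :func:`evaluate_both`, a single trajectory is developed at
    ``sensor_level`` and measured against X1 (giving w1) and X2 (w2).  This
    is the quantity used to classify intermediate phenotypes along an
    environmental gradient.
    """
    traj = develop(genotype, sensor_level, params)
    return FitnessPair(
        w1=lifetime_fitness(traj, params.optimum("E1"), params),
        w2=lifetime_fitness(traj, params.optimum("E2"), params),
    )


def trajectory_to_tsv(traj: Trajectory, path) -> None:
    """Write a trajectory as TSV with columns step, gene_index, expression."""
    with open(path, "w") as fh:
        fh.write("step\tgene_index\texpression\n")
        for tau in range(traj.x.shape[0]):
            for i in range(traj.x.shape[1]):
                fh.write(f"{tau}\t{i}\t{float(traj.x[tau, i])!r}\n")
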