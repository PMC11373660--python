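"""Hand-constructed genotypes with independently verified facts.

These fixtures are test/demonstration plumbing: small networks whose
attractor structure is known, checked at build time against a naive
step-by-step iteration written here from scratch (plain Python floats, no
shared helpers with :mod:`plastevo.model`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype import Genotype
from .model import evaluate_both
from .params import SimulationParams, preset

FIXTURE_NAMES = ("monostable_center", "bistable_diag", "adapted_pair")


@dataclass
class FixtureGenotype:
    name: str
    genotype: Genotype
    params: SimulationParams
    expected: dict


def _naive_develop(g, B, c, alpha, tau_c, tau_l, sensor_level):
    """Independent scalar-arithmetic development (the build-time oracle)."""
    n = len(g)
    x = [float(v) for v in g]
    for tau in range(tau_l):
        d = sensor_level / alpha if tau < tau_c else 0.0
        nxt = []
        for i in range(n):
            u = c[i] * d
            for j in range(n):
                u += B[i][j] * x[j]
            nxt.append((1.0 - alpha) * x[i] + 0.5 * (1.0 + math.tanh(u)))
        x = nxt
    return x


def _naive_equilibrium(start, B, alpha, iters=2000):
    """Iterate the sensor-silent map from ``start`` with scalar arithmetic."""
    n = len(start)
    x = [float(v) for v in start]
    for _ in range(iters):
        nxt = []
        for i in range(n):
            u = 0.0
            for j in range(n):
                u += B[i][j] * x[j]
            nxt.append((1.0 - alpha) * x[i] + 0.5 * (1.0 + math.tanh(u)))
        x = nxt
    return x


def make_fixture(name: str) -> FixtureGenotype:
    """Build one of the named fixtures, verifying its facts on the way.

    ``monostable_center``
        The ancestral eight-gene genotype (B = 0): a single equilibrium with
        every coordinate at 1/(2 alpha) = 2.5.
    ``bistable_diag``
        Two genes with strong mutual inhibition and self-activation,
        B = ((10, -10), (-10, 10)), sensor coupling c = (10, -10) and embryo
        state g = (2, 3): two attractors near (5, 0) and (0, 5), with the
        sensor flipping development between them.
    ``adapted_pair``
        A two-gene genotype whose adult phenotypes sit at the simplified-
        model optima in both environments (min(w1, w2) >= 0.99), produced by
        a short deterministic hill-climb from ``bistable_diag``.
    """
    if name == "monostable_center":
        params = preset("full_default")
        gt = Genotype.initial(params)
        eq = _naive_equilibrium([0.0] * 8, gt.B.tolist(), params.alpha)
        assert all(abs(v - 2.5) < 1e-9 for v in eq)
        return FixtureGenotype(name, gt, params,
                               expected={"equilibria": [[2.5] * 8]})

    if name == "bistable_diag":
        params = preset("simplified")
        gt = Genotype(g=[2.0, 3.0],
                      B=[[10.0, -10.0], [-10.0, 10.0]],
                      c=[10.0, -10.0])
        B = gt.B.tolist()
        eq_a = _naive_equilibrium([4.0, 1.0], B, params.alpha)
        eq_b = _naive_equilibrium([1.0, 4.0], B, params.alpha)
        adult_e1 = _naive_develop(gt.g, B, gt.c, params.alpha,
                                  params.tau_c, params.tau_l, 1.0)
        adult_e2 = _naive_develop(gt.g, B, gt.c, params.alpha,
                                  params.tau_c, params.tau_l, 0.0)
        assert abs(eq_a[0] - 5.0) < 1e-3 and abs(eq_a[1]) < 1e-3
        assert abs(eq_b[0]) < 1e-3 and abs(eq_b[1] - 5.0) < 1e-3
        assert abs(adult_e1[0] - 5.0) < 1e-3 and abs(adult_e1[1]) < 1e-3
        assert abs(adult_e2[0]) < 1e-3 and abs(adult_e2[1] - 5.0) < 1e-3
        return FixtureGenotype(name, gt, params, expected={
            "equilibria": [eq_a, eq_b],
            "adult_E1": adult_e1,
            "adult_E2": adult_e2,
        })

    if name == "adapted_pair":
        base = make_fixture("bistable_diag")
        params = base.params
        gt = base.genotype.copy()
        rng = np.random.default_rng(20240401)
        best = evaluate_both(gt, params).min()
        # deterministic hill-climb on min(w1, w2); usually converged already
        for _ in range(200):
            if best >= 0.99:
                break
            cand = gt.copy()
            cand.B += rng.uniform(-0.5, 0.5, size=cand.B.shape)
            cand.c += rng.uniform(-0.5, 0.5, size=cand.c.shape)
            score = evaluate_both(cand, params).min()
            if score > best:
                gt, best = cand, score
        fp = evaluate_both(gt, params)
        assert fp.w1 >= 0.99 and fp.w2 >= 0.99
        return FixtureGenotype(name, gt, params,
                               expected={"w1": fp.w1, "w2": fp.w2})

    raise ValueError(
        f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}")
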