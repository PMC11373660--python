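import numpy as np
import pytest

import plastevo as pv


@pytest.fixture(scope="session")
def full_params():
    return pv.preset("full_default")


@pytest.fixture(scope="session")
def simp_params():
    return pv.preset("simplified")


@pytest.fixture(scope="session")
def bistable():
    return pv.make_fixture("bistable_diag")


def naive_develop(g, B, c, alpha, tau_c, tau_l, sensor_level):
    """Brute-force development oracle: plain Python floats, step by step.

    Written independently of plastevo.model / plastevo._kernels (no shared
    helpers) so that agreement is a genuine cross-check.
    """
    import math

    n = len(g)
    xs = [[float(v) for v in g]]
    x = xs[0]
    for tau in range(tau_l):
        d = sensor_level / alpha if tau < tau_c else 0.0
        nxt = []
        for i in range(n):
            u = c[i] * d
            for j in range(n):
                u += B[i][j] * x[j]
            nxt.append((1.0 - alpha) * x[i] + 0.5 * (1.0 + math.tanh(u)))
        xs.append(nxt)
        x = nxt
    return np.array(xs)


def naive_fitness(xs, optimum, sigma, tau_v, tau_l):
    """Brute-force lifetime fitness: product of per-step Gaussian terms."""
    import math

    steps = tau_l - tau_v + 1
    w = 1.0
    for tau in range(tau_v, tau_l + 1):
        sq = sum((xs[tau][j] - optimum[j]) ** 2 for j in range(len(optimum)))
        w *= math.exp(-sq / (2.0 * sigma ** 2 * steps))
    return w


@pytest.fixture(scope="session")
def neutral_fixation_count():
    """Fixations of a selectively neutral tagged allele over 2000 WF
    replicates at N = 100, starting from one copy.

    The tag is a c-locus variant with tau_c = 0, which is exactly invisible
    to development and therefore to selection; drift alone decides its
    fate.  Expected fixation probability 1/N."""
    p = pv.preset("simplified", N=100, tau_c=0, tau_v=1, tau_l=2,
                  mu_g=0.0, mu_b=0.0, mu_c=0.0)
    base = pv.Population.initial(p)
    tag_col = p.n + p.n * p.n  # first c locus
    rng = np.random.default_rng(2024)
    fixed = 0
    for _ in range(2000):
        pop = base.copy()
        pop.rows[0, tag_col] = 1.0
        while True:
            freq = np.count_nonzero(pop.rows[:, tag_col] == 1.0)
            if freq == 0:
                break
            if freq == p.N:
                fixed += 1
                break
            pop, _, _ = pv.advance_generation(pop, p, rng)
    return fixed


def random_genotype(rng, n, x_max, scale=2.0):
    return pv.Genotype(
        g=rng.uniform(0.0, x_max, n),
        B=rng.uniform(-scale, scale, (n, n)),
        c=rng.uniform(-scale, scale, n),
    )
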