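"""Simulation parameters and named parameter presets.

The model couples a developmental recurrence (a Wagner-type recurrent gene
network with a transient environmental sensor input) to a haploid
Wright-Fisher population evolving in an environment that alternates between
two states, E1 and E2, every ``IT`` generations.  All tunable constants of
the model live in :class:`SimulationParams`; the three presets reproduce the
standard parameterizations: the eight-gene default, the two-gene simplified
variant, and the intermediate-optima variant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np

E1 = "E1"
E2 = "E2"

#: Names accepted by :func:`preset`.
PRESET_NAMES = ("full_default", "simplified", "intermediate_optima")


@dataclass(frozen=True)
class SimulationParams:
    """All constants of the developmental model and the evolutionary run.

    Parameters
    ----------
    n : int
        Number of expressed (type-G) genes; the phenotype is their expression
        vector.
    N : int
        Haploid population size of the Wright-Fisher population.
    alpha : float
        Per-step decay rate of gene expression, in (0, 1].  Expression levels
        are confined to [0, 1/alpha].
    tau_c : int
        Developmental step at which sensor-gene expression ends.  The sensor
        input is applied while computing x(1) .. x(tau_c).
    tau_v, tau_l : int
        First and last developmental step of the adult phase; selection acts
        on expression at steps tau_v..tau_l inclusive.
    sigma : float
        Inverse selection strength (Gaussian fitness width).
    mu_g, mu_b, mu_c : float
        Per-element mutation probabilities per generation for the embryonic
        expression vector g, the regulatory matrix B, and the sensor-coupling
        vector c.
    gamma_g, gamma_b, gamma_c : float
        Maximum effect of a single mutation; increments are drawn from
        U(-gamma, gamma).
    IT : int
        Generations between environmental switches.
    X1, X2 : tuple of float
        Optimal adult expression patterns in E1 and E2; entries in
        [0, 1/alpha].
    T_max : int
        Generation cap of a run.
    initial_env : str
        Environment at generation 0 ("E1" or "E2").
    seed : int
        Default random seed for :func:`plastevo.evolution.run`.
    b_mutation : str
        "element": each of the n^2 entries of B is an independent mutation
        trial (default).  "row": one trial per row of B; on success a single
        uniformly chosen entry of that row is perturbed.
    """

    n: int = 8
    N: int = 1000
    alpha: float = 0.2
    tau_c: int = 10
    tau_v: int = 21
    tau_l: int = 40
    sigma: float = 5.0
    mu_g: float = 1e-5
    mu_b: float = 1e-5
    mu_c: float = 1e-5
    gamma_g: float = 0.1
    gamma_b: float = 0.1
    gamma_c: float = 0.1
    IT: int = 1
    X1: tuple = (0.0, 0.0, 5.0, 5.0, 5.0, 5.0, 0.0, 0.0)
    X2: tuple = (0.0, 0.0, 5.0, 5.0, 0.0, 0.0, 5.0, 5.0)
    T_max: int = 10_000_000
    initial_env: str = E1
    seed: int = 0
    b_mutation: str = "element"

    def __post_init__(self):
        object.__setattr__(self, "X1", tuple(float(v) for v in self.X1))
        object.__setattr__(self, "X2", tuple(float(v) for v in self.X2))
        if self.n < 1:
            raise ValueError("n must be a positive integer")
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 <= self.tau_c <= self.tau_v <= self.tau_l:
            raise ValueError("require 0 <= tau_c <= tau_v <= tau_l")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in ("mu_g", "mu_b", "mu_c"):
            mu = getattr(self, name)
            if not 0.0 <= mu <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("gamma_g", "gamma_b", "gamma_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.IT < 1:
            raise ValueError("IT must be a positive integer")
        if self.T_max < 0:
            raise ValueError("T_max must be non-negative")
        if len(self.X1) != self.n or len(self.X2) != self.n:
            raise ValueError("X1 and X2 must have length n")
        hi = 1.0 / self.alpha
        for X in (self.X1, self.X2):
            if any(not 0.0 <= v <= hi for v in X):
                raise ValueError("optimum entries must lie in [0, 1/alpha]")
        if self.initial_env not in (E1, E2):
            raise ValueError("initial_env must be 'E1' or 'E2'")
        if self.b_mutation not in ("element", "row"):
            raise ValueError("b_mutation must be 'element' or 'row'")

    # -- derived quantities -------------------------------------------------

    @property
    def x_max(self) -> float:
        """Upper bound 1/alpha of any expression level."""
        return 1.0 / self.alpha

    @property
    def n_loci(self) -> int:
        """Number of scalar loci per genotype: n + n^2 + n."""
        return self.n + self.n * self.n + self.n

    @property
    def adult_steps(self) -> int:
        """Number of developmental steps in the adult phase (inclusive)."""
        return self.tau_l - self.tau_v + 1

    def optimum(self, env: str) -> np.ndarray:
        """Optimal expression pattern for environment ``env`` as an array."""
        if env == E1:
            return np.asarray(self.X1, dtype=float)
        if env == E2:
            return np.asarray(self.X2, dtype=float)
        raise ValueError(f"unknown environment {env!r}")

    def mu_vector(self) -> np.ndarray:
        """Per-locus mutation probabilities in packed order [g | B | c]."""
        n = self.n
        out = np.empty(self.n_loci)
        out[:n] = self.mu_g
        out[n:n + n * n] = self.mu_b
        out[n + n * n:] = self.mu_c
        return out

    def gamma_vector(self) -> np.ndarray:
        """Per-locus maximum mutation effects in packed order [g | B | c]."""
        n = self.n
        out = np.empty(self.n_loci)
        out[:n] = self.gamma_g
        out[n:n + n * n] = self.gamma_b
        out[n + n * n:] = self.gamma_c
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["X1"] = list(d["X1"])
        d["X2"] = list(d["X2"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SimulationParams":
        return cls.from_dict(json.loads(s))

    def params_hash(self) -> str:
        """Short stable digest of every field (identifies a parameter set)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def preset(name: str, **overrides) -> SimulationParams:
    """Return one of the named parameter sets.

    ``full_default``
        Eight type-G genes, N=1000, alpha=0.2, tau_c=10, tau_v=21, tau_l=40,
        sigma=5, all mu=1e-5, all gamma=0.1, X1=(0,0,5,5,5,5,0,0),
        X2=(0,0,5,5,0,0,5,5).
    ``simplified``
        Two type-G genes with X1=(5,0), X2=(0,5), higher mutation rates
        (1e-4) and stronger selection (sigma=5/2); all else as full_default.
    ``intermediate_optima``
        full_default with optima pulled off the expression bounds:
        X1=(1,1,4,4,4,4,1,1), X2=(1,1,4,4,1,1,4,4).

    IT has no table default; it is 1 unless overridden.  Any field of
    :class:`SimulationParams` may be overridden by keyword.
    """
    if name == "full_default":
        p = SimulationParams()
    elif name == "simplified":
        p = SimulationParams(
            n=2,
            mu_g=1e-4, mu_b=1e-4, mu_c=1e-4,
            sigma=2.5,
            X1=(5.0, 0.0), X2=(0.0, 5.0),
        )
    elif name == "intermediate_optima":
        p = SimulationParams(
            X1=(1.0, 1.0, 4.0, 4.0, 4.0, 4.0, 1.0, 1.0),
            X2=(1.0, 1.0, 4.0, 4.0, 1.0, 1.0, 4.0, 4.0),
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    return p.with_overrides(**overrides) if overrides else p
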