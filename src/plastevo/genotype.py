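"""The heritable state of one individual.

A genotype consists of three parts: the embryonic expression vector ``g``
(one entry per expressed gene, bounded to [0, 1/alpha]), the regulatory
matrix ``B`` (entry ``B[i, j]`` is the effect of gene j's expression on gene
i, unbounded), and the sensor-coupling vector ``c`` (the effect of the
sensor input on each gene, unbounded).

Internally the evolution engine stores genotypes as flat rows in packed
order ``[g | B row-major | c]``; :meth:`Genotype.to_vector` and
:meth:`Genotype.from_vector` convert between the two layouts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass
class Genotype:
    g: np.ndarray
    B: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.g = np.atleast_1d(np.asarray(self.g, dtype=float))
        self.B = np.asarray(self.B, dtype=float)
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        n = self.g.shape[0]
        if self.B.shape != (n, n):
            raise ValueError(f"B must be {n}x{n}, got {self.B.shape}")
        if self.c.shape != (n,):
            raise ValueError(f"c must have length {n}, got {self.c.shape}")

    @property
    def n(self) -> int:
        return self.g.shape[0]

    def validate_bounds(self, x_max: float) -> None:
        """Check the invariant 0 <= g_i <= 1/alpha."""
        if np.any(self.g < 0) or np.any(self.g > x_max):
            raise ValueError("g entries must lie in [0, 1/alpha]")

    # -- packed-vector layout ----------------------------------------------

    def to_vector(self) -> np.ndarray:
        """Flatten to packed order [g | B row-major | c]."""
        return np.concatenate([self.g, self.B.ravel(), self.c])

    @classmethod
    def from_vector(cls, vec: np.ndarray, n: int) -> "Genotype":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (n + n * n + n,):
            raise ValueError("packed vector length must be n + n^2 + n")
        return cls(
            g=vec[:n].copy(),
            B=vec[n:n + n * n].reshape(n, n).copy(),
            c=vec[n + n * n:].copy(),
        )

    @classmethod
    def initial(cls, params) -> "Genotype":
        """The ancestral state: g_i = 1/(2 alpha), B = 0, c = 0."""
        n = params.n
        return cls(
            g=np.full(n, 0.5 / params.alpha),
            B=np.zeros((n, n)),
            c=np.zeros(n),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self, params_hash: str | None = None) -> dict:
        d = {
            "n": self.n,
            "g": self.g.tolist(),
            "B": self.B.tolist(),
            "c": self.c.tolist(),
        }
        if params_hash is not None:
            d["params_hash"] = params_hash
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Genotype":
        return cls(g=d["g"], B=d["B"], c=d["c"])

    def to_json(self, params_hash: str | None = None) -> str:
        return json.dumps(self.to_dict(params_hash), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "Genotype":
        return cls.from_dict(json.loads(s))

    def copy(self) -> "Genotype":
        return Genotype(self.g.copy(), self.B.copy(), self.c.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return (
            np.array_equal(self.g, other.g)
            and np.array_equal(self.B, other.B)
            and np.array_equal(self.c, other.c)
        )
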