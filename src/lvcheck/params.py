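"""Parameter containers shared across the package.

The basic currency of the analysis is a set of per-isolate logistic growth
parameters (growth rate ``r`` in 1/h, carrying capacity ``K`` in OD600,
inoculum ``S0`` in OD600, lag time in hours) together with a dimensionless
interaction matrix ``c`` in the spent-medium convention: ``c[i, j]`` is the
effect of isolate *j* on isolate *i*, negative for inhibition, positive for
facilitation, estimated from cell-free spent medium (CFSM) assays as
``c_ij = (K_ij - K_i) / K_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class FitError(RuntimeError):
    """An estimation routine could not produce a usable fit."""


class SchemaError(ValueError):
    """An input table is missing required structure."""


@dataclass(frozen=True)
class LogisticParams:
    """Baseline logistic kinetics of one isolate in one medium.

    Parameters
    ----------
    r : float
        Exponential growth rate (1/h), ``r >= 0``.
    K : float
        Carrying capacity (OD600), ``K > 0``.
    S0 : float
        Initial density (OD600), ``0 < S0 <= K``.
    lag : float
        Lag time before growth starts (h), ``lag >= 0``.
    name : str
        Optional isolate identifier.
    """

    r: float
    K: float
    S0: float
    lag: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.r >= 0.0):
            raise ParameterError(f"growth rate must be >= 0, got {self.r}")
        if not (self.K > 0.0):
            raise ParameterError(f"carrying capacity must be > 0, got {self.K}")
        if not (0.0 < self.S0 <= self.K):
            raise ParameterError(
                f"initial density must satisfy 0 < S0 <= K, got S0={self.S0}, K={self.K}"
            )
        if not (self.lag >= 0.0):
            raise ParameterError(f"lag must be >= 0, got {self.lag}")

    def with_(self, **kwargs) -> "LogisticParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader measurement noise.

    Observed OD is ``max(detection_floor, true * exp(N(0, multiplicative_sd))
    + N(0, additive_sd) + blank_offset)``: lognormal multiplicative noise on
    the true density, Gaussian read noise, and a constant blank (medium
    turbidity) offset. Defaults reflect a well-maintained bench-top reader;
    the study itself reports replicate counts but no error structure.
    """

    multiplicative_sd: float = 0.02
    additive_sd: float = 0.003
    blank_offset: float = 0.0
    detection_floor: float = 0.001

    def __post_init__(self) -> None:
        for f in ("multiplicative_sd", "additive_sd", "blank_offset", "detection_floor"):
            if getattr(self, f) < 0:
                raise ParameterError(f"{f} must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noise-free observation (floor kept at 0 so truth passes through)."""
        return cls(multiplicative_sd=0.0, additive_sd=0.0, blank_offset=0.0,
                   detection_floor=0.0)

    def apply(self, rng: np.random.Generator, true_od: np.ndarray) -> np.ndarray:
        od = np.asarray(true_od, dtype=float)
        if self.multiplicative_sd > 0:
            od = od * np.exp(rng.normal(0.0, self.multiplicative_sd, od.shape))
        if self.additive_sd > 0:
            od = od + rng.normal(0.0, self.additive_sd, od.shape)
        od = od + self.blank_offset
        return np.maximum(od, self.detection_floor)


@dataclass(frozen=True)
class CFSMRecord:
    """One conditioned-growth observation: focal isolate *i* grown in the
    cell-free spent medium of context isolate *j*.

    ``r`` and ``K`` are the growth rate (1/h) and carrying capacity (OD600)
    measured (or predicted) in that medium. ``suppressed`` flags records where
    the predicted capacity was non-positive (growth fully inhibited)."""

    focal: str
    context: str
    r: float
    K: float
    suppressed: bool = False

    def __post_init__(self) -> None:
        if not self.suppressed:
            if self.r < 0 or self.K < 0:
                raise ParameterError("CFSM record requires r >= 0 and K >= 0")


@dataclass
class LVSystem:
    """A community of isolates plus their interaction matrix.

    ``c[i, j]`` is the dimensionless effect of isolate *j* on isolate *i*
    (spent-medium convention; inhibition negative). The diagonal is stored —
    the self-spent-medium assay is a real measurement — but excluded from the
    dynamics, whose self-limitation already lives in ``K_i``.
    """

    isolates: list[LogisticParams]
    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        n = len(self.isolates)
        if self.c.shape != (n, n):
            raise ParameterError(
                f"interaction matrix must be {n}x{n}, got {self.c.shape}"
            )

    @property
    def n(self) -> int:
        return len(self.isolates)

    @property
    def r(self) -> np.ndarray:
        return np.array([p.r for p in self.isolates])

    @property
    def K(self) -> np.ndarray:
        return np.array([p.K for p in self.isolates])

    @property
    def lag(self) -> np.ndarray:
        return np.array([p.lag for p in self.isolates])

    @property
    def names(self) -> list[str]:
        return [p.name or f"isolate{i + 1}" for i, p in enumerate(self.isolates)]

    def K_matrix(self) -> np.ndarray:
        """Conditioned carrying capacities ``K_ij = K_i + c_ij K_j``."""
        K = self.K
        return K[:, None] + self.c * K[None, :]

    def a_matrix(self) -> np.ndarray:
        """Classical LV rate coefficients ``a_ij = c_ij r_i / K_i``."""
        return self.c * (self.r / self.K)[:, None]

    def to_dict(self) -> dict:
        return {
            "isolates": [
                {"name": p.name, "r": p.r, "K": p.K, "S0": p.S0, "lag": p.lag}
                for p in self.isolates
            ],
            "c": self.c.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LVSystem":
        isolates = [
            LogisticParams(r=e["r"], K=e["K"], S0=e["S0"], lag=e.get("lag", 0.0),
                           name=e.get("name", ""))
            for e in d["isolates"]
        ]
        return cls(isolates=isolates, c=np.asarray(d["c"], dtype=float))
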