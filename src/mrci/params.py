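"""Model parameters, sub-model definitions and coordinate transforms.

The full model describes every SNP as a member of one of four components:
``G1`` (specific to trait 1), ``G2`` (specific to trait 2), ``GC``
(pleiotropic, affecting both traits with correlated direct effects) and the
null component ``G0``.  Two reciprocal causal paths ``delta12`` (Y2 -> Y1)
and ``delta21`` (Y1 -> Y2) connect the phenotypes, and three nuisance terms
absorb systematic bias: variance inflation ``a1``/``a2`` (for example
population stratification) and the cross-trait covariance bias ``rho0``
(sample overlap).

Free parameters are optimized in an unconstrained coordinate system:
log scale for variances, mixing proportions and inflation terms; ``atanh``
for the causal effects (bounding them to (-1, 1)); the pleiotropy covariance
through an ``atanh`` of its correlation (so the Cauchy-Schwarz bound holds by
construction); ``rho0`` untransformed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "ModelParams",
    "SubModelSpec",
    "SUBMODELS",
    "FULL_MODEL",
    "ParamTransform",
]

#: Canonical ordering of the full parameter vector theta.
PARAM_NAMES = (
    "pi1",
    "pi2",
    "piC",
    "sigma1_sq",
    "sigma2_sq",
    "sigmaC1_sq",
    "sigmaC2_sq",
    "rhoC1C2",
    "delta12",
    "delta21",
    "a1",
    "a2",
    "rho0",
)

#: Parameters owned by each non-null mixture component.
_COMPONENT_PARAMS = {
    "G1": ("pi1", "sigma1_sq"),
    "G2": ("pi2", "sigma2_sq"),
    "GC": ("piC", "sigmaC1_sq", "sigmaC2_sq", "rhoC1C2"),
}

_LOG_PARAMS = frozenset(
    {"pi1", "pi2", "piC", "sigma1_sq", "sigma2_sq", "sigmaC1_sq", "sigmaC2_sq", "a1", "a2"}
)
_TANH_PARAMS = frozenset({"delta12", "delta21"})

_LOG_FLOOR = 1e-14


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the bivariate mixture model."""

    pi1: float = 0.0
    pi2: float = 0.0
    piC: float = 0.0
    sigma1_sq: float = 0.0
    sigma2_sq: float = 0.0
    sigmaC1_sq: float = 0.0
    sigmaC2_sq: float = 0.0
    rhoC1C2: float = 0.0
    delta12: float = 0.0
    delta21: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    rho0: float = 0.0

    @property
    def pi0(self) -> float:
        """Implied null-component proportion (never a free parameter)."""
        return 1.0 - self.pi1 - self.pi2 - self.piC

    @property
    def pleiotropy_correlation(self) -> float:
        """rhoC1C2 re-expressed as a correlation of the direct effects."""
        denom = math.sqrt(self.sigmaC1_sq * self.sigmaC2_sq)
        if denom == 0.0:
            return 0.0
        return self.rhoC1C2 / denom

    def validate(self) -> None:
        """Raise ``ValueError`` on an inadmissible parameter vector."""
        for name in ("pi1", "pi2", "piC"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pi0 < -1e-12:
            raise ValueError(f"pi0={self.pi0} negative")
        for name in ("sigma1_sq", "sigma2_sq", "sigmaC1_sq", "sigmaC2_sq", "a1", "a2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} negative")
        bound = math.sqrt(self.sigmaC1_sq * self.sigmaC2_sq)
        if abs(self.rhoC1C2) > bound + 1e-12:
            raise ValueError("rhoC1C2 violates Cauchy-Schwarz bound")
        if abs(self.delta12 * self.delta21) >= 1.0:
            raise ValueError("|delta12*delta21| >= 1")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ModelParams":
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, arr)})

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items() if k in PARAM_NAMES})

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def swap_traits(self) -> "ModelParams":
        """Exchange the roles of the two phenotypes (1 <-> 2)."""
        return ModelParams(
            pi1=self.pi2,
            pi2=self.pi1,
            piC=self.piC,
            sigma1_sq=self.sigma2_sq,
            sigma2_sq=self.sigma1_sq,
            sigmaC1_sq=self.sigmaC2_sq,
            sigmaC2_sq=self.sigmaC1_sq,
            rhoC1C2=self.rhoC1C2,
            delta12=self.delta21,
            delta21=self.delta12,
            a1=self.a2,
            a2=self.a1,
            rho0=self.rho0,
        )


@dataclass(frozen=True)
class SubModelSpec:
    """A model in the five-model set, identified by its active components.

    Parameters owned by inactive components are pinned at zero during
    estimation and excluded from the free-parameter count.
    """

    id: str
    active: frozenset

    @property
    def free_names(self) -> tuple:
        names = []
        for name in PARAM_NAMES:
            owner = next(
                (c for c, ps in _COMPONENT_PARAMS.items() if name in ps), None
            )
            if owner is None or owner in self.active:
                names.append(name)
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def pin(self, params: ModelParams) -> ModelParams:
        """Zero every parameter owned by an inactive component."""
        updates = {}
        for comp, names in _COMPONENT_PARAMS.items():
            if comp not in self.active:
                updates.update({n: 0.0 for n in names})
        return params.replace(**updates) if updates else params


SUBMODELS = {
    "s_12C": SubModelSpec("s_12C", frozenset({"G1", "G2", "GC"})),
    "s_2C": SubModelSpec("s_2C", frozenset({"G2", "GC"})),
    "s_1C": SubModelSpec("s_1C", frozenset({"G1", "GC"})),
    "s_12": SubModelSpec("s_12", frozenset({"G1", "G2"})),
    "s_C": SubModelSpec("s_C", frozenset({"GC"})),
}

FULL_MODEL = SUBMODELS["s_12C"]

#: Order in which the model set is fitted and reported.
MODEL_SET_ORDER = ("s_12C", "s_2C", "s_1C", "s_12", "s_C")


class ParamTransform:
    """Bijection between a subset of natural parameters and R^p.

    ``names`` lists the free parameters (a subset of :data:`PARAM_NAMES`,
    in canonical order).  Values not in ``names`` are taken from the ``base``
    parameter vector when mapping back.
    """

    def __init__(self, names, rho0_scale: float = 1.0):
        self.names = tuple(names)
        self._idx = {n: i for i, n in enumerate(self.names)}
        unknown = set(self.names) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names {unknown}")
        # rho0's natural magnitude is O(1/n); optimizing and differentiating
        # it in units of sqrt(n1*n2) puts it on the same footing as the rest
        self.rho0_scale = float(rho0_scale)

    @property
    def n(self) -> int:
        return len(self.names)

    def to_z(self, params: ModelParams) -> np.ndarray:
        z = np.empty(self.n)
        for i, name in enumerate(self.names):
            v = getattr(params, name)
            if name in _LOG_PARAMS:
                z[i] = math.log(max(v, _LOG_FLOOR))
            elif name in _TANH_PARAMS:
                z[i] = math.atanh(np.clip(v, -1 + 1e-9, 1 - 1e-9))
            elif name == "rhoC1C2":
                r = params.pleiotropy_correlation
                z[i] = math.atanh(np.clip(r, -1 + 1e-9, 1 - 1e-9))
            else:  # rho0
                z[i] = v * self.rho0_scale
        return z

    def to_params(self, z, base: ModelParams) -> ModelParams:
        updates = {}
        z = np.asarray(z, dtype=float)
        for i, name in enumerate(self.names):
            if name in _LOG_PARAMS:
                updates[name] = math.exp(min(z[i], 50.0))
            elif name in _TANH_PARAMS:
                updates[name] = math.tanh(z[i])
            elif name == "rhoC1C2":
                continue  # needs the sigmas; second pass below
            else:
                updates[name] = z[i] / self.rho0_scale
        if "rhoC1C2" in self._idx:
            s1 = updates.get("sigmaC1_sq", base.sigmaC1_sq)
            s2 = updates.get("sigmaC2_sq", base.sigmaC2_sq)
            r = math.tanh(z[self._idx["rhoC1C2"]])
            updates["rhoC1C2"] = r * math.sqrt(s1 * s2)
        return base.replace(**updates)

    def jacobian(self, z, base: ModelParams) -> np.ndarray:
        """d(natural)/d(z) at ``z`` -- used to map covariances back."""
        z = np.asarray(z, dtype=float)
        params = self.to_params(z, base)
        G = np.zeros((self.n, self.n))
        for i, name in enumerate(self.names):
            v = getattr(params, name)
            if name in _LOG_PARAMS:
                G[i, i] = v
            elif name in _TANH_PARAMS:
                G[i, i] = 1.0 - v * v
            elif name == "rhoC1C2":
                r = math.tanh(z[i])
                scale = math.sqrt(params.sigmaC1_sq * params.sigmaC2_sq)
                G[i, i] = (1.0 - r * r) * scale
                for sname in ("sigmaC1_sq", "sigmaC2_sq"):
                    j = self._idx.get(sname)
                    if j is not None:
                        G[i, j] = 0.5 * v
            else:
                G[i, i] = 1.0 / self.rho0_scale
        return G
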