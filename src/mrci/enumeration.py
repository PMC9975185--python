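"""Enumeration of latent tagging-set compositions.

For SNP ``k`` with tagging-set size ``N_k*``, the latent variable is the
composition ``N_k = (N^G1, N^G2, N^GC, N^G0)`` counting how many of the
tagged SNPs fall in each mixture component.  Its prior is multinomial with
probabilities ``(pi1, pi2, piC, pi0)`` and size ``N_k*``.

The likelihood sums over all compositions; because the non-null proportions
are tiny (1e-4 .. 1e-3 in typical architectures), compositions with several
causal tags carry negligible prior mass.  The sum is therefore truncated:
per-component counts are capped at ``c_max`` and the total non-null count at
``c_total``, and the multinomial prior is renormalized over the retained set.
Setting both caps at ``N_k*`` (or above) makes the enumeration exhaustive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .params import ModelParams

__all__ = ["ComponentCounts", "component_count_prob", "EnumerationPlan"]

_ACTIVE_ALL = frozenset({"G1", "G2", "GC"})


@dataclass(frozen=True)
class ComponentCounts:
    """Composition of one SNP's tagging set across the four components."""

    n_g1: int
    n_g2: int
    n_gc: int
    n_g0: int

    @property
    def total(self) -> int:
        return self.n_g1 + self.n_g2 + self.n_gc + self.n_g0

    def as_tuple(self):
        return (self.n_g1, self.n_g2, self.n_gc, self.n_g0)


def component_count_prob(counts: ComponentCounts, params: ModelParams) -> float:
    """Exact multinomial prior probability of one composition.

    This is the untruncated pmf; :class:`EnumerationPlan` renormalizes over
    its truncated composition set.
    """
    n = counts.as_tuple()
    if any(c < 0 for c in n):
        raise ValueError("negative component counts")
    p = np.array([params.pi1, params.pi2, params.piC, params.pi0], dtype=float)
    if p[3] < -1e-12:
        raise ValueError("pi0 negative")
    p = np.clip(p, 0.0, 1.0)
    n_arr = np.array(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(n_arr > 0, n_arr * np.log(p), 0.0)
    if np.any(np.isneginf(logterm) | np.isnan(logterm)):
        return 0.0
    logcoef = gammaln(counts.total + 1) - gammaln(n_arr + 1).sum()
    return float(math.exp(logcoef + logterm.sum()))


def _compositions(nstar: int, caps: dict, c_total: int):
    """All (n_g1, n_g2, n_gc) with per-component caps and a total cap."""
    out = []
    t_cap = min(nstar, c_total)
    for a in range(min(caps["G1"], t_cap) + 1):
        for b in range(min(caps["G2"], t_cap - a) + 1):
            for c in range(min(caps["GC"], t_cap - a - b) + 1):
                out.append((a, b, c, nstar - a - b - c))
    return np.array(out, dtype=np.int64)


class EnumerationPlan:
    """Truncated composition sets, cached per distinct tagging-set size.

    Parameters
    ----------
    n_tagged_values : iterable of int
        The distinct ``N_k*`` values occurring in the dataset.
    c_max : int
        Per-component cap on the number of causal tags.
    c_total : int
        Cap on the total number of non-null tags across components.
    active : frozenset
        Active components of the sub-model being fitted; compositions with
        causal tags in inactive components are excluded outright.
    """

    def __init__(self, n_tagged_values, c_max: int = 4, c_total: int = 4,
                 active=_ACTIVE_ALL):
        self.c_max = int(c_max)
        self.c_total = int(c_total)
        self.active = frozenset(active)
        caps = {h: (self.c_max if h in self.active else 0) for h in _ACTIVE_ALL}
        self._table = {}
        for nstar in sorted(set(int(v) for v in n_tagged_values)):
            if nstar < 1:
                raise ValueError("tagging-set size must be >= 1")
            counts = _compositions(nstar, caps, self.c_total)
            logcoef = (
                gammaln(nstar + 1) - gammaln(counts + 1.0).sum(axis=1)
            )
            self._table[nstar] = (counts, logcoef)

    @property
    def n_tagged_values(self):
        return tuple(self._table.keys())

    def counts(self, nstar: int) -> np.ndarray:
        """(C, 4) integer array of enumerated compositions for ``nstar``."""
        return self._table[int(nstar)][0]

    def log_priors(self, nstar: int, params: ModelParams) -> np.ndarray:
        """Renormalized log prior over the truncated composition set."""
        counts, logcoef = self._table[int(nstar)]
        logp = logcoef + self._log_pi_terms(counts, params)
        return logp - logsumexp(logp)

    def prior_mass(self, nstar: int, params: ModelParams) -> float:
        """Untruncated multinomial mass captured by the enumerated set."""
        counts, logcoef = self._table[int(nstar)]
        return float(np.exp(logsumexp(logcoef + self._log_pi_terms(counts, params))))

    @staticmethod
    def _log_pi_terms(counts: np.ndarray, params: ModelParams) -> np.ndarray:
        p = np.array(
            [params.pi1, params.pi2, params.piC, max(params.pi0, 0.0)], dtype=float
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.log(p)
            terms = counts * logp[None, :]
        terms = np.where(counts == 0, 0.0, terms)
        return terms.sum(axis=1)

    @classmethod
    def for_dataset(cls, data, c_max: int = 4, c_total: int = 4,
                    active=_ACTIVE_ALL) -> "EnumerationPlan":
        return cls(np.unique(data.n_tagged), c_max=c_max, c_total=c_total,
                   active=active)
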