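"""Synthetic bivariate GWAS summary statistics under the reciprocal model.

The generator reproduces the study conditions the estimator is built for:

* four-component SNP membership with exact causal counts ``round(pi_h * M)``,
* normal direct effects, correlated across traits for the pleiotropic
  component, with per-SNP variances derived from target heritabilities as
  ``sigma^2 = h^2 / (pi * M)``,
* reciprocal causal mixing of direct into joint effects through
  ``[I - Delta]^{-1}``,
* LD-induced marginal effects ``tau = R beta`` inside AR-1 correlation
  blocks,
* sampling noise with per-trait variance ``1/n + a`` and cross-trait
  covariance ``rho0`` (sample overlap), correlated across SNPs through the
  same block correlation.

A small individual-level simulator (genotypes thresholded from a latent
block-multivariate normal, phenotypes built from the structural equations,
per-SNP least squares) serves as the ground-truth oracle for the
summary-level path at small scale.

Drawn effect vectors are rescaled so each component's realized heritability
hits its target exactly (the residual-scaling convention of standard
phenotype simulators); second moments of the effect distribution are
preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm

from .data import LdReference, SummaryDataset
from .params import ModelParams

__all__ = [
    "SimulationScenario",
    "LdStructure",
    "build_ld_structure",
    "assign_components_and_effects",
    "direct_to_joint",
    "simulate_marginal_estimates",
    "simulate_summary_dataset",
    "simulate_individual_level",
    "scenario",
    "SCENARIO_NAMES",
]

#: Component codes used in label arrays.
NULL, G1, G2, GC = 0, 1, 2, 3


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth parameters and LD/architecture settings for one run."""

    name: str = "custom"
    M: int = 30_000
    n1: int = 50_000
    n2: int = 50_000
    pi1: float = 1e-3
    pi2: float = 1e-3
    piC: float = 1e-3
    h2_1spec: float = 0.3
    h2_2spec: float = 0.3
    h2_pleio: float = 0.1
    pleiotropy_corr: float = 0.1
    delta12: float = 0.1
    delta21: float = 0.05
    overlap_fraction: float = 1.0
    a1: float = 0.0
    a2: float = 0.0
    block_size: int = 50
    ar1_r: float = 0.5
    tag_r2_threshold: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if abs(self.delta12 * self.delta21) >= 1.0:
            raise ValueError("|delta12*delta21| >= 1")
        for pi, h2 in ((self.pi1, self.h2_1spec), (self.pi2, self.h2_2spec),
                       (self.piC, self.h2_pleio)):
            if h2 > 0 and pi * self.M < 1:
                raise ValueError("active component has pi*M < 1")

    # -- derived per-SNP parameters -------------------------------------
    @property
    def sigma1_sq(self) -> float:
        return self.h2_1spec / (self.pi1 * self.M) if self.pi1 > 0 else 0.0

    @property
    def sigma2_sq(self) -> float:
        return self.h2_2spec / (self.pi2 * self.M) if self.pi2 > 0 else 0.0

    @property
    def sigmaC1_sq(self) -> float:
        return self.h2_pleio / (self.piC * self.M) if self.piC > 0 else 0.0

    @property
    def sigmaC2_sq(self) -> float:
        return self.h2_pleio / (self.piC * self.M) if self.piC > 0 else 0.0

    @property
    def rhoC1C2(self) -> float:
        return self.pleiotropy_corr * math.sqrt(self.sigmaC1_sq * self.sigmaC2_sq)

    def phenotypic_covariance(self) -> np.ndarray:
        """2x2 covariance of the standardized phenotypes implied by the model.

        Residual variances are solved so both phenotypes have unit variance
        after the reciprocal feedback; raises if the heritabilities leave no
        room for a non-negative residual.
        """
        d = np.array([[0.0, self.delta12], [self.delta21, 0.0]])
        B = np.linalg.inv(np.eye(2) - d)
        rho_pl = self.pleiotropy_corr * self.h2_pleio if self.piC > 0 else 0.0
        vg = np.array(
            [
                [self.h2_1spec + (self.h2_pleio if self.piC > 0 else 0.0), rho_pl],
                [rho_pl, self.h2_2spec + (self.h2_pleio if self.piC > 0 else 0.0)],
            ]
        )
        # Solve diag(B (vg + diag(e)) B') = 1 for the residual variances e.
        A = B ** 2  # elementwise squares hit the diagonal terms
        rhs = 1.0 - np.diag(B @ vg @ B.T)
        e = np.linalg.solve(A, rhs)
        if np.any(e < -1e-9):
            raise ValueError("heritability targets exceed unit phenotype variance")
        e = np.clip(e, 0.0, None)
        return B @ (vg + np.diag(e)) @ B.T

    @property
    def rho0(self) -> float:
        """Sample-overlap covariance bias of the paired estimation errors."""
        if self.overlap_fraction == 0.0:
            return 0.0
        n_shared = self.overlap_fraction * min(self.n1, self.n2)
        rho_y = self.phenotypic_covariance()[0, 1]
        return n_shared * rho_y / (self.n1 * self.n2)

    def true_params(self) -> ModelParams:
        return ModelParams(
            pi1=self.pi1,
            pi2=self.pi2,
            piC=self.piC,
            sigma1_sq=self.sigma1_sq,
            sigma2_sq=self.sigma2_sq,
            sigmaC1_sq=self.sigmaC1_sq,
            sigmaC2_sq=self.sigmaC2_sq,
            rhoC1C2=self.rhoC1C2,
            delta12=self.delta12,
            delta21=self.delta21,
            a1=self.a1,
            a2=self.a2,
            rho0=self.rho0,
        )

    def replace(self, **kwargs) -> "SimulationScenario":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------

def _base(**kw) -> SimulationScenario:
    return SimulationScenario(**kw)


_CAUSATION = {
    "null": dict(delta12=0.0, delta21=0.0),
    "uni": dict(delta12=0.1, delta21=0.0),
    "bi": dict(delta12=0.1, delta21=0.05),
}

_PRESETS: dict = {}

# Low-polygenicity full model: pi = 1e-4, independent or correlated pleiotropy.
for caus, dd in _CAUSATION.items():
    for pl, rho in (("indep", 0.0), ("corr", 0.1)):
        _PRESETS[f"los-{caus}-{pl}"] = dict(
            pi1=1e-4, pi2=1e-4, piC=1e-4, pleiotropy_corr=rho, **dd
        )

# High-polygenicity full model: pi = 1e-3, correlated pleiotropy.
for caus, dd in _CAUSATION.items():
    _PRESETS[f"his-{caus}"] = dict(
        pi1=1e-3, pi2=1e-3, piC=1e-3, pleiotropy_corr=0.1, **dd
    )

# Sub-model data: one or two components absent (pi = 1e-3 for the present
# ones, correlated pleiotropy where the pleiotropic component is present).
for caus, dd in _CAUSATION.items():
    _PRESETS[f"s2c-{caus}"] = dict(
        pi1=0.0, pi2=1e-3, piC=1e-3, h2_1spec=0.0, pleiotropy_corr=0.1, **dd
    )
    _PRESETS[f"s12-{caus}"] = dict(
        pi1=1e-3, pi2=1e-3, piC=0.0, h2_pleio=0.0, pleiotropy_corr=0.0, **dd
    )
    _PRESETS[f"sc-{caus}"] = dict(
        pi1=0.0, pi2=0.0, piC=1e-3, h2_1spec=0.0, h2_2spec=0.0,
        pleiotropy_corr=0.1, **dd
    )

# Small-sample variant of the bi-directional full model.
_PRESETS["small-sample-bi"] = dict(
    pi1=1e-3, pi2=1e-3, piC=1e-3, pleiotropy_corr=0.1,
    n1=20_000, n2=20_000, **_CAUSATION["bi"]
)

SCENARIO_NAMES = tuple(sorted(_PRESETS))


def scenario(name: str, **overrides) -> SimulationScenario:
    """Look up a named preset, optionally overriding fields."""
    if name not in _PRESETS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIO_NAMES)}"
        )
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return SimulationScenario(name=name, **kw)


# ---------------------------------------------------------------------------
# LD structure
# ---------------------------------------------------------------------------

@dataclass
class LdStructure:
    """Block AR-1 LD: reference summaries plus the block correlations."""

    reference: LdReference
    block_slices: list
    block_corr: list  # per-block correlation matrix R

    @property
    def M(self) -> int:
        return len(self.reference.snp_ids)


def build_ld_structure(scn: SimulationScenario) -> LdStructure:
    """Partition M SNPs into AR-1 blocks and derive the LD reference.

    Within a block the correlation between SNPs i and k is ``r^|i-k|``; the
    LD score is the within-block sum of squared correlations (self term
    included) and the tagging set keeps pairs with ``r^2 >=`` the threshold.
    """
    M, bs, r = scn.M, scn.block_size, scn.ar1_r
    snp_ids = np.array([f"rs{i:07d}" for i in range(M)], dtype=object)
    slices = [slice(s, min(s + bs, M)) for s in range(0, M, bs)]
    corr_cache: dict = {}
    ld_score = np.empty(M)
    rows, cols = [], []
    for sl in slices:
        size = sl.stop - sl.start
        if size not in corr_cache:
            d = np.abs(np.subtract.outer(np.arange(size), np.arange(size)))
            corr_cache[size] = r ** d if r != 0.0 else np.eye(size)
        R = corr_cache[size]
        R2 = R * R
        ld_score[sl] = R2.sum(axis=1)
        tag = R2 >= scn.tag_r2_threshold
        ii, jj = np.nonzero(tag)
        rows.append(ii + sl.start)
        cols.append(jj + sl.start)
    adj = sp.coo_matrix(
        (np.ones(sum(len(x) for x in rows), dtype=np.int8),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(M, M),
    ).tocsr()
    ref = LdReference(snp_ids, ld_score, adj)
    block_corr = [corr_cache[sl.stop - sl.start] for sl in slices]
    return LdStructure(ref, slices, block_corr)


# ---------------------------------------------------------------------------
# effect assignment
# ---------------------------------------------------------------------------

def _rescale(vec: np.ndarray, target: float) -> np.ndarray:
    """Scale a draw so its sum of squares equals the target exactly."""
    ss = float(vec @ vec)
    if ss == 0.0 or target == 0.0:
        return np.zeros_like(vec)
    return vec * math.sqrt(target / ss)


def assign_components_and_effects(scn: SimulationScenario, rng: np.random.Generator):
    """Draw component labels and direct effect sizes.

    Exact counts ``round(pi_h * M)`` per component are sampled without
    replacement; effects are normal draws, rescaled so each component's
    realized heritability contribution equals its target.

    Returns ``(labels, gamma1, gamma2)``.
    """
    M = scn.M
    counts = {
        G1: int(round(scn.pi1 * M)),
        G2: int(round(scn.pi2 * M)),
        GC: int(round(scn.piC * M)),
    }
    total = sum(counts.values())
    labels = np.zeros(M, dtype=np.int8)
    chosen = rng.choice(M, size=total, replace=False)
    ofs = 0
    for comp in (G1, G2, GC):
        labels[chosen[ofs : ofs + counts[comp]]] = comp
        ofs += counts[comp]
    gamma1 = np.zeros(M)
    gamma2 = np.zeros(M)
    i1 = labels == G1
    i2 = labels == G2
    ic = labels == GC
    if counts[G1]:
        gamma1[i1] = _rescale(
            rng.normal(0.0, math.sqrt(scn.sigma1_sq), counts[G1]), scn.h2_1spec
        )
    if counts[G2]:
        gamma2[i2] = _rescale(
            rng.normal(0.0, math.sqrt(scn.sigma2_sq), counts[G2]), scn.h2_2spec
        )
    if counts[GC]:
        # draw directions, then pin the realized (non-centered) correlation
        # and both heritability contributions exactly -- the pleiotropy
        # analogue of the exact-count / exact-h2 convention above
        r = scn.pleiotropy_corr
        n_c = counts[GC]
        u = rng.standard_normal(n_c)
        v = rng.standard_normal(n_c)
        if n_c >= 2 and abs(r) < 1.0:
            u_hat = u / np.linalg.norm(u)
            v_perp = v - (v @ u_hat) * u_hat
            v_hat = v_perp / np.linalg.norm(v_perp)
            dir2 = r * u_hat + math.sqrt(1.0 - r * r) * v_hat
        else:
            u_hat = u / np.linalg.norm(u)
            dir2 = math.copysign(1.0, r if r != 0 else 1.0) * u_hat
        gamma1[ic] = math.sqrt(scn.h2_pleio) * u_hat
        gamma2[ic] = math.sqrt(scn.h2_pleio) * dir2
    return labels, gamma1, gamma2


def direct_to_joint(gamma1, gamma2, delta12: float, delta21: float):
    """Convert direct effects to joint effects via ``[I - Delta]^{-1}``."""
    prod = delta12 * delta21
    if abs(prod) >= 1.0:
        raise ValueError("|delta12*delta21| >= 1")
    denom = 1.0 - prod
    beta1 = (np.asarray(gamma1, float) + delta12 * np.asarray(gamma2, float)) / denom
    beta2 = (np.asarray(gamma2, float) + delta21 * np.asarray(gamma1, float)) / denom
    return beta1, beta2


# ---------------------------------------------------------------------------
# summary-level simulation
# ---------------------------------------------------------------------------

def simulate_marginal_estimates(
    scn: SimulationScenario,
    ld: LdStructure,
    beta1: np.ndarray,
    beta2: np.ndarray,
    rng: np.random.Generator,
) -> SummaryDataset:
    """Draw the bivariate marginal-effect estimates given joint effects.

    True marginals are ``tau = R beta`` within each block; estimation noise
    is matrix-normal with row covariance R (LD) and column covariance
    ``[[1/n1 + a1, rho0], [rho0, 1/n2 + a2]]`` (sampling error, inflation
    and sample overlap).
    """
    M = ld.M
    tau1 = np.empty(M)
    tau2 = np.empty(M)
    col_cov = np.array(
        [
            [1.0 / scn.n1 + scn.a1, scn.rho0],
            [scn.rho0, 1.0 / scn.n2 + scn.a2],
        ]
    )
    Lc = np.linalg.cholesky(col_cov)
    chol_cache: dict = {}
    for sl, R in zip(ld.block_slices, ld.block_corr):
        size = sl.stop - sl.start
        if size not in chol_cache:
            chol_cache[size] = np.linalg.cholesky(
                R + 1e-10 * np.eye(size)
            )
        Lr = chol_cache[size]
        z = rng.standard_normal((size, 2))
        noise = Lr @ z @ Lc.T
        tau1[sl] = R @ beta1[sl] + noise[:, 0]
        tau2[sl] = R @ beta2[sl] + noise[:, 1]
    return SummaryDataset(
        ld.reference.snp_ids,
        tau1,
        tau2,
        ld.reference.ld_score,
        ld.reference.adjacency,
        scn.n1,
        scn.n2,
    )


def simulate_summary_dataset(scn: SimulationScenario, seed=None):
    """One-call generator: LD, labels, effects and summary estimates.

    Returns ``(dataset, truth)`` where ``truth`` carries the true parameter
    vector, component labels and the direct/joint effects. Byte-identical
    output under a fixed seed.
    """
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    ld = build_ld_structure(scn)
    labels, gamma1, gamma2 = assign_components_and_effects(scn, rng)
    beta1, beta2 = direct_to_joint(gamma1, gamma2, scn.delta12, scn.delta21)
    data = simulate_marginal_estimates(scn, ld, beta1, beta2, rng)
    truth = {
        "params": scn.true_params(),
        "labels": labels,
        "gamma1": gamma1,
        "gamma2": gamma2,
        "beta1": beta1,
        "beta2": beta2,
        "scenario": scn,
    }
    return data, truth


# ---------------------------------------------------------------------------
# individual-level oracle (small scale only)
# ---------------------------------------------------------------------------

def simulate_individual_level(scn: SimulationScenario, seed=None, maf_range=(0.05, 0.5)):
    """Individual-level ground-truth simulation at oracle scale.

    Genotypes arise from a latent block-multivariate normal thresholded into
    {0, 1, 2} under Hardy-Weinberg at uniform MAFs, then standardized.
    Phenotypes follow the structural equations with residuals scaled for
    unit variance; per-SNP least squares gives the marginal estimates.

    Returns a dict with genotypes ``X`` (n x M), phenotypes ``Y`` (n x 2),
    the per-SNP estimates ``tau1_hat``/``tau2_hat`` and the joint effects.
    """
    n = min(scn.n1, scn.n2)
    if scn.M > 5000 or n > 5000:
        raise ValueError("individual-level oracle limited to M<=5000, n<=5000")
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    ld = build_ld_structure(scn)
    labels, gamma1, gamma2 = assign_components_and_effects(scn, rng)
    beta1, beta2 = direct_to_joint(gamma1, gamma2, scn.delta12, scn.delta21)

    maf = rng.uniform(*maf_range, size=scn.M)
    thr = norm.ppf(maf)
    X = np.empty((n, scn.M))
    for sl, R in zip(ld.block_slices, ld.block_corr):
        size = sl.stop - sl.start
        L = np.linalg.cholesky(R + 1e-10 * np.eye(size))
        hap1 = (rng.standard_normal((n, size)) @ L.T) < thr[sl]
        hap2 = (rng.standard_normal((n, size)) @ L.T) < thr[sl]
        X[:, sl] = hap1.astype(float) + hap2.astype(float)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd

    g = np.column_stack([X @ beta1, X @ beta2])
    # residuals mixed through the reciprocal feedback, as in the scenario's
    # phenotypic-covariance bookkeeping
    d = np.array([[0.0, scn.delta12], [scn.delta21, 0.0]])
    B = np.linalg.inv(np.eye(2) - d)
    cov_y = scn.phenotypic_covariance()
    vg = np.array(
        [
            [scn.h2_1spec + (scn.h2_pleio if scn.piC > 0 else 0.0),
             scn.pleiotropy_corr * scn.h2_pleio if scn.piC > 0 else 0.0],
            [scn.pleiotropy_corr * scn.h2_pleio if scn.piC > 0 else 0.0,
             scn.h2_2spec + (scn.h2_pleio if scn.piC > 0 else 0.0)],
        ]
    )
    A = B ** 2
    evar = np.linalg.solve(A, 1.0 - np.diag(B @ vg @ B.T))
    evar = np.clip(evar, 0.0, None)
    e = rng.standard_normal((n, 2)) * np.sqrt(evar)
    Y = g + e @ B.T

    tau1_hat = X.T @ Y[:, 0] / n
    tau2_hat = X.T @ Y[:, 1] / n
    return {
        "X": X,
        "Y": Y,
        "genetic_values": g,
        "tau1_hat": tau1_hat,
        "tau2_hat": tau2_hat,
        "beta1": beta1,
        "beta2": beta2,
        "labels": labels,
        "cov_y": cov_y,
    }
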