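"""Composite-likelihood maximization by a generalized EM algorithm.

Each iteration alternates:

1. **E-step** -- posterior responsibilities of every enumerated tagging-set
   composition given the current parameters;
2. **closed-form M-step** for the mixing proportions -- the expected fraction
   of tagged slots falling in each component (the complete-data maximizer
   under the multinomial prior);
3. **Nelder-Mead M-step** for the continuous block (variances, pleiotropy
   covariance, causal effects, inflation and overlap terms), ascending the
   observed composite likelihood in unconstrained coordinates with the
   mixing proportions held fixed (an ECM-style conditional maximization,
   which preserves the monotone-CL guarantee).

Inactive components of a sub-model are pinned at zero throughout and their
compositions are excluded from the enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data import SummaryDataset
from .enumeration import EnumerationPlan
from .likelihood import LikelihoodWorkspace
from .params import FULL_MODEL, ModelParams, ParamTransform, SubModelSpec

__all__ = [
    "FitConfig",
    "FitResult",
    "e_step",
    "m_step_mixing",
    "m_step_continuous",
    "moment_init",
    "fit_model",
]

_PI_NAMES = ("pi1", "pi2", "piC")


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs for one EM fit (all iteration counts are positive)."""

    max_em_iter: int = 45
    cl_tol: float = 5e-3
    nm_max_eval: int = 100
    nm_xatol: float = 1e-4
    nm_fatol: float = 1e-3
    c_max: int = 4
    c_total: int = 3
    n_starts: int = 1
    seed: int = 0
    clamp_abort_fraction: float = 0.01
    # label-swap correction: at convergence, propose exchanging a trait's
    # specific and pleiotropic variance mass, advance a few EM steps, and
    # adopt the swap only if the CL clearly improves
    swap_check: bool = True
    swap_em_iter: int = 3
    swap_margin: float = 0.5
    # null-preferring resolution of likelihood-equivalent causal
    # parameterizations: a causal path and the pleiotropy covariance can be
    # exactly interchangeable (pleiotropy-dominated data); when the
    # delta = 0 profile is within null_margin CL units of the maximum, the
    # null-compatible point is reported
    null_check: bool = True
    null_margin: float = 1.0

    def __post_init__(self):
        if min(self.max_em_iter, self.nm_max_eval, self.n_starts, self.c_max,
               self.c_total) < 1:
            raise ValueError("iteration counts must be positive")


@dataclass
class FitResult:
    """Maximum composite-likelihood estimate for one sub-model."""

    params_hat: ModelParams
    cl: float
    submodel: SubModelSpec
    n_iter: int
    converged: bool
    trace: list = field(default_factory=list)
    clamp_count: int = 0
    clamp_fraction: float = 0.0
    seed: int | None = None
    config: FitConfig | None = None

    def to_dict(self) -> dict:
        return {
            "submodel": self.submodel.id,
            "cl": self.cl,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "params": self.params_hat.to_dict(),
            "trace": list(self.trace),
            "clamp_fraction": self.clamp_fraction,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# E-step and M-steps
# ---------------------------------------------------------------------------

def _e_step_ws(ws: LikelihoodWorkspace, params: ModelParams):
    """Responsibilities r_k(N) over compositions, grouped by tag count."""
    out = []
    for g, logterms in ws.log_terms(params):
        norm = logsumexp(logterms, axis=1, keepdims=True)
        bad = np.flatnonzero(~np.isfinite(norm.ravel()))
        if bad.size:
            snp = ws.data.snp_ids[g["idx"][bad[0]]]
            raise FloatingPointError(f"zero posterior mass at SNP {snp}")
        out.append((g, np.exp(logterms - norm)))
    return out


def e_step(data: SummaryDataset, params: ModelParams, plan: EnumerationPlan):
    """Spec-level E-step on a dataset; see :func:`_e_step_ws`."""
    return _e_step_ws(LikelihoodWorkspace(data, plan), params)


def m_step_mixing(responsibilities, data: SummaryDataset):
    """Closed-form update of (pi1, pi2, piC).

    The expected number of tagged slots in each component, divided by the
    total number of tagged slots: the maximizer of the expected
    complete-data log-likelihood under the multinomial prior.
    """
    num = np.zeros(3)
    denom = float(np.sum(data.n_tagged))
    for g, resp in responsibilities:
        counts = g["counts"][:, :3].astype(float)
        num += (resp @ counts).sum(axis=0)
    pis = num / denom
    return float(pis[0]), float(pis[1]), float(pis[2])


def _continuous_transform(submodel: SubModelSpec, data: SummaryDataset) -> ParamTransform:
    names = [n for n in submodel.free_names if n not in _PI_NAMES]
    return ParamTransform(names, rho0_scale=np.sqrt(data.n1 * data.n2))


def m_step_continuous(
    ws: LikelihoodWorkspace,
    params: ModelParams,
    submodel: SubModelSpec,
    config: FitConfig,
):
    """Nelder-Mead ascent of the observed CL over the continuous block.

    Returns ``(params, cl)`` with ``cl`` never below the incoming value
    minus the Nelder-Mead ``fatol`` (the incoming point is a simplex vertex,
    and the better point is kept on any optimizer failure).
    """
    transform = _continuous_transform(submodel, ws.data)
    z0 = transform.to_z(params)

    def objective(z):
        cand = transform.to_params(z, params)
        try:
            cl = ws.cl(cand)
        except FloatingPointError:
            return 1e12
        return -cl if np.isfinite(cl) else 1e12

    f0 = objective(z0)
    res = minimize(
        objective,
        z0,
        method="Nelder-Mead",
        options={
            "maxfev": config.nm_max_eval,
            "xatol": config.nm_xatol,
            "fatol": config.nm_fatol,
            "adaptive": True,
        },
    )
    if np.isfinite(res.fun) and res.fun <= f0:
        return transform.to_params(res.x, params), -float(res.fun)
    return params, -float(f0)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def moment_init(
    data: SummaryDataset,
    submodel: SubModelSpec = FULL_MODEL,
    specific_share: float = 0.5,
) -> ModelParams:
    """Method-of-moments style starting values.

    Mixing proportions from the excess of |z| > 2 SNPs spread over the mean
    tag count; genetic variances from the LD-score-deflated second moments,
    split evenly between the active trait-specific and pleiotropic
    components; overlap covariance from null-looking SNPs; causal effects
    from crude ratio (Wald-type) estimates over strongly associated SNPs --
    pleiotropy-contaminated, but a far better basin of attraction than zero.
    """
    n1, n2 = data.n1, data.n2
    z1 = data.tau1 * np.sqrt(n1)
    z2 = data.tau2 * np.sqrt(n2)
    ell_bar = float(np.mean(data.ld_score))
    K = data.K

    excess = 0.5 * (
        max(np.mean(np.abs(z1) > 2) - 0.0455, 1e-4)
        + max(np.mean(np.abs(z2) > 2) - 0.0455, 1e-4)
    )
    pi_guess = float(np.clip(excess / max(np.mean(data.n_tagged), 1.0), 1e-5, 5e-3))

    h1 = max(K * (np.mean(data.tau1**2) - 1.0 / n1) / ell_bar, 1e-4)
    h2 = max(K * (np.mean(data.tau2**2) - 1.0 / n2) / ell_bar, 1e-4)

    null_mask = (np.abs(z1) < 1.0) & (np.abs(z2) < 1.0)
    rho0 = float(np.mean(data.tau1[null_mask] * data.tau2[null_mask])) if null_mask.any() else 0.0

    # crude ratio estimates over exposure-specific-looking instruments:
    # strong in the exposure, weak in the outcome.  The second condition
    # excludes pleiotropic SNPs, whose ratio reflects the effect correlation
    # rather than causation -- without it, scenarios dominated by pleiotropy
    # start (and, where the causal path is weakly identified, stay) biased.
    d12 = d21 = 0.0
    s_exp1 = (np.abs(z1) > 4.0) & (np.abs(z2) < 0.5 * np.abs(z1))
    s_exp2 = (np.abs(z2) > 4.0) & (np.abs(z1) < 0.5 * np.abs(z2))
    if np.count_nonzero(s_exp1) >= 5:
        t1s, t2s = data.tau1[s_exp1], data.tau2[s_exp1]
        d21 = float(np.clip((t1s @ t2s) / (t1s @ t1s), -0.5, 0.5))
    if np.count_nonzero(s_exp2) >= 5:
        t1s, t2s = data.tau1[s_exp2], data.tau2[s_exp2]
        d12 = float(np.clip((t2s @ t1s) / (t2s @ t2s), -0.5, 0.5))

    active = submodel.active
    kw = dict(delta12=d12, delta21=d21, a1=0.05 / n1, a2=0.05 / n2, rho0=rho0)
    share1 = specific_share if ("G1" in active and "GC" in active) else 1.0
    share2 = specific_share if ("G2" in active and "GC" in active) else 1.0
    if "G1" in active:
        kw["pi1"] = pi_guess
        kw["sigma1_sq"] = share1 * h1 / (pi_guess * K)
    if "G2" in active:
        kw["pi2"] = pi_guess
        kw["sigma2_sq"] = share2 * h2 / (pi_guess * K)
    if "GC" in active:
        kw["piC"] = pi_guess
        shareC1 = (1.0 - share1) if "G1" in active else 1.0
        shareC2 = (1.0 - share2) if "G2" in active else 1.0
        kw["sigmaC1_sq"] = shareC1 * h1 / (pi_guess * K)
        kw["sigmaC2_sq"] = shareC2 * h2 / (pi_guess * K)
        # residual cross-trait genetic covariance after the causal-path
        # share implied by the delta starts; assigning the full residual to
        # the pleiotropy covariance keeps weakly identified causal paths
        # from soaking it up instead
        cg = K * (np.mean(data.tau1 * data.tau2) - rho0) / ell_bar
        cg_resid = cg - d21 * share1 * h1 - d12 * share2 * h2
        bound = 0.9 * np.sqrt(kw["sigmaC1_sq"] * kw["sigmaC2_sq"])
        kw["rhoC1C2"] = float(np.clip(cg_resid / (pi_guess * K), -bound, bound))
    return ModelParams(**kw)


# ---------------------------------------------------------------------------
# full EM driver
# ---------------------------------------------------------------------------

def _swap_proposals(p: ModelParams, submodel: SubModelSpec):
    """Candidates exchanging a trait's specific and pleiotropic h2 mass.

    The mixture is nearly invariant under reallocating one trait's genetic
    variance between its specific component and the pleiotropic component,
    which creates competing local optima.  Each proposal swaps the per-trait
    heritability masses (pi * sigma^2) while preserving the pleiotropy
    correlation.
    """
    if "GC" not in submodel.active or p.piC <= 0:
        return
    r = p.pleiotropy_correlation
    for trait in (1, 2):
        if trait == 1 and ("G1" in submodel.active) and p.pi1 > 0:
            s_new = p.piC * p.sigmaC1_sq / p.pi1
            c_new = p.pi1 * p.sigma1_sq / p.piC
            q = p.replace(sigma1_sq=s_new, sigmaC1_sq=c_new)
        elif trait == 2 and ("G2" in submodel.active) and p.pi2 > 0:
            s_new = p.piC * p.sigmaC2_sq / p.pi2
            c_new = p.pi2 * p.sigma2_sq / p.piC
            q = p.replace(sigma2_sq=s_new, sigmaC2_sq=c_new)
        else:
            continue
        yield q.replace(
            rhoC1C2=r * np.sqrt(q.sigmaC1_sq * q.sigmaC2_sq)
        )


def _swap_correction(ws, submodel, config, params, cl, trace, converged, n_iter):
    """Escape label-swapped local optima by short EM runs from proposals."""
    probe_cfg = replace(
        config,
        max_em_iter=config.swap_em_iter,
        nm_max_eval=min(60, config.nm_max_eval),
        cl_tol=1e-9,
        swap_check=False,
    )
    best = (cl, None)
    for cand in _swap_proposals(params, submodel):
        p, tr, _, _ = _run_em(ws, cand, submodel, probe_cfg)
        if tr and tr[-1] > best[0] + config.swap_margin:
            best = (tr[-1], p)
    if best[1] is not None:
        cont_cfg = replace(config, max_em_iter=min(30, config.max_em_iter))
        params2, trace2, converged2, n_iter2 = _run_em(
            ws, best[1], submodel, cont_cfg
        )
        if trace2 and trace2[-1] > cl:
            return params2, trace2[-1], trace + trace2, converged2, n_iter + n_iter2
    return params, cl, trace, converged, n_iter

@dataclass(frozen=True)
class _DeltaFrozen(SubModelSpec):
    """Sub-model variant with one causal path frozen (not a free parameter)."""

    frozen: str = ""

    @property
    def free_names(self):
        return tuple(
            n for n in SubModelSpec.free_names.fget(self) if n != self.frozen
        )


def _null_delta_candidates(p: ModelParams, submodel: SubModelSpec):
    """Likelihood-equivalent candidates with one causal path set to zero.

    The joint-effect covariance of pleiotropic SNPs is invariant under
    trading a causal path against the direct-effect covariance:
    ``C_joint = B Gamma B^T`` with ``B = [I - Delta]^{-1}``, so setting a
    delta to zero and re-solving ``Gamma`` by congruence leaves the
    pleiotropic mixture term unchanged.  Only the (usually tiny)
    trait-specific contributions can tell the two points apart.
    """
    for name in ("delta12", "delta21"):
        if getattr(p, name) == 0.0:
            continue
        q = p.replace(**{name: 0.0})
        if "GC" in submodel.active and p.piC > 0 and p.sigmaC1_sq > 0:
            eye = np.eye(2)
            d_old = np.array([[0.0, p.delta12], [p.delta21, 0.0]])
            B = np.linalg.inv(eye - d_old)
            gam = np.array(
                [[p.sigmaC1_sq, p.rhoC1C2], [p.rhoC1C2, p.sigmaC2_sq]]
            )
            c_joint = B @ gam @ B.T
            A = eye - np.array([[0.0, q.delta12], [q.delta21, 0.0]])
            g0 = A @ c_joint @ A.T
            if g0[0, 0] > 0 and g0[1, 1] > 0:
                q = q.replace(
                    sigmaC1_sq=float(g0[0, 0]),
                    sigmaC2_sq=float(g0[1, 1]),
                    rhoC1C2=float(g0[0, 1]),
                )
        yield name, q


def _null_preference(ws, submodel, config, params, cl):
    """Prefer the delta = 0 parameterization when the CL cannot tell.

    Returns possibly-updated ``(params, cl)``.  Candidates whose raw CL is
    far below the fit are rejected without polishing; otherwise a short EM
    with the causal path frozen at zero lets the remaining parameters
    re-adjust, and the null-compatible point is adopted if it lands within
    ``null_margin`` of the unrestricted maximum.
    """
    for _pass in range(2):
        adopted = False
        for name, cand in _null_delta_candidates(params, submodel):
            # the frozen polish recovers at most a few CL units; candidates
            # starting further below the maximum cannot reach the margin
            if ws.cl(cand) < cl - 10.0:
                continue
            frozen = _DeltaFrozen(submodel.id, submodel.active, frozen=name)
            polish_cfg = replace(
                config, max_em_iter=3, cl_tol=1e-9, swap_check=False,
                null_check=False,
            )
            p2, tr, _, _ = _run_em(ws, cand, frozen, polish_cfg)
            if tr and tr[-1] >= cl - config.null_margin:
                params, cl = p2, tr[-1]
                adopted = True
                break
        if not adopted:
            break
    return params, cl


def _run_em(ws, init: ModelParams, submodel: SubModelSpec, config: FitConfig):
    params = submodel.pin(init)
    trace = []
    converged = False
    cl_prev = None
    n_iter = 0
    has = {c: (c in submodel.active) for c in ("G1", "G2", "GC")}
    # the first iterations decide the likelihood basin and get the full
    # search budget; later iterations only refine within it
    refine_cfg = replace(
        config, nm_max_eval=max(50, int(0.6 * config.nm_max_eval))
    )
    for n_iter in range(1, config.max_em_iter + 1):
        resp = _e_step_ws(ws, params)
        pi1, pi2, piC = m_step_mixing(resp, ws.data)
        params = params.replace(
            pi1=pi1 if has["G1"] else 0.0,
            pi2=pi2 if has["G2"] else 0.0,
            piC=piC if has["GC"] else 0.0,
        )
        params, cl = m_step_continuous(
            ws, params, submodel, config if n_iter <= 5 else refine_cfg
        )
        trace.append(cl)
        if cl_prev is not None and abs(cl - cl_prev) < config.cl_tol:
            converged = True
            break
        cl_prev = cl
    return params, trace, converged, n_iter


def fit_model(
    data: SummaryDataset,
    submodel: SubModelSpec = FULL_MODEL,
    config: FitConfig = FitConfig(),
    init: ModelParams | None = None,
) -> FitResult:
    """Fit one sub-model by generalized EM; best of ``n_starts`` starts.

    Deterministic under a fixed ``config.seed``: repeated calls return
    bit-for-bit identical results.
    """
    plan = EnumerationPlan.for_dataset(
        data, c_max=config.c_max, c_total=config.c_total, active=submodel.active
    )
    ws = LikelihoodWorkspace(data, plan)
    transform = _continuous_transform(submodel, data)
    rng = np.random.default_rng(config.seed)
    base_init = submodel.pin(init if init is not None else moment_init(data, submodel))

    best = None
    for start in range(config.n_starts):
        if start == 0:
            start_params = base_init
        else:
            z = transform.to_z(base_init) + rng.normal(0.0, 0.3, transform.n)
            start_params = transform.to_params(z, base_init)
        params, trace, converged, n_iter = _run_em(ws, start_params, submodel, config)
        cl = trace[-1] if trace else -np.inf
        if best is None or cl > best[1]:
            best = (params, cl, trace, converged, n_iter)

    params, cl, trace, converged, n_iter = best

    if config.swap_check:
        params, cl, trace, converged, n_iter = _swap_correction(
            ws, submodel, config, params, cl, trace, converged, n_iter
        )

    if config.null_check:
        params, cl = _null_preference(ws, submodel, config, params, cl)
    # clamp diagnostics at the estimate
    ws.loglik_per_snp(params)
    clamp_fraction = ws._last_clamped / max(ws.n_evaluations, 1)
    if clamp_fraction > config.clamp_abort_fraction:
        raise RuntimeError(
            f"covariance clamped for {clamp_fraction:.1%} of mixture terms at "
            f"the estimate; the fit left the admissible region"
        )
    return FitResult(
        params_hat=params,
        cl=cl,
        submodel=submodel,
        n_iter=n_iter,
        converged=converged,
        trace=trace,
        clamp_count=ws.clamp_count,
        clamp_fraction=clamp_fraction,
        seed=config.seed,
        config=config,
    )
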