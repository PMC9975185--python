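"""Five-model set, composite-likelihood AIC, weight optimization, model
averaging, and the final-model choice.

When a SNP component is genuinely absent, estimation assuming the full
model can hallucinate it and bias the causal effects.  The remedy fits the
full model and the four sub-models, averages parameter estimates with
simplex weights chosen to maximize the composite likelihood of the averaged
parameter vector (initialized from composite-likelihood Akaike weights),
and then picks between the full and the averaged model by explicit
criteria.  The point is robustness, not selection of a single best model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize

from .data import SummaryDataset
from .em import FitResult
from .enumeration import EnumerationPlan
from .likelihood import LikelihoodWorkspace
from .params import MODEL_SET_ORDER, PARAM_NAMES, ModelParams
from .sandwich import SandwichResult

__all__ = [
    "cl_aic",
    "initial_weights",
    "averaged_estimates",
    "optimize_weights",
    "select_final_model",
    "ModelSetResult",
]


def cl_aic(fit: FitResult, sandwich: SandwichResult) -> float:
    """Composite-likelihood AIC: ``-2 CL + 2 trace(I^{-1} J)``.

    The trace term is the effective number of parameters under composite
    likelihood (it reduces to the parameter count when information equality
    ``J = I`` holds); it is invariant to the coordinate system, so the
    z-space matrices are used directly.  Falls back to the free-parameter
    count when the trace is not finite.
    """
    I, J = sandwich.I_hat, sandwich.J_hat
    p = len(sandwich.free_names)
    penalty = np.nan
    try:
        # boundary-pinned parameters have vanishing curvature and corrupt
        # the trace; restrict to the identified subspace and invert in
        # correlation form (parameters live on very different scales)
        keep = np.array(
            [n not in sandwich.dropped for n in sandwich.free_names]
        )
        Ik = 0.5 * (I + I.T)[np.ix_(keep, keep)]
        Jk = J[np.ix_(keep, keep)]
        d = np.sqrt(np.abs(np.diag(Ik)))
        d[d == 0] = 1.0
        W = 1.0 / d
        I_s = W[:, None] * Ik * W[None, :]
        w, V = eigh(I_s)
        good = np.abs(w) > 1e-8 * np.abs(w).max()
        w_inv = np.where(good, 1.0 / np.where(good, w, 1.0), 0.0)
        I_inv = (W[:, None] * ((V * w_inv) @ V.T)) * W[None, :]
        penalty = float(np.trace(I_inv @ Jk))
    except Exception:  # pragma: no cover - defensive
        pass
    if not np.isfinite(penalty) or not 0.0 < penalty <= 20.0 * p:
        warnings.warn("CL-AIC trace penalty unusable; using parameter count")
        penalty = float(p)
    return -2.0 * fit.cl + 2.0 * penalty


def initial_weights(cl_aics) -> np.ndarray:
    """Akaike weights ``exp(-0.5 dAIC) / sum exp(-0.5 dAIC)``."""
    a = np.asarray(cl_aics, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite CL-AIC scores")
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def averaged_estimates(fits, weights, sandwiches=None):
    """Weighted average of the model set's estimates and its variance.

    ``fits`` is a sequence of :class:`FitResult` aligned with ``weights``;
    a parameter absent from a model contributes 0 with zero variance.  The
    variance of the averaged parameter is

        ( sum_s w_s sqrt(var_js + (theta_js - theta_ma_j)^2) )^2.

    Returns ``(ModelParams, dict name -> variance)``.
    """
    weights = np.asarray(weights, dtype=float)
    theta = {}
    var = {}
    for name in PARAM_NAMES:
        ests = np.array(
            [
                getattr(f.params_hat, name) if name in f.submodel.free_names else 0.0
                for f in fits
            ]
        )
        theta[name] = float(weights @ ests)
        vs = np.zeros(len(fits))
        if sandwiches is not None:
            for s_i, (f, sw) in enumerate(zip(fits, sandwiches)):
                if name in f.submodel.free_names:
                    v = sw.cov[sw.free_names.index(name), sw.free_names.index(name)]
                    vs[s_i] = v if np.isfinite(v) and v > 0 else 0.0
        var[name] = float(
            (weights @ np.sqrt(vs + (ests - theta[name]) ** 2)) ** 2
        )
    return ModelParams(**theta), var


def _softmax(logits: np.ndarray) -> np.ndarray:
    full = np.concatenate([[0.0], logits])
    e = np.exp(full - full.max())
    return e / e.sum()


def optimize_weights(
    data: SummaryDataset,
    fits,
    init_weights_,
    plan: EnumerationPlan,
    n_restarts: int = 5,
    maxfev: int = 80,
    fatol: float = 1e-3,
    seed: int = 0,
):
    """Maximize ``CL(theta_ma(w))`` over the 5-simplex (softmax coords).

    Returns ``(weights, cl_at_weights)``; never returns a point whose CL is
    below the initialization's minus ``fatol``.
    """
    ws = LikelihoodWorkspace(data, plan)
    w0 = np.clip(np.asarray(init_weights_, dtype=float), 1e-8, None)
    w0 = w0 / w0.sum()

    def cl_of(weights):
        theta, _ = averaged_estimates(fits, weights)
        try:
            return ws.cl(theta)
        except FloatingPointError:
            return -np.inf

    def objective(logits):
        v = cl_of(_softmax(logits))
        return -v if np.isfinite(v) else 1e12

    logits0 = np.log(w0[1:]) - np.log(w0[0])
    rng = np.random.default_rng(seed)
    best_logits, best_f = logits0, objective(logits0)
    for start in range(n_restarts):
        x0 = logits0 if start == 0 else logits0 + rng.normal(0.0, 0.5, logits0.size)
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": fatol,
                     "adaptive": False},
        )
        if np.isfinite(res.fun) and res.fun < best_f - 1e-9:
            best_logits, best_f = res.x, res.fun
    weights = _softmax(best_logits)
    return weights, -float(best_f)


def select_final_model(
    full_fit: FitResult,
    full_sandwich: SandwichResult,
    averaged_cl: float,
    data: SummaryDataset,
    h2_threshold: float = 0.05,
    alpha: float = 0.05,
):
    """Choose between the full-model fit and the averaged model.

    The averaged model is selected if (1) its composite likelihood exceeds
    the full model's, or (2) for either trait the full-model trait-specific
    heritability (``K * pi_t * sigma_t^2``) is below ``h2_threshold`` while
    the trait-specific mixing proportion is not significant (a
    boundary-pinned proportion with unavailable SE counts as not
    significant).  Otherwise the full model stands.

    Returns ``(choice, reasons)`` with ``choice`` in {"full", "averaged"}.
    """
    reasons = []
    p = full_fit.params_hat
    K = data.K
    if averaged_cl > full_fit.cl:
        reasons.append("averaged CL exceeds full-model CL")
    for t, (pi_name, s_sq) in enumerate(
        (("pi1", p.pi1 * p.sigma1_sq), ("pi2", p.pi2 * p.sigma2_sq)), start=1
    ):
        h2 = K * s_sq
        pval = full_sandwich.p_of(pi_name)
        not_sig = (not np.isfinite(pval)) or pval >= alpha
        if h2 < h2_threshold and not_sig:
            reasons.append(
                f"trait-{t} specific heritability {h2:.3f} < {h2_threshold} "
                f"with non-significant {pi_name}"
            )
    choice = "averaged" if reasons else "full"
    return choice, reasons


@dataclass
class ModelSetResult:
    """Everything produced by fitting and averaging the five-model set."""

    fits: dict
    sandwiches: dict
    cl_aics: dict
    init_weights: np.ndarray
    weights: np.ndarray
    theta_ma: ModelParams
    var_ma: dict
    cl_ma: float
    final_choice: str
    selection_reasons: list = field(default_factory=list)

    @property
    def model_ids(self):
        return tuple(MODEL_SET_ORDER)

    def weight_of(self, model_id: str) -> float:
        return float(self.weights[MODEL_SET_ORDER.index(model_id)])
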