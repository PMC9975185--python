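"""Model and Results objects tying the full pipeline together.

:class:`MrciModel` wraps an analysis-ready :class:`~mrci.data.SummaryDataset`
and its :meth:`fit` runs the estimation pipeline: full-model EM, the four
sub-model EMs, sandwich variances, composite-likelihood AIC weights, weight
optimization, model averaging and final-model selection.  The returned
:class:`MrciResults` carries the final estimates with their uncertainties,
the genetic correlation, per-model diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .averaging import (
    ModelSetResult,
    averaged_estimates,
    cl_aic,
    initial_weights,
    optimize_weights,
    select_final_model,
)
from .data import SummaryDataset
from .em import FitConfig, FitResult, fit_model
from .enumeration import EnumerationPlan
from .likelihood import genetic_correlation, rg_variance
from .params import FULL_MODEL, MODEL_SET_ORDER, PARAM_NAMES, SUBMODELS, ModelParams
from .sandwich import SandwichResult, sandwich_covariance, wald_test

__all__ = ["MrciModel", "MrciResults"]


class MrciModel:
    """Reciprocal-causation mixture model for one phenotype pair.

    Parameters
    ----------
    data : SummaryDataset
        Aligned bivariate summary statistics with LD reference.
    config : FitConfig, optional
        Estimation settings shared by all sub-model fits.
    """

    def __init__(self, data: SummaryDataset, config: FitConfig | None = None):
        self.data = data
        self.config = config if config is not None else FitConfig()

    @classmethod
    def from_files(cls, gwas1, gwas2, ld_scores, ld_pairs=None,
                   config=None, qc=True, column_map=None):
        """Build from GWAS summary files plus an LD reference on disk."""
        from . import io as mio

        data, _report = mio.load_pipeline(
            gwas1, gwas2, ld_scores, ld_pairs, qc=qc, column_map=column_map
        )
        return cls(data, config=config)

    def fit(self, model_averaging: bool = True, seed: int | None = None) -> "MrciResults":
        """Run the estimation pipeline and return a results object."""
        cfg = self.config if seed is None else self.config.__class__(
            **{**self.config.__dict__, "seed": seed}
        )
        timings = {}
        t0 = time.perf_counter()

        fits: dict[str, FitResult] = {}
        sandwiches: dict[str, SandwichResult] = {}
        model_ids = MODEL_SET_ORDER if model_averaging else ("s_12C",)
        # Sub-models are fitted independently (from their own moment
        # starts): when a causal path is weakly identified, independent
        # fits land at different points of the likelihood ridge, and that
        # spread is exactly what inflates the averaged variance and keeps
        # the Wald test honest.
        sub_cfg = dc_replace(
            cfg, max_em_iter=min(12, cfg.max_em_iter), swap_check=False,
            null_check=False, cl_tol=max(0.05, cfg.cl_tol),
        )
        for mid in model_ids:
            t = time.perf_counter()
            cfg_m = cfg if mid == "s_12C" else sub_cfg
            fits[mid] = fit_model(self.data, SUBMODELS[mid], cfg_m)
            timings[mid] = time.perf_counter() - t

        # A nested sub-model can never truly exceed the full model's CL; if
        # one does, the full-model EM stopped short -- restart it from that
        # point (absent components re-seeded from the original full fit).
        if model_averaging:
            t = time.perf_counter()
            best_sub = max(
                (fits[m] for m in MODEL_SET_ORDER[1:]), key=lambda f: f.cl
            )
            if best_sub.cl > fits["s_12C"].cl + 2.0:
                full_p = fits["s_12C"].params_hat
                merged = best_sub.params_hat
                for name in SUBMODELS["s_12C"].free_names:
                    if name not in best_sub.submodel.free_names:
                        merged = merged.replace(**{name: getattr(full_p, name)})
                rescued = fit_model(self.data, SUBMODELS["s_12C"], cfg, init=merged)
                if rescued.cl > fits["s_12C"].cl:
                    fits["s_12C"] = rescued
            timings["rescue"] = time.perf_counter() - t

        for mid in model_ids:
            t = time.perf_counter()
            sandwiches[mid] = sandwich_covariance(self.data, fits[mid])
            timings[mid] += time.perf_counter() - t

        full_fit = fits["s_12C"]
        full_sw = sandwiches["s_12C"]

        model_set = None
        if model_averaging:
            t = time.perf_counter()
            aics = {mid: cl_aic(fits[mid], sandwiches[mid]) for mid in MODEL_SET_ORDER}
            w0 = initial_weights([aics[mid] for mid in MODEL_SET_ORDER])
            plan_full = EnumerationPlan.for_dataset(
                self.data, c_max=cfg.c_max, c_total=cfg.c_total,
                active=FULL_MODEL.active,
            )
            ordered_fits = [fits[mid] for mid in MODEL_SET_ORDER]
            weights, cl_ma = optimize_weights(
                self.data, ordered_fits, w0, plan_full,
                n_restarts=2, maxfev=60, seed=cfg.seed,
            )
            theta_ma, var_ma = averaged_estimates(
                ordered_fits, weights, [sandwiches[mid] for mid in MODEL_SET_ORDER]
            )
            choice, reasons = select_final_model(
                full_fit, full_sw, cl_ma, self.data
            )
            model_set = ModelSetResult(
                fits=fits,
                sandwiches=sandwiches,
                cl_aics=aics,
                init_weights=w0,
                weights=weights,
                theta_ma=theta_ma,
                var_ma=var_ma,
                cl_ma=cl_ma,
                final_choice=choice,
                selection_reasons=reasons,
            )
            timings["averaging"] = time.perf_counter() - t

        timings["total"] = time.perf_counter() - t0
        return MrciResults(self, cfg, fits, sandwiches, model_set, timings)


@dataclass
class MrciResults:
    """Final estimates, uncertainties and diagnostics of an MRCI fit."""

    model: MrciModel
    config: FitConfig
    fits: dict
    sandwiches: dict
    model_set: ModelSetResult | None
    timings: dict = field(default_factory=dict)

    # -- final estimates -------------------------------------------------
    @property
    def final_choice(self) -> str:
        if self.model_set is None:
            return "full"
        return self.model_set.final_choice

    @property
    def params(self) -> ModelParams:
        """Final parameter estimates (averaged or full, per selection)."""
        if self.final_choice == "averaged":
            return self.model_set.theta_ma
        return self.fits["s_12C"].params_hat

    def _variance(self, name: str) -> float:
        if self.final_choice == "averaged":
            return self.model_set.var_ma.get(name, float("nan"))
        sw = self.sandwiches["s_12C"]
        s = sw.se_of(name)
        return s * s

    @property
    def bse(self) -> dict:
        """Standard errors of the final estimates, keyed by parameter."""
        return {n: float(np.sqrt(self._variance(n))) for n in PARAM_NAMES}

    @property
    def pvalues(self) -> dict:
        out = {}
        for n in PARAM_NAMES:
            se = self.bse[n]
            est = getattr(self.params, n)
            if np.isfinite(se) and se > 0:
                _, out[n] = wald_test(est, se)
            else:
                out[n] = float("nan")
        return out

    @property
    def delta12(self) -> float:
        return self.params.delta12

    @property
    def delta21(self) -> float:
        return self.params.delta21

    # -- derived genetic quantities -------------------------------------
    def heritability(self, component: str) -> float:
        """Heritability contributed by one component ('1', '2', 'C1', 'C2')."""
        p = self.params
        K = self.model.data.K
        return {
            "1": K * p.pi1 * p.sigma1_sq,
            "2": K * p.pi2 * p.sigma2_sq,
            "C1": K * p.piC * p.sigmaC1_sq,
            "C2": K * p.piC * p.sigmaC2_sq,
        }[component]

    @property
    def rg(self) -> float:
        try:
            return genetic_correlation(self.params)
        except ValueError:
            return float("nan")

    @property
    def rg_se(self) -> float:
        names = FULL_MODEL.free_names
        if self.final_choice == "averaged":
            cov = np.diag([self._variance(n) for n in names])
        else:
            sw = self.sandwiches["s_12C"]
            cov = np.where(np.isfinite(sw.cov), sw.cov, 0.0)
        try:
            return float(np.sqrt(rg_variance(self.params, cov, names)))
        except (ValueError, FloatingPointError):
            return float("nan")

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        p = self.params
        se = self.bse
        pv = self.pvalues
        lines = [
            "MRCI reciprocal causation fit",
            "=" * 64,
            f"SNPs: {self.model.data.K}   n1: {self.model.data.n1:.0f}   "
            f"n2: {self.model.data.n2:.0f}",
            f"final model: {self.final_choice}",
        ]
        if self.model_set is not None:
            w = ", ".join(
                f"{mid}={self.model_set.weight_of(mid):.3f}"
                for mid in MODEL_SET_ORDER
            )
            lines.append(f"model weights: {w}")
            for r in self.model_set.selection_reasons:
                lines.append(f"  selection: {r}")
        lines.append("-" * 64)
        lines.append(f"{'parameter':<12}{'estimate':>14}{'std err':>12}{'P>chi2':>12}")
        for n in PARAM_NAMES:
            lines.append(
                f"{n:<12}{getattr(p, n):>14.4e}{se[n]:>12.3e}{pv[n]:>12.3g}"
            )
        lines.append("-" * 64)
        lines.append(
            f"delta12 (Y2->Y1): {p.delta12:+.4f} +/- {se['delta12']:.4f}   "
            f"p={pv['delta12']:.3g}"
        )
        lines.append(
            f"delta21 (Y1->Y2): {p.delta21:+.4f} +/- {se['delta21']:.4f}   "
            f"p={pv['delta21']:.3g}"
        )
        lines.append(f"genetic correlation rg: {self.rg:+.4f} +/- {self.rg_se:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "final_choice": self.final_choice,
            "params": self.params.to_dict(),
            "se": self.bse,
            "p": self.pvalues,
            "rg": self.rg,
            "rg_se": self.rg_se,
            "cl_full": self.fits["s_12C"].cl,
            "seed": self.config.seed,
            "timings": self.timings,
            "fits": {mid: f.to_dict() for mid, f in self.fits.items()},
        }
        if self.model_set is not None:
            ms = self.model_set
            out.update(
                {
                    "cl_aic": ms.cl_aics,
                    "weights": {
                        mid: ms.weight_of(mid) for mid in MODEL_SET_ORDER
                    },
                    "cl_averaged": ms.cl_ma,
                    "selection_reasons": ms.selection_reasons,
                }
            )
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=float, **kwargs)
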