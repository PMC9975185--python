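"""Numba kernels for the mixture likelihood (hot path).

The per-SNP likelihood is a finite mixture over tagging-set compositions.
For a fixed composition the 2x2 covariance of the bivariate marginal-effect
estimate is affine in the SNP's LD score, so each composition is described
by three slopes (variance 1, variance 2, covariance) plus shared intercepts
(``a + 1/n`` and ``rho0``).  The kernels evaluate the mixture density for a
group of SNPs sharing one tagging-set size.
"""

import numpy as np
from numba import njit

_LOG2PI = 1.8378770664093453
_JITTER = 1e-12
_LOG_FLOOR = -745.0


@njit(cache=True, fastmath=True, nogil=True)
def group_loglik(tau1, tau2, ell, s1, s2, sc, b1, b2, b0, logprior, out):
    """Per-SNP mixture log-density for one tagging-set-size group.

    Returns the number of (SNP, composition) evaluations where the
    covariance had to be clamped to keep the 2x2 matrix positive definite.
    """
    m = tau1.shape[0]
    C = s1.shape[0]
    clamped = 0
    for i in range(m):
        x1 = tau1[i]
        x2 = tau2[i]
        li = ell[i]
        acc = 0.0
        for c in range(C):
            v1 = s1[c] * li + b1 + _JITTER
            v2 = s2[c] * li + b2 + _JITTER
            cv = sc[c] * li + b0
            bound = np.sqrt(v1 * v2)
            if cv > 0.999 * bound:
                cv = 0.999 * bound
                clamped += 1
            elif cv < -0.999 * bound:
                cv = -0.999 * bound
                clamped += 1
            det = v1 * v2 - cv * cv
            quad = (v2 * x1 * x1 - 2.0 * cv * x1 * x2 + v1 * x2 * x2) / det
            e = logprior[c] - 0.5 * (quad + np.log(det)) - _LOG2PI
            if e > _LOG_FLOOR:
                acc += np.exp(e)
        if acc > 0.0:
            out[i] = np.log(acc)
        else:
            out[i] = _LOG_FLOOR
    return clamped


@njit(cache=True, fastmath=True, nogil=True)
def group_logterms(tau1, tau2, ell, s1, s2, sc, b1, b2, b0, logprior, out):
    """(m, C) matrix of log(prior * density) terms, for responsibilities."""
    m = tau1.shape[0]
    C = s1.shape[0]
    clamped = 0
    for i in range(m):
        x1 = tau1[i]
        x2 = tau2[i]
        li = ell[i]
        for c in range(C):
            v1 = s1[c] * li + b1 + _JITTER
            v2 = s2[c] * li + b2 + _JITTER
            cv = sc[c] * li + b0
            bound = np.sqrt(v1 * v2)
            if cv > 0.999 * bound:
                cv = 0.999 * bound
                clamped += 1
            elif cv < -0.999 * bound:
                cv = -0.999 * bound
                clamped += 1
            det = v1 * v2 - cv * cv
            quad = (v2 * x1 * x1 - 2.0 * cv * x1 * x2 + v1 * x2 * x2) / det
            out[i, c] = logprior[c] - 0.5 * (quad + np.log(det)) - _LOG2PI
    return clamped
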