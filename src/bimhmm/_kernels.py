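"""Compiled numerical kernels (numba) for the bivariate mixed HMM.

These are the hot loops of the package: the scaled forward recursion for
the per-subject conditional log-likelihood, the Viterbi dynamic program,
and a damped-Newton Laplace approximation over the active random-effect
dimensions.  Everything operates on plain float64/bool arrays; the
wrapping, validation and bookkeeping live in :mod:`bimhmm.inference`.

Parameter vector layout ``p`` (length 19), matching
:data:`bimhmm.parameters.PARAM_ORDER`::

    0 theta_fev1_r   1 theta_fev1_e   2 theta_pro_r   3 theta_pro_e
    4 init           5 theta_pi_re    6 theta_pi_er   7 slp
    8 pe             9 phl
    10..14 omega2 (fev1_r, fev1_e, pro_r, pro_e, pi_re)
    15 sigma2_fev1   16 sigma2_pro    17 rho_r        18 rho_e

Eta layout (length 5): (fev1_r, fev1_e, pro_r, pro_e, pi_re); dimension
``d`` pairs with variance ``p[10 + d]``.

Numerical policy: emissions are computed in log space; the forward and
Viterbi recursions renormalize per step, so the returned log-likelihood is
the sum of log step-normalizers and never underflows for finite inputs.
"""

import numpy as np
from numba import njit

_LN2 = 0.6931471805599453
_LN2PI = 1.8378770664093453


@njit(cache=False)
def _emission_logpdf(yf, yp, obf, obp, muf, mup, s2f, s2p, rho):
    # obf/obp: endpoint observed flags.  A row with neither endpoint
    # contributes log-density 0 (the chain still advances).
    if obf and obp:
        zf = (yf - muf) / np.sqrt(s2f)
        zp = (yp - mup) / np.sqrt(s2p)
        omr2 = 1.0 - rho * rho
        quad = (zf * zf - 2.0 * rho * zf * zp + zp * zp) / omr2
        return -_LN2PI - 0.5 * np.log(s2f * s2p * omr2) - 0.5 * quad
    elif obf:
        return -0.5 * (_LN2PI + np.log(s2f)) - 0.5 * (yf - muf) ** 2 / s2f
    elif obp:
        return -0.5 * (_LN2PI + np.log(s2p)) - 0.5 * (yp - mup) ** 2 / s2p
    return 0.0


@njit(cache=False)
def conditional_loglik(yf, yp, obf, obp, times, trt, p, eta):
    """Forward log-likelihood of one subject given the random effects.

    Initializes with the initial-state probabilities times the first-row
    emissions, then recurses with transition-weighted normalized state
    probabilities (phi) multiplied by the state emissions, renormalizing
    each step; returns the accumulated sum of log step-normalizers.
    """
    fev1_r = p[0] * np.exp(eta[0])
    fev1_e = fev1_r - p[1] * np.exp(eta[1])
    pro_r0 = p[2] + eta[2]
    pro_e_add = p[3] + eta[3]
    p_init_r = p[4]
    x_re = np.log(p[5] / (1.0 - p[5])) + eta[4] - trt * p[7]
    pi_re = 1.0 / (1.0 + np.exp(-x_re))
    pi_er = p[6]
    s2f = p[15]
    s2p = p[16]
    rho_r = p[17]
    rho_e = p[18]

    T = times.shape[0]
    ll = 0.0
    phi_r = 0.0
    phi_e = 0.0
    for j in range(T):
        fac = 1.0 - p[8] * (1.0 - np.exp(-_LN2 * times[j] / p[9]))
        mup_r = pro_r0 * fac
        mup_e = mup_r + pro_e_add
        le_r = _emission_logpdf(yf[j], yp[j], obf[j], obp[j], fev1_r, mup_r, s2f, s2p, rho_r)
        le_e = _emission_logpdf(yf[j], yp[j], obf[j], obp[j], fev1_e, mup_e, s2f, s2p, rho_e)
        if j == 0:
            w_r = p_init_r
            w_e = 1.0 - p_init_r
        else:
            w_r = phi_r * (1.0 - pi_re) + phi_e * pi_er
            w_e = phi_r * pi_re + phi_e * (1.0 - pi_er)
        m = le_r if le_r >= le_e else le_e
        if not np.isfinite(m):
            # emission underflow/overflow at extreme parameter values:
            # signal an impossible configuration to the caller
            return -np.inf
        a_r = w_r * np.exp(le_r - m)
        a_e = w_e * np.exp(le_e - m)
        norm = a_r + a_e
        if not norm > 0.0:
            return -np.inf
        ll += m + np.log(norm)
        phi_r = a_r / norm
        phi_e = a_e / norm
    return ll


@njit(cache=False)
def conditional_loglik_many(yf, yp, obf, obp, times, trt, p, etas):
    """Conditional log-likelihood of one subject at each row of ``etas``."""
    m = etas.shape[0]
    out = np.empty(m)
    for i in range(m):
        out[i] = conditional_loglik(yf, yp, obf, obp, times, trt, p, etas[i])
    return out


@njit(cache=False)
def viterbi(yf, yp, obf, obp, times, trt, p, eta):
    """Most likely state path (0 = remission, 1 = exacerbation).

    Log-space dynamic program with back-pointers; ties break toward
    remission (the lower state index).  Returns ``(path, log_joint)``
    where ``log_joint`` is the joint log-probability of the returned path
    and the observations.
    """
    fev1_r = p[0] * np.exp(eta[0])
    fev1_e = fev1_r - p[1] * np.exp(eta[1])
    pro_r0 = p[2] + eta[2]
    pro_e_add = p[3] + eta[3]
    x_re = np.log(p[5] / (1.0 - p[5])) + eta[4] - trt * p[7]
    pi_re = 1.0 / (1.0 + np.exp(-x_re))
    pi_er = p[6]
    s2f = p[15]
    s2p = p[16]

    la = np.empty((2, 2))
    la[0, 0] = np.log(1.0 - pi_re)
    la[0, 1] = np.log(pi_re)
    la[1, 0] = np.log(pi_er)
    la[1, 1] = np.log(1.0 - pi_er)

    T = times.shape[0]
    delta = np.empty((T, 2))
    psi = np.zeros((T, 2), dtype=np.int8)
    for j in range(T):
        fac = 1.0 - p[8] * (1.0 - np.exp(-_LN2 * times[j] / p[9]))
        mup_r = pro_r0 * fac
        mup_e = mup_r + pro_e_add
        le_r = _emission_logpdf(yf[j], yp[j], obf[j], obp[j], fev1_r, mup_r, s2f, s2p, p[17])
        le_e = _emission_logpdf(yf[j], yp[j], obf[j], obp[j], fev1_e, mup_e, s2f, s2p, p[18])
        if j == 0:
            delta[0, 0] = np.log(p[4]) + le_r
            delta[0, 1] = np.log(1.0 - p[4]) + le_e
        else:
            for s in range(2):
                cand_r = delta[j - 1, 0] + la[0, s]
                cand_e = delta[j - 1, 1] + la[1, s]
                if cand_r >= cand_e:
                    best = cand_r
                    psi[j, s] = 0
                else:
                    best = cand_e
                    psi[j, s] = 1
                delta[j, s] = best + (le_r if s == 0 else le_e)
    path = np.empty(T, dtype=np.int8)
    path[T - 1] = 0 if delta[T - 1, 0] >= delta[T - 1, 1] else 1
    for j in range(T - 2, -1, -1):
        path[j] = psi[j + 1, path[j + 1]]
    log_joint = delta[T - 1, path[T - 1]]
    return path, log_joint


@njit(cache=False)
def _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x):
    """-(conditional loglik + log normal eta prior) over active dims."""
    eta = np.zeros(5)
    for i in range(active.shape[0]):
        eta[active[i]] = x[i]
    val = conditional_loglik(yf, yp, obf, obp, times, trt, p, eta)
    for i in range(active.shape[0]):
        w2 = p[10 + active[i]]
        val += -0.5 * (_LN2PI + np.log(w2)) - 0.5 * x[i] * x[i] / w2
    return -val


@njit(cache=False)
def _fd_grad_hess(yf, yp, obf, obp, times, trt, p, active, x, f0, grad, hess):
    """Central finite-difference gradient and Hessian of the penalized
    objective at ``x`` (in place)."""
    k = x.shape[0]
    h = np.empty(k)
    for i in range(k):
        h[i] = 5e-4 * (1.0 + np.abs(x[i]))
    for i in range(k):
        xi = x[i]
        x[i] = xi + h[i]
        fp = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x)
        x[i] = xi - h[i]
        fm = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x)
        x[i] = xi
        grad[i] = (fp - fm) / (2.0 * h[i])
        hess[i, i] = (fp + fm - 2.0 * f0) / (h[i] * h[i])
    for i in range(k):
        for j in range(i + 1, k):
            xi = x[i]
            xj = x[j]
            x[i] = xi + h[i]
            x[j] = xj + h[j]
            fpp = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x)
            x[j] = xj - h[j]
            fpm = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x)
            x[i] = xi - h[i]
            fmm = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x)
            x[j] = xj + h[j]
            fmp = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x)
            x[i] = xi
            x[j] = xj
            hij = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
            hess[i, j] = hij
            hess[j, i] = hij


@njit(cache=False)
def laplace_subject(yf, yp, obf, obp, times, trt, p, active, eta_init, tol, maxit):
    """Laplace-approximate log marginal likelihood of one subject.

    Finds the posterior mode of the active random effects by a damped
    (modified-eigenvalue) Newton iteration with finite-difference
    derivatives, then applies the Laplace correction
    ``0.5*k*log(2*pi) - 0.5*log|H|``.  Returns ``(log_marginal, eta_mode)``
    with ``eta_mode`` embedded in the full 5-vector.
    """
    k = active.shape[0]
    eta_full = np.zeros(5)
    if k == 0:
        return conditional_loglik(yf, yp, obf, obp, times, trt, p, eta_full), eta_full

    x = np.empty(k)
    for i in range(k):
        x[i] = eta_init[active[i]]
    f0 = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x)
    if not np.isfinite(f0):
        for i in range(k):
            x[i] = 0.0
        f0 = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x)

    grad = np.empty(k)
    hess = np.empty((k, k))
    have_hess_at_x = False
    for _ in range(maxit):
        _fd_grad_hess(yf, yp, obf, obp, times, trt, p, active, x, f0, grad, hess)
        have_hess_at_x = True
        gnorm = 0.0
        for i in range(k):
            g = np.abs(grad[i])
            if g > gnorm:
                gnorm = g
        if gnorm < tol:
            break
        # modified-eigenvalue Newton direction (guaranteed descent)
        w, v = np.linalg.eigh(hess)
        wmax = 0.0
        for a in range(k):
            if np.abs(w[a]) > wmax:
                wmax = np.abs(w[a])
        floor = 1e-6 * wmax
        if floor < 1e-8:
            floor = 1e-8
        dx = np.zeros(k)
        for a in range(k):
            wa = w[a]
            if wa < floor:
                wa = floor
            coef = 0.0
            for i in range(k):
                coef += v[i, a] * grad[i]
            coef /= wa
            for i in range(k):
                dx[i] -= v[i, a] * coef
        step = 1.0
        improved = False
        for _ls in range(25):
            xt = x + step * dx
            ft = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, xt)
            if np.isfinite(ft) and ft < f0:
                x = xt
                f0 = ft
                improved = True
                have_hess_at_x = False
                break
            step *= 0.5
        if not improved:
            break
    if not have_hess_at_x:
        _fd_grad_hess(yf, yp, obf, obp, times, trt, p, active, x, f0, grad, hess)

    w, v = np.linalg.eigh(hess)
    logdet = 0.0
    for a in range(k):
        wa = w[a]
        if wa < 1e-10:
            wa = 1e-10
        logdet += np.log(wa)
    log_marginal = -f0 + 0.5 * k * _LN2PI - 0.5 * logdet
    for i in range(k):
        eta_full[active[i]] = x[i]
    return log_marginal, eta_full


@njit(cache=False)
def _moment_start(yf, yp, obf, obp, times, p, active):
    """Data-informed eta start: explain the subject's average level as a
    mostly-remission trajectory with shifted individual modes.

    This targets the main secondary basin of the penalized objective,
    where a level shift is instead explained by extra exacerbation time
    with compensating state-mode effects.
    """
    eta = np.zeros(5)
    sf = 0.0
    nf = 0
    for j in range(yf.shape[0]):
        if obf[j]:
            sf += yf[j]
            nf += 1
    if nf > 0 and p[0] > 0.0:
        m = sf / nf
        if m > 0.05 * p[0]:
            eta[0] = np.log(m / p[0])
    sp = 0.0
    sfac = 0.0
    npro = 0
    for j in range(yp.shape[0]):
        if obp[j]:
            fac = 1.0 - p[8] * (1.0 - np.exp(-_LN2 * times[j] / p[9]))
            sp += yp[j]
            sfac += fac
            npro += 1
    if npro > 0 and sfac > 0.0:
        eta[2] = sp / sfac - p[2]
    for d in range(5):
        keep = False
        for a in range(active.shape[0]):
            if active[a] == d:
                keep = True
        if not keep:
            eta[d] = 0.0
    return eta


@njit(cache=False)
def dataset_laplace(yf, yp, obf, obp, times, trt, p, active, eta_cache, tol, maxit, dual):
    """Per-subject Laplace log marginal likelihoods for a whole dataset.

    ``eta_cache`` (n, 5) is read as warm starts for the inner Newton and
    overwritten with the converged modes (empirical Bayes estimates).
    The penalized objective can have secondary modes (alternative hidden
    path explanations); with ``dual`` each warm-started subject is also
    optimized from zero and the better mode kept, making the reported
    values independent of the warm-start history.
    """
    n = yf.shape[0]
    out = np.empty(n)
    zero = np.zeros(5)
    for s in range(n):
        lm, ef = laplace_subject(
            yf[s], yp[s], obf[s], obp[s], times, trt[s], p, active, eta_cache[s], tol, maxit
        )
        if dual:
            warm = False
            for d in range(5):
                if eta_cache[s, d] != 0.0:
                    warm = True
            if warm:
                lm0, ef0 = laplace_subject(
                    yf[s], yp[s], obf[s], obp[s], times, trt[s], p, active, zero, tol, maxit
                )
                if lm0 > lm:
                    lm = lm0
                    ef = ef0
            start_m = _moment_start(yf[s], yp[s], obf[s], obp[s], times, p, active)
            lm1, ef1 = laplace_subject(
                yf[s], yp[s], obf[s], obp[s], times, trt[s], p, active, start_m, tol, maxit
            )
            if lm1 > lm:
                lm = lm1
                ef = ef1
        out[s] = lm
        for d in range(5):
            eta_cache[s, d] = ef[d]
    return out


@njit(cache=False)
def laplace_subject_mode_hess(yf, yp, obf, obp, times, trt, p, active, eta_init, tol, maxit):
    """Posterior mode and Hessian of the penalized objective (for the
    importance-sampling proposal).  Returns ``(f_mode, x_mode, hess)`` in
    the active-dimension coordinates."""
    k = active.shape[0]
    x = np.empty(k)
    for i in range(k):
        x[i] = eta_init[active[i]]
    _, eta_full = laplace_subject(yf, yp, obf, obp, times, trt, p, active, eta_init, tol, maxit)
    for i in range(k):
        x[i] = eta_full[active[i]]
    f0 = _neg_penalized(yf, yp, obf, obp, times, trt, p, active, x)
    grad = np.empty(k)
    hess = np.empty((k, k))
    _fd_grad_hess(yf, yp, obf, obp, times, trt, p, active, x, f0, grad, hess)
    return f0, x, hess
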