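"""Independent reference implementations used as test oracles.

Everything here is deliberately brute force — exhaustive enumeration over
all hidden state sequences, dense numerical integration — and built only
from the public per-observation model functions, so it shares no code
with the compiled forward/Viterbi/Laplace kernels it checks.
"""

import itertools
import math

import numpy as np
from scipy.special import logsumexp

from bimhmm import (
    IndividualEffects,
    emission_logpdf,
    individual_parameters,
    initial_state_prob,
    transition_matrix,
)


def enum_loglik(pop, eta, subject):
    """Log-likelihood by summing the joint over all 2^T state sequences."""
    eta = eta if isinstance(eta, IndividualEffects) else IndividualEffects.from_array(eta)
    indiv = individual_parameters(pop, eta, subject.trt)
    p_r = initial_state_prob(pop)
    mat = transition_matrix(pop, eta.eta_pi_re, subject.trt)
    T = subject.times.size
    log_init = np.log([p_r, 1.0 - p_r])
    log_a = np.log(mat)
    terms = []
    for seq in itertools.product((0, 1), repeat=T):
        lp = log_init[seq[0]]
        for j in range(1, T):
            lp += log_a[seq[j - 1], seq[j]]
        for j, s in enumerate(seq):
            yf = subject.y_fev1[j] if subject.obs_fev1[j] else None
            yp = subject.y_pro[j] if subject.obs_pro[j] else None
            if yf is None and yp is None:
                continue
            lp += emission_logpdf(yf, yp, s, indiv, pop, subject.times[j])
        terms.append(lp)
    return float(logsumexp(terms))


def enum_viterbi(pop, eta, subject):
    """Most likely state sequence by exhaustive search; ties favor the
    sequence that is lexicographically earliest with R < E (matching the
    tie-break toward remission)."""
    eta = eta if isinstance(eta, IndividualEffects) else IndividualEffects.from_array(eta)
    indiv = individual_parameters(pop, eta, subject.trt)
    p_r = initial_state_prob(pop)
    mat = transition_matrix(pop, eta.eta_pi_re, subject.trt)
    T = subject.times.size
    log_init = np.log([p_r, 1.0 - p_r])
    log_a = np.log(mat)
    best, best_lp = None, -math.inf
    for seq in itertools.product((0, 1), repeat=T):
        lp = log_init[seq[0]]
        for j in range(1, T):
            lp += log_a[seq[j - 1], seq[j]]
        for j, s in enumerate(seq):
            yf = subject.y_fev1[j] if subject.obs_fev1[j] else None
            yp = subject.y_pro[j] if subject.obs_pro[j] else None
            if yf is None and yp is None:
                continue
            lp += emission_logpdf(yf, yp, s, indiv, pop, subject.times[j])
        if lp > best_lp:
            best, best_lp = seq, lp
    return np.array(best, dtype=np.int8), float(best_lp)
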