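"""JIT-compiled inner loops for the three from-scratch optimizers.

Each kernel receives a pre-drawn table of per-epoch permutations so that
all shuffling randomness lives outside the hot loop (and outside numba's
own RNG). Arithmetic is written as explicit scalar loops in a fixed
order, so an independent pure-Python transcription of the update rules
reproduces every step bit for bit.

Return convention: ``(theta0, theta1, epochs_run, final_grad_norm,
status, trace)`` with ``status`` 0 for a normal finish and 1 for a
non-finite parameter detected after epoch ``epochs_run``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sgd_kernel", "rmsprop_kernel", "adam_kernel"]


@njit(cache=True)
def _objective(x, y, t0, t1):
    m = x.shape[0]
    q = 0.0
    for i in range(m):
        r = t0 + t1 * x[i] - y[i]
        q += r * r
    return q / m


@njit(cache=True)
def _full_grad_norm(x, y, t0, t1):
    m = x.shape[0]
    s0 = 0.0
    s1 = 0.0
    for i in range(m):
        r = t0 + t1 * x[i] - y[i]
        s0 += r
        s1 += r * x[i]
    g0 = 2.0 * s0 / m
    g1 = 2.0 * s1 / m
    return np.sqrt(g0 * g0 + g1 * g1)


@njit(cache=True)
def sgd_kernel(x, y, theta0, theta1, eta, grad_tol, perms):
    max_epochs = perms.shape[0]
    m = x.shape[0]
    trace = np.empty(max_epochs)
    gn = _full_grad_norm(x, y, theta0, theta1)
    if gn <= grad_tol:
        return theta0, theta1, 0, gn, 0, trace[:0]
    epochs = 0
    for e in range(max_epochs):
        for k in range(m):
            i = perms[e, k]
            r = theta0 + theta1 * x[i] - y[i]
            new0 = theta0 - eta * 2.0 * r
            new1 = theta1 - eta * 2.0 * x[i] * r
            theta0 = new0
            theta1 = new1
        epochs = e + 1
        trace[e] = _objective(x, y, theta0, theta1)
        if not (np.isfinite(theta0) and np.isfinite(theta1)):
            return theta0, theta1, epochs, np.inf, 1, trace[:epochs]
        gn = _full_grad_norm(x, y, theta0, theta1)
        if gn <= grad_tol:
            break
    return theta0, theta1, epochs, gn, 0, trace[:epochs]


@njit(cache=True)
def rmsprop_kernel(x, y, theta0, theta1, eta, beta, eps, batch_size, grad_tol, perms):
    max_epochs = perms.shape[0]
    m = x.shape[0]
    trace = np.empty(max_epochs)
    gn = _full_grad_norm(x, y, theta0, theta1)
    if gn <= grad_tol:
        return theta0, theta1, 0, gn, 0, trace[:0]
    v0 = 0.0
    v1 = 0.0
    epochs = 0
    for e in range(max_epochs):
        start = 0
        while start < m:
            end = min(start + batch_size, m)
            bs = end - start
            s0 = 0.0
            s1 = 0.0
            for k in range(start, end):
                i = perms[e, k]
                r = theta0 + theta1 * x[i] - y[i]
                s0 += r
                s1 += r * x[i]
            g0 = 2.0 * s0 / bs
            g1 = 2.0 * s1 / bs
            v0 = beta * v0 + (1.0 - beta) * g0 * g0
            v1 = beta * v1 + (1.0 - beta) * g1 * g1
            theta0 = theta0 - eta * g0 / np.sqrt(v0 + eps)
            theta1 = theta1 - eta * g1 / np.sqrt(v1 + eps)
            start = end
        epochs = e + 1
        trace[e] = _objective(x, y, theta0, theta1)
        if not (np.isfinite(theta0) and np.isfinite(theta1)):
            return theta0, theta1, epochs, np.inf, 1, trace[:epochs]
        gn = _full_grad_norm(x, y, theta0, theta1)
        if gn <= grad_tol:
            break
    return theta0, theta1, epochs, gn, 0, trace[:epochs]


@njit(cache=True)
def adam_kernel(
    x, y, theta0, theta1, eta, beta1, beta2, eps, batch_size, grad_tol, perms, time_scaled
):
    max_epochs = perms.shape[0]
    m = x.shape[0]
    trace = np.empty(max_epochs)
    gn = _full_grad_norm(x, y, theta0, theta1)
    if gn <= grad_tol:
        return theta0, theta1, 0, gn, 0, trace[:0]
    m0 = 0.0
    m1 = 0.0
    v0 = 0.0
    v1 = 0.0
    t = 0
    epochs = 0
    for e in range(max_epochs):
        start = 0
        while start < m:
            end = min(start + batch_size, m)
            bs = end - start
            s0 = 0.0
            s1 = 0.0
            for k in range(start, end):
                i = perms[e, k]
                r = theta0 + theta1 * x[i] - y[i]
                s0 += r
                s1 += r * x[i]
            g0 = 2.0 * s0 / bs
            g1 = 2.0 * s1 / bs
            t += 1
            m0 = beta1 * m0 + (1.0 - beta1) * g0
            m1 = beta1 * m1 + (1.0 - beta1) * g1
            v0 = beta2 * v0 + (1.0 - beta2) * g0 * g0
            v1 = beta2 * v1 + (1.0 - beta2) * g1 * g1
            if time_scaled:
                c1 = 1.0 - beta1 ** t
                c2 = 1.0 - beta2 ** t
            else:
                c1 = 1.0 - beta1
                c2 = 1.0 - beta2
            m0h = m0 / c1
            m1h = m1 / c1
            v0h = v0 / c2
            v1h = v1 / c2
            theta0 = theta0 - eta * m0h / (np.sqrt(v0h) + eps)
            theta1 = theta1 - eta * m1h / (np.sqrt(v1h) + eps)
            start = end
        epochs = e + 1
        trace[e] = _objective(x, y, theta0, theta1)
        if not (np.isfinite(theta0) and np.isfinite(theta1)):
            return theta0, theta1, epochs, np.inf, 1, trace[:epochs]
        gn = _full_grad_norm(x, y, theta0, theta1)
        if gn <= grad_tol:
            break
    return theta0, theta1, epochs, gn, 0, trace[:epochs]
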