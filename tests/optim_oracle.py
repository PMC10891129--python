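"""Independent step-by-step transcription of the three update rules.

Deliberately naive pure-Python loops over the printed equations, kept
free of any code from the package's fitting path; used to cross-check
the JIT-compiled implementation step for step.
"""

import math


def full_grad_norm(x, y, t0, t1):
    m = len(x)
    s0 = sum(t0 + t1 * xi - yi for xi, yi in zip(x, y))
    s1 = sum((t0 + t1 * xi - yi) * xi for xi, yi in zip(x, y))
    return math.sqrt((2.0 * s0 / m) ** 2 + (2.0 * s1 / m) ** 2)


def sgd_epochs(x, y, t0, t1, eta, perms):
    for perm in perms:
        for i in perm:
            r = t0 + t1 * x[i] - y[i]
            t0, t1 = t0 - eta * 2.0 * r, t1 - eta * 2.0 * x[i] * r
    return t0, t1


def _batches(perm, batch_size):
    for start in range(0, len(perm), batch_size):
        yield perm[start : start + batch_size]


def rmsprop_epochs(x, y, t0, t1, eta, beta, eps, batch_size, perms):
    v0 = v1 = 0.0
    for perm in perms:
        for batch in _batches(perm, batch_size):
            s0 = 0.0
            s1 = 0.0
            for i in batch:
                r = t0 + t1 * x[i] - y[i]
                s0 += r
                s1 += r * x[i]
            g0 = 2.0 * s0 / len(batch)
            g1 = 2.0 * s1 / len(batch)
            v0 = beta * v0 + (1.0 - beta) * g0 * g0
            v1 = beta * v1 + (1.0 - beta) * g1 * g1
            assert v0 >= 0.0 and v1 >= 0.0
            t0 = t0 - eta * g0 / math.sqrt(v0 + eps)
            t1 = t1 - eta * g1 / math.sqrt(v1 + eps)
    return t0, t1


def adam_epochs(x, y, t0, t1, eta, beta1, beta2, eps, batch_size, perms, time_scaled):
    m0 = m1 = v0 = v1 = 0.0
    t = 0
    for perm in perms:
        for batch in _batches(perm, batch_size):
            s0 = 0.0
            s1 = 0.0
            for i in batch:
                r = t0 + t1 * x[i] - y[i]
                s0 += r
                s1 += r * x[i]
            g0 = 2.0 * s0 / len(batch)
            g1 = 2.0 * s1 / len(batch)
            t += 1
            m0 = beta1 * m0 + (1.0 - beta1) * g0
            m1 = beta1 * m1 + (1.0 - beta1) * g1
            v0 = beta2 * v0 + (1.0 - beta2) * g0 * g0
            v1 = beta2 * v1 + (1.0 - beta2) * g1 * g1
            assert v0 >= 0.0 and v1 >= 0.0
            c1 = 1.0 - beta1**t if time_scaled else 1.0 - beta1
            c2 = 1.0 - beta2**t if time_scaled else 1.0 - beta2
            t0 = t0 - eta * (m0 / c1) / (math.sqrt(v0 / c2) + eps)
            t1 = t1 - eta * (m1 / c1) / (math.sqrt(v1 / c2) + eps)
    return t0, t1
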