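"""Compiled likelihood kernels (numba).

These evaluate the same per-trial log-likelihoods as the numpy grid
implementations in :mod:`obslearn.obs_models` and :mod:`obslearn.hier_fit`,
specialized for a (batch, participant) parameter grid.  The numpy paths
remain the reference implementations; tests assert agreement.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep of the env
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco

_KIND_CODES = {"full": 0, "action_only": 1, "reward_only": 2}
_PROB_FLOOR = 1e-300


@njit(cache=False)
def _obs_pointwise_jit(alpha_v, alpha_a, w_a, beta, pc, pr, cc, bounds, kind, out):  # pragma: no cover
    B, N = beta.shape
    nb = bounds.shape[0] - 1
    Q = np.empty(3)
    for i in range(B):
        for n in range(N):
            av = alpha_v[i, n]
            aa = alpha_a[i, n]
            w = w_a[i, n]
            bt = beta[i, n]
            for b in range(nb):
                V0, V1, V2 = 0.5, 0.5, 0.5
                A0, A1, A2 = 1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0
                for t in range(bounds[b], bounds[b + 1]):
                    c = pc[n, t]
                    r = pr[n, t]
                    if c == 0:
                        V0 += av * (r - V0)
                    elif c == 1:
                        V1 += av * (r - V1)
                    else:
                        V2 += av * (r - V2)
                    A0 *= 1.0 - aa
                    A1 *= 1.0 - aa
                    A2 *= 1.0 - aa
                    if c == 0:
                        A0 += aa
                    elif c == 1:
                        A1 += aa
                    else:
                        A2 += aa
                    if kind == 0:
                        Q[0] = (1.0 - w) * V0 + w * A0
                        Q[1] = (1.0 - w) * V1 + w * A1
                        Q[2] = (1.0 - w) * V2 + w * A2
                    elif kind == 1:
                        Q[0] = A0
                        Q[1] = A1
                        Q[2] = A2
                    else:
                        Q[0] = V0
                        Q[1] = V1
                        Q[2] = V2
                    z0 = bt * Q[0]
                    z1 = bt * Q[1]
                    z2 = bt * Q[2]
                    m = max(z0, max(z1, z2))
                    e0 = np.exp(z0 - m)
                    e1 = np.exp(z1 - m)
                    e2 = np.exp(z2 - m)
                    s = e0 + e1 + e2
                    ch = cc[n, t]
                    if ch == 0:
                        p = e0 / s
                    elif ch == 1:
                        p = e1 / s
                    else:
                        p = e2 / s
                    if p < _PROB_FLOOR:
                        p = _PROB_FLOOR
                    out[i, n, t] = np.log(p)


@njit(cache=False)
def _info_bonus_pointwise_jit(alpha, beta, kappa, choices, rewards, out):  # pragma: no cover
    B, N = beta.shape
    T = choices.shape[1]
    for i in range(B):
        for n in range(N):
            al = alpha[i, n]
            bt = beta[i, n]
            kp = kappa[i, n]
            q0, q1, q2 = 0.5, 0.5, 0.5
            n0, n1, n2 = 1.0, 1.0, 1.0
            for t in range(T):
                z0 = bt * (q0 + kp / n0)
                z1 = bt * (q1 + kp / n1)
                z2 = bt * (q2 + kp / n2)
                m = max(z0, max(z1, z2))
                e0 = np.exp(z0 - m)
                e1 = np.exp(z1 - m)
                e2 = np.exp(z2 - m)
                s = e0 + e1 + e2
                c = choices[n, t]
                r = rewards[n, t]
                if c == 0:
                    p = e0 / s
                    q0 += al * (r - q0)
                    n0 += 1.0
                elif c == 1:
                    p = e1 / s
                    q1 += al * (r - q1)
                    n1 += 1.0
                else:
                    p = e2 / s
                    q2 += al * (r - q2)
                    n2 += 1.0
                if p < _PROB_FLOOR:
                    p = _PROB_FLOOR
                out[i, n, t] = np.log(p)


def obs_pointwise(alpha_v, alpha_a, w_a, beta, blocks, kind: str) -> np.ndarray:
    """Jit-compiled per-trial log-likelihood grid; same contract as
    :func:`obslearn.obs_models.pointwise_loglik_grid` with lead shape (B, N)."""
    B, N = beta.shape
    pc = np.ascontiguousarray(np.concatenate([b[0] for b in blocks], axis=-1), dtype=np.int64)
    pr = np.ascontiguousarray(np.concatenate([b[1] for b in blocks], axis=-1), dtype=np.int64)
    cc = np.ascontiguousarray(np.concatenate([b[2] for b in blocks], axis=-1), dtype=np.int64)
    bounds = np.zeros(len(blocks) + 1, dtype=np.int64)
    bounds[1:] = np.cumsum([b[0].shape[-1] for b in blocks])
    out = np.empty((B, N, pc.shape[1]))
    _obs_pointwise_jit(
        np.ascontiguousarray(alpha_v, dtype=np.float64),
        np.ascontiguousarray(alpha_a, dtype=np.float64),
        np.ascontiguousarray(w_a, dtype=np.float64),
        np.ascontiguousarray(beta, dtype=np.float64),
        pc, pr, cc, bounds, _KIND_CODES[kind], out,
    )
    return out


def info_bonus_pointwise(alpha, beta, kappa, choices, rewards) -> np.ndarray:
    out = np.empty((beta.shape[0], beta.shape[1], choices.shape[1]))
    _info_bonus_pointwise_jit(
        np.ascontiguousarray(alpha, dtype=np.float64),
        np.ascontiguousarray(beta, dtype=np.float64),
        np.ascontiguousarray(kappa, dtype=np.float64),
        np.ascontiguousarray(choices, dtype=np.int64),
        np.ascontiguousarray(rewards, dtype=np.int64),
        out,
    )
    return out
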