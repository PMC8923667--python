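"""Independent brute-force oracles the implementation is checked against.

Each oracle takes a deliberately different route from the package: the
diffusion oracle uses scipy's dense *non-symmetric* eigensolver on the Markov
operator itself (the package goes through the symmetric conjugate), the
affinity oracle loops over explicit dot products, and the projection oracles
are per-column loops with full sorts.
"""
import numpy as np
from scipy.linalg import eig


def dense_diffusion_oracle(w: np.ndarray, n_components: int, alpha: float = 0.5,
                           diffusion_time: float = 0.0):
    """Diffusion-map components via dense eig of the row-normalised operator.

    Components are scaled to unit norm under the chain's stationary
    distribution, the same weight under which they are orthogonal.
    """
    w = np.asarray(w, dtype=float)
    d = w.sum(axis=1)
    k = w / np.outer(d**alpha, d**alpha) if alpha > 0 else w
    d2 = k.sum(axis=1)
    p = k / d2[:, None]
    evals, evecs = eig(p)
    evals, evecs = evals.real, evecs.real
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    pi = d2 / d2.sum()
    lam = evals[1:n_components + 1]
    comps = []
    for j in range(1, n_components + 1):
        u = evecs[:, j] / np.sqrt(np.sum(pi * evecs[:, j] ** 2))
        lj = lam[j - 1]
        scale = lj / (1 - lj) if diffusion_time == 0 else lj**diffusion_time
        comps.append(u * scale)
    return np.array(comps), lam


def cosine_affinity_oracle(x: np.ndarray) -> np.ndarray:
    """Cosine similarity by explicit per-pair dot products, negatives clipped."""
    n = x.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = np.dot(x[i], x[j]) / (np.linalg.norm(x[i]) * np.linalg.norm(x[j]))
    a = np.clip(a, 0.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return a


def project_gradient_oracle(grad: np.ndarray, fc: np.ndarray) -> np.ndarray:
    """Per-column argmax by explicit scan (ties -> lowest source index)."""
    out = np.empty(fc.shape[1])
    for j in range(fc.shape[1]):
        best_i, best_v = 0, -np.inf
        for i in range(fc.shape[0]):
            if fc[i, j] > best_v:
                best_i, best_v = i, fc[i, j]
        out[j] = grad[best_i]
    return out


def project_int_oracle(ints: np.ndarray, fc: np.ndarray, k: int) -> np.ndarray:
    """Per-row full sort, take the k largest signed correlations, average."""
    out = np.empty(fc.shape[0])
    for j in range(fc.shape[0]):
        order = sorted(range(fc.shape[1]), key=lambda i: (-fc[j, i], i))
        out[j] = np.mean([ints[i] for i in order[:k]])
    return out


def match_up_to_sign(a: np.ndarray, b: np.ndarray, atol: float) -> bool:
    """True when every row of a equals +/- the same row of b within atol."""
    return all(
        min(np.abs(ra - rb).max(), np.abs(ra + rb).max()) <= atol
        for ra, rb in zip(np.atleast_2d(a), np.atleast_2d(b))
    )
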