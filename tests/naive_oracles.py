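"""Independent naive-loop reference implementations of the point-calculation
stages (gather, offsets, similarity softmax, soft-argmax).

Deliberately written with scalar Python loops and ``math`` so they share no
code path with the vectorized implementations they check.
"""

import math

import numpy as np


def naive_gather(enc_m: np.ndarray, X: np.ndarray, p: int, grid: int) -> np.ndarray:
    out = np.zeros((len(X), enc_m.shape[1]))
    for i, (y, x) in enumerate(X):
        for iy in range(grid):
            for ix in range(grid):
                if iy * p <= y < (iy + 1) * p and ix * p <= x < (ix + 1) * p:
                    out[i] = enc_m[iy * grid + ix]
    return out


def naive_offsets(X: np.ndarray, p: int) -> np.ndarray:
    out = np.zeros_like(X, dtype=float)
    for i in range(len(X)):
        for j in range(2):
            out[i, j] = math.fmod(X[i, j], p) - math.floor(p / 2)
            if out[i, j] < -math.floor(p / 2):
                out[i, j] += p
    return out


def naive_similarity(gathered: np.ndarray, enc_f: np.ndarray) -> np.ndarray:
    L, N = len(gathered), len(enc_f)
    S = np.zeros((L, N))
    for i in range(L):
        logits = [float(gathered[i] @ enc_f[j]) for j in range(N)]
        m = max(logits)
        exps = [math.exp(v - m) for v in logits]
        tot = sum(exps)
        S[i] = [e / tot for e in exps]
    return S


def naive_soft_argmax(S: np.ndarray, p: int, image_size: int) -> np.ndarray:
    grid = image_size // p
    out = np.zeros((len(S), 2))
    for i in range(len(S)):
        for j in range(S.shape[1]):
            out[i, 0] += S[i, j] * (p / 2 + p * (j // grid))
            out[i, 1] += S[i, j] * (p / 2 + p * (j % grid))
    return out
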