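"""Independent scalar-loop reference implementations used as test oracles.

These deliberately avoid the vectorized code paths of ``thymixer.nn`` /
``thymixer.mixer``: everything is written as explicit per-index loops over
tokens and channels so that agreement with the package is a genuine
cross-check, not a tautology.
"""

import math

import numpy as np


def gelu_scalar(x: float) -> float:
    return 0.5 * x * (1.0 + math.erf(x / math.sqrt(2.0)))


def mlp_rows_loop(a: np.ndarray, block) -> np.ndarray:
    """Row-by-row layernorm -> W1 -> GELU -> W2 on a 2-D array.

    ``block`` is a thymixer MlpBlock whose parameters are read (never its
    forward path).
    """
    g = np.asarray(block.norm.params["gamma"], dtype=float)
    be = np.asarray(block.norm.params["beta"], dtype=float)
    w1 = np.asarray(block.fc1.params["W"], dtype=float)
    b1 = np.asarray(block.fc1.params["b"], dtype=float)
    w2 = np.asarray(block.fc2.params["W"], dtype=float)
    b2 = np.asarray(block.fc2.params["b"], dtype=float)
    out = np.zeros_like(np.asarray(a, dtype=float))
    for i in range(a.shape[0]):
        v = np.asarray(a[i], dtype=float)
        mu = sum(v) / len(v)
        var = sum((x - mu) ** 2 for x in v) / len(v)
        xhat = [(x - mu) / math.sqrt(var + block.norm.eps) for x in v]
        z = [g[j] * xhat[j] + be[j] for j in range(len(v))]
        h = []
        for k in range(w1.shape[1]):
            s = b1[k]
            for j in range(len(z)):
                s += z[j] * w1[j, k]
            h.append(gelu_scalar(s))
        for m in range(w2.shape[1]):
            s = b2[m]
            for k in range(len(h)):
                s += h[k] * w2[k, m]
            out[i, m] = s
    return out


def token_mixer_loop(x: np.ndarray, block) -> np.ndarray:
    """Transpose, per-channel MLP over the token axis, transpose back, add x."""
    t = mlp_rows_loop(x.T, block.token_mlp)
    return x + t.T


def channel_mixer_loop(x: np.ndarray, block) -> np.ndarray:
    """Per-token MLP over the channel axis, add x."""
    return x + mlp_rows_loop(x, block.channel_mlp)


def mixer_forward_loop(x: np.ndarray, blocks) -> np.ndarray:
    for b in blocks:
        x = channel_mixer_loop(token_mixer_loop(x, b), b)
    return x


def tokenize_loop(fmap: np.ndarray, projection) -> np.ndarray:
    """Loop over the h*w spatial positions in row-major order."""
    w = np.asarray(projection.params["W"], dtype=float)
    b = np.asarray(projection.params["b"], dtype=float)
    h, ww, c = fmap.shape
    out = np.zeros((h * ww, w.shape[1]))
    pos = 0
    for r in range(h):
        for cc in range(ww):
            out[pos] = np.asarray(fmap[r, cc], dtype=float) @ w + b
            pos += 1
    return out


def grid_crop_cells(sl: np.ndarray) -> np.ndarray:
    """Independent crop oracle: build the 3x3 cells by floor indexing and
    vertically stack cells (0,1) and (1,1)."""
    h, w = sl.shape
    ch, cw = h // 3, w // 3
    cells = {(i, j): sl[i * ch:(i + 1) * ch, j * cw:(j + 1) * cw]
             for i in range(3) for j in range(3)}
    return np.vstack([cells[(0, 1)], cells[(1, 1)]])


def any_positive_loop(labels, positive):
    """Brute-force any-positive rule by explicit scan."""
    found = False
    for l in labels:
        if l == positive:
            found = True
    return found
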