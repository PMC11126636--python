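"""Independent brute-force reference implementations used only by tests.

Everything here is written as literally as possible — explicit loops,
no shared code with the package — so that agreement with the package is
evidence of correctness rather than tautology.
"""

import math

import numpy as np


def naive_conv2d(x, w, b=None, stride=1, padding=0):
    """Quadruple-loop cross-correlation, NCHW."""
    n, c, h, wid = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (xp.shape[2] - kh) // stride + 1
    ow = (xp.shape[3] - kw) // stride + 1
    out = np.zeros((n, o, oh, ow), dtype=np.float64)
    for ni in range(n):
        for oi in range(o):
            for yi in range(oh):
                for xi in range(ow):
                    patch = xp[ni, :, yi * stride:yi * stride + kh,
                               xi * stride:xi * stride + kw]
                    out[ni, oi, yi, xi] = float((patch * w[oi]).sum())
                    if b is not None:
                        out[ni, oi, yi, xi] += b[oi]
    return out


def naive_bilinear(x, out_h, out_w):
    """Per-pixel bilinear interpolation, half-pixel convention."""
    n, c, h, w = x.shape
    out = np.zeros((n, c, out_h, out_w), dtype=np.float64)
    for ni in range(n):
        for ci in range(c):
            for i in range(out_h):
                for j in range(out_w):
                    sy = min(max((i + 0.5) * h / out_h - 0.5, 0), h - 1)
                    sx = min(max((j + 0.5) * w / out_w - 0.5, 0), w - 1)
                    y0, x0 = int(math.floor(sy)), int(math.floor(sx))
                    y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                    fy, fx = sy - y0, sx - x0
                    out[ni, ci, i, j] = (
                        x[ni, ci, y0, x0] * (1 - fy) * (1 - fx)
                        + x[ni, ci, y0, x1] * (1 - fy) * fx
                        + x[ni, ci, y1, x0] * fy * (1 - fx)
                        + x[ni, ci, y1, x1] * fy * fx)
    return out


def naive_csra(score_maps, lam, temperature):
    """Literal position-by-position evaluation of the CSRA pooling rule."""
    d, h, w = score_maps.shape
    out = np.zeros(d, dtype=np.float64)
    for k in range(d):
        xs = [float(score_maps[k, i, j]) for i in range(h) for j in range(w)]
        avg = sum(xs) / len(xs)
        exps = [math.exp(temperature * v - max(temperature * u for u in xs))
                for v in xs]
        z = sum(exps)
        attn = sum((e / z) * v for e, v in zip(exps, xs))
        out[k] = avg + lam * attn
    return out


def naive_coordinate_attention(x, module):
    """Step-by-step CA block evaluation using the module's weights."""
    n, c, h, w = x.shape

    def conv1x1(inp, conv):
        wt = conv.weight.data  # (O, C, 1, 1)
        out = np.einsum("nchw,oc->nohw", inp, wt[:, :, 0, 0])
        if conv.bias is not None:
            out = out + conv.bias.data[None, :, None, None]
        return out

    pool_h = x.mean(axis=3, keepdims=True)                     # N,C,H,1
    pool_w = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)
    y = np.concatenate([pool_h, pool_w], axis=2)               # N,C,H+W,1
    y = conv1x1(y, module.conv_in)
    # batch-norm with running statistics (module in eval mode)
    mu = module.bn.running_mean[None, :, None, None]
    var = module.bn.running_var[None, :, None, None]
    y = (y - mu) / np.sqrt(var + module.bn.eps)
    y = y * module.bn.weight.data[None, :, None, None] \
        + module.bn.bias.data[None, :, None, None]
    y = np.maximum(y, 0.0)
    a_h, a_w = y[:, :, :h, :], y[:, :, h:, :].transpose(0, 1, 3, 2)
    g_h = 1.0 / (1.0 + np.exp(-conv1x1(a_h, module.conv_h)))
    g_w = 1.0 / (1.0 + np.exp(-conv1x1(a_w, module.conv_w)))
    return x * g_h * g_w


def naive_se_attention(x, module):
    pooled = x.mean(axis=(2, 3))
    hidden = np.maximum(pooled @ module.fc1.weight.data.T, 0.0)
    gate = 1.0 / (1.0 + np.exp(-(hidden @ module.fc2.weight.data.T)))
    return x * gate[:, :, None, None]


def pairwise_auc(scores, labels):
    """Mann-Whitney pair enumeration with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ca_param_count(c, reduction=32, min_hidden=8):
    """Closed-form CA block parameter count (biased convs + BN affine)."""
    cm = max(min_hidden, c // reduction)
    return (c * cm + cm) + 2 * cm + 2 * (cm * c + c)
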