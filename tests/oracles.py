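"""Independent brute-force reference computations used by the tests.

Everything here is written as plain, loop-level NumPy so it shares no
code path with the package's vectorised implementations.
"""

from __future__ import annotations

import numpy as np


def avgpool_ref(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Count-normalised average pooling (border windows use valid taps only)."""
    B, C, H, W = x.shape
    Hout = (H + 2 * pad - k) // stride + 1
    Wout = (W + 2 * pad - k) // stride + 1
    y = np.zeros((B, C, Hout, Wout))
    for i in range(Hout):
        for j in range(Wout):
            acc = np.zeros((B, C))
            cnt = 0
            for u in range(k):
                for v in range(k):
                    r, c = i * stride + u - pad, j * stride + v - pad
                    if 0 <= r < H and 0 <= c < W:
                        acc += x[:, :, r, c]
                        cnt += 1
            y[:, :, i, j] = acc / cnt
    return y


def conv2d_ref(x, w, b=None, stride=1, pad=0, dilation=1, groups=1):
    """Direct quadruple-loop grouped convolution (zero padding)."""
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    Cout_g = Cout // groups
    Hout = (H + 2 * pad - dilation * (kh - 1) - 1) // stride + 1
    Wout = (W + 2 * pad - dilation * (kw - 1) - 1) // stride + 1
    y = np.zeros((B, Cout, Hout, Wout))
    for bi in range(B):
        for o in range(Cout):
            gi = o // Cout_g
            for i in range(Hout):
                for j in range(Wout):
                    acc = 0.0
                    for ci in range(Cin_g):
                        c = gi * Cin_g + ci
                        for u in range(kh):
                            for v in range(kw):
                                r = i * stride + u * dilation - pad
                                s = j * stride + v * dilation - pad
                                if 0 <= r < H and 0 <= s < W:
                                    acc += w[o, ci, u, v] * x[bi, c, r, s]
                    y[bi, o, i, j] = acc + (b[o] if b is not None else 0.0)
    return y


def eca_gates_ref(feats: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Channel gates: global average pool, zero-padded 1-D conv, sigmoid."""
    B, C = feats.shape[:2]
    w = weight.reshape(-1).astype(np.float64)
    k = w.size
    pad = k // 2
    gap = feats.mean(axis=(2, 3))
    padded = np.pad(gap, ((0, 0), (pad, pad)))
    out = np.zeros((B, C))
    for c in range(C):
        for t in range(k):
            out[:, c] += w[t] * padded[:, c + t]
    return 1.0 / (1.0 + np.exp(-out))


def scarf_forward_ref(module, x: np.ndarray) -> np.ndarray:
    """Enumerated weighted-sum reference for the receptive-field branch.

    For each output position, explicitly enumerates the k^2 attention-
    weighted samples and applies the fusion-convolution weights as a
    direct sum — no mosaic rearrangement.  Uses the module's own
    parameters; the module must be in inference mode.
    """
    spec = module.spec
    k, s = spec.kernel_size, spec.stride
    B, C, H, W = x.shape
    k2 = k * k
    # attention path: pooled context -> grouped 1x1 expansion -> softmax over k^2
    pooled = avgpool_ref(x, k, s, k // 2)
    Hout, Wout = pooled.shape[2:]
    aw = module.attn_conv.weight.data.astype(np.float64)
    ab = module.attn_conv.bias.data.astype(np.float64)
    logits = conv2d_ref(pooled, aw, ab, groups=module.attn_conv.groups)
    A = np.empty((B, C, k2, Hout, Wout))
    for b in range(B):
        for c in range(C):
            z = logits[b, c * k2 : (c + 1) * k2]
            e = np.exp(z - z.max(axis=0, keepdims=True))
            A[b, c] = e / e.sum(axis=0, keepdims=True)
    # feature path: grouped kxk conv -> BN (inference stats) -> ReLU -> ECA
    fw = module.feat_conv.weight.data.astype(np.float64)
    z = conv2d_ref(x, fw, None, stride=s, pad=k // 2, groups=C)
    bn = module.bn
    rm = bn._buffers["running_mean"].astype(np.float64)
    rv = bn._buffers["running_var"].astype(np.float64)
    z = (
        bn.weight.data.astype(np.float64)[None, :, None, None]
        * (z - rm[None, :, None, None])
        / np.sqrt(rv[None, :, None, None] + bn.eps)
        + bn.bias.data.astype(np.float64)[None, :, None, None]
    )
    z = np.maximum(z, 0.0)
    F = z * eca_gates_ref(z, module.eca.weight.data)[:, :, None, None]
    # fusion: direct weighted sum over the k^2 samples of each position
    Fr = F.reshape(B, C, k2, Hout, Wout)
    weighted = A * Fr
    fw2 = module.fuse.weight.data.astype(np.float64)  # (Cout, C, k, k)
    fb = module.fuse.bias.data.astype(np.float64)
    Cout = fw2.shape[0]
    y = np.zeros((B, Cout, Hout, Wout))
    for b in range(B):
        for o in range(Cout):
            for i in range(Hout):
                for j in range(Wout):
                    acc = fb[o]
                    for c in range(C):
                        for u in range(k):
                            for v in range(k):
                                acc += fw2[o, c, u, v] * weighted[b, c, u * k + v, i, j]
                    y[b, o, i, j] = acc
    return y


def classification_counts_ref(y_true, y_pred, n_classes):
    """Per-class TP/FP/FN/TN by direct enumeration."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = []
    for c in range(n_classes):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        tn = int(np.sum((y_true != c) & (y_pred != c)))
        out.append((tp, fp, fn, tn))
    return out
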