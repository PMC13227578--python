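"""Dual-head Vision Transformer in NumPy.

The model splits a grayscale image into non-overlapping P×P patches, embeds
each patch linearly, adds sinusoidal positional encodings, runs a stack of
pre-norm encoder blocks (multi-head self-attention + ReLU MLP, residual
connections), optionally one cross-attention block whose queries come from the
final layer and keys/values from an earlier one, mean-pools the tokens and
feeds the pooled feature to two heads:

* a softmax classification head  ``prob = softmax(W_class · x + b_class)``
* an affine severity head        ``score = w_severity · x + b_severity``

Both the forward pass and the exact reverse-mode gradients are implemented
here; gradients are verified against central differences in the test suite.
With ``heads=1`` the attention blocks reduce exactly to the single-head
formula ``softmax(Q Kᵀ / √d_k) V``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatchGrid",
    "ViTConfig",
    "DualHeadOutput",
    "patchify",
    "unpatchify",
    "embed_patches",
    "positional_encoding",
    "positional_encoding_2d",
    "self_attention",
    "cross_attention",
    "classification_head",
    "severity_head",
    "init_params",
    "forward",
    "backward",
]


# ---------------------------------------------------------------------------
# patch handling


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping P×P patches of an image, row-major."""

    patch_size: int
    rows: int
    cols: int
    patches: np.ndarray  # (N, P, P)

    @property
    def n(self) -> int:
        return self.rows * self.cols


def patchify(img: np.ndarray, patch_size: int) -> PatchGrid:
    """Split an H×W image into (H/P)·(W/P) patches of size P×P.

    P must divide both dimensions exactly; no implicit padding is applied.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {arr.shape}")
    h, w = arr.shape
    p = int(patch_size)
    if p < 1 or h % p or w % p:
        raise ValueError(f"patch size {p} must divide image shape {(h, w)}")
    rows, cols = h // p, w // p
    patches = (
        arr.reshape(rows, p, cols, p).transpose(0, 2, 1, 3).reshape(rows * cols, p, p)
    )
    return PatchGrid(patch_size=p, rows=rows, cols=cols, patches=patches)


def unpatchify(grid: PatchGrid) -> np.ndarray:
    """Exact inverse of :func:`patchify`."""
    p, r, c = grid.patch_size, grid.rows, grid.cols
    return (
        grid.patches.reshape(r, c, p, p).transpose(0, 2, 1, 3).reshape(r * p, c * p)
    )


def embed_patches(
    grid: PatchGrid, projection: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Linear patch embedding: row i = flatten(patch_i) · projection + bias.

    ``projection`` is P²×D, ``bias`` is a D-vector; the result is N×D.
    """
    proj = np.asarray(projection, dtype=np.float64)
    b = np.asarray(bias, dtype=np.float64)
    p2 = grid.patch_size * grid.patch_size
    if proj.ndim != 2 or proj.shape[0] != p2:
        raise ValueError(f"projection must have {p2} rows, got {proj.shape}")
    if b.shape != (proj.shape[1],):
        raise ValueError("bias length must equal the embedding dimension")
    flat = grid.patches.reshape(grid.n, p2)
    return flat @ proj + b


# ---------------------------------------------------------------------------
# positional encodings


def positional_encoding(n: int, d: int) -> np.ndarray:
    """Sinusoidal positional encoding over token index.

    entry(pos, 2i) = sin(pos / 10000^(2i/d)); entry(pos, 2i+1) = cos(same).
    ``d`` must be even.
    """
    if d % 2:
        raise ValueError(f"embedding dimension must be even, got {d}")
    pos = np.arange(n, dtype=np.float64)[:, None]
    i = np.arange(d // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d)
    pe = np.empty((n, d), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def positional_encoding_2d(rows: int, cols: int, d: int) -> np.ndarray:
    """Factored 2-D variant: half the channels encode the patch row, half the
    patch column, each with the 1-D sinusoidal scheme."""
    if d % 4:
        raise ValueError("2-D positional encoding needs d divisible by 4")
    pe_r = positional_encoding(rows, d // 2)
    pe_c = positional_encoding(cols, d // 2)
    pe = np.empty((rows * cols, d), dtype=np.float64)
    for r in range(rows):
        for c in range(cols):
            pe[r * cols + c, : d // 2] = pe_r[r]
            pe[r * cols + c, d // 2 :] = pe_c[c]
    return pe


# ---------------------------------------------------------------------------
# attention primitives (single-head reference forms)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def self_attention(
    e: np.ndarray, w_q: np.ndarray, w_k: np.ndarray, w_v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """softmax(Q Kᵀ / √d_k) V with Q = E·W_Q, K = E·W_K, V = E·W_V.

    Returns ``(output, weights)`` where ``weights`` is the row-stochastic
    N×N attention matrix.
    """
    return cross_attention(e, e, w_q, w_k, w_v)


def cross_attention(
    e_query: np.ndarray,
    e_context: np.ndarray,
    w_q: np.ndarray,
    w_k: np.ndarray,
    w_v: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Attention with queries from one representation and keys/values from
    another: softmax(Q Kᵀ / √d_k) V with Q = E_q·W_Q, K = E_c·W_K, V = E_c·W_V."""
    eq = np.asarray(e_query, dtype=np.float64)
    ec = np.asarray(e_context, dtype=np.float64)
    if eq.shape[-1] != w_q.shape[0] or ec.shape[-1] != w_k.shape[0]:
        raise ValueError("embedding/query-key dimension mismatch")
    d_k = w_q.shape[1]
    if d_k == 0:
        raise ValueError("key dimension d_k must be positive")
    q = eq @ w_q
    k = ec @ w_k
    v = ec @ w_v
    weights = _softmax(q @ k.T / np.sqrt(d_k))
    return weights @ v, weights


# ---------------------------------------------------------------------------
# heads


def classification_head(
    features: np.ndarray, w_class: np.ndarray, b_class: np.ndarray
) -> np.ndarray:
    """softmax(W_class · x + b_class) — a C-vector of class probabilities."""
    x = np.asarray(features, dtype=np.float64)
    w = np.asarray(w_class, dtype=np.float64)
    b = np.asarray(b_class, dtype=np.float64)
    if w.ndim != 2 or w.shape[1] != x.shape[-1] or b.shape != (w.shape[0],):
        raise ValueError("classification head shape mismatch")
    return _softmax(w @ x + b)


def severity_head(
    features: np.ndarray, w_severity: np.ndarray, b_severity: float
) -> float:
    """Affine severity score: w_severity · x + b_severity."""
    x = np.asarray(features, dtype=np.float64)
    w = np.asarray(w_severity, dtype=np.float64)
    if w.shape != x.shape:
        raise ValueError("severity head shape mismatch")
    return float(w @ x + b_severity)


# ---------------------------------------------------------------------------
# full model


@dataclass(frozen=True)
class ViTConfig:
    """Architecture hyperparameters.

    Defaults are small enough for CPU training while keeping the structure of
    the full architecture: 64×64 inputs, 16×16 patches (16 tokens), embedding
    dimension 32, two pre-norm blocks with 2 attention heads each, a 4×
    feed-forward expansion and mean pooling over tokens.
    """

    image_size: tuple[int, int] = (64, 64)
    patch_size: int = 16
    embed_dim: int = 32
    depth: int = 2
    heads: int = 2
    num_classes: int = 4
    mlp_ratio: int = 4
    use_positional: bool = True
    positional: str = "1d"  # "1d" or "2d"
    use_self_attention: bool = True
    use_cross_attention: bool = False
    cross_source: int = 0  # encoder block whose output provides keys/values
    use_severity_head: bool = True

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h % self.patch_size or w % self.patch_size:
            raise ValueError("patch size must divide both image dimensions")
        if self.embed_dim % self.heads:
            raise ValueError("heads must divide embed_dim")
        if self.embed_dim % 2:
            raise ValueError("embed_dim must be even")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.use_cross_attention and not 0 <= self.cross_source < max(self.depth, 1):
            raise ValueError("cross_source must index an encoder block")
        if self.positional not in ("1d", "2d"):
            raise ValueError("positional must be '1d' or '2d'")

    @property
    def grid(self) -> tuple[int, int]:
        return (self.image_size[0] // self.patch_size, self.image_size[1] // self.patch_size)

    @property
    def n_tokens(self) -> int:
        r, c = self.grid
        return r * c


@dataclass
class DualHeadOutput:
    """Joint prediction: class probabilities, severity score, attention maps."""

    class_probs: np.ndarray  # (B, C)
    severity_score: np.ndarray  # (B,)
    attention_maps: list[np.ndarray] = field(default_factory=list)  # (B, h, N, N)
    features: np.ndarray | None = None  # (B, D) pooled


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: ViTConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Scaled-uniform (Glorot) initialization of all learnable arrays."""
    rng = np.random.default_rng(seed)
    d = config.embed_dim
    p2 = config.patch_size**2
    params: dict[str, np.ndarray] = {
        "embed.W": _glorot(rng, (p2, d)),
        "embed.b": np.zeros(d),
    }
    for i in range(config.depth):
        pre = f"blk{i}."
        params[pre + "ln1.g"] = np.ones(d)
        params[pre + "ln1.b"] = np.zeros(d)
        params[pre + "Wq"] = _glorot(rng, (d, d))
        params[pre + "Wk"] = _glorot(rng, (d, d))
        params[pre + "Wv"] = _glorot(rng, (d, d))
        params[pre + "ln2.g"] = np.ones(d)
        params[pre + "ln2.b"] = np.zeros(d)
        params[pre + "W1"] = _glorot(rng, (d, config.mlp_ratio * d))
        params[pre + "b1"] = np.zeros(config.mlp_ratio * d)
        params[pre + "W2"] = _glorot(rng, (config.mlp_ratio * d, d))
        params[pre + "b2"] = np.zeros(d)
    if config.use_cross_attention:
        params["cross.lnq.g"] = np.ones(d)
        params["cross.lnq.b"] = np.zeros(d)
        params["cross.lnc.g"] = np.ones(d)
        params["cross.lnc.b"] = np.zeros(d)
        params["cross.Wq"] = _glorot(rng, (d, d))
        params["cross.Wk"] = _glorot(rng, (d, d))
        params["cross.Wv"] = _glorot(rng, (d, d))
    params["final_ln.g"] = np.ones(d)
    params["final_ln.b"] = np.zeros(d)
    params["head.Wc"] = _glorot(rng, (config.num_classes, d))
    params["head.bc"] = np.zeros(config.num_classes)
    if config.use_severity_head:
        params["head.ws"] = _glorot(rng, (d, 1))[:, 0]
        params["head.bs"] = np.zeros(())
    return params


# --- layer norm -------------------------------------------------------------

_LN_EPS = 1e-5


def _ln_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc**2).mean(-1, keepdims=True) + _LN_EPS)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


# --- multi-head attention ---------------------------------------------------


def _split_heads(x: np.ndarray, heads: int) -> np.ndarray:
    b, n, d = x.shape
    return x.reshape(b, n, heads, d // heads).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    b, h, n, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, n, h * dh)


def _mha_fwd(xq, xc, wq, wk, wv, heads):
    dh = wq.shape[1] // heads
    q = _split_heads(xq @ wq, heads)
    k = _split_heads(xc @ wk, heads)
    v = _split_heads(xc @ wv, heads)
    s = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
    a = _softmax(s)
    out = _merge_heads(a @ v)
    return out, a, (xq, xc, q, k, v, a, heads, dh)


def _mha_bwd(dout, cache, wq, wk, wv):
    xq, xc, q, k, v, a, heads, dh = cache
    do = _split_heads(dout, heads)
    da = do @ v.transpose(0, 1, 3, 2)
    dv = a.transpose(0, 1, 3, 2) @ do
    ds = a * (da - (da * a).sum(-1, keepdims=True))
    dq = ds @ k / np.sqrt(dh)
    dk = ds.transpose(0, 1, 3, 2) @ q / np.sqrt(dh)
    dq, dk, dv = _merge_heads(dq), _merge_heads(dk), _merge_heads(dv)
    dwq = np.einsum("bnd,bne->de", xq, dq)
    dwk = np.einsum("bnd,bne->de", xc, dk)
    dwv = np.einsum("bnd,bne->de", xc, dv)
    dxq = dq @ wq.T
    dxc = dk @ wk.T + dv @ wv.T
    return dxq, dxc, dwq, dwk, dwv


# --- forward / backward -----------------------------------------------------


def _pos_encoding_for(config: ViTConfig) -> np.ndarray:
    r, c = config.grid
    if config.positional == "2d":
        return positional_encoding_2d(r, c, config.embed_dim)
    return positional_encoding(r * c, config.embed_dim)


def _patchify_batch(images: np.ndarray, p: int) -> np.ndarray:
    b, h, w = images.shape
    r, c = h // p, w // p
    return (
        images.reshape(b, r, p, c, p).transpose(0, 1, 3, 2, 4).reshape(b, r * c, p * p)
    )


def forward(
    params: dict[str, np.ndarray],
    images: np.ndarray,
    config: ViTConfig,
    *,
    return_cache: bool = False,
):
    """Run the full model on a batch of images.

    ``images`` is (B, H, W) or (H, W); returns a :class:`DualHeadOutput`
    whose arrays carry a leading batch axis (length 1 for a single image).
    With ``return_cache=True`` also returns the intermediate activations
    needed by :func:`backward`.
    """
    imgs = np.asarray(images, dtype=np.float64)
    if imgs.ndim == 2:
        imgs = imgs[None]
    if imgs.shape[1:] != tuple(config.image_size):
        raise ValueError(
            f"image shape {imgs.shape[1:]} does not match config {config.image_size}"
        )
    flat = _patchify_batch(imgs, config.patch_size)  # (B, N, P²)
    x = flat @ params["embed.W"] + params["embed.b"]
    if config.use_positional:
        x = x + _pos_encoding_for(config)[None]

    cache: dict = {"flat": flat, "blocks": [], "outs": []}
    attn_maps: list[np.ndarray] = []
    for i in range(config.depth):
        pre = f"blk{i}."
        blk: dict = {}
        if config.use_self_attention:
            a_in, blk["ln1"] = _ln_fwd(x, params[pre + "ln1.g"], params[pre + "ln1.b"])
            att, a_weights, blk["mha"] = _mha_fwd(
                a_in, a_in, params[pre + "Wq"], params[pre + "Wk"], params[pre + "Wv"],
                config.heads,
            )
            x = x + att
            attn_maps.append(a_weights)
        m_in, blk["ln2"] = _ln_fwd(x, params[pre + "ln2.g"], params[pre + "ln2.b"])
        h1 = m_in @ params[pre + "W1"] + params[pre + "b1"]
        hr = np.maximum(h1, 0.0)
        x = x + hr @ params[pre + "W2"] + params[pre + "b2"]
        blk["m_in"] = m_in
        blk["relu_mask"] = h1 > 0
        blk["hr"] = hr
        cache["blocks"].append(blk)
        cache["outs"].append(x)

    if config.use_cross_attention and config.depth > 0:
        ctx = cache["outs"][config.cross_source]
        q_in, cache["cross_lnq"] = _ln_fwd(
            x, params["cross.lnq.g"], params["cross.lnq.b"]
        )
        c_in, cache["cross_lnc"] = _ln_fwd(
            ctx, params["cross.lnc.g"], params["cross.lnc.b"]
        )
        att, a_weights, cache["cross_mha"] = _mha_fwd(
            q_in, c_in, params["cross.Wq"], params["cross.Wk"], params["cross.Wv"],
            config.heads,
        )
        x = x + att
        attn_maps.append(a_weights)

    xf, cache["final_ln"] = _ln_fwd(x, params["final_ln.g"], params["final_ln.b"])
    feats = xf.mean(axis=1)  # (B, D) mean pooling over tokens
    logits = feats @ params["head.Wc"].T + params["head.bc"]
    probs = _softmax(logits)
    if config.use_severity_head:
        sev = feats @ params["head.ws"] + params["head.bs"]
    else:
        sev = np.zeros(imgs.shape[0])
    cache["feats"] = feats
    cache["probs"] = probs
    out = DualHeadOutput(
        class_probs=probs,
        severity_score=sev,
        attention_maps=attn_maps,
        features=feats,
    )
    if return_cache:
        return out, cache
    return out


def backward(
    params: dict[str, np.ndarray],
    cache: dict,
    dlogits: np.ndarray,
    dsev: np.ndarray,
    config: ViTConfig,
) -> dict[str, np.ndarray]:
    """Exact gradients of a scalar loss given its gradients w.r.t. the class
    logits (B×C) and severity outputs (B,)."""
    grads: dict[str, np.ndarray] = {}
    feats = cache["feats"]
    grads["head.Wc"] = dlogits.T @ feats
    grads["head.bc"] = dlogits.sum(0)
    dfeats = dlogits @ params["head.Wc"]
    if config.use_severity_head:
        grads["head.ws"] = feats.T @ dsev
        grads["head.bs"] = np.asarray(dsev.sum())
        dfeats = dfeats + dsev[:, None] * params["head.ws"]

    n = config.n_tokens
    dxf = np.repeat(dfeats[:, None, :], n, axis=1) / n
    dx, grads["final_ln.g"], grads["final_ln.b"] = _ln_bwd(dxf, cache["final_ln"])

    dctx = None
    if config.use_cross_attention and config.depth > 0:
        dq_in, dc_in, dwq, dwk, dwv = _mha_bwd(
            dx, cache["cross_mha"], params["cross.Wq"], params["cross.Wk"],
            params["cross.Wv"],
        )
        grads["cross.Wq"], grads["cross.Wk"], grads["cross.Wv"] = dwq, dwk, dwv
        dxq, grads["cross.lnq.g"], grads["cross.lnq.b"] = _ln_bwd(
            dq_in, cache["cross_lnq"]
        )
        dctx_ln, grads["cross.lnc.g"], grads["cross.lnc.b"] = _ln_bwd(
            dc_in, cache["cross_lnc"]
        )
        dx = dx + dxq  # residual + query path
        dctx = dctx_ln

    for i in reversed(range(config.depth)):
        if dctx is not None and i == config.cross_source:
            dx = dx + dctx
            dctx = None
        pre = f"blk{i}."
        blk = cache["blocks"][i]
        # MLP sub-layer
        dm_out = dx
        grads[pre + "W2"] = np.einsum("bnd,bne->de", blk["hr"], dm_out)
        grads[pre + "b2"] = dm_out.sum((0, 1))
        dhr = dm_out @ params[pre + "W2"].T
        dh1 = dhr * blk["relu_mask"]
        grads[pre + "W1"] = np.einsum("bnd,bne->de", blk["m_in"], dh1)
        grads[pre + "b1"] = dh1.sum((0, 1))
        dm_in = dh1 @ params[pre + "W1"].T
        dx_ln, grads[pre + "ln2.g"], grads[pre + "ln2.b"] = _ln_bwd(dm_in, blk["ln2"])
        dx = dx + dx_ln
        # attention sub-layer
        if config.use_self_attention:
            da_in_q, da_in_c, dwq, dwk, dwv = _mha_bwd(
                dx, blk["mha"], params[pre + "Wq"], params[pre + "Wk"],
                params[pre + "Wv"],
            )
            grads[pre + "Wq"], grads[pre + "Wk"], grads[pre + "Wv"] = dwq, dwk, dwv
            da_in = da_in_q + da_in_c
            dx_ln, grads[pre + "ln1.g"], grads[pre + "ln1.b"] = _ln_bwd(
                da_in, blk["ln1"]
            )
            dx = dx + dx_ln

    if dctx is not None:  # cross source was the embedding stage (depth>0 guaranteed)
        dx = dx + dctx

    grads["embed.W"] = np.einsum("bnp,bnd->pd", cache["flat"], dx)
    grads["embed.b"] = dx.sum((0, 1))
    return grads
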