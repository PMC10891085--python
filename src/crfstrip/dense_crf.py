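"""Fully-connected CRF energy and differentiable mean-field inference.

The model couples every voxel pair ``(i, j)`` through Gaussian kernels over
voxel features: an *appearance* kernel on position, image intensity and
(optionally) learned deep-feature channels, and a *smoothness* kernel on
position alone::

    k1(f_i, f_j) = exp(-|p_i-p_j|^2 / 2 th_a^2 - |I_i-I_j|^2 / 2 th_b^2
                       - sum_c (d_ic-d_jc)^2 / 2 th_d_c^2)
    k2(f_i, f_j) = exp(-|p_i-p_j|^2 / 2 th_g^2)

The Gibbs energy of a hard labelling ``x`` is the sum of unary potentials
``-U_i(x_i)`` (network logits are negative unary energies) and pairwise
potentials ``mu(x_i, x_j) * (w1 k1 + w2 k2)`` over unordered pairs.  Mean
field replaces the intractable posterior by a product of per-voxel
distributions ``Q_i`` and iterates a fixed-point update; unrolled for a set
number of iterations it becomes a recurrent layer that is differentiable in
the unaries, the deep features, the kernel parameters and the label
compatibility matrix.

Two message-passing paths are provided: an exact ``O(N^2)`` reference and a
truncated-window fast path.  With the window radius covering the whole grid
the fast path is exact; smaller radii trade the distant (exponentially
suppressed) tail for speed.  Self-pairs are excluded by filtering with the
full window (where ``k(f_i, f_i) = 1``) and subtracting ``Q_i``.

Array layout is channel-first throughout: probability fields and unaries are
``(L, X, Y, Z)``, deep features ``(D, X, Y, Z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor, from_op

__all__ = [
    "VoxelFeatures", "KernelBank", "Compatibility",
    "kernel_value", "gaussian_messages", "gaussian_messages_reference",
    "meanfield_step", "crf_inference", "gibbs_energy",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelFeatures:
    """Per-voxel feature channels driving the CRF kernels.

    positions : (3, X, Y, Z) voxel coordinates (numpy, never trained)
    intensity : (1, X, Y, Z) image intensities in [0, 1] (numpy)
    deep      : (D, X, Y, Z) learned feature channels (Tensor; D may be 0)
    """

    positions: np.ndarray
    intensity: np.ndarray
    deep: Tensor | None = None

    @classmethod
    def from_image(cls, image: np.ndarray, deep: Tensor | None = None
                   ) -> "VoxelFeatures":
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 3:
            img = img[None]
        shape = img.shape[1:]
        grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                            indexing="ij")
        pos = np.stack(grids)
        if deep is not None and deep.shape[1:] != shape:
            raise ValueError("deep feature grid does not match image grid")
        return cls(positions=pos, intensity=img, deep=deep)

    @property
    def spatial_shape(self):
        return self.intensity.shape[1:]

    @property
    def n_deep(self) -> int:
        return 0 if self.deep is None else self.deep.shape[0]


def _scalar(x, trainable: bool) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Parameter(np.float64(x), requires_grad=trainable)


@dataclass
class KernelBank:
    """Kernel weights and Gaussian bandwidths of the dense CRF.

    Bandwidths are in voxel units (positions) and intensity units.  In the
    reference configuration the weights and bandwidths are fixed
    hyperparameters (``trainable=False``); they can be promoted to trainable
    parameters for experimentation, and gradients flow through them either
    way.
    """

    w1: Tensor
    w2: Tensor
    theta_alpha: Tensor
    theta_beta: Tensor
    theta_gamma: Tensor
    theta_delta: Tensor | None = None

    @classmethod
    def create(cls, n_deep: int = 0, w1: float = 1.0, w2: float = 1.0,
               theta_alpha: float = 3.0, theta_beta: float = 0.1,
               theta_gamma: float = 3.0, theta_delta=1.0,
               trainable: bool = False) -> "KernelBank":
        for name, v in [("theta_alpha", theta_alpha), ("theta_beta", theta_beta),
                        ("theta_gamma", theta_gamma)]:
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        td = None
        if n_deep > 0:
            td = np.broadcast_to(np.asarray(theta_delta, dtype=np.float64),
                                 (n_deep,)).copy()
            if not (td > 0).all():
                raise ValueError("theta_delta entries must be positive")
            td = Parameter(td, requires_grad=trainable)
        return cls(w1=_scalar(w1, trainable), w2=_scalar(w2, trainable),
                   theta_alpha=_scalar(theta_alpha, trainable),
                   theta_beta=_scalar(theta_beta, trainable),
                   theta_gamma=_scalar(theta_gamma, trainable),
                   theta_delta=td)

    def trainable_params(self) -> dict:
        out = {}
        for name in ("w1", "w2", "theta_alpha", "theta_beta", "theta_gamma",
                     "theta_delta"):
            t = getattr(self, name)
            if t is not None and t.requires_grad:
                out[name] = t
        return out


@dataclass
class Compatibility:
    """Label-compatibility matrix mu(l, l') penalising label disagreement."""

    mu: Tensor = field(default=None)

    @classmethod
    def potts(cls, n_labels: int = 2, trainable: bool = True) -> "Compatibility":
        m = 1.0 - np.eye(n_labels)
        return cls(mu=Parameter(m, requires_grad=trainable))

    @property
    def n_labels(self) -> int:
        return self.mu.shape[0]


# ---------------------------------------------------------------------------
# Pairwise kernels
# ---------------------------------------------------------------------------

def kernel_value(i, j, features: VoxelFeatures, bank: KernelBank):
    """Appearance and smoothness kernel values for one voxel pair.

    `i`, `j` are voxel index triples.  Weights w1/w2 are *not* folded in.
    """
    i, j = tuple(i), tuple(j)
    if i == j:
        raise ValueError("self-pairs are excluded from the pairwise term")
    pi = features.positions[(slice(None),) + i]
    pj = features.positions[(slice(None),) + j]
    d2 = float(((pi - pj) ** 2).sum())
    ta = float(bank.theta_alpha.data)
    tb = float(bank.theta_beta.data)
    tg = float(bank.theta_gamma.data)
    s = -d2 / (2 * ta ** 2)
    di = float(features.intensity[(0,) + i] - features.intensity[(0,) + j])
    s -= di ** 2 / (2 * tb ** 2)
    if features.n_deep:
        fd = features.deep.data
        delta = fd[(slice(None),) + i] - fd[(slice(None),) + j]
        s -= float((delta ** 2 / (2 * bank.theta_delta.data ** 2)).sum())
    k1 = float(np.exp(s))
    k2 = float(np.exp(-d2 / (2 * tg ** 2)))
    return k1, k2


# ---------------------------------------------------------------------------
# Fast path: truncated-window filtering as fused autodiff ops
# ---------------------------------------------------------------------------

def _offsets(shape, radius: int | None):
    """Displacement vectors of the filtering window (0 included)."""
    if radius is None:
        ranges = [range(-(s - 1), s) for s in shape]
    else:
        if radius < 0:
            raise ValueError("radius must be >= 0")
        ranges = [range(-min(radius, s - 1), min(radius, s - 1) + 1)
                  for s in shape]
    return [(dx, dy, dz) for dx in ranges[0] for dy in ranges[1]
            for dz in ranges[2]]


def _shift(a: np.ndarray, o) -> np.ndarray:
    """shift(a, o)[..., v] = a[..., v - o], zero-filled outside the grid."""
    out = np.zeros_like(a)
    src, dst = [], []
    for d, s in zip(o, a.shape[-3:]):
        src.append(slice(max(0, -d), s - max(0, d)))
        dst.append(slice(max(0, d), s - max(0, -d)))
    lead = (slice(None),) * (a.ndim - 3)
    out[lead + tuple(dst)] = a[lead + tuple(src)]
    return out


def _appearance_stack(features: VoxelFeatures, bank: KernelBank,
                      offsets) -> Tensor:
    """Fused op: per-offset appearance kernel maps k1_o[v] = k1(f_v, f_{v-o}).

    Returns a Tensor of shape (n_offsets, X, Y, Z), differentiable in the
    deep features and in theta_alpha / theta_beta / theta_delta.
    """
    I = features.intensity[0]
    deep = features.deep
    dd = deep.data if deep is not None else None
    ta, tb = bank.theta_alpha, bank.theta_beta
    td = bank.theta_delta
    sq = np.array([dx * dx + dy * dy + dz * dz for (dx, dy, dz) in offsets],
                  dtype=np.float64)
    shape = features.spatial_shape

    data = np.empty((len(offsets),) + shape)
    for n, o in enumerate(offsets):
        s = np.full(shape, -sq[n] / (2 * ta.data ** 2))
        dI = I - _shift(I, o)
        s -= dI * dI / (2 * tb.data ** 2)
        if dd is not None:
            delta = dd - _shift(dd, o)
            s -= (delta * delta / (2 * td.data[:, None, None, None] ** 2)
                  ).sum(axis=0)
        data[n] = np.exp(s)

    parents = tuple(t for t in (deep, ta, tb, td) if t is not None)
    out = from_op(data, parents)

    def bw():
        g = out.grad * data  # dL/ds_o per offset
        if ta.requires_grad:
            ta._accumulate((g.sum(axis=(1, 2, 3)) * sq).sum()
                           / float(ta.data) ** 3)
        for n, o in enumerate(offsets):
            dI = I - _shift(I, o)
            if tb.requires_grad:
                tb._accumulate((g[n] * dI * dI).sum() / float(tb.data) ** 3)
            if dd is not None and (deep.requires_grad_path or td.requires_grad):
                delta = dd - _shift(dd, o)
                if td.requires_grad:
                    td._accumulate((g[n][None] * delta * delta
                                    ).sum(axis=(1, 2, 3)) / td.data ** 3)
                if deep.requires_grad_path:
                    t = g[n][None] * delta / td.data[:, None, None, None] ** 2
                    deep._accumulate(_shift(t, tuple(-d for d in o)) - t)

    out._backward = bw
    return out


def _smoothness_stack(bank: KernelBank, offsets) -> Tensor:
    """Per-offset smoothness kernel values (position only): shape (n_off,)."""
    sq = np.array([dx * dx + dy * dy + dz * dz for (dx, dy, dz) in offsets],
                  dtype=np.float64)
    tg = bank.theta_gamma
    data = np.exp(-sq / (2 * tg.data ** 2))
    out = from_op(data, (tg,))

    def bw():
        if tg.requires_grad:
            tg._accumulate((out.grad * data * sq).sum() / float(tg.data) ** 3)

    out._backward = bw
    return out


def _slices(o, shape):
    """(dst, src) slice tuples with dst = src + o, both inside the grid."""
    src, dst = [], []
    for d, s in zip(o, shape):
        src.append(slice(max(0, -d), s - max(0, d)))
        dst.append(slice(max(0, d), s - max(0, -d)))
    return tuple(dst), tuple(src)


def _windowed_filter(Q: Tensor, W: Tensor, offsets) -> Tensor:
    """Fused op: M[l, v] = sum_o W_o[v] * Q[l, v - o].

    W has shape (n_offsets, X, Y, Z) or (n_offsets,).  Includes the o = 0
    term; callers subtract Q for self-exclusion.
    """
    per_voxel = W.ndim == 4
    shape = Q.shape[1:]
    M = np.zeros_like(Q.data)
    all_ = (slice(None),)
    for n, o in enumerate(offsets):
        dst, src = _slices(o, shape)
        w = W.data[n][dst] if per_voxel else W.data[n]
        M[all_ + dst] += w * Q.data[all_ + src]
    out = from_op(M, (Q, W))

    def bw():
        if Q.requires_grad_path:
            gq = np.zeros_like(Q.data)
        need_w = W.requires_grad_path
        if need_w and W.grad is None:
            W.grad = np.zeros_like(W.data)
        for n, o in enumerate(offsets):
            dst, src = _slices(o, shape)
            w = W.data[n][dst] if per_voxel else W.data[n]
            if Q.requires_grad_path:
                gq[all_ + src] += w * out.grad[all_ + dst]
            if need_w:
                contrib = (out.grad[all_ + dst] * Q.data[all_ + src]
                           ).sum(axis=0)
                if per_voxel:
                    W.grad[n][dst] += contrib
                else:
                    W.grad[n] += contrib.sum()
        if Q.requires_grad_path:
            Q._accumulate(gq)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Message passing
# ---------------------------------------------------------------------------

def _check_normalized(Q: np.ndarray, tol: float = 1e-4):
    sums = Q.sum(axis=0)
    if np.abs(sums - 1.0).max() > tol:
        raise ValueError("belief field Q is not normalized per voxel "
                         f"(max deviation {np.abs(sums - 1.0).max():.2e})")


def gaussian_messages(Q, features: VoxelFeatures, bank: KernelBank,
                      radius: int | None = None):
    """Per-kernel message grids M^m_i(l) = sum_{j != i} k^m(f_i, f_j) Q_j(l).

    Weights w1/w2 are not folded in.  `radius` truncates the filtering
    window; `None` spans the whole grid (exact dense messages).  Q may be a
    numpy array or a Tensor; Tensors keep the computation differentiable.
    """
    q = Q.data if isinstance(Q, Tensor) else np.asarray(Q, dtype=np.float64)
    _check_normalized(q)
    if not isinstance(Q, Tensor):
        Q = Tensor(q)
    offs = _offsets(features.spatial_shape, radius)
    K1 = _appearance_stack(features, bank, offs)
    K2 = _smoothness_stack(bank, offs)
    M1 = _windowed_filter(Q, K1, offs) - Q   # k1(f_i, f_i) = 1
    M2 = _windowed_filter(Q, K2, offs) - Q
    return M1, M2


def _combined_weights(features: VoxelFeatures, bank: KernelBank, offs):
    """w1 * k1 + w2 * k2 per offset, precomputed once per inference."""
    K1 = _appearance_stack(features, bank, offs)
    K2 = _smoothness_stack(bank, offs)
    n_off = len(offs)
    return bank.w1 * K1 + bank.w2 * K2.reshape(n_off, 1, 1, 1)


def gaussian_messages_reference(Q, features: VoxelFeatures, bank: KernelBank):
    """Exact O(N^2) reference message passing (numpy, non-differentiable)."""
    q = Q.data if isinstance(Q, Tensor) else np.asarray(Q, dtype=np.float64)
    _check_normalized(q)
    L = q.shape[0]
    shape = features.spatial_shape
    n = int(np.prod(shape))
    p = features.positions.reshape(3, n).T
    I = features.intensity.reshape(1, n).T
    d2p = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    d2I = ((I[:, None, :] - I[None, :, :]) ** 2).sum(-1)
    s = (-d2p / (2 * float(bank.theta_alpha.data) ** 2)
         - d2I / (2 * float(bank.theta_beta.data) ** 2))
    if features.n_deep:
        fd = features.deep.data.reshape(features.n_deep, n).T
        td = bank.theta_delta.data
        d2d = ((fd[:, None, :] - fd[None, :, :]) ** 2 / (2 * td ** 2)).sum(-1)
        s = s - d2d
    K1 = np.exp(s)
    K2 = np.exp(-d2p / (2 * float(bank.theta_gamma.data) ** 2))
    np.fill_diagonal(K1, 0.0)
    np.fill_diagonal(K2, 0.0)
    qf = q.reshape(L, n).T
    M1 = (K1 @ qf).T.reshape(q.shape)
    M2 = (K2 @ qf).T.reshape(q.shape)
    return M1, M2


def _apply_compat(M: Tensor, mu: Compatibility) -> Tensor:
    L = M.shape[0]
    n = int(np.prod(M.shape[1:]))
    return mu.mu.matmul(M.reshape(L, n)).reshape(L, *M.shape[1:])


def _finite_or_raise(Q: Tensor) -> Tensor:
    if not np.isfinite(Q.data).all():
        bad = np.argwhere(~np.isfinite(Q.data))[0]
        raise FloatingPointError(
            f"non-finite belief at label {bad[0]}, voxel {tuple(bad[1:])}")
    return Q


def meanfield_step(Q, U, features: VoxelFeatures, bank: KernelBank,
                   mu: Compatibility, radius: int | None = None) -> Tensor:
    """One mean-field update: Q' = softmax(U - mu (w1 M1 + w2 M2))."""
    M1, M2 = gaussian_messages(Q, features, bank, radius=radius)
    C = _apply_compat(bank.w1 * M1 + bank.w2 * M2, mu)
    if not isinstance(U, Tensor):
        U = Tensor(U)
    return _finite_or_raise((U - C).softmax(axis=0))


def crf_inference(U, features: VoxelFeatures, bank: KernelBank,
                  mu: Compatibility, n_iter: int = 20,
                  radius: int | None = None,
                  normalize_messages: bool = False) -> Tensor:
    """Unrolled mean-field inference starting from Q0 = softmax(U).

    Fully differentiable with respect to the unaries, the deep features and
    any trainable kernel/compatibility parameters.  ``n_iter = 0`` returns
    softmax(U).  The kernel stacks depend only on the (fixed) features, so
    they are computed once and shared across all iterations.

    With ``normalize_messages`` the pairwise message at each voxel is
    divided by that voxel's total kernel mass, turning it into a weighted
    neighbourhood average of Q.  Raw message magnitude grows with the
    kernel support, which saturates the update softmax within a few
    unrolled iterations and kills the gradient; the recurrent layer in the
    segmentation network therefore trains with normalised messages, while
    the default keeps the textbook unnormalised update.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if not isinstance(U, Tensor):
        U = Tensor(np.asarray(U, dtype=np.float64))
    Q = U.softmax(axis=0)
    if n_iter == 0:
        return Q
    offs = _offsets(features.spatial_shape, radius)
    Wc = _combined_weights(features, bank, offs)
    wsum = bank.w1 + bank.w2
    inv_mass = None
    if normalize_messages:
        ones = Tensor(np.ones((1,) + features.spatial_shape))
        mass = _windowed_filter(ones, Wc, offs) - wsum * ones
        inv_mass = (mass + 1e-12) ** -1.0
    for _ in range(n_iter):
        _check_normalized(Q.data)
        M = _windowed_filter(Q, Wc, offs) - wsum * Q
        if inv_mass is not None:
            M = M * inv_mass
        C = _apply_compat(M, mu)
        Q = _finite_or_raise((U - C).softmax(axis=0))
    return Q


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def gibbs_energy(x: np.ndarray, U, features: VoxelFeatures, bank: KernelBank,
                 mu: Compatibility) -> float:
    """Gibbs energy of a hard labelling (exact double loop; diagnostic only).

    E(x) = sum_i -U_i(x_i) + sum_{i<j} mu(x_i, x_j) (w1 k1 + w2 k2).
    """
    u = U.data if isinstance(U, Tensor) else np.asarray(U, dtype=np.float64)
    x = np.asarray(x)
    L = u.shape[0]
    if x.min() < 0 or x.max() >= L:
        raise ValueError(f"labels must lie in [0, {L})")
    shape = x.shape
    n = x.size
    xf = x.reshape(n)
    uf = u.reshape(L, n)
    energy = -uf[xf, np.arange(n)].sum()
    coords = [tuple(c) for c in np.argwhere(np.ones(shape, dtype=bool))]
    m = mu.mu.data
    w1, w2 = float(bank.w1.data), float(bank.w2.data)
    for a in range(n):
        for b in range(a + 1, n):
            k1, k2 = kernel_value(coords[a], coords[b], features, bank)
            energy += m[xf[a], xf[b]] * (w1 * k1 + w2 * k2)
    return float(energy)
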