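"""Dense-CRF kernels, message passing, mean-field updates and energy.

The fast (windowed) message path is checked against a brute-force double
loop written independently in this file, pair by pair via the scalar
kernel formula; the Gibbs energy is checked against a monolithic
re-implementation.
"""

import numpy as np
import pytest

from crfstrip.autodiff import Tensor
from crfstrip.dense_crf import (Compatibility, KernelBank, VoxelFeatures,
                                crf_inference, gaussian_messages,
                                gaussian_messages_reference, gibbs_energy,
                                kernel_value, meanfield_step)

from conftest import finite_difference, rel_err


def make_instance(seed, shape=(4, 4, 4), n_deep=2, labels=2):
    rng = np.random.default_rng(seed)
    img = rng.random(shape)
    deep = Tensor(rng.random((n_deep,) + shape)) if n_deep else None
    feats = VoxelFeatures.from_image(img, deep=deep)
    bank = KernelBank.create(n_deep=n_deep, theta_beta=0.5, theta_delta=0.8)
    U = rng.normal(size=(labels,) + shape)
    Q = rng.random((labels,) + shape)
    Q /= Q.sum(axis=0)
    return feats, bank, U, Q


def naive_messages(Q, feats, bank):
    """Independent O(N^2) oracle built on the scalar kernel formula."""
    shape = Q.shape[1:]
    coords = [tuple(c) for c in np.ndindex(shape)]
    M1 = np.zeros_like(Q)
    M2 = np.zeros_like(Q)
    for i in coords:
        for j in coords:
            if i == j:
                continue
            k1, k2 = kernel_value(i, j, feats, bank)
            for l in range(Q.shape[0]):
                M1[(l,) + i] += k1 * Q[(l,) + j]
                M2[(l,) + i] += k2 * Q[(l,) + j]
    return M1, M2


# ---------------------------------------------------------------------------
# kernel_value
# ---------------------------------------------------------------------------

def test_kernel_identical_features_give_one():
    # custom features in which two distinct voxels carry identical
    # position/intensity/deep entries
    pos = np.zeros((3, 2, 1, 1))
    inten = np.full((1, 2, 1, 1), 0.4)
    deep = Tensor(np.full((2, 2, 1, 1), 1.3))
    feats = VoxelFeatures(positions=pos, intensity=inten, deep=deep)
    bank = KernelBank.create(n_deep=2)
    k1, k2 = kernel_value((0, 0, 0), (1, 0, 0), feats, bank)
    assert k1 == pytest.approx(1.0)
    assert k2 == pytest.approx(1.0)


def test_kernel_infinite_bandwidth_limit(rng):
    feats, _, _, _ = make_instance(0)
    bank = KernelBank.create(n_deep=2, theta_alpha=1e12, theta_beta=1e12,
                             theta_delta=1e12)
    k1, _ = kernel_value((0, 0, 0), (3, 2, 1), feats, bank)
    assert k1 == pytest.approx(1.0, abs=1e-12)


def test_kernel_hand_value():
    # |p_i - p_j| = (3,0,0), equal intensity and deep features, theta_a = 3
    img = np.full((4, 1, 1), 0.5)
    feats = VoxelFeatures.from_image(img)
    bank = KernelBank.create(theta_alpha=3.0)
    k1, _ = kernel_value((0, 0, 0), (3, 0, 0), feats, bank)
    assert k1 == pytest.approx(np.exp(-0.5), rel=1e-12)


def test_kernel_self_pair_rejected():
    feats, bank, _, _ = make_instance(1)
    with pytest.raises(ValueError):
        kernel_value((1, 1, 1), (1, 1, 1), feats, bank)


def test_two_kernel_reduction_without_deep_channels():
    """With D = 0 the appearance kernel is exactly the two-feature form."""
    rng = np.random.default_rng(3)
    img = rng.random((3, 3, 3))
    feats = VoxelFeatures.from_image(img)
    bank = KernelBank.create(n_deep=0, theta_alpha=2.0, theta_beta=0.3)
    i, j = (0, 1, 2), (2, 0, 1)
    k1, k2 = kernel_value(i, j, feats, bank)
    d2 = sum((a - b) ** 2 for a, b in zip(i, j))
    dI2 = (img[i] - img[j]) ** 2
    assert k1 == pytest.approx(np.exp(-d2 / 8 - dI2 / 0.18), rel=1e-12)
    assert k2 == pytest.approx(np.exp(-d2 / (2 * 9)), rel=1e-12)


# ---------------------------------------------------------------------------
# messages
# ---------------------------------------------------------------------------

def test_messages_single_voxel_zero():
    feats = VoxelFeatures.from_image(np.array([[[0.5]]]))
    bank = KernelBank.create()
    Q = np.ones((2, 1, 1, 1)) * 0.5
    M1, M2 = gaussian_messages(Q, feats, bank)
    assert np.abs(M1.data).max() == 0
    assert np.abs(M2.data).max() == 0


def test_messages_all_ones_kernel():
    rng = np.random.default_rng(5)
    Q = rng.random((2, 3, 3, 3))
    Q /= Q.sum(axis=0)
    feats = VoxelFeatures.from_image(rng.random((3, 3, 3)))
    bank = KernelBank.create(theta_alpha=1e9, theta_beta=1e9, theta_gamma=1e9)
    M1, M2 = gaussian_messages(Q, feats, bank)
    expect = Q.sum(axis=(1, 2, 3), keepdims=True) - Q
    assert np.abs(M1.data - expect).max() < 1e-6
    assert np.abs(M2.data - expect).max() < 1e-6


@pytest.mark.parametrize("seed", range(3))
def test_messages_match_naive_oracle(seed):
    feats, bank, _, Q = make_instance(seed)
    M1, M2 = gaussian_messages(Q, feats, bank)
    N1, N2 = naive_messages(Q, feats, bank)
    assert rel_err(M1.data, N1) < 1e-3
    assert rel_err(M2.data, N2) < 1e-3


def test_reference_path_matches_fast_path():
    feats, bank, _, Q = make_instance(11)
    M1, M2 = gaussian_messages(Q, feats, bank)
    R1, R2 = gaussian_messages_reference(Q, feats, bank)
    assert rel_err(M1.data, R1) < 1e-10
    assert rel_err(M2.data, R2) < 1e-10


def test_messages_reject_unnormalized_q():
    feats, bank, _, Q = make_instance(2)
    with pytest.raises(ValueError, match="not normalized"):
        gaussian_messages(Q * 1.2, feats, bank)


def test_truncated_window_approximates_dense():
    """A radius-2 window captures the bulk of a theta=1 kernel's mass."""
    feats, _, _, Q = make_instance(7)
    bank = KernelBank.create(n_deep=2, theta_alpha=1.0, theta_gamma=1.0,
                             theta_beta=0.5, theta_delta=0.8)
    Mf, _ = gaussian_messages(Q, feats, bank, radius=2)
    Md, _ = gaussian_messages(Q, feats, bank, radius=None)
    assert rel_err(Mf.data, Md.data) < 0.02


# ---------------------------------------------------------------------------
# mean-field updates
# ---------------------------------------------------------------------------

def test_step_with_zero_weights_is_softmax():
    feats, _, U, Q = make_instance(4)
    bank = KernelBank.create(n_deep=2, w1=0.0, w2=0.0)
    mu = Compatibility.potts(2)
    out = meanfield_step(Q, U, feats, bank, mu)
    expect = np.exp(U - U.max(0)) / np.exp(U - U.max(0)).sum(0)
    assert np.abs(out.data - expect).max() < 1e-12


def test_step_permutation_equivariance():
    shape = (3, 3, 3)
    rng = np.random.default_rng(9)
    feats = VoxelFeatures.from_image(rng.random(shape))
    bank = KernelBank.create(theta_beta=0.5)
    U = rng.normal(size=(3,) + shape)
    Q = rng.random((3,) + shape)
    Q /= Q.sum(0)
    mu = Compatibility(mu=Tensor(rng.random((3, 3))))
    perm = [2, 0, 1]
    out = meanfield_step(Q, U, feats, bank, mu).data
    mu_p = Compatibility(mu=Tensor(mu.mu.data[np.ix_(perm, perm)]))
    out_p = meanfield_step(Q[perm], U[perm], feats, bank, mu_p).data
    assert np.abs(out_p - out[perm]).max() < 1e-12


def test_step_majority_flips_weak_center():
    """Homogeneous 3^3 toy: the centre weakly prefers label 1 but all its
    neighbours strongly prefer label 0; one update flips the centre."""
    shape = (3, 3, 3)
    feats = VoxelFeatures.from_image(np.full(shape, 0.5))
    bank = KernelBank.create(theta_alpha=3.0)
    mu = Compatibility.potts(2)
    U = np.zeros((2,) + shape)
    U[0] = 3.0
    U[0, 1, 1, 1], U[1, 1, 1, 1] = 0.0, 0.5
    Q0 = np.exp(U) / np.exp(U).sum(0)
    assert Q0[:, 1, 1, 1].argmax() == 1
    out = meanfield_step(Q0, U, feats, bank, mu)
    assert out.data[:, 1, 1, 1].argmax() == 0
    # oracle: direct evaluation of the update formula at the centre
    M1, M2 = naive_messages(Q0, feats, bank)
    C = np.einsum("lk,k...->l...", mu.mu.data, M1 + M2)
    ref = np.exp(U - C)
    ref /= ref.sum(0)
    assert np.abs(out.data - ref).max() < 1e-10


def _noisy_ball_instance():
    """6^3 two-label ball with 5% of interior unaries flipped.

    The kernel bank uses a localized smoothness bandwidth (theta_gamma =
    1.5 voxels): on a grid this small a 3-voxel smoothness kernel couples
    the whole volume and majority-votes the minority object away, which is
    a property of the toy scale, not of the layer.
    """
    shape = (6, 6, 6)
    g = np.mgrid[0:6, 0:6, 0:6].astype(float)
    rho = np.sqrt(((g - 2.5) ** 2).sum(0))
    ball = rho <= 2.2
    img = np.where(ball, 0.8, 0.2)
    U = np.where(ball[None], np.array([-1.0, 1.0])[:, None, None, None],
                 np.array([1.0, -1.0])[:, None, None, None])
    rng = np.random.default_rng(0)
    interior = np.argwhere(rho <= 1.8)
    n_flip = max(1, int(0.05 * len(interior)))
    flips = interior[rng.choice(len(interior), n_flip, replace=False)]
    for v in flips:
        U[(slice(None),) + tuple(v)] = U[(slice(None),) + tuple(v)][::-1]
    feats = VoxelFeatures.from_image(img)
    bank = KernelBank.create(theta_gamma=1.5)
    return U, feats, ball, bank


def test_inference_denoises_ball():
    U, feats, ball, bank = _noisy_ball_instance()
    mu = Compatibility.potts(2)
    assert (np.argmax(U, axis=0) != ball).sum() > 0   # instance is corrupted
    Q = crf_inference(U, feats, bank, mu, n_iter=20)
    assert np.array_equal(Q.data.argmax(0), ball.astype(int))


def test_inference_zero_iters_is_softmax():
    feats, bank, U, _ = make_instance(6)
    Q = crf_inference(U, feats, bank, Compatibility.potts(2), n_iter=0)
    expect = np.exp(U - U.max(0)) / np.exp(U - U.max(0)).sum(0)
    assert np.abs(Q.data - expect).max() < 1e-12


def test_inference_converges_on_fixed_toy():
    U, feats, _, bank = _noisy_ball_instance()
    mu = Compatibility.potts(2)
    Q19 = crf_inference(U, feats, bank, mu, n_iter=19)
    Q20 = crf_inference(U, feats, bank, mu, n_iter=20)
    assert np.abs(Q20.data - Q19.data).max() < 1e-4


def test_inference_rejects_negative_iters():
    feats, bank, U, _ = make_instance(8)
    with pytest.raises(ValueError):
        crf_inference(U, feats, bank, Compatibility.potts(2), n_iter=-1)


def test_inference_output_normalized():
    feats, bank, U, _ = make_instance(10)
    Q = crf_inference(U, feats, bank, Compatibility.potts(2), n_iter=3)
    assert np.abs(Q.data.sum(0) - 1.0).max() < 1e-6


def _count_isolated_islands(labels):
    """Voxels whose 6-neighbours all carry a different label."""
    count = 0
    s = labels.shape
    for v in np.ndindex(s):
        nb = []
        for ax in range(3):
            for d in (-1, 1):
                w = list(v)
                w[ax] += d
                if 0 <= w[ax] < s[ax]:
                    nb.append(labels[tuple(w)])
        if nb and all(n != labels[v] for n in nb):
            count += 1
    return count


@pytest.mark.parametrize("seed", range(3))
def test_inference_never_adds_isolated_islands(seed):
    U, feats, _, bank = _noisy_ball_instance()
    rng = np.random.default_rng(seed)
    U = U + 0.1 * rng.normal(size=U.shape)
    mu = Compatibility.potts(2)
    before = _count_isolated_islands(np.argmax(U, axis=0))
    Q = crf_inference(U, feats, bank, mu, n_iter=20)
    after = _count_isolated_islands(Q.data.argmax(0))
    assert after <= before


# ---------------------------------------------------------------------------
# Gibbs energy
# ---------------------------------------------------------------------------

def test_energy_uniform_labeling_has_no_pairwise_term():
    feats, bank, U, _ = make_instance(12, shape=(3, 3, 3))
    mu = Compatibility.potts(2)
    x = np.ones((3, 3, 3), dtype=int)
    e = gibbs_energy(x, U, feats, bank, mu)
    assert e == pytest.approx(-U[1].sum(), rel=1e-12)


def test_energy_increases_on_single_flip():
    shape = (3, 3, 3)
    feats = VoxelFeatures.from_image(np.full(shape, 0.5))
    bank = KernelBank.create()
    mu = Compatibility.potts(2)
    U = np.zeros((2,) + shape)
    x = np.zeros(shape, dtype=int)
    e0 = gibbs_energy(x, U, feats, bank, mu)
    x[1, 1, 1] = 1
    e1 = gibbs_energy(x, U, feats, bank, mu)
    assert e1 > e0


def test_energy_matches_monolithic_reimplementation():
    feats, bank, U, _ = make_instance(13, shape=(3, 3, 3))
    mu = Compatibility.potts(2)
    rng = np.random.default_rng(13)
    x = rng.integers(0, 2, size=(3, 3, 3))

    # independent single-loop re-implementation
    coords = [tuple(c) for c in np.ndindex((3, 3, 3))]
    e_ref = 0.0
    for n, i in enumerate(coords):
        e_ref -= U[(x[i],) + i]
        for j in coords[n + 1:]:
            pi = np.array(i, float)
            pj = np.array(j, float)
            d2 = ((pi - pj) ** 2).sum()
            dI2 = float(feats.intensity[(0,) + i]
                        - feats.intensity[(0,) + j]) ** 2
            dd2 = float(((feats.deep.data[(slice(None),) + i]
                          - feats.deep.data[(slice(None),) + j]) ** 2
                         / (2 * bank.theta_delta.data ** 2)).sum())
            k1 = np.exp(-d2 / (2 * float(bank.theta_alpha.data) ** 2)
                        - dI2 / (2 * float(bank.theta_beta.data) ** 2) - dd2)
            k2 = np.exp(-d2 / (2 * float(bank.theta_gamma.data) ** 2))
            e_ref += mu.mu.data[x[i], x[j]] * (k1 + k2)
    e = gibbs_energy(x, U, feats, bank, mu)
    assert e == pytest.approx(e_ref, abs=1e-12 * max(1, abs(e_ref)))


def test_energy_rejects_bad_labels():
    feats, bank, U, _ = make_instance(14, shape=(2, 2, 2))
    with pytest.raises(ValueError):
        gibbs_energy(np.full((2, 2, 2), 3), U, feats, bank,
                     Compatibility.potts(2))


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def test_crf_gradients_match_finite_differences():
    """Autodiff through 3 unrolled iterations vs central differences for the
    unaries, kernel weight w1, bandwidth theta_alpha and compatibility mu."""
    shape = (3, 3, 3)
    rng = np.random.default_rng(21)
    img = rng.random(shape)
    from crfstrip.autodiff import Parameter
    U = Parameter(0.3 * rng.normal(size=(2,) + shape))
    deep = Parameter(rng.random((2,) + shape))
    feats = VoxelFeatures.from_image(img, deep=deep)
    # moderate coupling keeps the beliefs soft; saturated beliefs make the
    # loss locally flat and the comparison vacuous
    bank = KernelBank.create(n_deep=2, w1=0.2, w2=0.2, theta_beta=0.5,
                             theta_delta=0.8, trainable=True)
    mu = Compatibility.potts(2, trainable=True)
    t = rng.normal(size=(2,) + shape)

    def loss():
        Q = crf_inference(U, feats, bank, mu, n_iter=3)
        return (Q * Tensor(t)).sum()

    l0 = loss()
    l0.backward()
    for name, p in [("U", U), ("w1", bank.w1),
                    ("theta_alpha", bank.theta_alpha), ("mu", mu.mu),
                    ("deep", deep)]:
        num = finite_difference(loss, p)
        assert rel_err(p.grad, num) < 1e-3, name
        p.grad = None
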