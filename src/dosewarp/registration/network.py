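"""Registration networks.

``MTDIRNetwork`` — the mix-transformer registration network: two separate
(non-weight-shared) strided-CNN encoders reduce the fixed and moving images
by a factor of 16 in-plane (configurable through-plane factor), the resulting
feature maps are flattened to tokens, projected to the embedding dimension
and fused with learned positional embeddings by element-wise summation.
Cross-attention with the moving image as query and the fixed image as key and
value produces correlation features (fused with the query tokens through a
residual connection), which a transposed-convolution decoder — with skip
connections tapping both encoders' intermediate features — upsamples back to
a full-resolution 3-component displacement field (mm), smoothed by a fixed
Gaussian stage.  The final head is zero-initialized so the untrained network
outputs the identity transform.

``CNNBaselineNetwork`` — a plain U-Net-style encoder/decoder with additive
skip connections that maps the concatenated image pair directly to the
displacement field (a VoxelMorph-style comparator sharing the warp and the
losses).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .attention import MixAttention, feature_map_from_tokens, tokens_from_feature_map
from .layers import Conv3d, ConvTranspose3d, LeakyReLU, Linear, Param


class FieldSmoother:
    """Fixed Gaussian smoothing of the decoded field (voxel units).

    Constrains the network to the smooth-field family the diffusion
    regularizer favours, which stabilizes unsupervised training.  The kernel
    is symmetric and zero-padded, so the operator is self-adjoint: the
    backward pass applies the same filter to the incoming gradient.
    """

    def __init__(self, sigma_voxels: float = 2.0):
        self.sigma = sigma_voxels

    def _apply(self, u: np.ndarray) -> np.ndarray:
        if self.sigma <= 0:
            return u
        out = np.empty_like(u)
        for c in range(u.shape[-1]):
            out[..., c] = gaussian_filter(u[..., c], self.sigma, mode="constant")
        return out

    forward = _apply
    backward = _apply


def _z_strides(through_plane_factor: int, n_stages: int = 4) -> list[int]:
    m = int(np.log2(through_plane_factor))
    if 2**m != through_plane_factor or m > n_stages:
        raise ValueError(
            f"through-plane factor must be a power of two <= {2**n_stages}, "
            f"got {through_plane_factor}"
        )
    return [1] * (n_stages - m) + [2] * m


def check_divisible(grid_shape, factors) -> None:
    for axis, (n, f) in enumerate(zip(grid_shape, factors)):
        if n % f != 0:
            need = (f - n % f) % f
            raise ValueError(
                f"grid axis {axis} has size {n}, not divisible by the "
                f"downsampling factor {f}; pad by {need} voxels first"
            )


class _Encoder:
    """Four strided conv + LeakyReLU stages; 16x in-plane downsampling.

    Keeps every stage's post-activation output so the decoder can tap
    intermediate resolutions through skip connections; the backward pass
    accepts the matching extra gradients.
    """

    def __init__(self, channels, z_strides, rng):
        self.stages = []
        cin = 1
        for stage, (cout, sz) in enumerate(zip(channels, z_strides)):
            self.stages.append(
                (
                    Conv3d(
                        cin,
                        cout,
                        kernel=3,
                        stride=(2, 2, sz),
                        pad=1,
                        rng=rng,
                        input_grad=(stage > 0),
                    ),
                    LeakyReLU(),
                )
            )
            cin = cout
        self.out_channels = cin
        self.stage_channels = tuple(channels)

    def params(self):
        return [p for conv, _ in self.stages for p in conv.params()]

    def forward(self, x):
        """Returns the list of per-stage outputs (last one is the feature map)."""
        outs = []
        for conv, act in self.stages:
            x = act.forward(conv.forward(x))
            outs.append(x)
        return outs

    def backward(self, g, extra=None):
        """g: gradient w.r.t. the last stage; extra: optional per-stage
        gradients (index into stages) added on the way down."""
        extra = extra or {}
        n = len(self.stages)
        for i in range(n - 1, -1, -1):
            if i in extra and i != n - 1:
                g = g + extra[i]
            conv, act = self.stages[i]
            g = conv.backward(act.backward(g))
        return g


class _Decoder:
    """Transposed-conv upsampling with encoder skip connections and a
    zero-initialized 3-channel head.

    Upsampling kernels equal the strides (non-overlapping synthesis): each
    stage is a learned interpolation, free of checkerboard artifacts; the
    field-smoothing stage downstream removes residual blockiness.  After
    each upsampling stage except the last, the concatenated fixed/moving
    encoder features at the matching resolution are merged in through a
    1x1x1 adapter convolution — the attention bottleneck alone (one token
    per 16x16 in-plane patch) cannot resolve millimetre-scale
    correspondence, so the decoder needs direct access to fine image phase.
    """

    def __init__(self, d_in, channels, z_strides, enc_channels, rng,
                 flow_scale: float = 20.0):
        self.stages = []
        self.adapters = []  # adapter i merges encoder stage (n-2-i) after decoder stage i
        n = len(z_strides)
        cin = d_in
        for i, (cout, sz) in enumerate(zip(channels, reversed(z_strides))):
            stride = (2, 2, sz)
            self.stages.append(
                (
                    ConvTranspose3d(cin, cout, kernel=stride, stride=stride, pad=0, rng=rng),
                    LeakyReLU(),
                )
            )
            enc_idx = n - 2 - i
            if enc_idx >= 0:
                c_skip = 2 * enc_channels[enc_idx]  # fixed + moving features
                # zero-init: skips switch on as training needs them instead
                # of injecting noise into the early field
                self.adapters.append(
                    Conv3d(c_skip, cout, kernel=1, stride=1, pad=0, zero_init=True)
                )
            else:
                self.adapters.append(None)
            cin = cout
        # fixed gain (mm per unit head activation): keeps the zero-init
        # identity start while letting millimetre-scale fields emerge within
        # a modest epoch budget
        self.flow_scale = flow_scale
        self.head = Conv3d(cin, 3, kernel=1, stride=1, pad=0, zero_init=True)
        self._cache = None

    def params(self):
        ps = [p for conv, _ in self.stages for p in conv.params()]
        ps += [p for a in self.adapters if a is not None for p in a.params()]
        return ps + self.head.params()

    def forward(self, x, fixed_feats, moving_feats):
        """fixed_feats/moving_feats: per-stage encoder outputs (index 0 is
        the highest resolution)."""
        n = len(self.stages)
        for i, (conv, act) in enumerate(self.stages):
            x = act.forward(conv.forward(x))
            enc_idx = n - 2 - i
            if self.adapters[i] is not None:
                skip = np.concatenate([fixed_feats[enc_idx], moving_feats[enc_idx]])
                x = x + self.adapters[i].forward(skip)
        return self.head.forward(x) * self.flow_scale

    def backward(self, g):
        """Returns (g_bottleneck, fixed_extras, moving_extras) where the
        extras map encoder stage index -> gradient."""
        g = self.head.backward(g * self.flow_scale)
        n = len(self.stages)
        fixed_extras: dict[int, np.ndarray] = {}
        moving_extras: dict[int, np.ndarray] = {}
        for i in range(n - 1, -1, -1):
            conv, act = self.stages[i]
            enc_idx = n - 2 - i
            if self.adapters[i] is not None:
                g_skip = self.adapters[i].backward(g)
                half = g_skip.shape[0] // 2
                fixed_extras[enc_idx] = g_skip[:half]
                moving_extras[enc_idx] = g_skip[half:]
            g = conv.backward(act.backward(g))
        return g, fixed_extras, moving_extras


class MTDIRNetwork:
    def __init__(
        self,
        grid_shape,
        embed_dim: int = 256,
        enc_channels=(16, 16, 32, 32),
        dec_channels=(32, 16, 8, 8),
        through_plane_factor: int = 4,
        flow_scale: float = 20.0,
        field_smooth_voxels: float = 2.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        zs = _z_strides(through_plane_factor)
        factors = (16, 16, through_plane_factor)
        check_divisible(grid_shape, factors)
        self.grid_shape = tuple(grid_shape)
        self.factors = factors
        self.lattice = tuple(n // f for n, f in zip(grid_shape, factors))
        self.embed_dim = embed_dim

        # the two encoders are separate (not weight-shared) but start from
        # identical initialization: their features then live in a common
        # basis, so the decoder's skip adapters and the attention scores can
        # compare fixed and moving content meaningfully from the first step
        enc_seed = int(rng.integers(2**31))
        self.enc_fixed = _Encoder(enc_channels, zs, np.random.default_rng(enc_seed))
        self.enc_moving = _Encoder(enc_channels, zs, np.random.default_rng(enc_seed))
        c = self.enc_fixed.out_channels
        proj_seed = int(rng.integers(2**31))
        self.proj_fixed = Linear(c, embed_dim, rng=np.random.default_rng(proj_seed))
        self.proj_moving = Linear(c, embed_dim, rng=np.random.default_rng(proj_seed))
        n_tokens = int(np.prod(self.lattice))
        self.pos_fixed = Param(rng.normal(0.0, 0.02, size=(n_tokens, embed_dim)))
        self.pos_moving = Param(rng.normal(0.0, 0.02, size=(n_tokens, embed_dim)))
        self.attn = MixAttention()
        self.decoder = _Decoder(
            embed_dim, dec_channels, zs, enc_channels, rng, flow_scale=flow_scale
        )
        self.smoother = FieldSmoother(field_smooth_voxels)

    def params(self):
        return (
            self.enc_fixed.params()
            + self.enc_moving.params()
            + self.proj_fixed.params()
            + self.proj_moving.params()
            + [self.pos_fixed, self.pos_moving]
            + self.decoder.params()
        )

    def encode(self, volume: np.ndarray, which: str) -> np.ndarray:
        """Feature map of one image; which is 'fixed' or 'moving'."""
        enc = {"fixed": self.enc_fixed, "moving": self.enc_moving}[which]
        return enc.forward(np.asarray(volume, dtype=np.float64)[None])[-1]

    def tokenize(self, fmap: np.ndarray, which: str) -> np.ndarray:
        proj = {"fixed": self.proj_fixed, "moving": self.proj_moving}[which]
        pos = {"fixed": self.pos_fixed, "moving": self.pos_moving}[which]
        return proj.forward(tokens_from_feature_map(fmap)) + pos.value

    def forward(self, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
        """Predict the displacement field u (nx, ny, nz, 3) in mm."""
        ff = self.enc_fixed.forward(np.asarray(fixed, dtype=np.float64)[None])
        fm = self.enc_moving.forward(np.asarray(moving, dtype=np.float64)[None])
        kv = self.proj_fixed.forward(tokens_from_feature_map(ff[-1])) + self.pos_fixed.value
        q = self.proj_moving.forward(tokens_from_feature_map(fm[-1])) + self.pos_moving.value
        # correlation features: attention output fused with the query tokens
        # (residual connection), so the decoder sees both the cross-image
        # correlation and the moving image's own embedding
        corr = self.attn.forward(q, kv, kv) + q
        cmap = feature_map_from_tokens(corr, self.lattice)
        field = self.decoder.forward(cmap, ff, fm)  # (3, nx, ny, nz)
        u = np.ascontiguousarray(field.transpose(1, 2, 3, 0))
        return self.smoother.forward(u)

    def backward(self, g_u: np.ndarray) -> None:
        g_u = self.smoother.backward(g_u)
        g = np.ascontiguousarray(g_u.transpose(3, 0, 1, 2))
        g_cmap, fixed_extras, moving_extras = self.decoder.backward(g)
        g_corr = tokens_from_feature_map(g_cmap)
        g_q, g_k, g_v = self.attn.backward(g_corr)
        g_q = g_q + g_corr  # residual path
        g_kv = g_k + g_v
        self.pos_moving.grad += g_q
        self.pos_fixed.grad += g_kv
        g_fm_tok = self.proj_moving.backward(g_q)
        g_ff_tok = self.proj_fixed.backward(g_kv)
        self.enc_moving.backward(
            feature_map_from_tokens(g_fm_tok, self.lattice), extra=moving_extras
        )
        self.enc_fixed.backward(
            feature_map_from_tokens(g_ff_tok, self.lattice), extra=fixed_extras
        )


class CNNBaselineNetwork:
    def __init__(
        self,
        grid_shape,
        width: int = 16,
        flow_scale: float = 20.0,
        field_smooth_voxels: float = 2.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        check_divisible(grid_shape, (4, 4, 2))
        self.grid_shape = tuple(grid_shape)
        self.flow_scale = flow_scale
        self.smoother = FieldSmoother(field_smooth_voxels)
        w = width
        self.d1 = Conv3d(2, w, kernel=3, stride=(2, 2, 1), pad=1, rng=rng, input_grad=False)
        self.a1 = LeakyReLU()
        self.d2 = Conv3d(w, w, kernel=3, stride=(2, 2, 2), pad=1, rng=rng)
        self.a2 = LeakyReLU()
        self.b = Conv3d(w, w, kernel=3, stride=1, pad=1, rng=rng)
        self.ab = LeakyReLU()
        self.u1 = ConvTranspose3d(w, w, kernel=(2, 2, 2), stride=(2, 2, 2), pad=0, rng=rng)
        self.au1 = LeakyReLU()
        self.m1 = Conv3d(w, w // 2, kernel=1, stride=1, pad=0, rng=rng)
        self.am1 = LeakyReLU()
        self.u2 = ConvTranspose3d(w // 2, w // 2, kernel=(2, 2, 1), stride=(2, 2, 1), pad=0, rng=rng)
        self.au2 = LeakyReLU()
        self.head = Conv3d(w // 2, 3, kernel=1, stride=1, pad=0, zero_init=True)

    def params(self):
        layers = [self.d1, self.d2, self.b, self.u1, self.m1, self.u2, self.head]
        return [p for layer in layers for p in layer.params()]

    def forward(self, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
        x = np.stack(
            [np.asarray(fixed, dtype=np.float64), np.asarray(moving, dtype=np.float64)]
        )
        h1 = self.a1.forward(self.d1.forward(x))
        h2 = self.a2.forward(self.d2.forward(h1))
        hb = self.ab.forward(self.b.forward(h2))
        hu = self.au1.forward(self.u1.forward(hb))
        hu = hu + h1  # additive skip at half resolution
        hm = self.am1.forward(self.m1.forward(hu))
        hf = self.au2.forward(self.u2.forward(hm))
        field = self.head.forward(hf) * self.flow_scale
        u = np.ascontiguousarray(field.transpose(1, 2, 3, 0))
        return self.smoother.forward(u)

    def backward(self, g_u: np.ndarray) -> None:
        g_u = self.smoother.backward(g_u)
        g = np.ascontiguousarray(g_u.transpose(3, 0, 1, 2)) * self.flow_scale
        g = self.u2.backward(self.au2.backward(self.head.backward(g)))
        g = self.m1.backward(self.am1.backward(g))
        g_skip = g  # flows to h1 through the additive skip
        g = self.u1.backward(self.au1.backward(g))
        g = self.b.backward(self.ab.backward(g))
        g = self.d2.backward(self.a2.backward(g))
        self.d1.backward(self.a1.backward(g + g_skip))
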