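"""Capsule forwarding primitives.

A capsule is a vector-valued feature unit: its Euclidean length encodes the
probability that an entity is present, its orientation the entity's pose.  A
layer holds a spatial grid of ``n_types`` capsule types, each a ``dim``-vector
(:class:`CapsuleField`).  Forwarding to the next layer is three steps:

1. *Voting* — every input capsule inside the receptive field predicts each
   output capsule through a trainable matrix ``W_{t'|t}`` shared across
   spatial positions (:func:`vote`).
2. *Clustering* — votes are combined by coupling weights obtained from
   agreement-based iterative routing (:func:`route_cluster`).
3. *Nonlinear mapping* — the dominant capsule is squashed so its length lies
   in [0, 1) (:func:`squash` or the cheaper :func:`modified_squash`).

Grouped layers partition the capsule types into ``g`` equal, disjoint groups
and confine voting/routing within each group, cutting both the number of
weight matrices and the number of intermediate vote capsules by a factor of
``g`` (:func:`grouped_capsule_layer`, :func:`count_votes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class ConfigurationError(ValueError):
    """Invalid layer/network configuration (dimension or divisibility)."""


class NumericError(FloatingPointError):
    """Non-finite values encountered during capsule forwarding."""


_EPS = 1e-8


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RoutingConfig:
    """Agreement-routing settings; the reference iteration count is 3."""

    iterations: int = 3

    def __post_init__(self):
        if self.iterations < 1:
            raise ConfigurationError("routing iterations must be >= 1")


@dataclass
class GroupPartition:
    """Equal-size, disjoint, covering split of type indices into g groups.

    Types are assigned to contiguous index blocks: group i holds types
    [i*T/g, (i+1)*T/g).  Any fixed partition is admissible (training is
    assumed to gather related types into a group); contiguous blocks make the
    block-diagonal weight structure explicit.
    """

    g: int
    n_types: int

    def __post_init__(self):
        if self.g < 1 or self.n_types < 1:
            raise ConfigurationError("g and n_types must be >= 1")
        if self.n_types % self.g:
            raise ConfigurationError(
                f"{self.n_types} capsule types not divisible into "
                f"{self.g} equal groups")

    @property
    def block_size(self) -> int:
        return self.n_types // self.g

    @property
    def blocks(self) -> list[range]:
        s = self.block_size
        return [range(i * s, (i + 1) * s) for i in range(self.g)]


@dataclass
class CapsuleField:
    """A batched spatial grid of typed capsule vectors.

    ``values`` has shape (batch, height, width, n_types, dim).
    """

    values: Tensor

    def __post_init__(self):
        if not isinstance(self.values, Tensor):
            self.values = Tensor(np.asarray(self.values))
        if self.values.ndim != 5:
            raise ConfigurationError(
                "CapsuleField values must be (batch, H, W, n_types, dim), "
                f"got shape {self.values.shape}")

    @property
    def batch(self):
        return self.values.shape[0]

    @property
    def height(self):
        return self.values.shape[1]

    @property
    def width(self):
        return self.values.shape[2]

    @property
    def n_types(self):
        return self.values.shape[3]

    @property
    def dim(self):
        return self.values.shape[4]

    def lengths(self) -> np.ndarray:
        v = self.values.data
        return np.sqrt((v * v).sum(axis=-1))


class WeightBank:
    """Trainable transformation matrices for one capsule layer.

    One ``out_dim x in_dim`` matrix exists per (output type, input type within
    the same group, kernel offset); matrices are shared across spatial
    positions.  ``matrices`` is a Tensor of shape
    ``(g, out_types/g, in_types/g, n_offsets, out_dim, in_dim)`` where
    ``n_offsets`` is ``kh*kw``, or 1 when the matrix is shared across the
    kernel (``kernel_shared=True``).
    """

    def __init__(self, in_types, out_types, in_dim, out_dim, kernel,
                 partition: GroupPartition, kernel_shared=False,
                 rng=None, dtype=np.float32, name="capsule_layer"):
        g = partition.g
        if in_types % g or out_types % g:
            raise ConfigurationError(
                f"{name}: in_types={in_types}, out_types={out_types} must "
                f"both be divisible by g={g}")
        self.in_types, self.out_types = in_types, out_types
        self.in_dim, self.out_dim = in_dim, out_dim
        self.kernel = tuple(kernel)
        self.partition = partition
        self.kernel_shared = bool(kernel_shared)
        self.name = name
        kh, kw = self.kernel
        n_off = 1 if kernel_shared else kh * kw
        shape = (g, out_types // g, in_types // g, n_off, out_dim, in_dim)
        if rng is None:
            data = np.zeros(shape, dtype=dtype)
        else:
            # fan-in scaled init: variance ~ 1 / (in_dim * kernel area)
            std = 1.0 / np.sqrt(in_dim * kh * kw)
            data = rng.normal(0.0, std, size=shape).astype(dtype)
        self.matrices = Tensor(data, requires_grad=True)

    @property
    def n_matrices(self) -> int:
        return int(np.prod(self.matrices.shape[:4]))

    @property
    def n_weights(self) -> int:
        return self.matrices.data.size


@dataclass
class VoteSet:
    """Vote capsules u_{t'|t} grouped for routing.

    ``votes`` has shape (g, contributions, N, out_types/g, out_dim) where
    ``contributions`` enumerates (input type within group, kernel offset)
    pairs and N = batch * out_height * out_width flattens the spatial grid
    (this layout keeps voting and routing on contiguous BLAS-friendly
    arrays).  ``couplings`` is filled by :func:`route_cluster`.
    """

    votes: Tensor
    batch: int
    height: int
    width: int
    couplings: np.ndarray | None = None

    @property
    def votes_per_sample(self) -> int:
        g, c, n, og, _ = self.votes.shape
        return (n // self.batch) * g * og * c

    def __post_init__(self):
        if self.votes.ndim != 5:
            raise ConfigurationError(
                f"votes must be (g, C, N, out_types/g, out_dim), got "
                f"{self.votes.shape}")
        if self.votes.shape[2] != self.batch * self.height * self.width:
            raise ConfigurationError("vote N axis != batch*height*width")


# ---------------------------------------------------------------------------
# Squashing nonlinearities
# ---------------------------------------------------------------------------

def _sq_norm(v: Tensor, eps: float):
    s2 = ad.tsum(ad.square(v), axis=-1, keepdims=True)
    return s2, ad.sqrt(s2 + eps)


def _squash_t(v: Tensor, eps: float = _EPS) -> Tensor:
    s2, n = _sq_norm(v, eps)
    return (s2 / (1.0 + s2)) * (v / n)


def _modified_squash_t(v: Tensor, eps: float = _EPS) -> Tensor:
    _, n = _sq_norm(v, eps)
    return v / (1.0 + n)


def squash(v):
    """Squashing nonlinearity: (|v|^2 / (1 + |v|^2)) * v / |v|.

    Length maps through x^2/(1+x^2) into [0, 1); direction preserved; the
    zero vector maps to zero (an epsilon inside the norm guards the
    division).
    """
    if isinstance(v, Tensor):
        return _squash_t(v)
    with ad.no_grad():
        return _squash_t(Tensor(np.asarray(v, dtype=float))).data


def modified_squash(v):
    """Cheaper squashing variant: v / (1 + |v|).

    Length maps through x/(1+x); agrees with :func:`squash` exactly at
    lengths 0 and 1 and needs fewer floating-point operations per capsule
    (no squared-norm ratio).
    """
    if isinstance(v, Tensor):
        return _modified_squash_t(v)
    with ad.no_grad():
        return _modified_squash_t(Tensor(np.asarray(v, dtype=float))).data


NONLINEARITIES = {"squash": squash, "modified_squash": modified_squash}


def _flops_squash(dim: int) -> int:
    # d mul + (d-1) add (sq norm); 1 sqrt; 1 add; 1 div (ratio); d div; d mul
    return dim + (dim - 1) + 1 + 1 + 1 + dim + dim


def _flops_modified_squash(dim: int) -> int:
    # d mul + (d-1) add (sq norm); 1 sqrt; 1 add; d div
    return dim + (dim - 1) + 1 + 1 + dim


def squash_flops(dim: int, variant: str = "squash") -> int:
    """Analytic per-capsule floating-point operation count for a squashing
    variant; the modified form is strictly cheaper at every dim."""
    if variant == "squash":
        return _flops_squash(dim)
    if variant == "modified_squash":
        return _flops_modified_squash(dim)
    raise ConfigurationError(f"unknown squashing variant {variant!r}")


# ---------------------------------------------------------------------------
# Voting
# ---------------------------------------------------------------------------

def vote(input_field: CapsuleField, weights: WeightBank, stride: int = 1,
         padding: str | int = "same") -> VoteSet:
    """Compute vote capsules u_{t'|t} = W_{t'|t} . v_t over the receptive
    field.

    3x3 kernels at stride 1 use zero padding that preserves spatial extent;
    2x2 kernels at stride 2 use no padding (exact halving).  Votes are laid
    out (g, C, N, out_types/g, out_dim) so the transformation runs as one
    batched matrix product.
    """
    if weights.in_dim != input_field.dim:
        raise ConfigurationError(
            f"{weights.name}: weight in_dim {weights.in_dim} != field dim "
            f"{input_field.dim}")
    if weights.in_types != input_field.n_types:
        raise ConfigurationError(
            f"{weights.name}: weight in_types {weights.in_types} != field "
            f"n_types {input_field.n_types}")
    kh, kw = weights.kernel
    x = input_field.values
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        if ph or pw:
            x = ad.pad_hw(x, ph, pw)
    elif padding:
        x = ad.pad_hw(x, int(padding), int(padding))
    if x.shape[1] < kh or x.shape[2] < kw:
        raise ConfigurationError(
            f"{weights.name}: kernel {kh}x{kw} does not fit in padded "
            f"extent {x.shape[1]}x{x.shape[2]} (empty receptive field)")
    patches = ad.patches_hw(x, kh, kw, stride, stride)
    b, ho, wo = patches.shape[:3]
    n = b * ho * wo
    g = weights.partition.g
    ti = weights.in_types // g
    to = weights.out_types // g
    kk = kh * kw
    di, do = weights.in_dim, weights.out_dim
    p = ad.reshape(patches, (b, ho, wo, kk, g, ti, di))
    w = weights.matrices                      # (g,To,Ti,Koff,do,di)
    if weights.kernel_shared:
        p = ad.transpose(p, (4, 5, 3, 0, 1, 2, 6))        # (g,Ti,K,B,H,W,d)
        p = ad.reshape(p, (g, ti, kk * n, di))
        wm = ad.transpose(w, (0, 2, 3, 5, 1, 4))          # (g,Ti,1,di,To,do)
        wm = ad.reshape(wm, (g, ti, di, to * do))
        u = ad.matmul(p, wm)                              # (g,Ti,K*N,To*do)
        u = ad.reshape(u, (g, ti, kk, n, to, do))
        u = ad.reshape(u, (g, ti * kk, n, to, do))
    else:
        p = ad.transpose(p, (4, 3, 5, 0, 1, 2, 6))        # (g,K,Ti,B,H,W,d)
        p = ad.reshape(p, (g, kk, ti, n, di))
        wm = ad.transpose(w, (0, 3, 2, 5, 1, 4))          # (g,K,Ti,di,To,do)
        wm = ad.reshape(wm, (g, kk, ti, di, to * do))
        u = ad.matmul(p, wm)                              # (g,K,Ti,N,To*do)
        u = ad.reshape(u, (g, kk * ti, n, to, do))
    return VoteSet(votes=u, batch=b, height=ho, width=wo)


# ---------------------------------------------------------------------------
# Routing / clustering
# ---------------------------------------------------------------------------

def route_cluster(votes: VoteSet, routing: RoutingConfig,
                  nonlinearity=squash, name="capsule_layer") -> CapsuleField:
    """Aggregate votes into dominant capsules by agreement routing.

    Coupling logits start at zero and are normalised by softmax across the
    output types of each group (per contributing capsule); each iteration
    adds the scalar product between a vote and the squashed current output.
    Returns the *pre-nonlinearity* dominant capsules v-hat = sum c * u.
    """
    if routing.iterations < 1:
        raise ConfigurationError(f"{name}: routing iterations must be >= 1")
    u = votes.votes                              # (g, C, N, o, e)
    if not np.isfinite(u.data).all():
        raise NumericError(f"{name}: non-finite vote capsules")
    g, c, n, to, do = u.shape
    if to == 1:
        # softmax over a single output type is identically 1 whatever the
        # logits, so every iteration yields unit couplings: v-hat = sum u.
        v_hat = ad.tsum(u, axis=1)               # (g, N, 1, e)
        votes.couplings = np.ones((g, n, 1, c), dtype=u.dtype)
    else:
        u2 = ad.transpose(u, (0, 2, 3, 1, 4))    # (g, N, o, C, e)
        logits = Tensor(np.zeros((g, n, to, 1, c), dtype=u.dtype))
        coup = None
        v_hat = None
        for it in range(routing.iterations):
            coup = ad.softmax(logits, axis=2)
            v_hat = ad.matmul(coup, u2)          # (g, N, o, 1, e)
            if it + 1 < routing.iterations:
                a = nonlinearity(v_hat)
                agree = ad.matmul(u2, ad.transpose(a, (0, 1, 2, 4, 3)))
                logits = logits + ad.transpose(agree, (0, 1, 2, 4, 3))
        votes.couplings = coup.data.reshape(g, n, to, c)
    out = ad.reshape(v_hat, (g, n, to, do))
    out = ad.transpose(out, (1, 0, 2, 3))        # (N, g, o, e)
    out = ad.reshape(out, (votes.batch, votes.height, votes.width,
                           g * to, do))
    return CapsuleField(out)


def _route_multi(vote_sets: Sequence[VoteSet], routing, nonlinearity, name):
    """Route a fused contribution set (e.g. deconv output + encoder skip)."""
    first = vote_sets[0]
    u = ad.concat([vs.votes for vs in vote_sets], axis=1)
    fused = VoteSet(u, batch=first.batch, height=first.height,
                    width=first.width)
    return route_cluster(fused, routing, nonlinearity, name)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _check_compat(input_field: CapsuleField, weights: WeightBank):
    if weights.in_dim != input_field.dim:
        raise ConfigurationError(
            f"{weights.name}: weight in_dim {weights.in_dim} != field dim "
            f"{input_field.dim}")
    if weights.in_types != input_field.n_types:
        raise ConfigurationError(
            f"{weights.name}: weight in_types {weights.in_types} != field "
            f"n_types {input_field.n_types}")


def _extract_grouped_patches(input_field, weights, stride, padding):
    """Shared receptive-field extraction: returns (patches Tensor shaped
    (B,Ho,Wo,K,g,Ti,di), b, ho, wo)."""
    kh, kw = weights.kernel
    x = input_field.values
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        if ph or pw:
            x = ad.pad_hw(x, ph, pw)
    elif padding:
        x = ad.pad_hw(x, int(padding), int(padding))
    if x.shape[1] < kh or x.shape[2] < kw:
        raise ConfigurationError(
            f"{weights.name}: kernel {kh}x{kw} does not fit in padded "
            f"extent {x.shape[1]}x{x.shape[2]} (empty receptive field)")
    patches = ad.patches_hw(x, kh, kw, stride, stride)
    b, ho, wo = patches.shape[:3]
    g = weights.partition.g
    p = ad.reshape(patches, (b, ho, wo, kh * kw, g,
                             weights.in_types // g, weights.in_dim))
    return p, b, ho, wo


def _dominant_single_type(input_field, weights, stride, padding):
    """Pre-nonlinearity dominant capsules for a layer whose groups each have
    a single output type.

    With one output type per group the routing softmax is identically 1, so
    the dominant capsule is the plain vote sum — computable as one batched
    matrix product over (kernel offset, in-group type, in dim) without
    materializing individual votes.  Exactly equivalent to
    vote -> route_cluster up to float summation order.
    """
    g = weights.partition.g
    ti, di, do = weights.in_types // g, weights.in_dim, weights.out_dim
    p, b, ho, wo = _extract_grouped_patches(input_field, weights, stride,
                                            padding)
    n = b * ho * wo
    kk = weights.kernel[0] * weights.kernel[1]
    w = weights.matrices                       # (g, 1, Ti, Koff, do, di)
    if weights.kernel_shared:
        p = ad.tsum(p, axis=3)                 # sum over kernel first
        p = ad.transpose(p, (3, 0, 1, 2, 4, 5))
        p = ad.reshape(p, (g, n, ti * di))
        wm = ad.reshape(w, (g, ti, do, di))
        wm = ad.transpose(wm, (0, 1, 3, 2))
        wm = ad.reshape(wm, (g, ti * di, do))
    else:
        p = ad.transpose(p, (4, 0, 1, 2, 3, 5, 6))   # (g,B,Ho,Wo,K,Ti,di)
        p = ad.reshape(p, (g, n, kk * ti * di))
        wm = ad.transpose(w, (0, 3, 2, 5, 1, 4))     # (g,K,Ti,di,1,do)
        wm = ad.reshape(wm, (g, kk * ti * di, do))
    v_hat = ad.matmul(p, wm)                   # (g, N, do)
    return v_hat, b, ho, wo


def _field_from_grouped(v_hat, g, to, do, b, ho, wo, nonlinearity):
    out = ad.reshape(v_hat, (g, b * ho * wo, to, do))
    out = ad.transpose(out, (1, 0, 2, 3))
    out = ad.reshape(out, (b, ho, wo, g * to, do))
    return CapsuleField(nonlinearity(out))


def grouped_capsule_layer(input_field: CapsuleField, weights: WeightBank,
                          partition: GroupPartition, routing: RoutingConfig,
                          nonlinearity=squash, stride: int = 1,
                          padding: str | int = "same") -> CapsuleField:
    """Grouped convolutional capsule layer: vote -> route -> squash.

    Output type block i is computed from input type block i only; blocks are
    concatenated in group order.  With g=1 this is the ordinary non-grouped
    convolutional capsule layer.
    """
    if weights.partition.g != partition.g:
        raise ConfigurationError(
            f"{weights.name}: weight bank built for g={weights.partition.g}, "
            f"layer called with g={partition.g}")
    _check_compat(input_field, weights)
    g = weights.partition.g
    if weights.out_types == g and routing.iterations >= 1:
        v_hat, b, ho, wo = _dominant_single_type(input_field, weights,
                                                 stride, padding)
        return _field_from_grouped(v_hat, g, 1, weights.out_dim, b, ho, wo,
                                   nonlinearity)
    vs = vote(input_field, weights, stride=stride, padding=padding)
    clustered = route_cluster(vs, routing, nonlinearity, weights.name)
    return CapsuleField(nonlinearity(clustered.values))


def grouped_fusion_layer(input_fields: Sequence[CapsuleField],
                         banks: Sequence[WeightBank],
                         routing: RoutingConfig,
                         nonlinearity=squash) -> CapsuleField:
    """Grouped layer over the type-axis concatenation of several fields.

    Used for skip fusion, where the decoder field and the encoder skip may
    carry different capsule dims: votes are computed per source field with
    its own weight bank, then routed jointly group-by-group (equivalent to
    concatenating types group-interleaved and re-partitioning contiguously).
    """
    if len(input_fields) != len(banks):
        raise ConfigurationError("one weight bank per fused input required")
    for f, bk in zip(input_fields, banks):
        _check_compat(f, bk)
    g = banks[0].partition.g
    if all(bk.out_types == g for bk in banks):
        parts = [_dominant_single_type(f, bk, 1, "same")
                 for f, bk in zip(input_fields, banks)]
        v_hat = parts[0][0]
        for other, *_ in parts[1:]:
            v_hat = v_hat + other
        _, b, ho, wo = parts[0]
        return _field_from_grouped(v_hat, g, 1, banks[0].out_dim, b, ho, wo,
                                   nonlinearity)
    vsets = [vote(f, bk, stride=1, padding="same")
             for f, bk in zip(input_fields, banks)]
    clustered = _route_multi(vsets, routing, nonlinearity, banks[0].name)
    return CapsuleField(nonlinearity(clustered.values))


def deconv_capsule_layer(input_field: CapsuleField, weights: WeightBank,
                         partition: GroupPartition, routing: RoutingConfig,
                         nonlinearity=squash) -> CapsuleField:
    """Deconvolutional (transposed) grouped capsule layer.

    Doubles spatial height and width with a 2x2 stride-2 transposed kernel:
    every input position scatters votes to a disjoint 2x2 output block, so
    each output capsule is routed from the in-group capsules of exactly one
    parent position.
    """
    if weights.kernel != (2, 2):
        raise ConfigurationError(
            f"{weights.name}: deconv capsule uses a 2x2 stride-2 kernel")
    if weights.in_dim != input_field.dim:
        raise ConfigurationError(
            f"{weights.name}: weight in_dim {weights.in_dim} != field dim "
            f"{input_field.dim}")
    if weights.in_types != input_field.n_types:
        raise ConfigurationError(
            f"{weights.name}: weight in_types {weights.in_types} != field "
            f"n_types {input_field.n_types}")
    g = weights.partition.g
    x = input_field.values
    b, h, w, t, d = x.shape
    ti, to = t // g, weights.out_types // g
    do = weights.out_dim
    wm = weights.matrices                     # (g,To,Ti,Koff,do,di)
    if to == 1:
        # unit couplings: the dominant capsule of each child is the plain
        # in-group vote sum, one batched matrix product per kernel offset
        xf = ad.reshape(x, (b, h, w, g, ti, d))
        xf = ad.transpose(xf, (3, 0, 1, 2, 4, 5))
        xf = ad.reshape(xf, (g, b * h * w, ti * d))
        koff = 1 if weights.kernel_shared else 4
        w2 = ad.reshape(wm, (g, ti, koff, do, d))        # drop unit To axis
        w2 = ad.transpose(w2, (0, 1, 4, 2, 3))           # (g,Ti,di,Koff,do)
        w2 = ad.reshape(w2, (g, ti * d, koff * do))
        v = ad.matmul(xf, w2)                            # (g,N,Koff*do)
        if weights.kernel_shared:
            field = _field_from_grouped(v, g, 1, do, b, h, w, nonlinearity)
            return CapsuleField(ad.upsample2(field.values))
        v = ad.reshape(v, (g, b, h, w, 2, 2, do))
        v = ad.transpose(v, (0, 1, 2, 4, 3, 5, 6))       # (g,B,H,2,W,2,do)
        v = ad.reshape(v, (g, b * 4 * h * w, do))
        return _field_from_grouped(v, g, 1, do, b, 2 * h, 2 * w,
                                   nonlinearity)
    xg = ad.reshape(x, (b, h, w, g, ti, d))
    xg = ad.transpose(xg, (3, 4, 0, 1, 2, 5))             # (g,Ti,B,H,W,d)
    xg = ad.reshape(xg, (g, ti, b * h * w, d))
    if weights.kernel_shared:
        # All four children of a parent receive identical votes, so routing
        # is identical across each 2x2 block: route once at parent
        # resolution and upsample the routed field.
        w2 = ad.transpose(wm, (0, 2, 3, 5, 1, 4))         # (g,Ti,1,di,To,do)
        w2 = ad.reshape(w2, (g, ti, d, to * do))
        u = ad.matmul(xg, w2)                             # (g,Ti,N,To*do)
        u = ad.reshape(u, (g, ti, b * h * w, to, do))
        votes = VoteSet(u, batch=b, height=h, width=w)
        clustered = route_cluster(votes, routing, nonlinearity, weights.name)
        out = nonlinearity(clustered.values)
        return CapsuleField(ad.upsample2(out))
    # Per-offset matrices: each output position receives the votes of its
    # parent through the offset matching its position parity.
    w2 = ad.transpose(wm, (0, 2, 3, 5, 1, 4))             # (g,Ti,K,di,To,do)
    w2 = ad.reshape(w2, (g, ti, 4 * d, to * do))          # stack offsets
    # votes for offset k: matmul per offset; compute all four in one product
    w4 = ad.reshape(w2, (g, ti, 4, d, to * do))
    u = ad.einsum("gind,gikdm->giknm", ad.reshape(xg, (g, ti, b * h * w, d)),
                  w4)                                     # (g,Ti,4,N,To*do)
    u = ad.reshape(u, (g, ti, 2, 2, b, h, w, to, do))
    u = ad.transpose(u, (0, 1, 4, 5, 2, 6, 3, 7, 8))      # (g,Ti,B,H,2,W,2,..)
    u = ad.reshape(u, (g, ti, b * 4 * h * w, to, do))
    votes = VoteSet(u, batch=b, height=2 * h, width=2 * w)
    clustered = route_cluster(votes, routing, nonlinearity, weights.name)
    return CapsuleField(nonlinearity(clustered.values))


# ---------------------------------------------------------------------------
# Analytic accounting
# ---------------------------------------------------------------------------

def count_votes(in_types: int, out_types: int, kernel_area: int,
                height: int, width: int, g: int = 1) -> int:
    """Exact number of intermediate vote capsules one forward pass of a
    grouped layer materialises.

    Every output capsule (height*width*out_types of them) receives one vote
    from each in-group input type at each kernel offset, so the grouped count
    is exactly 1/g of the non-grouped count.
    """
    if in_types % g or out_types % g:
        raise ConfigurationError(
            f"type counts ({in_types}, {out_types}) must be divisible by "
            f"g={g}")
    return height * width * out_types * (in_types // g) * kernel_area
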