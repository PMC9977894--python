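"""GroupCapsNet: U-shaped grouped capsule network for binary segmentation.

The network follows a symmetric encoder-decoder design.  A two-convolution
stem lifts the input slice to 16 channels, reinterpreted as the initial
capsule field of ``g`` types x ``16/g`` dims (the group-count variant G#g
fixes these).  Each encoder stage starts with a 2x2 stride-2 downsampling
grouped capsule layer and the stage grouped-layer totals double stage to
stage (2, 4, 8, 16).  Each decoder stage starts with a deconvolutional
capsule layer doubling spatial resolution, fuses the matching encoder stage
output by type concatenation, and its layer count halves stage to stage
(16, 8, 4, 2).  A 1x1 segmentation head emits one 8-dim capsule per pixel
whose length, after thresholding, is the hemorrhage mask.

Dimension schedule (the printed stage rules underdetermine it; this is the
resolution calibrated against the published per-variant weight totals, see
docs/methods.md): encoder capsule dims double from 16 and cap at 32 for every
variant; decoder dims at pyramid level l are (16/g) * 2^l; encoder layers use
per-offset 3x3 matrices while decoder and deconv layers share one matrix
across the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .capsule_core import (
    CapsuleField, ConfigurationError, GroupPartition, RoutingConfig,
    WeightBank, NONLINEARITIES, count_votes, deconv_capsule_layer,
    grouped_capsule_layer, grouped_fusion_layer,
)

STEM_CHANNELS = 16
HEAD_TYPES = 1
HEAD_DIM = 8


def _default_enc_layers(n_stages):
    return tuple(2 ** k for k in range(1, n_stages + 1))


def _default_dec_layers(n_stages):
    return tuple(2 ** k for k in range(n_stages, 0, -1))


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of a GroupCapsNet variant.

    ``enc_layers[k]`` is the total number of grouped capsule layers in
    encoder stage k+1 (the first of which downsamples); ``dec_layers[j]`` the
    number of post-fusion grouped layers in decoder stage j+1 (a deconv layer
    precedes each).  Defaults follow the doubling/halving stage rules.
    """

    variant_g: int = 1
    input_size: int = 256
    n_stages: int = 4
    enc_layers: tuple = None
    dec_layers: tuple = None
    routing_iterations: int = 3
    nonlinearity: str = "modified_squash"

    def __post_init__(self):
        if self.enc_layers is None:
            object.__setattr__(self, "enc_layers",
                               _default_enc_layers(self.n_stages))
        if self.dec_layers is None:
            object.__setattr__(self, "dec_layers",
                               _default_dec_layers(self.n_stages))
        self.validate()

    # -- derived schedules -------------------------------------------------
    @property
    def initial_types(self):
        return self.variant_g

    @property
    def initial_dims(self):
        return STEM_CHANNELS // self.variant_g

    def types(self):
        """Capsule types per pyramid level 0..n_stages (level 0 = initial)."""
        g = self.variant_g
        return [g] + [g * 2 ** max(0, k - 1) for k in range(1, self.n_stages + 1)]

    def encoder_dims(self):
        """Capsule dims per level in the encoder (doubling, capped at 32)."""
        return ([self.initial_dims]
                + [min(32, 16 * 2 ** (k - 1)) for k in range(1, self.n_stages + 1)])

    def decoder_dims(self):
        """Capsule dims per level in the decoder: (16/g) * 2^level."""
        return [self.initial_dims * 2 ** l for l in range(self.n_stages)]

    def validate(self):
        g = self.variant_g
        if g < 1 or STEM_CHANNELS % g:
            raise ConfigurationError(
                f"variant_g={g} must divide the {STEM_CHANNELS}-channel stem")
        if self.initial_types * self.initial_dims != STEM_CHANNELS:
            raise ConfigurationError("initial types x dims must equal 16")
        if self.n_stages < 1:
            raise ConfigurationError("need at least one stage")
        if len(self.enc_layers) != self.n_stages or \
                len(self.dec_layers) != self.n_stages:
            raise ConfigurationError("one layer count per stage required")
        if any(n < 1 for n in self.enc_layers + self.dec_layers):
            raise ConfigurationError("stage layer counts must be >= 1")
        if self.input_size % (2 ** self.n_stages):
            raise ConfigurationError(
                f"input size {self.input_size} must be divisible by "
                f"2^{self.n_stages}")
        for t in self.types():
            if t % g:
                raise ConfigurationError(
                    f"type count {t} not divisible by g={g}")

    # -- canonical variants ------------------------------------------------
    @classmethod
    def variant(cls, g, **kw):
        """Full-scale GroupCapsNet-G#g (256x256, four stages)."""
        return cls(variant_g=g, **kw)

    @classmethod
    def desk_scale(cls, nonlinearity="modified_squash"):
        """Reduced G2 benchmark: 64x64 inputs, two stages, halved depths."""
        return cls(variant_g=2, input_size=64, n_stages=2,
                   enc_layers=(1, 2), dec_layers=(2, 1),
                   nonlinearity=nonlinearity)


@dataclass
class SegmentationOutput:
    """Per-pixel segmentation capsule lengths and the thresholded mask."""

    lengths: np.ndarray
    threshold: float = 0.5

    @property
    def mask(self) -> np.ndarray:
        return self.lengths > self.threshold


class GroupCapsNet:
    """Instantiated model; built by :func:`build_network`."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator,
                 dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.dtype = dtype
        self.routing = RoutingConfig(spec.routing_iterations)
        self.nonlinearity = NONLINEARITIES[spec.nonlinearity]
        g = spec.variant_g
        T = spec.types()
        De = spec.encoder_dims()
        Dd = spec.decoder_dims()
        n = spec.n_stages

        def bank(t_in, t_out, d_in, d_out, kernel, shared, name):
            return WeightBank(t_in, t_out, d_in, d_out, kernel,
                              GroupPartition(g, max(t_in, g)), shared,
                              rng=rng, dtype=dtype, name=name)

        std1 = 1.0 / np.sqrt(9)
        std2 = 1.0 / np.sqrt(9 * STEM_CHANNELS)
        self.stem_w1 = Tensor(rng.normal(0, std1, (STEM_CHANNELS, 3, 3, 1))
                              .astype(dtype), requires_grad=True)
        self.stem_b1 = Tensor(np.zeros(STEM_CHANNELS, dtype=dtype),
                              requires_grad=True)
        self.stem_w2 = Tensor(
            rng.normal(0, std2, (STEM_CHANNELS, 3, 3, STEM_CHANNELS))
            .astype(dtype), requires_grad=True)
        self.stem_b2 = Tensor(np.zeros(STEM_CHANNELS, dtype=dtype),
                              requires_grad=True)

        self.enc_banks = []      # per stage: [down, conv, conv, ...]
        for k in range(1, n + 1):
            stage = [bank(T[k - 1], T[k], De[k - 1], De[k], (2, 2), False,
                          f"enc{k}.down")]
            for i in range(spec.enc_layers[k - 1] - 1):
                stage.append(bank(T[k], T[k], De[k], De[k], (3, 3), False,
                                  f"enc{k}.conv{i}"))
            self.enc_banks.append(stage)

        self.dec_banks = []      # per stage: (deconv, fuse_dec, fuse_skip, convs)
        prevT, prevD = T[n], De[n]
        for j, l in enumerate(range(n - 1, -1, -1)):
            deconv = bank(prevT, T[l], prevD, Dd[l], (2, 2), True,
                          f"dec{l}.deconv")
            fuse_dec = bank(T[l], T[l], Dd[l], Dd[l], (3, 3), True,
                            f"dec{l}.fuse_dec")
            fuse_skip = bank(T[l], T[l], De[l], Dd[l], (3, 3), True,
                             f"dec{l}.fuse_skip")
            convs = [bank(T[l], T[l], Dd[l], Dd[l], (3, 3), True,
                          f"dec{l}.conv{i}")
                     for i in range(spec.dec_layers[j] - 1)]
            self.dec_banks.append((deconv, fuse_dec, fuse_skip, convs))
            prevT, prevD = T[l], Dd[l]

        self.head_bank = WeightBank(
            T[0], HEAD_TYPES, Dd[0], HEAD_DIM, (1, 1),
            GroupPartition(1, T[0]), False, rng=rng, dtype=dtype,
            name="head")

    # ------------------------------------------------------------------
    def parameters(self):
        ps = [self.stem_w1, self.stem_b1, self.stem_w2, self.stem_b2]
        for stage in self.enc_banks:
            ps += [b.matrices for b in stage]
        for deconv, fd, fs, convs in self.dec_banks:
            ps += [deconv.matrices, fd.matrices, fs.matrices]
            ps += [c.matrices for c in convs]
        ps.append(self.head_bank.matrices)
        return ps

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # ------------------------------------------------------------------
    def _conv3x3(self, x: Tensor, w: Tensor, bias: Tensor) -> Tensor:
        b, hh, ww, c = x.shape
        p = ad.patches_hw(ad.pad_hw(x, 1, 1), 3, 3, 1, 1)
        p = ad.reshape(p, (b * hh * ww, 9 * c))
        wm = ad.reshape(ad.transpose(w, (1, 2, 3, 0)), (9 * c, w.shape[0]))
        h = ad.matmul(p, wm)
        return ad.reshape(h, (b, hh, ww, w.shape[0])) + bias

    def _stem(self, x: Tensor) -> CapsuleField:
        h = ad.relu(self._conv3x3(x, self.stem_w1, self.stem_b1))
        h = self._conv3x3(h, self.stem_w2, self.stem_b2)
        b, hh, ww, _ = h.shape
        caps = ad.reshape(h, (b, hh, ww, self.spec.initial_types,
                              self.spec.initial_dims))
        return CapsuleField(self.nonlinearity(caps))

    def forward(self, x) -> Tensor:
        """x: (batch, H, W) or (batch, H, W, 1) in [0, 1].  Returns the
        per-pixel segmentation capsule lengths as a (batch, H, W) Tensor."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        if x.ndim == 3:
            x = ad.reshape(x, x.shape + (1,))
        if x.shape[1] != self.spec.input_size or \
                x.shape[2] != self.spec.input_size:
            raise ConfigurationError(
                f"expected {self.spec.input_size}x{self.spec.input_size} "
                f"input, got {x.shape[1]}x{x.shape[2]}")
        g = self.spec.variant_g
        part = lambda t: GroupPartition(g, t)
        nl, rt = self.nonlinearity, self.routing

        levels = [self._stem(x)]
        cur = levels[0]
        for stage in self.enc_banks:
            cur = grouped_capsule_layer(cur, stage[0], part(stage[0].in_types),
                                        rt, nl, stride=2, padding=0)
            for bk in stage[1:]:
                cur = grouped_capsule_layer(cur, bk, part(bk.in_types), rt, nl)
            levels.append(cur)

        n = self.spec.n_stages
        for (deconv, fd, fs, convs), l in zip(self.dec_banks,
                                              range(n - 1, -1, -1)):
            cur = deconv_capsule_layer(cur, deconv, part(deconv.in_types),
                                       rt, nl)
            cur = grouped_fusion_layer([cur, levels[l]], [fd, fs], rt, nl)
            for bk in convs:
                cur = grouped_capsule_layer(cur, bk, part(bk.in_types), rt, nl)

        head = grouped_capsule_layer(cur, self.head_bank,
                                     GroupPartition(1, self.head_bank.in_types),
                                     rt, nl, stride=1, padding=0)
        v = head.values                         # (B, H, W, 1, 8)
        s2 = ad.tsum(ad.square(v), axis=-1)
        lengths = ad.sqrt(s2 + 1e-12)
        return ad.reshape(lengths, v.shape[:3])

    def predict(self, image, threshold: float = 0.5) -> SegmentationOutput:
        """Segment a single preprocessed slice (H, W) in [0, 1]."""
        img = np.asarray(image, dtype=self.dtype)
        if img.ndim != 2:
            raise ConfigurationError("predict expects a single (H, W) slice")
        with ad.no_grad():
            lengths = self.forward(img[None]).data[0]
        return SegmentationOutput(lengths=lengths, threshold=threshold)


def build_network(spec: NetworkSpec, nonlinearity: str | None = None,
                  seed: int = 0, dtype=np.float32) -> GroupCapsNet:
    """Instantiate a GroupCapsNet from its declarative spec."""
    if nonlinearity is not None:
        spec = NetworkSpec(**{**spec.__dict__, "nonlinearity": nonlinearity})
    if spec.nonlinearity not in NONLINEARITIES:
        raise ConfigurationError(
            f"unknown nonlinearity {spec.nonlinearity!r}")
    return GroupCapsNet(spec, np.random.default_rng(seed), dtype=dtype)


# ---------------------------------------------------------------------------
# Analytic accounting
# ---------------------------------------------------------------------------

def count_parameters(spec: NetworkSpec) -> int:
    """Exact number of trainable scalars, as a deterministic function of the
    spec (stem kernels + biases, every capsule transformation matrix)."""
    g = spec.variant_g
    T = spec.types()
    De = spec.encoder_dims()
    Dd = spec.decoder_dims()
    n = spec.n_stages

    def lw(t_in, t_out, d_in, d_out, karea):
        return (t_in * t_out // g) * d_in * d_out * karea

    total = STEM_CHANNELS * 9 * 1 + STEM_CHANNELS \
        + STEM_CHANNELS * 9 * STEM_CHANNELS + STEM_CHANNELS
    for k in range(1, n + 1):
        total += lw(T[k - 1], T[k], De[k - 1], De[k], 4)
        total += (spec.enc_layers[k - 1] - 1) * lw(T[k], T[k], De[k], De[k], 9)
    prevT, prevD = T[n], De[n]
    for j, l in enumerate(range(n - 1, -1, -1)):
        total += lw(prevT, T[l], prevD, Dd[l], 1)          # deconv (shared)
        total += lw(T[l], T[l], Dd[l], Dd[l], 1)           # fuse: decoder part
        total += lw(T[l], T[l], De[l], Dd[l], 1)           # fuse: skip part
        total += (spec.dec_layers[j] - 1) * lw(T[l], T[l], Dd[l], Dd[l], 1)
        prevT, prevD = T[l], Dd[l]
    total += T[0] * HEAD_TYPES * Dd[0] * HEAD_DIM          # 1x1 head
    return total


def count_network_votes(spec: NetworkSpec) -> int:
    """Total intermediate vote capsules in one forward pass (per sample)."""
    g = spec.variant_g
    T = spec.types()
    n = spec.n_stages
    s = spec.input_size
    total = 0
    size = s
    for k in range(1, n + 1):
        size //= 2
        total += count_votes(T[k - 1], T[k], 4, size, size, g)
        total += (spec.enc_layers[k - 1] - 1) * count_votes(
            T[k], T[k], 9, size, size, g)
    prevT = T[n]
    for j, l in enumerate(range(n - 1, -1, -1)):
        size *= 2
        total += count_votes(prevT, T[l], 1, size, size, g)   # deconv: 1/pos
        total += count_votes(T[l], T[l], 9, size, size, g) * 2  # fusion
        total += (spec.dec_layers[j] - 1) * count_votes(
            T[l], T[l], 9, size, size, g)
        prevT = T[l]
    total += count_votes(T[0], HEAD_TYPES, 1, size, size, 1)
    return total


def shape_plan(spec: NetworkSpec):
    """Statically propagate (H, W, types, dim) through the network."""
    T = spec.types()
    De = spec.encoder_dims()
    Dd = spec.decoder_dims()
    n = spec.n_stages
    s = spec.input_size
    plan = [("initial", (s, s, T[0], De[0]))]
    size = s
    for k in range(1, n + 1):
        size //= 2
        plan.append((f"enc{k}", (size, size, T[k], De[k])))
    for l in range(n - 1, -1, -1):
        size *= 2
        plan.append((f"dec{l}", (size, size, T[l], Dd[l])))
    plan.append(("head", (size, size, HEAD_TYPES, HEAD_DIM)))
    return plan


TABLE_VARIANTS = (1, 2, 4, 8)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: GroupCapsNet, path):
    """Serialize spec + all trainable tensors to a single .npz file."""
    import json
    spec_json = json.dumps(model.spec.__dict__)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, spec=np.frombuffer(spec_json.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> GroupCapsNet:
    """Rebuild a model from :func:`save_checkpoint` output."""
    import json
    with np.load(path) as data:
        spec_kw = json.loads(bytes(data["spec"]).decode())
        spec_kw["enc_layers"] = tuple(spec_kw["enc_layers"])
        spec_kw["dec_layers"] = tuple(spec_kw["dec_layers"])
        spec = NetworkSpec(**spec_kw)
        model = build_network(spec, seed=0)
        params = model.parameters()
        for i, p in enumerate(params):
            arr = data[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ConfigurationError(
                    f"checkpoint param {i} shape {arr.shape} != model "
                    f"{p.data.shape}")
            p.data = arr.astype(p.data.dtype)
    return model
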