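"""Complex-valued encoder-decoder for slice-wise B1+ estimation.

The architecture maps a 9-channel complex localizer slice (8 receive
channels + root-sum-of-squares magnitude) to 8 complex transmit-channel B1+
maps. It is a U-Net-style encoder-decoder: four stages, two 3x3 complex
convolutions per stage with ModReLU activations, stride-2 (up-)convolutions
for resampling, concatenating skip connections and dropout at stage ends,
followed by one small head of four convolutions per transmit channel.

The trainable model is exposed as a scikit-learn-style estimator
(:class:`ComplexB1Mapper`), with ``fit``/``predict``/``get_params`` and
fitted attributes carrying a trailing underscore. A real-valued baseline of
the same topology (real/imaginary channel splitting, 17 in / 16 out
channels) is available through ``variant="real_split"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._autograd import Tensor, conv2d_same, conv2d_transpose_same, concat_channels
from .complex_nn import (
    CConv2d,
    CConvTranspose2d,
    CDropout,
    ModReLU,
    perp_l2_loss_autograd,
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    height: int = 128
    width: int = 96
    in_channels: int = 9
    out_channels: int = 8
    n_stages: int = 4
    base_features: int = 16
    convs_per_stage: int = 2
    head_convs: int = 4
    dropout_rate: float = 0.1
    variant: str = "complex"  # "complex" | "real_split"
    full_split_decoder: bool = False
    feature_multiplier: float = 1.0  # real baseline width scaling

    def validate(self):
        div = 2 ** self.n_stages
        if self.height % div or self.width % div:
            raise ValueError(
                f"spatial dims ({self.height}, {self.width}) must be divisible "
                f"by 2^n_stages = {div}"
            )
        if self.variant not in ("complex", "real_split"):
            raise ValueError(f"unknown variant {self.variant!r}")
        return self


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    lr_decay: float = 0.0019  # fraction per epoch: lr(e) = lr0 (1 - decay)^e
    epochs: int = 1000
    batch_size: int = 1
    lambda_l2: float = 1.0
    seed: int = 0


def learning_rate(tc: TrainConfig, epoch: int) -> float:
    """Exponentially decaying schedule lr(e) = lr0 * (1 - decay)^e."""
    return tc.lr0 * (1.0 - tc.lr_decay) ** epoch


# Desk-scale profile: half-resolution grid, half-width features, short
# schedule with a proportionally larger step and the full schedule's total
# decay compressed into it. Used by the test-suite and the reproduction
# script; the full-size profile is the default config above.
SCALED_NETWORK = dict(height=64, width=48, base_features=8)
SCALED_TRAIN = dict(lr0=5e-4, lr_decay=0.04, epochs=30)


# ---------------------------------------------------------------------------
# Subject-wise cross-validation folds
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """k subject-disjoint folds; each subject is held out exactly once."""

    folds: list  # list of (train_ids, test_ids) tuples
    seed: int = 0

    @property
    def k(self):
        return len(self.folds)


def make_subject_folds(subject_ids, k: int, seed: int) -> FoldSplit:
    """Randomly partition subjects into k folds (subject-disjoint)."""
    ids = list(subject_ids)
    if k < 2 or k > len(ids):
        raise ValueError(f"k must be in [2, n_subjects={len(ids)}], got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, k)
    folds = []
    for c in chunks:
        test = sorted(ids[i] for i in c)
        train = sorted(x for x in ids if x not in test)
        folds.append((train, test))
    return FoldSplit(folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# Dataset normalization
# ---------------------------------------------------------------------------

CP_WEIGHTS = np.exp(-1j * 2 * np.pi * np.arange(8) / 8).astype(np.complex64)


def cp_combined(b1):
    """CP+ channel combination of an (..., 8) complex B1+ array."""
    return np.tensordot(b1, CP_WEIGHTS, axes=([-1], [0]))


def normalize_dataset(library):
    """Normalize a library per subject: B1+ maps by the 99th percentile of
    the CP+-combined magnitude, localizers by their maximum combined
    magnitude. Returns (normalized library, {subject: scales})."""
    from .containers import ComplexSliceStack, SimulatedPair

    out, scales = {}, {}
    for subj, pairs in library.items():
        cp_mags, loc_mags = [], []
        for pair in pairs.values():
            cp_mags.append(np.abs(cp_combined(pair.b1.data)).ravel())
            loc_mags.append(np.abs(pair.localizer.data[..., -1]).ravel())
        cp_all = np.concatenate(cp_mags)
        if not cp_all.any():
            raise ValueError(f"all-zero B1+ fields for subject {subj!r}")
        b1_scale = float(np.percentile(cp_all, 99))
        loc_scale = float(np.max(np.concatenate(loc_mags)))
        scales[subj] = {"b1": b1_scale, "localizer": loc_scale}
        out[subj] = {}
        for orient, pair in pairs.items():
            out[subj][orient] = SimulatedPair(
                localizer=ComplexSliceStack(
                    pair.localizer.data / loc_scale,
                    subject=subj,
                    orientation=orient,
                    mask=pair.localizer.mask,
                    positions=pair.localizer.positions,
                    spacing=pair.localizer.spacing,
                ),
                b1=ComplexSliceStack(
                    pair.b1.data / b1_scale,
                    subject=subj,
                    orientation=orient,
                    mask=pair.b1.mask,
                    positions=pair.b1.positions,
                    spacing=pair.b1.spacing,
                ),
                meta=dict(pair.meta),
            )
    return out, scales


def denormalize(b1_data, scale):
    """Invert :func:`normalize_dataset` for a B1+ array."""
    return b1_data * scale["b1"]


def collect_slices(library, subjects=None, orientations=None):
    """Flatten a library into training arrays.

    Returns (X, Y, masks, records): X complex (N, H, W, 9), Y complex
    (N, H, W, 8), masks bool (N, H, W), records a list of
    (subject, orientation, slice index) in stack order.
    """
    xs, ys, ms, recs = [], [], [], []
    for sid in sorted(library):
        if subjects is not None and sid not in subjects:
            continue
        for orient in sorted(library[sid]):
            if orientations is not None and orient not in orientations:
                continue
            pair = library[sid][orient]
            xs.append(pair.localizer.data)
            ys.append(pair.b1.data)
            ms.append(pair.b1.mask)
            recs += [(sid, orient, i) for i in range(pair.b1.n_slices)]
    if not xs:
        raise ValueError("no slices selected from the library")
    return (
        np.concatenate(xs, axis=0),
        np.concatenate(ys, axis=0),
        np.concatenate(ms, axis=0),
        recs,
    )


# ---------------------------------------------------------------------------
# Network graphs
# ---------------------------------------------------------------------------


class _RConv2d:
    """Real convolution + bias (baseline building block)."""

    def __init__(self, cin, cout, stride=1, seed=0, transpose=False):
        rng = np.random.default_rng(seed)
        fan_in, fan_out = 9 * cin, 9 * cout
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        if transpose:
            shape = (3, 3, cout, cin)
        else:
            shape = (3, 3, cin, cout)
        self.w = Tensor(
            rng.uniform(-limit, limit, size=shape).astype(np.float32),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.transpose = transpose

    @property
    def params(self):
        return [self.w, self.b]

    def __call__(self, x):
        if self.transpose:
            return conv2d_transpose_same(x, self.w, 2) + self.b
        return conv2d_same(x, self.w, self.stride) + self.b


class ComplexUNet:
    """Complex-valued U-Net with per-Tx-channel heads (see module docstring)."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        cfg.validate()
        if cfg.variant != "complex":
            raise ValueError("ComplexUNet requires variant='complex'")
        self.cfg = cfg
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        seeds = iter(ss.generate_state(4096).tolist())
        f = [cfg.base_features * 2 ** s for s in range(cfg.n_stages)]
        self.enc = []
        cin = cfg.in_channels
        for s in range(cfg.n_stages):
            convs = []
            for _ in range(cfg.convs_per_stage):
                convs.append((CConv2d(cin, f[s], 1, seed=next(seeds)), ModReLU(f[s])))
                cin = f[s]
            down_f = f[s] if s == cfg.n_stages - 1 else f[s + 1]
            down = (CConv2d(cin, down_f, 2, seed=next(seeds)), ModReLU(down_f))
            self.enc.append((convs, down, CDropout(cfg.dropout_rate)))
            cin = down_f

        def make_decoder():
            dec, c = [], f[-1]
            for s in reversed(range(cfg.n_stages)):
                up = (CConvTranspose2d(c, f[s], seed=next(seeds)), ModReLU(f[s]))
                convs, c2 = [], 2 * f[s]  # concat with skip
                for _ in range(cfg.convs_per_stage):
                    convs.append((CConv2d(c2, f[s], 1, seed=next(seeds)), ModReLU(f[s])))
                    c2 = f[s]
                dec.append((up, convs, CDropout(cfg.dropout_rate)))
                c = f[s]
            return dec

        def make_head():
            feats, head = cfg.base_features, []
            c = cfg.base_features
            for i in range(cfg.head_convs):
                cout = max(1, feats // 2 ** i) if i < cfg.head_convs - 1 else 1
                act = ModReLU(cout) if i < cfg.head_convs - 1 else None
                head.append((CConv2d(c, cout, 1, seed=next(seeds)), act))
                c = cout
            return head

        if cfg.full_split_decoder:
            self.decoders = [make_decoder() for _ in range(cfg.out_channels)]
        else:
            self.decoders = [make_decoder()]
        self.heads = [make_head() for _ in range(cfg.out_channels)]

    # -- parameters ------------------------------------------------------

    @property
    def params(self):
        ps = []
        for convs, down, _ in self.enc:
            for conv, act in convs:
                ps += conv.params + act.params
            ps += down[0].params + down[1].params
        for dec in self.decoders:
            for up, convs, _ in dec:
                ps += up[0].params + up[1].params
                for conv, act in convs:
                    ps += conv.params + act.params
        for head in self.heads:
            for conv, act in head:
                ps += conv.params
                if act is not None:
                    ps += act.params
        return ps

    @property
    def n_params(self):
        return int(sum(p.data.size for p in self.params))

    # -- forward ---------------------------------------------------------

    def forward(self, x, training=False, rng=None):
        """x: complex (N, H, W, in_channels) -> list of (pr, pi) per Tx head,
        concatenated to (N, H, W, out_channels) complex by :meth:`predict`."""
        x = np.asarray(x, dtype=np.complex64)
        if x.ndim != 4 or x.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (N, H, W, {self.cfg.in_channels}) input, got {x.shape}"
            )
        xr = Tensor(np.ascontiguousarray(x.real))
        xi = Tensor(np.ascontiguousarray(x.imag))
        skips = []
        for convs, down, drop in self.enc:
            for conv, act in convs:
                xr, xi = act(*conv(xr, xi))
            skips.append((xr, xi))
            xr, xi = down[1](*down[0](xr, xi))
            xr, xi = drop(xr, xi, training=training, rng=rng)

        def run_decoder(dec, br, bi):
            for (up, convs, drop), (sr, si) in zip(dec, reversed(skips)):
                br, bi = up[1](*up[0](br, bi))
                br = concat_channels([br, sr])
                bi = concat_channels([bi, si])
                for conv, act in convs:
                    br, bi = act(*conv(br, bi))
                br, bi = drop(br, bi, training=training, rng=rng)
            return br, bi

        outs = []
        if self.cfg.full_split_decoder:
            trunks = [run_decoder(dec, xr, xi) for dec in self.decoders]
        else:
            trunks = [run_decoder(self.decoders[0], xr, xi)] * self.cfg.out_channels
        for head, (tr, ti) in zip(self.heads, trunks):
            hr, hi = tr, ti
            for conv, act in head:
                hr, hi = conv(hr, hi)
                if act is not None:
                    hr, hi = act(hr, hi)
            outs.append((hr, hi))
        return outs

    def predict(self, x):
        """Inference: complex (N, H, W, 9) -> complex (N, H, W, 8)."""
        outs = self.forward(x, training=False)
        return np.stack(
            [(hr.data + 1j * hi.data)[..., 0] for hr, hi in outs], axis=-1
        ).astype(np.complex64)


class RealSplitUNet:
    """Real-valued baseline: identical topology, real arithmetic, complex
    data split into real/imaginary channels (17 in, 16 out)."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        seeds = iter(ss.generate_state(4096).tolist())
        m = cfg.feature_multiplier
        f = [max(1, int(round(cfg.base_features * m))) * 2 ** s for s in range(cfg.n_stages)]
        self.in_channels = 2 * (cfg.in_channels - 1) + 1  # 8 re + 8 im + magnitude
        self.out_channels = 2 * cfg.out_channels
        self.enc, cin = [], self.in_channels
        for s in range(cfg.n_stages):
            convs = []
            for _ in range(cfg.convs_per_stage):
                convs.append(_RConv2d(cin, f[s], 1, seed=next(seeds)))
                cin = f[s]
            down_f = f[s] if s == cfg.n_stages - 1 else f[s + 1]
            self.enc.append((convs, _RConv2d(cin, down_f, 2, seed=next(seeds))))
            cin = down_f
        self.dec = []
        c = f[-1]
        for s in reversed(range(cfg.n_stages)):
            up = _RConv2d(c, f[s], seed=next(seeds), transpose=True)
            convs, c2 = [], 2 * f[s]
            for _ in range(cfg.convs_per_stage):
                convs.append(_RConv2d(c2, f[s], 1, seed=next(seeds)))
                c2 = f[s]
            self.dec.append((up, convs))
            c = f[s]
        self.out = _RConv2d(c, self.out_channels, 1, seed=next(seeds))

    @property
    def params(self):
        ps = []
        for convs, down in self.enc:
            for c in convs:
                ps += c.params
            ps += down.params
        for up, convs in self.dec:
            ps += up.params
            for c in convs:
                ps += c.params
        return ps + self.out.params

    @property
    def n_params(self):
        return int(sum(p.data.size for p in self.params))

    @staticmethod
    def split_input(x):
        """Complex (N, H, W, 9) -> real (N, H, W, 17): 8 re, 8 im, magnitude."""
        x = np.asarray(x, dtype=np.complex64)
        return np.concatenate(
            [x[..., :-1].real, x[..., :-1].imag, x[..., -1:].real], axis=-1
        ).astype(np.float32)

    @staticmethod
    def recombine_output(y):
        """Real (N, H, W, 16) -> complex (N, H, W, 8)."""
        n = y.shape[-1] // 2
        return (y[..., :n] + 1j * y[..., n:]).astype(np.complex64)

    def forward(self, x, training=False, rng=None):
        xr = Tensor(self.split_input(x))
        skips = []
        for convs, down in self.enc:
            for conv in convs:
                xr = conv(xr).relu()
            skips.append(xr)
            xr = down(xr).relu()
        for (up, convs), s in zip(self.dec, reversed(skips)):
            xr = up(xr).relu()
            xr = concat_channels([xr, s])
            for conv in convs:
                xr = conv(xr).relu()
        return self.out(xr)

    def predict(self, x):
        return self.recombine_output(self.forward(x).data)


def build_complex_unet(cfg: NetworkConfig = None, seed: int = 0) -> ComplexUNet:
    """Build the complex-valued encoder-decoder with the default configuration."""
    return ComplexUNet(cfg or NetworkConfig(), seed=seed)


def build_real_baseline(cfg: NetworkConfig = None, seed: int = 0) -> RealSplitUNet:
    cfg = cfg or NetworkConfig(variant="real_split")
    if cfg.variant != "real_split":
        raise ValueError("real baseline requires variant='real_split'")
    return RealSplitUNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Optimizer + training loop
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
            p.grad = None


def train_model(network, X, Y, masks, tc: TrainConfig, verbose=False, log=None):
    """Train on slices X (N, H, W, 9 complex), targets Y (N, H, W, 8 complex),
    masks (N, H, W bool), minimizing the perpendicular + L2 loss with Adam and
    the exponentially decaying schedule. Returns (network, history)."""
    X = np.asarray(X, dtype=np.complex64)
    Y = np.asarray(Y, dtype=np.complex64)
    masks = np.asarray(masks, dtype=bool)
    if len(X) == 0:
        raise ValueError("empty training dataset")
    if X.shape[:3] != Y.shape[:3]:
        raise ValueError(f"input/target grids differ: {X.shape} vs {Y.shape}")
    is_real = isinstance(network, RealSplitUNet)
    rng = np.random.default_rng(tc.seed)
    opt = Adam(network.params)
    history = []
    for epoch in range(tc.epochs):
        lr = learning_rate(tc, epoch)
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb, yb, mb = X[idx], Y[idx], masks[idx]
            if is_real:
                out = network.forward(xb, training=True, rng=rng)
                yr = np.concatenate([yb.real, yb.imag], axis=-1)
                diff = out - Tensor(yr)
                w = mb[..., None].astype(np.float32) / max(mb.sum(), 1)
                loss = (diff.square() * Tensor(np.broadcast_to(w, yr.shape).copy())).sum()
            else:
                outs = network.forward(xb, training=True, rng=rng)
                pr = concat_channels([h for h, _ in outs])
                pi = concat_channels([h for _, h in outs])
                loss = perp_l2_loss_autograd(
                    pr, pi, yb, mb[..., None], lambda_l2=tc.lambda_l2
                )
            loss.backward()
            opt.step(lr)
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if log is not None:
            log(epoch=epoch, lr=lr, loss=history[-1])
        if verbose:
            print(f"epoch {epoch:4d}  lr {lr:.3e}  loss {history[-1]:.5f}")
    return network, history


def predict_b1(network, localizers):
    """Slice-wise prediction preserving slice order.

    localizers: complex (N, H, W, 9) -> complex (N, H, W, 8).
    """
    if not getattr(network, "params", None):
        raise ValueError("network is not initialized")
    return network.predict(localizers)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class ComplexB1Mapper(BaseEstimator):
    """Scikit-learn-style estimator: complex localizer slices in, complex
    channel-wise B1+ maps out.

    Parameters mirror :class:`NetworkConfig` and :class:`TrainConfig`;
    fitted state lives in ``net_``, ``history_`` and ``n_params_``.
    """

    def __init__(
        self,
        height=128,
        width=96,
        in_channels=9,
        out_channels=8,
        n_stages=4,
        base_features=16,
        dropout_rate=0.1,
        variant="complex",
        full_split_decoder=False,
        feature_multiplier=1.0,
        lr0=1e-4,
        lr_decay=0.0019,
        epochs=1000,
        batch_size=1,
        lambda_l2=1.0,
        gain="auto",
        seed=0,
        verbose=False,
    ):
        self.height = height
        self.width = width
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.n_stages = n_stages
        self.base_features = base_features
        self.dropout_rate = dropout_rate
        self.variant = variant
        self.full_split_decoder = full_split_decoder
        self.feature_multiplier = feature_multiplier
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.lambda_l2 = lambda_l2
        self.gain = gain
        self.seed = seed
        self.verbose = verbose

    # -- config plumbing -------------------------------------------------

    def _network_config(self):
        return NetworkConfig(
            height=self.height,
            width=self.width,
            in_channels=self.in_channels,
            out_channels=self.out_channels,
            n_stages=self.n_stages,
            base_features=self.base_features,
            dropout_rate=self.dropout_rate,
            variant=self.variant,
            full_split_decoder=self.full_split_decoder,
            feature_multiplier=self.feature_multiplier,
        ).validate()

    def _train_config(self):
        return TrainConfig(
            lr0=self.lr0,
            lr_decay=self.lr_decay,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lambda_l2=self.lambda_l2,
            seed=self.seed,
        )

    # -- sklearn API -----------------------------------------------------

    def fit(self, X, y, mask=None):
        X = np.asarray(X, dtype=np.complex64)
        y = np.asarray(y, dtype=np.complex64)
        if X.ndim != 4:
            raise ValueError(f"X must be (n_slices, H, W, C), got shape {X.shape}")
        cfg = self._network_config()
        if X.shape[1:3] != (cfg.height, cfg.width):
            raise ValueError(
                f"slice grid {X.shape[1:3]} does not match configured "
                f"({cfg.height}, {cfg.width})"
            )
        if mask is None:
            mask = np.ones(X.shape[:3], dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        # internal conditioning gain: bring field magnitudes to O(1) so that
        # Adam's parameter steps stay small relative to the feature scale
        if self.gain == "auto":
            g = float(np.clip(1.0 / max(np.abs(y).mean(), 1e-12), 1.0, 100.0))
        else:
            g = float(self.gain)
        if cfg.variant == "complex":
            net = ComplexUNet(cfg, seed=self.seed)
        else:
            net = RealSplitUNet(cfg, seed=self.seed)
        net, history = train_model(
            net, X * g, y * g, mask, self._train_config(), verbose=self.verbose
        )
        self.net_ = net
        self.gain_ = g
        self.history_ = history
        self.n_params_ = net.n_params
        return self

    def predict(self, X):
        if not hasattr(self, "net_"):
            raise ValueError("this ComplexB1Mapper instance is not fitted yet")
        X = np.asarray(X, dtype=np.complex64)
        g = getattr(self, "gain_", 1.0)
        return (self.net_.predict(X * g) / g).astype(np.complex64)

    # -- checkpointing ---------------------------------------------------

    def save(self, path):
        """Serialize fitted weights + configuration to an .npz container."""
        if not hasattr(self, "net_"):
            raise ValueError("cannot save an unfitted model")
        arrays = {f"p{i}": p.data for i, p in enumerate(self.net_.params)}
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(self.get_params()).encode(), dtype=np.uint8
            ),
            __history__=np.asarray(self.history_, dtype=np.float64),
            __gain__=np.asarray(getattr(self, "gain_", 1.0)),
            **arrays,
        )

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            params = json.loads(bytes(z["__config__"].tobytes()).decode())
            est = cls(**params)
            cfg = est._network_config()
            if cfg.variant == "complex":
                net = ComplexUNet(cfg, seed=est.seed)
            else:
                net = RealSplitUNet(cfg, seed=est.seed)
            for i, p in enumerate(net.params):
                p.data = z[f"p{i}"].astype(np.float32)
            est.net_ = net
            est.history_ = list(z["__history__"])
            est.gain_ = float(z["__gain__"]) if "__gain__" in z else 1.0
            est.n_params_ = net.n_params
        return est
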