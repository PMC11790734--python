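"""Residual convolutional denoiser turning accelerated images into DLR images.

The network is the 3-layer super-resolution-CNN topology with a global
residual (skip) connection: 9x9 kernels / 64 channels, then 5x5 / 32, then
5x5 / 1, each with biases; ReLU follows the first two layers, the third is
linear, and the input is added to the output so the network learns a signed
noise correction.  Same-padding uses reflect boundaries to avoid edge
ringing.  Total parameter count: (9*9*1*64 + 64) + (5*5*64*32 + 32) +
(5*5*32*1 + 1) = 57,281.

Everything — forward pass, backpropagation and the Adam optimizer — is
implemented directly on numpy arrays (float32, im2col convolutions), which
is ample for a network this small; training the default configuration takes
a few minutes on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kspace import apply_mask, make_equidistant_mask, simulate_multicoil_kspace
from .phantom import PhantomCase, generate_coil_sensitivities
from .recon import PocsConfig, ReconImage, pocs_wavelet_recon, reference_recon

__all__ = [
    "DenoiserModel",
    "TrainingPairSet",
    "TrainingDivergedError",
    "init_model",
    "make_training_pairs",
    "train_denoiser",
    "apply_denoiser",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; a lower learning rate is the usual fix."""


def _reflect_index(n: int, pad: int) -> np.ndarray:
    """Source index for each position of a reflect-padded axis."""
    return np.pad(np.arange(n), pad, mode="reflect")


class _ConvLayer:
    """Same-padded 2D convolution with reflect boundary and bias.

    Activations are channels-last (B, H, W, C); the convolution is computed
    as k*k shifted matrix products, which keeps every memory access pattern
    block-contiguous (no im2col materialization).
    """

    def __init__(self, w: np.ndarray, b: np.ndarray):
        self.w = w  # (out_ch, in_ch, k, k)
        self.b = b  # (out_ch,)
        self._cache = None

    @property
    def k(self) -> int:
        return self.w.shape[-1]

    def _wk(self) -> np.ndarray:
        # (k, k, in_ch, out_ch)
        return np.ascontiguousarray(self.w.transpose(2, 3, 1, 0))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        bsz, h, wdt, cin = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="reflect")
        wk = self._wk()
        if cin == 1:
            # single gemm over stacked shifts (row-contiguous patch matrix)
            cols_t = np.empty((k * k, bsz * h * wdt), dtype=x.dtype)
            for u in range(k):
                for v in range(k):
                    cols_t[u * k + v] = xp[:, u:u + h, v:v + wdt, 0].reshape(-1)
            y = cols_t.T @ wk.reshape(k * k, -1) + self.b
            if train:
                self._cache = (xp, x.shape, cols_t)
            return y.reshape(bsz, h, wdt, -1)
        y = np.empty((bsz * h * wdt, wk.shape[-1]), dtype=x.dtype)
        y[:] = self.b
        for u in range(k):
            for v in range(k):
                xsl = xp[:, u:u + h, v:v + wdt, :].reshape(-1, cin)
                y += xsl @ wk[u, v]
        if train:
            self._cache = (xp, x.shape, None)
        return y.reshape(bsz, h, wdt, -1)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        xp, xshape, cols_t = self._cache
        bsz, h, wdt, cin = xshape
        k, p = self.k, self.k // 2
        cout = dy.shape[-1]
        dyf = dy.reshape(-1, cout)
        db = dyf.sum(axis=0)
        wk = self._wk()
        dxp = np.zeros(xp.shape, dtype=dy.dtype) if need_dx else None
        if cols_t is not None:  # cin == 1 fast path
            dwk = (cols_t @ dyf).reshape(k, k, cin, cout)
            if need_dx:
                g_all = (dyf @ wk.reshape(k * k, cout).T)  # (BHW, k*k)
                g_all = g_all.reshape(bsz, h, wdt, k * k)
                for u in range(k):
                    for v in range(k):
                        dxp[:, u:u + h, v:v + wdt, 0] += g_all[..., u * k + v]
            dw = dwk.transpose(3, 2, 0, 1)
            if not need_dx:
                return None, dw, db
            return self._fold(dxp, xshape, p), dw, db
        dwk = np.empty((k, k, cin, cout), dtype=self.w.dtype)
        for u in range(k):
            for v in range(k):
                xsl = xp[:, u:u + h, v:v + wdt, :].reshape(-1, cin)
                dwk[u, v] = xsl.T @ dyf
                if need_dx:
                    g = (dyf @ wk[u, v].T).reshape(bsz, h, wdt, cin)
                    dxp[:, u:u + h, v:v + wdt, :] += g
        dw = dwk.transpose(3, 2, 0, 1)  # back to (out_ch, in_ch, k, k)
        if not need_dx:
            return None, dw, db
        return self._fold(dxp, xshape, p), dw, db

    @staticmethod
    def _fold(dxp: np.ndarray, xshape: tuple, p: int) -> np.ndarray:
        """Adjoint of reflect padding: fold border gradients onto the interior."""
        bsz, h, wdt, cin = xshape
        ridx = _reflect_index(h, p)
        cidx = _reflect_index(wdt, p)
        dx = np.zeros(xshape, dtype=dxp.dtype)
        tmp = np.zeros((bsz, h, wdt + 2 * p, cin), dtype=dxp.dtype)
        for r in range(h + 2 * p):
            tmp[:, ridx[r], :, :] += dxp[:, r, :, :]
        for c in range(wdt + 2 * p):
            dx[:, :, cidx[c], :] += tmp[:, :, c, :]
        return dx


@dataclass
class DenoiserModel:
    """3-layer residual CNN denoiser with its normalization contract."""

    weights: dict  # w1, b1, w2, b2, w3, b3 (float32)
    kernel_sizes: tuple[int, int, int] = (9, 5, 5)
    channels: tuple[int, int, int] = (64, 32, 1)
    residual: bool = True
    norm: dict = field(default_factory=lambda: {"plo": 1.0, "phi": 99.0})
    train_meta: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.weights.values()))

    def _layers(self) -> list[_ConvLayer]:
        w = self.weights
        return [_ConvLayer(w["w1"], w["b1"]), _ConvLayer(w["w2"], w["b2"]),
                _ConvLayer(w["w3"], w["b3"])]

    def forward(self, x: np.ndarray, train: bool = False,
                layers: list | None = None):
        """x: (B, 1, H, W) normalized float32 -> same-shape output.

        ReLU after layers 1 and 2, linear layer 3, plus the global skip
        connection when ``residual`` is set.  With ``train=True`` also
        returns the per-layer activations needed for backprop.
        """
        layers = layers if layers is not None else self._layers()
        xc = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # channels-last
        h1 = layers[0].forward(xc, train)
        a1 = np.maximum(h1, 0.0)
        h2 = layers[1].forward(a1, train)
        a2 = np.maximum(h2, 0.0)
        out = layers[2].forward(a2, train)
        if self.residual:
            out = out + xc
        out_cf = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        if train:
            return out_cf, (h1, h2)
        return out_cf


def init_model(seed: int = 0,
               kernel_sizes: tuple[int, int, int] = (9, 5, 5),
               channels: tuple[int, int, int] = (64, 32, 1),
               residual: bool = True) -> DenoiserModel:
    """Seeded He-normal initialization of the 3-layer architecture."""
    rng = np.random.default_rng(seed)
    k1, k2, k3 = kernel_sizes
    c1, c2, c3 = channels
    shapes = [(c1, 1, k1, k1), (c2, c1, k2, k2), (c3, c2, k3, k3)]
    weights = {}
    for i, shp in enumerate(shapes, start=1):
        fan_in = shp[1] * shp[2] * shp[3]
        scale = np.sqrt(2.0 / fan_in)
        if i == 3:
            scale *= 0.1  # small output layer: start near the identity map
        weights[f"w{i}"] = (rng.standard_normal(shp)
                            * scale).astype(np.float32)
        weights[f"b{i}"] = np.zeros(shp[0], dtype=np.float32)
    return DenoiserModel(weights=weights, kernel_sizes=tuple(kernel_sizes),
                         channels=tuple(channels), residual=residual)


@dataclass
class TrainingPairSet:
    """Aligned (reference, noisy) patch pairs drawn from reconstructions."""

    reference: np.ndarray  # (N, 1, ps, ps) float32, normalized
    noisy: np.ndarray  # same shape, co-located
    patch_size: int
    norm: dict
    seed: int

    def __post_init__(self) -> None:
        if self.reference.shape != self.noisy.shape:
            raise ValueError("reference and noisy patch stacks must align")

    @property
    def n_pairs(self) -> int:
        return self.reference.shape[0]


def _normalize(img: np.ndarray, plo: float, phi: float):
    lo, hi = np.percentile(img, [plo, phi])
    span = max(hi - lo, 1e-12)
    return (img - lo) / span, float(lo), float(span)


def make_training_pairs(
    cohort: list[PhantomCase],
    n_channels: int = 8,
    noise_std: float = 0.011,
    af: int = 3,
    offset: int = 0,
    pocs_cfg: PocsConfig | None = None,
    ref_noise_std: float = 0.0,
    n_patches: int = 384,
    patch_size: int = 32,
    seed: int = 0,
    plo: float = 1.0,
    phi: float = 99.0,
) -> TrainingPairSet:
    """Build co-located (reference, noisy) patch pairs from a cohort.

    Per case: the reference is the fully sampled reconstruction of low-noise
    data; the noisy input is the POCS reconstruction of equidistantly
    undersampled noisy data of the same case.  Both are normalized to [0, 1]
    with the case's reference-image 1st-99th percentile window before patch
    extraction, and patches are cut at identical coordinates.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    shape = cohort[0].shape
    if patch_size > min(shape):
        raise ValueError("patch larger than image")
    pocs_cfg = pocs_cfg or PocsConfig()
    rng = np.random.default_rng(seed)
    refs, noisies = [], []
    mask = make_equidistant_mask(shape[1], af, offset) if af > 1 else None
    per_case = int(np.ceil(n_patches / len(cohort)))
    for ci, case in enumerate(cohort):
        coils = generate_coil_sensitivities(case.shape, n_channels,
                                            seed=case.seed + 10_000)
        ks_ref = simulate_multicoil_kspace(case, coils, ref_noise_std,
                                           seed=case.seed + 1)
        ref_img = reference_recon(ks_ref, coils).image
        ks_noisy = simulate_multicoil_kspace(case, coils, noise_std,
                                             seed=case.seed + 2)
        if mask is not None:
            acc_img = pocs_wavelet_recon(apply_mask(ks_noisy, mask), coils,
                                         mask, pocs_cfg).image
        else:
            acc_img = reference_recon(ks_noisy, coils).image
        # normalize in the frame available at inference: the noisy image's
        # own percentile window (the reference shares the same window)
        acc_n, lo, span = _normalize(acc_img, plo, phi)
        ref_n = (ref_img - lo) / span
        # patch centers drawn from the brain so capacity is spent on tissue
        cand = np.argwhere(case.brain_mask)
        half = patch_size // 2
        for _ in range(per_case):
            r, c = cand[rng.integers(len(cand))]
            r0 = int(np.clip(r - half, 0, shape[0] - patch_size))
            c0 = int(np.clip(c - half, 0, shape[1] - patch_size))
            refs.append(ref_n[r0:r0 + patch_size, c0:c0 + patch_size])
            noisies.append(acc_n[r0:r0 + patch_size, c0:c0 + patch_size])
    refs = np.asarray(refs, dtype=np.float32)[:n_patches, None]
    noisies = np.asarray(noisies, dtype=np.float32)[:n_patches, None]
    return TrainingPairSet(reference=refs, noisy=noisies,
                           patch_size=patch_size,
                           norm={"plo": plo, "phi": phi}, seed=int(seed))


def train_denoiser(
    model: DenoiserModel,
    pairs: TrainingPairSet,
    epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
    val_fraction: float = 0.0,
) -> DenoiserModel:
    """Train with Adam on the MSE between network output and reference.

    Deterministic for a fixed seed (which also drives the per-epoch
    shuffle).  Raises :class:`TrainingDivergedError` if the loss becomes
    non-finite.  ``val_fraction`` > 0 holds out the trailing fraction of
    pairs and records a validation loss per epoch.
    """
    if pairs.n_pairs == 0:
        raise ValueError("no training pairs")
    rng = np.random.default_rng(seed)
    n_val = int(round(val_fraction * pairs.n_pairs))
    n_trn = pairs.n_pairs - n_val
    if n_trn < 1:
        raise ValueError("val_fraction leaves no training pairs")
    x_all, y_all = pairs.noisy[:n_trn], pairs.reference[:n_trn]
    x_val, y_val = pairs.noisy[n_trn:], pairs.reference[n_trn:]

    layers = model._layers()
    params = [(ly, attr) for ly in layers for attr in ("w", "b")]
    m_t = [np.zeros_like(getattr(ly, a)) for ly, a in params]
    v_t = [np.zeros_like(getattr(ly, a)) for ly, a in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    epoch_losses, val_losses = [], []
    for _epoch in range(epochs):
        # step the learning rate down late in training
        lr_now = lr * (0.3 ** sum(_epoch >= int(f * epochs)
                                  for f in (0.6, 0.85)))
        order = rng.permutation(n_trn)
        tot, nb = 0.0, 0
        for start in range(0, n_trn, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x_all[idx], y_all[idx]
            out, (h1, h2) = model.forward(xb, train=True, layers=layers)
            err = out - yb
            with np.errstate(over="ignore", invalid="ignore"):
                loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    "training diverged (non-finite loss); try a lower lr")
            tot += loss
            nb += 1
            dout = (2.0 / err.size) * err.astype(np.float32)
            dout_cl = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))
            da2, dw3, db3 = layers[2].backward(dout_cl)
            dh2 = da2 * (h2 > 0)
            da1, dw2, db2 = layers[1].backward(dh2)
            dh1 = da1 * (h1 > 0)
            _, dw1, db1 = layers[0].backward(dh1, need_dx=False)
            grads = [dw1, db1, dw2, db2, dw3, db3]
            step += 1
            for i, ((ly, attr), g) in enumerate(zip(params, grads)):
                m_t[i] = beta1 * m_t[i] + (1 - beta1) * g
                v_t[i] = beta2 * v_t[i] + (1 - beta2) * g**2
                mhat = m_t[i] / (1 - beta1**step)
                vhat = v_t[i] / (1 - beta2**step)
                val = getattr(ly, attr) - lr_now * mhat / (np.sqrt(vhat) + eps)
                setattr(ly, attr, val.astype(np.float32))
        epoch_losses.append(tot / max(nb, 1))
        if n_val:
            pv = model.forward(x_val, layers=layers)
            val_losses.append(float(np.mean((pv - y_val) ** 2)))

    model.weights = {"w1": layers[0].w, "b1": layers[0].b,
                     "w2": layers[1].w, "b2": layers[1].b,
                     "w3": layers[2].w, "b3": layers[2].b}
    model.norm = dict(pairs.norm)
    model.train_meta = {
        "epochs": epochs, "lr": lr, "batch_size": batch_size, "seed": seed,
        "final_loss": epoch_losses[-1], "epoch_losses": epoch_losses,
        "val_losses": val_losses, "n_pairs": pairs.n_pairs,
    }
    return model


def apply_denoiser(model: DenoiserModel, recon: ReconImage) -> ReconImage:
    """Denoise a whole reconstructed image (full-image convolution).

    The image is normalized with the model's stored percentile window,
    passed through the network in one shot, denormalized, and clamped to
    non-negative magnitudes.
    """
    if not model.train_meta:
        raise ValueError("model has not been trained")
    img = recon.image
    if img.ndim != 2:
        raise ValueError("expected a 2D magnitude image")
    xn, lo, span = _normalize(img, model.norm["plo"], model.norm["phi"])
    out = model.forward(xn[None, None].astype(np.float32))[0, 0]
    result = np.clip(out.astype(np.float64) * span + lo, 0.0, None)
    return ReconImage(image=result, method="dlr", af=recon.af,
                      meta={"denoised_from": recon.method})


def save_model_h5(model: DenoiserModel, path) -> None:
    import h5py
    import json

    with h5py.File(path, "w") as f:
        for k, v in model.weights.items():
            f.create_dataset(k, data=v)
        f.attrs["kernel_sizes"] = model.kernel_sizes
        f.attrs["channels"] = model.channels
        f.attrs["residual"] = model.residual
        f.attrs["norm"] = json.dumps(model.norm)
        f.attrs["train_meta"] = json.dumps(model.train_meta)


def load_model_h5(path) -> DenoiserModel:
    import h5py
    import json

    with h5py.File(path, "r") as f:
        weights = {k: f[k][...] for k in f.keys()}
        return DenoiserModel(
            weights=weights,
            kernel_sizes=tuple(int(v) for v in f.attrs["kernel_sizes"]),
            channels=tuple(int(v) for v in f.attrs["channels"]),
            residual=bool(f.attrs["residual"]),
            norm=json.loads(f.attrs["norm"]),
            train_meta=json.loads(f.attrs["train_meta"]),
        )


__all__ += ["save_model_h5", "load_model_h5"]
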