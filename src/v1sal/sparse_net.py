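"""Spiking sparse-coding network with local plasticity.

A single population of K leaky integrate-and-fire neurons encodes whitened
image patches into non-negative spike counts.  Feedforward weights Q (the
receptive fields), lateral inhibitory weights W and firing thresholds theta
are learned with purely local rules that drive the code toward a target
firing rate while keeping reconstruction error low — on natural-statistics
input the receptive fields converge to localized, oriented (Gabor-like)
filters and the spike-count distributions become sharply peaked at zero
with heavy tails.

Dynamics (per patch, T discrete steps, leak eta):

    u_i(t+1) = (1 - eta) u_i(t) + eta * (Q_i . x - sum_j W_ij s_j(t))

a neuron emits a spike (s_i = 1) and resets u_i to 0 whenever u_i exceeds
theta_i; the code is the vector of total spike counts n_i.

Learning (batch averages, target rate p spikes/patch):

    dW_ij    = alpha * (n_i n_j - p^2)        clipped at W >= 0, zero diagonal
    dQ_i     = beta  * n_i (x - n_i Q_i)
    dtheta_i = gamma * (n_i - p)

The feedforward rule is applied in its preconditioned fixed-point form
Q_i += beta (E[n_i x]/E[n_i^2] - Q_i), which shares the Hebbian rule's
fixed point Q_i = E[n_i x]/E[n_i^2] but remains stable when spike counts
exceed one.  All three rates anneal geometrically per epoch.

The module follows the statsmodels convention: build a
:class:`SparseCodingModel` from a patch matrix, call :meth:`fit`, and get a
:class:`SparseCodingResults` carrying the learned :class:`ReceptiveFieldSet`,
per-epoch diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "TrainingConfig",
    "ReceptiveFieldSet",
    "SparseCodingModel",
    "SparseCodingResults",
    "sample_patches",
    "whiten_patches",
    "apply_whitener",
    "encode_patches",
    "calibrate_thresholds",
    "compute_response_map",
    "reconstruct_patches",
    "reconstruct_image",
]


@dataclass
class TrainingConfig:
    """Network and optimizer settings.

    Defaults: K = 128 neurons on 14x14 patches (196 input dimensions);
    T = 50 integration steps with leak eta = 0.2; target rate p = 0.05
    spikes per patch per neuron — the sparse regime in which most counts
    are zero and the code distributions are zero-peaked and heavy-tailed.
    Learning rates decay by ``lr_decay`` per epoch so the weights settle
    onto their fixed points.
    """

    n_neurons: int = 128
    patch_side: int = 14
    lif_steps: int = 50
    lif_leak: float = 0.2
    target_rate: float = 0.05
    alpha: float = 0.1       # inhibitory learning rate (scaled by 1/p^2 internally)
    beta: float = 0.3        # feedforward learning rate
    gamma: float = 0.05      # threshold learning rate
    lr_decay: float = 0.9    # per-epoch multiplicative annealing
    n_epochs: int = 25
    batch_size: int = 200
    seed: int = 0
    q_bound: float = 100.0   # divergence guard, whitened units

    def __post_init__(self):
        if self.n_neurons < 1 or self.lif_steps < 1:
            raise ValueError("n_neurons and lif_steps must be >= 1")
        if not (0 < self.lif_leak <= 1):
            raise ValueError("lif_leak must lie in (0, 1]")
        for name in ("target_rate", "alpha", "beta", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must lie in (0, 1]")

    @property
    def patch_dim(self) -> int:
        return self.patch_side ** 2


@dataclass
class ReceptiveFieldSet:
    """Learned network parameters plus the whitening transform.

    Q : (K, patch_dim) feedforward weights — rows are receptive fields in
        whitened coordinates.
    W : (K, K) non-negative lateral inhibition, zero diagonal.
    theta : (K,) positive firing thresholds.
    whitener / mean : ZCA transform fitted on the training patches; applied
        to every patch at inference so the code is stationary across inputs.
    gain : least-squares reconstruction gain (see :func:`reconstruct_patches`).
    """

    Q: np.ndarray
    W: np.ndarray
    theta: np.ndarray
    whitener: np.ndarray
    mean: np.ndarray
    config: TrainingConfig
    gain: float = 1.0

    def __post_init__(self):
        K, D = self.Q.shape
        if self.W.shape != (K, K) or self.theta.shape != (K,):
            raise ValueError("inconsistent Q/W/theta shapes")
        if self.whitener.shape != (D, D) or self.mean.shape != (D,):
            raise ValueError("whitener shape does not match patch dimension")

    @property
    def n_neurons(self) -> int:
        return self.Q.shape[0]

    @property
    def patch_dim(self) -> int:
        return self.Q.shape[1]

    def pixel_space_fields(self) -> np.ndarray:
        """Receptive fields mapped back to pixel coordinates, (K, patch_dim)."""
        return self.Q @ np.linalg.pinv(self.whitener).T

    def save(self, path: str | Path) -> None:
        """Persist to a single NPZ container with a versioned schema tag."""
        cfg = asdict(self.config)
        np.savez(
            path,
            Q=self.Q, W=self.W, theta=self.theta,
            whitener_matrix=self.whitener, whitener_mean=self.mean,
            gain=np.float64(self.gain),
            config_json=np.array(json.dumps(cfg)),
            schema=np.array("v1sal-rfset-1"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReceptiveFieldSet":
        with np.load(path, allow_pickle=False) as z:
            if str(z["schema"]) != "v1sal-rfset-1":
                raise ValueError(f"unknown weight-container schema in {path}")
            cfg = TrainingConfig(**json.loads(str(z["config_json"])))
            return cls(
                Q=z["Q"], W=z["W"], theta=z["theta"],
                whitener=z["whitener_matrix"], mean=z["whitener_mean"],
                config=cfg, gain=float(z["gain"]),
            )


# ---------------------------------------------------------------------------
# patch sampling and whitening
# ---------------------------------------------------------------------------

def sample_patches(
    images: list[np.ndarray] | np.ndarray,
    n: int,
    side: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n side*side patches uniformly over images and positions.

    Patches are vectorized row-major into an (n, side**2) matrix.
    """
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images = [images]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for im in images:
        if im.shape[0] < side or im.shape[1] < side:
            raise ValueError(f"image of shape {im.shape} smaller than patch side {side}")
    idx = rng.integers(0, len(images), size=n)
    out = np.empty((n, side * side))
    for j, i in enumerate(idx):
        im = images[i]
        r = rng.integers(0, im.shape[0] - side + 1)
        c = rng.integers(0, im.shape[1] - side + 1)
        out[j] = im[r:r + side, c:c + side].ravel()
    return out


def whiten_patches(
    patches: np.ndarray, eig_floor: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center and ZCA-whiten a patch matrix.

    Eigenvalues below ``eig_floor * max_eigenvalue`` are floored to keep the
    transform bounded on ill-conditioned input.  Returns
    (whitened, whitener_matrix, mean); the stored pair reproduces the
    transform on new data via :func:`apply_whitener`.
    """
    patches = np.asarray(patches, dtype=np.float64)
    n, d = patches.shape
    if n <= d:
        warnings.warn(
            f"only {n} patches for {d} dimensions; covariance estimate is degenerate",
            stacklevel=2,
        )
    mean = patches.mean(axis=0)
    X = patches - mean
    cov = (X.T @ X) / n
    evals, evecs = np.linalg.eigh(cov)
    if evals.max() <= 0:
        raise ValueError("zero-variance patch matrix: cannot whiten")
    evals = np.maximum(evals, eig_floor * evals.max())
    V = (evecs * (1.0 / np.sqrt(evals))) @ evecs.T  # symmetric ZCA matrix
    return X @ V.T, V, mean


def apply_whitener(patches: np.ndarray, whitener: np.ndarray, mean: np.ndarray) -> np.ndarray:
    return (np.asarray(patches, dtype=np.float64) - mean) @ whitener.T


# ---------------------------------------------------------------------------
# LIF encoding
# ---------------------------------------------------------------------------

def encode_patches(
    X: np.ndarray,
    Q: np.ndarray,
    W: np.ndarray,
    theta: np.ndarray,
    T: int,
    eta: float,
) -> np.ndarray:
    """Spike counts for a batch of whitened patches, (n, K) integers.

    Deterministic leaky integrate-and-fire simulation: membrane potentials
    start at 0, inhibition uses the spikes of the previous step, a
    supra-threshold neuron spikes and resets to 0.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    K = Q.shape[0]
    drive = X @ Q.T                      # constant feedforward input, (n, K)
    u = np.zeros((n, K))
    s = np.zeros((n, K))
    counts = np.zeros((n, K), dtype=np.int64)
    for _ in range(T):
        u = (1.0 - eta) * u + eta * (drive - s @ W.T)
        fired = u > theta
        counts += fired
        u[fired] = 0.0
        s = fired.astype(np.float64)
    return counts


def calibrate_thresholds(
    Q: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    target_rate: float,
    T: int,
    eta: float,
) -> np.ndarray:
    """Uniform thresholds bisected so the mean spike count matches a target.

    Used to put an untrained network on the same rate budget as a trained
    one, which makes reconstruction-error comparisons fair.
    """
    K = Q.shape[0]
    lo, hi = 1e-4, 1e4
    for _ in range(50):
        mid = np.sqrt(lo * hi)
        rate = encode_patches(X, Q, W, np.full(K, mid), T, eta).mean()
        if rate > target_rate:
            lo = mid
        else:
            hi = mid
    return np.full(K, np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class SparseCodingModel:
    """Sparse-coding network to be fitted on a whitened patch matrix.

    Parameters
    ----------
    patches : (n, patch_dim) array
        Training patches.  If ``whitened=False`` (default) they are
        ZCA-whitened here and the transform is stored with the results.
    config : TrainingConfig
    """

    def __init__(
        self,
        patches: np.ndarray,
        config: TrainingConfig | None = None,
        whitened: bool = False,
        whitener: np.ndarray | None = None,
        mean: np.ndarray | None = None,
    ):
        self.config = config or TrainingConfig()
        patches = np.asarray(patches, dtype=np.float64)
        if patches.shape[1] != self.config.patch_dim:
            raise ValueError(
                f"patch dimension {patches.shape[1]} != side^2 = {self.config.patch_dim}"
            )
        if whitened:
            if whitener is None or mean is None:
                raise ValueError("whitened=True requires the whitener and mean")
            self.X, self.whitener, self.mean = patches, whitener, mean
        else:
            self.X, self.whitener, self.mean = whiten_patches(patches)

    @classmethod
    def from_images(
        cls,
        images: list[np.ndarray],
        n_patches: int = 50_000,
        config: TrainingConfig | None = None,
    ) -> "SparseCodingModel":
        config = config or TrainingConfig()
        pm = sample_patches(images, n_patches, config.patch_side, seed=config.seed)
        return cls(pm, config)

    def fit(self, verbose: bool = False) -> "SparseCodingResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n, D = self.X.shape
        K, T, eta, p = cfg.n_neurons, cfg.lif_steps, cfg.lif_leak, cfg.target_rate

        Q = rng.standard_normal((K, D))
        Q /= np.linalg.norm(Q, axis=1, keepdims=True)
        W = np.zeros((K, K))
        theta = np.full(K, 1.0)

        rate_log: list[float] = []
        err_log: list[float] = []
        probe_idx = rng.choice(n, size=min(500, n), replace=False)
        probe = self.X[probe_idx]
        unwhiten = np.linalg.pinv(self.whitener)
        probe_pix = probe @ unwhiten.T + self.mean
        probe_norm = np.linalg.norm(probe_pix)

        def probe_error(Q, W, theta):
            """Relative L2 patch-reconstruction error in pixel space.

            The scalar gain is the pixel-space least-squares fit of the
            un-whitened code reconstruction to the centered probe patches.
            """
            counts = encode_patches(probe, Q, W, theta, T, eta).astype(np.float64)
            recon_u = counts @ Q @ unwhiten.T
            centered = probe_pix - self.mean
            den = (recon_u * recon_u).sum()
            g = (recon_u * centered).sum() / den if den > 0 else 1.0
            err = np.linalg.norm(centered - g * recon_u) / probe_norm
            return float(err), g

        # untrained baseline at the same rate budget as the trained network
        theta0 = calibrate_thresholds(Q, W, probe, p, T, eta)
        err_log.append(probe_error(Q, W, theta0)[0])

        for epoch in range(cfg.n_epochs):
            # the W rule is normalized by the target rate so one alpha works
            # across p values; the weight rules anneal per epoch while the
            # threshold rule keeps tracking the target rate at full speed
            decay = cfg.lr_decay ** epoch
            alpha = cfg.alpha / (p * p) * decay
            beta = cfg.beta * decay
            gamma = cfg.gamma
            order = rng.permutation(n)
            spike_sum = 0.0
            for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
                batch = self.X[order[start:start + cfg.batch_size]]
                m = batch.shape[0]
                counts = encode_patches(batch, Q, W, theta, T, eta).astype(np.float64)
                spike_sum += counts.sum()

                W += alpha * ((counts.T @ counts) / m - p * p)
                np.fill_diagonal(W, 0.0)
                np.clip(W, 0.0, None, out=W)

                # Hebbian decay rule beta * n_i (x - n_i Q_i), preconditioned
                # by each neuron's batch second moment E[n_i^2]: the shared
                # fixed point is Q_i = E[n_i x] / E[n_i^2] and the step stays
                # stable when spike counts are well above 1
                m2 = (counts ** 2).mean(axis=0)
                cross = counts.T @ batch / m
                active = m2 > 0
                Q[active] += beta * (
                    cross[active] / m2[active, None] - Q[active]
                )
                theta += gamma * (counts.mean(axis=0) - p)
                np.clip(theta, 1e-6, None, out=theta)

                if np.abs(Q).max() > cfg.q_bound:
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: |Q| exceeded {cfg.q_bound}"
                    )

            n_batches = (n // cfg.batch_size) * cfg.batch_size
            rate_log.append(spike_sum / (n_batches * K))
            err, _ = probe_error(Q, W, theta)
            err_log.append(err)
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.n_epochs}: "
                      f"rate={rate_log[-1]:.3f} (target {p}), rel_err={err:.3f}")

        gain = float(probe_error(Q, W, theta)[1])

        rf = ReceptiveFieldSet(
            Q=Q, W=W, theta=theta,
            whitener=self.whitener, mean=self.mean,
            config=cfg, gain=gain,
        )
        return SparseCodingResults(self, rf, np.asarray(rate_log), np.asarray(err_log))


class SparseCodingResults:
    """Fit output: the receptive-field set plus per-epoch diagnostics.

    ``recon_error_per_epoch`` holds the relative L2 pixel-space patch
    reconstruction error on a fixed probe set, with the untrained network's
    error as its first entry followed by one entry per epoch
    (length n_epochs + 1).  ``mean_rate_per_epoch`` has one entry per epoch.
    """

    def __init__(
        self,
        model: SparseCodingModel,
        receptive_fields: ReceptiveFieldSet,
        mean_rate_per_epoch: np.ndarray,
        recon_error_per_epoch: np.ndarray,
    ):
        self.model = model
        self.receptive_fields = receptive_fields
        self.mean_rate_per_epoch = mean_rate_per_epoch
        self.recon_error_per_epoch = recon_error_per_epoch

    @property
    def final_rate(self) -> float:
        return float(self.mean_rate_per_epoch[-1])

    @property
    def final_recon_error(self) -> float:
        return float(self.recon_error_per_epoch[-1])

    def encode(self, patches: np.ndarray, whitened: bool = False) -> np.ndarray:
        rf = self.receptive_fields
        cfg = rf.config
        X = patches if whitened else apply_whitener(patches, rf.whitener, rf.mean)
        return encode_patches(X, rf.Q, rf.W, rf.theta, cfg.lif_steps, cfg.lif_leak)

    def summary(self) -> str:
        rf = self.receptive_fields
        cfg = rf.config
        buf = io.StringIO()
        w = buf.write
        w("Sparse-coding network fit\n")
        w("=" * 54 + "\n")
        rows = [
            ("neurons (K)", cfg.n_neurons),
            ("patch side / dim", f"{cfg.patch_side} / {cfg.patch_dim}"),
            ("LIF steps / leak", f"{cfg.lif_steps} / {cfg.lif_leak}"),
            ("target rate p (spikes/patch)", cfg.target_rate),
            ("epochs x batch", f"{cfg.n_epochs} x {cfg.batch_size}"),
            ("final mean rate", f"{self.final_rate:.4f}"),
            ("final rel. recon error", f"{self.final_recon_error:.4f}"),
            ("reconstruction gain", f"{rf.gain:.4f}"),
            ("mean threshold", f"{rf.theta.mean():.4f}"),
            ("mean lateral weight", f"{rf.W.mean():.5f}"),
        ]
        for k, v in rows:
            w(f"{k:<34}{v}\n")
        return buf.getvalue()


# ---------------------------------------------------------------------------
# whole-image responses and reconstruction
# ---------------------------------------------------------------------------

def _extract_patch_grid(
    channel: np.ndarray, side: int, stride: int
) -> tuple[np.ndarray, int, int]:
    """All side*side patches centered on a stride-subsampled pixel grid.

    Borders are reflect-padded so every pixel owns a full patch.
    """
    lo = side // 2
    hi = side - 1 - lo
    padded = np.pad(channel, ((lo, hi), (lo, hi)), mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (side, side))
    grid = windows[::stride, ::stride]
    gh, gw = grid.shape[:2]
    return grid.reshape(gh * gw, side * side), gh, gw


def compute_response_map(
    channel: np.ndarray,
    rf: ReceptiveFieldSet,
    stride: int = 1,
) -> np.ndarray:
    """Per-pixel spike-count responses of a single-channel image.

    Returns an integer array of shape (gh, gw, K) where (gh, gw) is the
    stride-subsampled pixel grid (the full image size when stride = 1).
    The patch centered at each grid pixel is whitened with the training
    whitener and encoded by the network.
    """
    cfg = rf.config
    patches, gh, gw = _extract_patch_grid(channel, cfg.patch_side, stride)
    X = apply_whitener(patches, rf.whitener, rf.mean)
    counts = encode_patches(X, rf.Q, rf.W, rf.theta, cfg.lif_steps, cfg.lif_leak)
    return counts.reshape(gh, gw, rf.n_neurons)


def reconstruct_patches(responses: np.ndarray, rf: ReceptiveFieldSet) -> np.ndarray:
    """Pixel-space patch estimates from spike counts: gain * n @ Q, un-whitened."""
    responses = np.atleast_2d(np.asarray(responses, dtype=np.float64))
    if responses.shape[-1] != rf.n_neurons:
        raise ValueError(
            f"response dimension {responses.shape[-1]} != K = {rf.n_neurons}"
        )
    recon_white = rf.gain * responses @ rf.Q
    return recon_white @ np.linalg.pinv(rf.whitener).T + rf.mean


def reconstruct_image(response_map: np.ndarray, rf: ReceptiveFieldSet) -> np.ndarray:
    """Overlap-average of per-pixel reconstructed patches (stride-1 maps)."""
    gh, gw, K = response_map.shape
    side = rf.config.patch_side
    lo = side // 2
    patches = reconstruct_patches(response_map.reshape(gh * gw, K), rf)
    acc = np.zeros((gh + side - 1, gw + side - 1))
    wgt = np.zeros_like(acc)
    tiles = patches.reshape(gh, gw, side, side)
    for dr in range(side):
        for dc in range(side):
            acc[dr:dr + gh, dc:dc + gw] += tiles[:, :, dr, dc]
            wgt[dr:dr + gh, dc:dc + gw] += 1.0
    out = acc / wgt
    return out[lo:lo + gh, lo:lo + gw]
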