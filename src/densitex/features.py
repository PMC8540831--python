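"""Feature fusion and dimensionality reduction (PCA, autoencoder).

The fused descriptor concatenates a 100-bin multifractal alpha-histogram
with the 512-length multi-resolution LBP histogram into a 612-length
vector.  Redundancy in the fused space is removed either by principal
component analysis (eigendecomposition of the sample covariance matrix,
M−1 denominator, top-n projection) or by the bottleneck code of an
hourglass autoencoder.

The autoencoder is a fully connected network with an odd number of hidden
layers, ReLU activations on hidden layers and a sigmoid output, trained
with binary cross entropy and Adam on features min-max scaled to [0, 1];
the middle (code) layer provides the reduced representation.  It is
implemented directly on numpy arrays with explicit backpropagation so
training is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidSpecError


def concatenate_descriptors(*blocks: np.ndarray) -> np.ndarray:
    """Fuse descriptor blocks (multifractal first, then LBP) bit-exactly."""
    arrays = [np.asarray(b, dtype=np.float64).ravel() for b in blocks]
    if len(arrays) < 2:
        raise InvalidInputError("at least two blocks required for fusion")
    if any(a.size == 0 for a in arrays):
        raise InvalidInputError("empty descriptor block")
    return np.concatenate(arrays)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    means: np.ndarray  # per-feature means
    covariance: np.ndarray  # N×N sample covariance (M−1 denominator)
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # eigenvectors in columns, matching order


def fit_pca(X: np.ndarray) -> PCAModel:
    """Eigendecomposition of the sample covariance with deterministic signs.

    Eigenvectors are sorted by descending eigenvalue; each eigenvector's
    largest-magnitude entry is made positive so repeated fits agree.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("PCA needs a 2-D matrix with at least 2 samples")
    means = X.mean(axis=0)
    centered = X - means
    cov = centered.T @ centered / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return PCAModel(means=means, covariance=cov, eigenvalues=eigvals,
                    components=eigvecs)


def project_pca(model: PCAModel, X: np.ndarray, n: int) -> np.ndarray:
    """Project mean-centered samples onto the first n principal axes."""
    X = np.asarray(X, dtype=np.float64)
    N = model.components.shape[0]
    if not 1 <= n <= N:
        raise InvalidInputError(f"component count {n} outside [1, {N}]")
    return (X - model.means) @ model.components[:, :n]


def backproject_pca(model: PCAModel, Z: np.ndarray) -> np.ndarray:
    """Map projected samples back to the centered original space."""
    n = Z.shape[1]
    return np.asarray(Z) @ model.components[:, :n].T


# ---------------------------------------------------------------------------
# Autoencoder
# ---------------------------------------------------------------------------

ALLOWED_HIDDEN_LAYERS = (5, 7, 9, 11, 13, 15)
ALLOWED_CODE_DIMS = (16, 32, 64, 128)


@dataclass(frozen=True)
class AutoencoderSpec:
    """Hourglass architecture and training hyperparameters.

    ``layer_widths`` (hidden layers only) defaults to a geometric
    interpolation from the input width down to the code width, mirrored on
    the decoder side.
    """

    input_dim: int
    n_hidden_layers: int = 11
    code_dim: int = 64
    layer_widths: tuple[int, ...] | None = None
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise InvalidSpecError("input_dim must be positive")
        if self.n_hidden_layers not in ALLOWED_HIDDEN_LAYERS:
            raise InvalidSpecError(
                f"n_hidden_layers must be one of {ALLOWED_HIDDEN_LAYERS}")
        if self.code_dim not in ALLOWED_CODE_DIMS:
            raise InvalidSpecError(f"code_dim must be one of {ALLOWED_CODE_DIMS}")
        if self.code_dim >= self.input_dim:
            raise InvalidSpecError("code_dim must be smaller than input_dim")
        widths = self.layer_widths or self._default_widths()
        m = self.n_hidden_layers // 2
        if len(widths) != self.n_hidden_layers:
            raise InvalidSpecError("layer_widths length must equal n_hidden_layers")
        if widths[m] != self.code_dim:
            raise InvalidSpecError("middle hidden layer must equal code_dim")
        if widths != tuple(reversed(widths)):
            raise InvalidSpecError("layer widths must be symmetric about the code")
        if any(widths[i] <= widths[i + 1] for i in range(m)):
            raise InvalidSpecError("widths must strictly decrease to the code")
        object.__setattr__(self, "layer_widths", widths)

    def _default_widths(self) -> tuple[int, ...]:
        m = self.n_hidden_layers // 2 + 1  # encoder hidden layers incl. code
        enc = []
        for j in range(1, m + 1):
            t = j / m
            width = round(self.input_dim ** (1 - t) * self.code_dim ** t)
            enc.append(int(width))
        # enforce strict decrease after rounding
        prev = self.input_dim
        for i, wdt in enumerate(enc):
            enc[i] = min(wdt, prev - 1)
            prev = enc[i]
        enc[-1] = self.code_dim
        return tuple(enc + enc[:-1][::-1])

    @property
    def all_widths(self) -> tuple[int, ...]:
        """Input, hidden, and output layer widths."""
        return (self.input_dim, *self.layer_widths, self.input_dim)

    @property
    def parameter_count(self) -> int:
        widths = self.all_widths
        return sum(widths[i] * widths[i + 1] + widths[i + 1]
                   for i in range(len(widths) - 1))


@dataclass
class Autoencoder:
    spec: AutoencoderSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_history: list[float] = field(default_factory=list)

    @property
    def code_layer_index(self) -> int:
        return self.spec.n_hidden_layers // 2 + 1  # after that many affine maps

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations of every layer (input first, sigmoid output last)."""
        acts = [X]
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ W + b
            if i == n_layers - 1:
                acts.append(1.0 / (1.0 + np.exp(-z)))
            else:
                acts.append(np.maximum(z, 0.0))
        return acts

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Code-layer activations for min-max scaled inputs."""
        X = np.asarray(X, dtype=np.float64)
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("non-finite inputs")
        return self._forward(X)[self.code_layer_index]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=np.float64))[-1]


def build_autoencoder(spec: AutoencoderSpec) -> Autoencoder:
    """He-initialized hourglass network; deterministic per ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    widths = spec.all_widths
    weights, biases = [], []
    for i in range(len(widths) - 1):
        scale = np.sqrt(2.0 / widths[i])
        weights.append(rng.normal(0.0, scale, size=(widths[i], widths[i + 1])))
        biases.append(np.zeros(widths[i + 1]))
    return Autoencoder(spec=spec, weights=weights, biases=biases)


def minmax_scale(X: np.ndarray, lo: np.ndarray | None = None,
                 hi: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature min-max scaling to [0, 1] (constant features map to 0)."""
    X = np.asarray(X, dtype=np.float64)
    if lo is None:
        lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.clip((X - lo) / span, 0.0, 1.0), lo, hi


def train_autoencoder(X: np.ndarray, spec: AutoencoderSpec) -> Autoencoder:
    """Train with Adam on binary cross entropy; deterministic per seed.

    ``X`` must already be min-max scaled to [0, 1] per feature (binary
    cross entropy requires targets in the unit interval).
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("non-finite inputs")
    if X.min() < 0 or X.max() > 1:
        raise InvalidInputError("inputs must be min-max scaled to [0, 1]")
    ae = build_autoencoder(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n_params = len(ae.weights)
    mW = [np.zeros_like(w) for w in ae.weights]
    vW = [np.zeros_like(w) for w in ae.weights]
    mb = [np.zeros_like(b) for b in ae.biases]
    vb = [np.zeros_like(b) for b in ae.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    M = X.shape[0]
    batch = min(spec.batch_size, M)

    for _ in range(spec.epochs):
        order = rng.permutation(M)
        epoch_loss = 0.0
        for start in range(0, M, batch):
            idx = order[start:start + batch]
            xb = X[idx]
            acts = ae._forward(xb)
            out = np.clip(acts[-1], 1e-12, 1 - 1e-12)
            loss = -np.mean(xb * np.log(out) + (1 - xb) * np.log(1 - out))
            epoch_loss += loss * len(idx)
            # BCE + sigmoid output: delta at the output pre-activation
            delta = (acts[-1] - xb) / (len(idx) * xb.shape[1])
            for i in range(n_params - 1, -1, -1):
                gW = acts[i].T @ delta
                gb = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ ae.weights[i].T) * (acts[i] > 0)
                step_i = step + 1
                for g, m, v, param in ((gW, mW[i], vW[i], ae.weights[i]),
                                       (gb, mb[i], vb[i], ae.biases[i])):
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g**2
                    m_hat = m / (1 - beta1**step_i)
                    v_hat = v / (1 - beta2**step_i)
                    param -= spec.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            step += 1
        ae.loss_history.append(epoch_loss / M)
    return ae
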