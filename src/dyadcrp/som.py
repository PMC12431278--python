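"""Self-organizing-map feature extraction from recurrence-plot images.

A 4×4 SOM is trained on the flattened plot images; each image is then
summarized by its *activity vector* — the 16 Euclidean distances from the
image to the trained weight vectors, in row-major neuron order.  These 16
distances are the predictors of the downstream stress regression.

Training is the classic online algorithm: per step the best-matching unit
(BMU, nearest neuron) is found and every weight moves toward the input,
scaled by a Gaussian neighborhood of the BMU on the map grid.  Learning
rate and neighborhood radius decay linearly over epochs.  Training is
restarted ``n_restarts`` times from consecutive seeds and the restart with
the lowest quantization error (mean distance to BMU) is kept.

``SOMFeatureExtractor`` follows the scikit-learn estimator contract
(``fit``/``transform``, ``get_params``/``set_params``, fitted attributes
with trailing underscores) and composes with sklearn pipelines.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .recurrence import RecurrenceImage

__all__ = ["SOMFeatureExtractor", "train_som", "activity_vector"]


def _as_matrix(images: Sequence[RecurrenceImage] | np.ndarray) -> np.ndarray:
    if isinstance(images, np.ndarray):
        X = np.asarray(images, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return X
    X = np.array([im.flat for im in images], dtype=float)
    return X


class SOMFeatureExtractor(TransformerMixin, BaseEstimator):
    """4×4 self-organizing map turning plot images into 16-distance vectors.

    Parameters
    ----------
    rows, cols : int
        Map grid shape (rectangular topology). Default 4×4 = 16 neurons.
    n_epochs : int
        Passes over the training set per restart. Default 2000.
    learning_rate_init, learning_rate_final : float
        Linear epoch-wise decay of the update step size.
    radius_init, radius_final : float
        Linear decay of the Gaussian neighborhood radius (map-grid units).
    n_restarts : int
        Independent trainings from seed, seed+1, …; the restart with the
        lowest quantization error is kept. Default 25.
    init : {"sample", "uniform"}
        Initial prototypes: draws from the training images (default; keeps
        prototypes on the data manifold, no dead units in high dimension)
        or uniform random in [0, 1] per dimension.
    random_state : int
        Base seed; identical seed and data give identical weights.

    Attributes
    ----------
    weights_ : ndarray of shape (rows*cols, n_features)
        Trained weight vectors, row-major neuron order.
    grid_ : ndarray of shape (rows*cols, 2)
        (row, col) map coordinate of each neuron.
    quantization_error_ : float
        Mean distance of the training images to their BMUs.
    restart_errors_ : ndarray of shape (n_restarts,)
        Quantization error of every restart (the kept one is the minimum).
    """

    def __init__(
        self,
        rows: int = 4,
        cols: int = 4,
        n_epochs: int = 100,
        learning_rate_init: float = 0.5,
        learning_rate_final: float = 0.01,
        radius_init: float = 2.0,
        radius_final: float = 0.5,
        n_restarts: int = 25,
        init: str = "sample",
        random_state: int = 0,
    ):
        self.rows = rows
        self.cols = cols
        self.n_epochs = n_epochs
        self.learning_rate_init = learning_rate_init
        self.learning_rate_final = learning_rate_final
        self.radius_init = radius_init
        self.radius_final = radius_final
        self.n_restarts = n_restarts
        self.init = init
        self.random_state = random_state

    # -- training ----------------------------------------------------------

    def _grid(self) -> np.ndarray:
        r, c = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.column_stack([r.ravel(), c.ravel()]).astype(float)

    def _train_once(self, X: np.ndarray, seed: int) -> tuple[np.ndarray, float]:
        rng = np.random.default_rng(seed)
        n, d = X.shape
        k = self.rows * self.cols
        grid = self._grid()
        # pairwise squared map-grid distances between neurons
        gdist2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
        if self.init == "sample":
            weights = X[rng.choice(n, size=k, replace=(n < k))].copy()
        elif self.init == "uniform":
            weights = rng.uniform(0.0, 1.0, size=(k, d))
        else:
            raise ValueError(f"unknown init {self.init!r}")
        for epoch in range(self.n_epochs):
            frac = epoch / max(self.n_epochs - 1, 1)
            alpha = self.learning_rate_init + frac * (
                self.learning_rate_final - self.learning_rate_init
            )
            radius = self.radius_init + frac * (self.radius_final - self.radius_init)
            order = rng.permutation(n)
            for i in order:
                x = X[i]
                diff = x[None, :] - weights
                bmu = int(np.argmin((diff**2).sum(1)))
                h = np.exp(-gdist2[bmu] / (2 * radius**2))
                weights += (alpha * h)[:, None] * diff
        qe = self._quantization_error(weights, X)
        return weights, qe

    @staticmethod
    def _quantization_error(weights: np.ndarray, X: np.ndarray) -> float:
        d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.min(axis=1)).mean())

    def fit(self, X, y=None):
        """Train the map; X is a list of RecurrenceImage or an (n, d) array."""
        X = _as_matrix(X)
        if X.shape[0] < 1:
            raise ValueError("need at least one training image")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        best_w, errors = None, []
        for r in range(self.n_restarts):
            w, qe = self._train_once(X, self.random_state + r)
            errors.append(qe)
            if best_w is None or qe < min(errors[:-1], default=np.inf):
                best_w = w
        self.weights_ = best_w
        self.grid_ = self._grid().astype(int)
        self.restart_errors_ = np.array(errors)
        self.quantization_error_ = float(self.restart_errors_.min())
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference ---------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Activity vectors: (n, 16) Euclidean distances to each neuron's weights."""
        check_is_fitted(self, "weights_")
        X = _as_matrix(X)
        if X.shape[1] != self.weights_.shape[1]:
            raise ValueError(
                f"image dimension {X.shape[1]} != weight dimension {self.weights_.shape[1]}"
            )
        d2 = ((X[:, None, :] - self.weights_[None, :, :]) ** 2).sum(-1)
        return np.sqrt(d2)

    def save(self, path) -> None:
        """Persist the trained map: a '#'-prefixed config header, then one
        CSV row of weights per neuron (row-major)."""
        check_is_fitted(self, "weights_")
        import json

        header = json.dumps({**self.get_params(),
                             "quantization_error": self.quantization_error_})
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            for w in self.weights_:
                fh.write(",".join(f"{v:.17g}" for v in w) + "\n")

    @classmethod
    def load(cls, path) -> "SOMFeatureExtractor":
        import json

        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("# "))
            weights = np.array(
                [[float(v) for v in line.split(",")] for line in fh if line.strip()]
            )
        qe = header.pop("quantization_error")
        model = cls(**header)
        model.weights_ = weights
        model.grid_ = model._grid().astype(int)
        model.quantization_error_ = qe
        model.n_features_in_ = weights.shape[1]
        return model

    def quantization_error(self, X) -> float:
        """Mean over images of the distance to the best-matching unit."""
        return float(self.transform(X).min(axis=1).mean())

    def map_layout(self, X) -> np.ndarray:
        """(row, col) BMU grid position per image; ties broken by lowest index."""
        d = self.transform(X)
        bmu = d.argmin(axis=1)  # argmin takes the first minimum
        return self.grid_[bmu]


def train_som(images, **params) -> SOMFeatureExtractor:
    """Functional wrapper: fit a :class:`SOMFeatureExtractor` on the images."""
    return SOMFeatureExtractor(**params).fit(images)


def activity_vector(model: SOMFeatureExtractor, image) -> np.ndarray:
    """The 16 distances d1..d16 from one image to the trained neuron weights."""
    if isinstance(image, RecurrenceImage):
        image = image.flat
    return model.transform(np.asarray(image, dtype=float)[None, :])[0]
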