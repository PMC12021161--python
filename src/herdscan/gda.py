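"""Gaussian discriminant analysis of infrastructure distance and feature fusion.

Active settlements sit closer to roads and waterways than other points, and
the class-conditional distributions of the nearest-infrastructure distance D
differ strongly.  We model, per infrastructure kind,

    y ~ Bernoulli(xi)
    D | y = 0 ~ N(mu0, var0)
    D | y = 1 ~ N(mu1, var1)

fit by maximum likelihood on a held-out subset of the training data, and turn
each tile's distance into auxiliary features: the two class-conditional
densities and the Bayes posterior P(y=1 | d).  These features are fused into
the image classifier at the embedding level (aux2), the logit level (aux1),
or both (aux12).  A raw-distance mode (min-max normalized distance, no GDA)
supports the ablation of the GDA preprocessing itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

VARIANCE_FLOOR = 1.0  # m^2; the MLE is degenerate at zero variance

AUX_MODES = ("gda", "raw_distance")
FUSION_STRATEGIES = ("none", "aux1", "aux2", "aux12")


@dataclass
class GDAClassModel:
    """Fitted univariate GDA for one infrastructure kind.

    ``xi`` is the prevalence of active settlements in the fitting subset;
    ``mu0/var0`` describe negatives, ``mu1/var1`` actives, in meters / m^2.
    """

    xi: float
    mu0: float
    mu1: float
    var0: float
    var1: float
    infra_kind: str
    n0: int
    n1: int

    def __post_init__(self) -> None:
        if not (0.0 < self.xi < 1.0):
            raise ValueError(f"xi must lie in (0, 1), got {self.xi}")
        if self.var0 < VARIANCE_FLOOR or self.var1 < VARIANCE_FLOOR:
            raise ValueError("variances below the floor; fit via fit_gda")
        if self.n0 < 2 or self.n1 < 2:
            raise ValueError("each class needs >= 2 fitting samples")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GDAClassModel":
        return cls(**json.loads(Path(path).read_text()))


def fit_gda(distances, labels, infra_kind: str) -> GDAClassModel:
    """Maximum-likelihood fit of the class-conditional Gaussians and prior.

    Class means are sample means; variances are the MLE (divide by n_c),
    floored at 1 m^2; xi is the fraction of label-1 samples.  Both classes
    must contribute at least two samples.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(labels)
    if d.shape != y.shape:
        raise ValueError("distances and labels must have equal length")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n0 + n1 != len(y):
        raise ValueError("labels must be binary 0/1")
    if n0 < 2 or n1 < 2:
        raise ValueError(f"need >= 2 samples per class, got n0={n0}, n1={n1}")
    d0, d1 = d[y == 0], d[y == 1]
    return GDAClassModel(
        xi=n1 / (n0 + n1),
        mu0=float(d0.mean()), mu1=float(d1.mean()),
        var0=float(max(d0.var(), VARIANCE_FLOOR)),
        var1=float(max(d1.var(), VARIANCE_FLOOR)),
        infra_kind=infra_kind, n0=n0, n1=n1)


def _log_density(d: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi * var) - 0.5 * (d - mu) ** 2 / var


def class_density(model: GDAClassModel, d, label: int) -> np.ndarray:
    """Gaussian density p(d | y=label) under the fitted model."""
    d = np.asarray(d, dtype=float)
    mu, var = (model.mu1, model.var1) if label == 1 else (model.mu0, model.var0)
    return np.exp(_log_density(d, mu, var))


def posterior_probability(model: GDAClassModel, d) -> np.ndarray | float:
    """Bayes posterior P(y=1 | d) = p(d|1) xi / (p(d|0)(1-xi) + p(d|1) xi).

    Evaluated through the log-density difference and the logistic function for
    numerical stability far in the tails.
    """
    darr = np.asarray(d, dtype=float)
    log_ratio = (_log_density(darr, model.mu1, model.var1)
                 - _log_density(darr, model.mu0, model.var0)
                 + np.log(model.xi) - np.log1p(-model.xi))
    post = expit(log_ratio)
    return float(post) if np.isscalar(d) or darr.ndim == 0 else post


@dataclass
class AuxFeatureVector:
    """Auxiliary features for one tile, in a fixed, documented ordering.

    gda mode: per requested kind, (p(d|y=0), p(d|y=1), P(y=1|d)) — length 3k.
    raw_distance mode: per kind, the min-max-normalized distance — length k.
    Kinds appear in the order requested.
    """

    values: np.ndarray
    kinds: tuple[str, ...]
    mode: str

    def __len__(self) -> int:
        return len(self.values)


def build_aux_features(models: dict[str, GDAClassModel] | None,
                       distances: dict[str, float],
                       kinds: tuple[str, ...] | list[str],
                       mode: str = "gda",
                       ranges: dict[str, tuple[float, float]] | None = None,
                       ) -> AuxFeatureVector:
    """Assemble the auxiliary feature vector for one tile.

    ``distances`` maps infrastructure kind to the tile's nearest distance.
    In ``gda`` mode a fitted model per requested kind is required; in
    ``raw_distance`` mode ``ranges[kind] = (min, max)`` supplies the min-max
    normalization bounds (fit on training data).
    """
    if mode not in AUX_MODES:
        raise ValueError(f"unknown aux mode {mode!r}")
    vals: list[float] = []
    for kind in kinds:
        if kind not in distances:
            raise KeyError(f"no distance provided for kind {kind!r}")
        d = float(distances[kind])
        if mode == "gda":
            if not models or kind not in models:
                raise KeyError(f"no fitted GDA model for kind {kind!r}")
            m = models[kind]
            vals.extend([float(class_density(m, d, 0)),
                         float(class_density(m, d, 1)),
                         float(posterior_probability(m, d))])
        else:
            if not ranges or kind not in ranges:
                raise KeyError(f"no normalization range for kind {kind!r}")
            lo, hi = ranges[kind]
            span = hi - lo if hi > lo else 1.0
            vals.append(float(np.clip((d - lo) / span, 0.0, 1.0)))
    return AuxFeatureVector(np.asarray(vals, dtype=np.float64),
                            tuple(kinds), mode)


def build_aux_matrix(models: dict[str, GDAClassModel] | None,
                     distance_df, kinds, mode: str = "gda",
                     ranges=None) -> np.ndarray:
    """Vectorized build_aux_features over a distance-record DataFrame."""
    cols = []
    for kind in kinds:
        d = distance_df[f"d_{kind}_m"].to_numpy(dtype=float)
        if mode == "gda":
            m = models[kind]
            cols.extend([class_density(m, d, 0), class_density(m, d, 1),
                         posterior_probability(m, d)])
        else:
            lo, hi = ranges[kind]
            span = hi - lo if hi > lo else 1.0
            cols.append(np.clip((d - lo) / span, 0.0, 1.0))
    return np.stack(cols, axis=1)


@dataclass(frozen=True)
class FusionSpec:
    """Wiring of auxiliary features into the classifier head.

    aux2 concatenates the k auxiliary features to the global-average-pooled
    embedding z (head input d+k); aux1 concatenates them to the pre-sigmoid
    class logit and maps through a learned linear combiner back to a scalar
    logit; aux12 applies both insertion points simultaneously.
    """

    strategy: str
    embed_dim: int
    aux_dim: int

    def __post_init__(self) -> None:
        if self.strategy not in FUSION_STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        if self.strategy != "none" and self.aux_dim <= 0:
            raise ValueError(f"strategy {self.strategy!r} requires aux_dim > 0")

    @property
    def head_input_dim(self) -> int:
        return self.embed_dim + (self.aux_dim if self.strategy in ("aux2", "aux12") else 0)

    @property
    def combiner_input_dim(self) -> int:
        """1 + aux_dim when a logit-level combiner exists, else 0."""
        return 1 + self.aux_dim if self.strategy in ("aux1", "aux12") else 0

    @property
    def uses_aux(self) -> bool:
        return self.strategy != "none"


def fuse(strategy: str, embed_dim: int, aux_dim: int) -> FusionSpec:
    """Head-input specification for a fusion strategy; see FusionSpec."""
    return FusionSpec(strategy, embed_dim, aux_dim if strategy != "none" else 0)
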