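"""Naive Bayes classification, written from first principles.

Two model kinds share the MAP/ML machinery:

* ``bernoulli`` — binary descriptors (BOSH bits).  Conditional probabilities
  use the m-estimate,  P(x_i = 1 | w_j) = (n_c + m_weight * alpha) /
  (n + m_weight)  with alpha = 1/t and t = 2 for binary features, so no
  parameter can reach 0 or 1 and every log-likelihood stays finite.
* ``gaussian`` — continuous descriptors (baseline HOG).  Per-class,
  per-feature mean and population variance (floored to keep densities
  proper).

Priors are class frequencies.  The MAP rule picks
argmax_j [log P(w_j) + sum_i log P(x_i | w_j)]; the ML rule is the same with
a uniform prior.  All probability arithmetic is in log space — at thousands
of features the literal product form underflows.  Ties break to the lowest
class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import FitError, NotFittedError, ParameterError

MODEL_MAGIC = "NBMODEL"
MODEL_VERSION = 1


@dataclass
class NBModel:
    kind: str  # "bernoulli" | "gaussian"
    classes: list  # ordered labels; index order is the tie-break order
    priors: np.ndarray  # (n_classes,), sums to 1
    n_features: int
    # bernoulli
    p1: np.ndarray | None = None  # (n_classes, n_features) = P(x_i=1 | w_j)
    m_weight: float = 2.0
    t: int = 2
    # gaussian
    mu: np.ndarray | None = None
    var: np.ndarray | None = None
    var_floor: float = 1e-9
    # optional descriptor-layout metadata for compatibility checks
    layout: dict | None = None

    def parameter_count(self) -> int:
        """m*N conditional parameters plus (m-1) free prior parameters."""
        cond = self.p1.size if self.kind == "bernoulli" else self.mu.size
        return cond + (len(self.classes) - 1)


@dataclass(frozen=True)
class Prediction:
    label: object
    log_scores: np.ndarray  # per-class unnormalized log posterior
    posterior: np.ndarray  # normalized, sums to 1


def _class_partition(y: Sequence) -> tuple[list, list[np.ndarray]]:
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise FitError(f"need at least 2 classes, got {classes}")
    return classes, [np.flatnonzero(y == c) for c in classes]


def fit_bernoulli_nb(X: np.ndarray, y: Sequence, m_weight: float = 2.0) -> NBModel:
    """Fit an m-estimate-smoothed Bernoulli model to binary feature rows."""
    X = np.asarray(X)
    if m_weight < 1:
        raise ParameterError(f"m_weight must be >= 1, got {m_weight}")
    if not np.isin(X, (0, 1)).all():
        raise TypeError("bernoulli model requires binary features")
    X = X.astype(np.float64)
    classes, idx = _class_partition(y)
    t = 2
    alpha = 1.0 / t
    p1 = np.empty((len(classes), X.shape[1]))
    priors = np.empty(len(classes))
    for j, rows in enumerate(idx):
        n = len(rows)
        if n < 1:
            raise FitError(f"class {classes[j]} has no samples")
        n_c = X[rows].sum(axis=0)
        p1[j] = (n_c + m_weight * alpha) / (n + m_weight)
        priors[j] = n
    priors /= priors.sum()
    return NBModel(kind="bernoulli", classes=classes, priors=priors,
                   n_features=X.shape[1], p1=p1, m_weight=m_weight, t=t)


def fit_gaussian_nb(X: np.ndarray, y: Sequence, var_floor: float = 1e-9) -> NBModel:
    """Fit per-class Gaussian class-conditionals (population variance)."""
    X = np.asarray(X, dtype=np.float64)
    classes, idx = _class_partition(y)
    mu = np.empty((len(classes), X.shape[1]))
    var = np.empty_like(mu)
    priors = np.empty(len(classes))
    for j, rows in enumerate(idx):
        if len(rows) < 2:
            raise FitError(f"class {classes[j]} needs >= 2 samples, got {len(rows)}")
        mu[j] = X[rows].mean(axis=0)
        var[j] = np.maximum(X[rows].var(axis=0), var_floor)
        priors[j] = len(rows)
    priors /= priors.sum()
    return NBModel(kind="gaussian", classes=classes, priors=priors,
                   n_features=X.shape[1], mu=mu, var=var, var_floor=var_floor)


def _check_x(model: NBModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != model.n_features:
        raise ParameterError(f"expected {model.n_features} features, got {x.shape[1]}")
    return x


def log_likelihood_matrix(model: NBModel, X: np.ndarray) -> np.ndarray:
    """(n_samples, n_classes) matrix of sum_i log P(x_i | w_j)."""
    X = _check_x(model, X)
    if model.kind == "bernoulli":
        if model.p1 is None:
            raise NotFittedError("model has no bernoulli parameters")
        log_p1 = np.log(model.p1)
        log_p0 = np.log1p(-model.p1)
        return X @ log_p1.T + (1.0 - X) @ log_p0.T
    if model.kind == "gaussian":
        if model.mu is None or model.var is None:
            raise NotFittedError("model has no gaussian parameters")
        out = np.empty((X.shape[0], len(model.classes)))
        for j in range(len(model.classes)):
            z = (X - model.mu[j]) ** 2 / model.var[j]
            out[:, j] = -0.5 * (np.log(2.0 * np.pi * model.var[j]) + z).sum(axis=1)
        return out
    raise ParameterError(f"unknown model kind {model.kind!r}")


def log_likelihood(model: NBModel, x: np.ndarray, class_j: int) -> float:
    """Log class-conditional likelihood of one sample under class ``class_j``."""
    return float(log_likelihood_matrix(model, x)[0, class_j])


def _predict(model: NBModel, x: np.ndarray, log_prior: np.ndarray) -> Prediction:
    scores = log_likelihood_matrix(model, x)[0] + log_prior
    posterior = np.exp(scores - logsumexp(scores))
    posterior /= posterior.sum()
    return Prediction(label=model.classes[int(np.argmax(scores))],
                      log_scores=scores, posterior=posterior)


def predict_map(model: NBModel, x: np.ndarray) -> Prediction:
    """Maximum-a-posteriori prediction (frequency priors)."""
    return _predict(model, x, np.log(model.priors))


def predict_ml(model: NBModel, x: np.ndarray) -> Prediction:
    """Maximum-likelihood prediction (uniform prior)."""
    return _predict(model, x, np.zeros(len(model.classes)))


def predict_map_batch(model: NBModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized MAP labels and posteriors for many samples."""
    scores = log_likelihood_matrix(model, X) + np.log(model.priors)
    posts = np.exp(scores - logsumexp(scores, axis=1, keepdims=True))
    posts /= posts.sum(axis=1, keepdims=True)
    labels = np.asarray(model.classes, dtype=object)[np.argmax(scores, axis=1)]
    return labels, posts


# ---------------------------------------------------------------------------
# model container (plain text, full double precision via repr round-trip)

def _fmt_row(row: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in row)


def save_model(path: str | Path, model: NBModel) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{MODEL_MAGIC} {MODEL_VERSION}\n")
        fh.write(f"kind {model.kind}\n")
        fh.write("classes " + " ".join(str(c) for c in model.classes) + "\n")
        fh.write(f"n_features {model.n_features}\n")
        fh.write(f"m_weight {model.m_weight!r}\n")
        fh.write(f"t {model.t}\n")
        fh.write(f"var_floor {model.var_floor!r}\n")
        fh.write("layout " + json.dumps(model.layout) + "\n")
        fh.write("priors " + _fmt_row(model.priors) + "\n")
        if model.kind == "bernoulli":
            for j in range(len(model.classes)):
                fh.write(f"p1 {j} " + _fmt_row(model.p1[j]) + "\n")
        else:
            for j in range(len(model.classes)):
                fh.write(f"mu {j} " + _fmt_row(model.mu[j]) + "\n")
                fh.write(f"var {j} " + _fmt_row(model.var[j]) + "\n")


def load_model(path: str | Path) -> NBModel:
    import json

    with open(path, "r", encoding="utf-8") as fh:
        magic = fh.readline().split()
        if magic[:1] != [MODEL_MAGIC] or int(magic[1]) != MODEL_VERSION:
            raise ParameterError(f"{path}: not a model file")
        fields: dict[str, str] = {}
        tables: dict[str, list[np.ndarray]] = {"p1": [], "mu": [], "var": []}
        for line in fh:
            key, _, rest = line.rstrip("\n").partition(" ")
            if key in tables:
                j, _, vals = rest.partition(" ")
                tables[key].insert(int(j), np.array([float(v) for v in vals.split()]))
            else:
                fields[key] = rest
    kind = fields["kind"]
    model = NBModel(
        kind=kind,
        classes=fields["classes"].split(),
        priors=np.array([float(v) for v in fields["priors"].split()]),
        n_features=int(fields["n_features"]),
        m_weight=float(fields["m_weight"]),
        t=int(fields["t"]),
        var_floor=float(fields["var_floor"]),
        layout=json.loads(fields["layout"]),
    )
    if kind == "bernoulli":
        model.p1 = np.vstack(tables["p1"])
    else:
        model.mu = np.vstack(tables["mu"])
        model.var = np.vstack(tables["var"])
    return model
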