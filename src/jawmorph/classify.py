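"""Linear discriminant analysis for feeding-group validation and for
classifying new or reconstructed-ancestor score vectors.

The model is the classical Gaussian equal-covariance LDA: class means, a
pooled within-class covariance (ridge-regularised when singular), and priors
proportional to class sizes. Jack-knife (leave-one-out) validation refits
the model without each taxon in turn and classifies it, reporting the
correct-classification rate and confusion table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LdaModel", "JackknifeReport", "lda_fit", "lda_fit_jackknife", "lda_classify"]


@dataclass
class LdaModel:
    class_ids: list
    class_means: np.ndarray  # class x variables
    pooled_covariance: np.ndarray
    priors: np.ndarray
    _prec: np.ndarray = None  # cached inverse

    def __post_init__(self):
        if not np.allclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if not np.allclose(self.pooled_covariance, self.pooled_covariance.T):
            raise ValueError("pooled covariance must be symmetric")
        if self._prec is None:
            self._prec = np.linalg.inv(self.pooled_covariance)

    @property
    def discriminant_axes(self):
        """Directions Sigma^-1 (mu_c - mu_bar), one per class."""
        mu_bar = self.priors @ self.class_means
        return (self._prec @ (self.class_means - mu_bar).T).T


@dataclass
class JackknifeReport:
    overall_rate: float
    per_class_rate: dict
    confusion: pd.DataFrame  # true x predicted counts
    misclassified: dict  # taxon -> (true, predicted, posterior margin)
    n_evaluated: int
    skipped: list = field(default_factory=list)


def _fit(X, y, ridge=1e-8):
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    p = X.shape[1]
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    n_eff = 0
    for c in classes:
        sub = X[y == c]
        if len(sub) > 1:
            d = sub - sub.mean(axis=0)
            pooled += d.T @ d
            n_eff += len(sub) - 1
    if n_eff == 0:
        raise ValueError("every class has a single member; covariance undefined")
    pooled /= n_eff
    # ridge keeps small subgroup problems well-posed
    eps = ridge * np.trace(pooled) / p
    try:
        np.linalg.cholesky(pooled + np.eye(p) * 1e-300)
        prec = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        pooled = pooled + eps * np.eye(p)
        prec = np.linalg.inv(pooled)
    counts = np.array([np.sum(y == c) for c in classes], dtype=float)
    priors = counts / counts.sum()
    pooled = 0.5 * (pooled + pooled.T)
    return LdaModel(
        class_ids=list(classes), class_means=means,
        pooled_covariance=pooled, priors=priors, _prec=prec,
    )


def lda_fit(scores, labels):
    """Fit an equal-covariance LDA.

    ``scores`` is a taxa x variables array or DataFrame; ``labels`` maps
    taxon (or row) to class.
    """
    X, y, _ = _coerce(scores, labels)
    return _fit(X, y)


def _coerce(scores, labels):
    if isinstance(scores, pd.DataFrame):
        taxa = list(scores.index)
        X = scores.to_numpy(dtype=float)
        y = np.asarray([labels[t] for t in taxa])
    else:
        X = np.asarray(scores, dtype=float)
        taxa = [f"r{i}" for i in range(len(X))]
        labels = np.asarray(labels)
        y = labels
    return X, np.asarray(y), taxa


def lda_fit_jackknife(scores, labels):
    """Fit on all data plus leave-one-out validation of the class labels.

    Each taxon is classified by a model refitted without it. Taxa whose
    class has a single member cannot be left out meaningfully and are
    skipped from the jack-knife denominator with a warning.

    Returns (model, report).
    """
    X, y, taxa = _coerce(scores, labels)
    model = _fit(X, y)
    classes = model.class_ids
    singletons = {c for c in classes if np.sum(y == c) < 2}
    if singletons:
        warnings.warn(
            f"classes with a single member skipped from jack-knife: "
            f"{sorted(singletons)}"
        )
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    mis = {}
    n_eval = 0
    skipped = []
    for i in range(len(X)):
        if y[i] in singletons:
            skipped.append(taxa[i])
            continue
        keep = np.ones(len(X), dtype=bool)
        keep[i] = False
        m_i = _fit(X[keep], y[keep])
        pred, post = lda_classify(m_i, X[i][None, :])
        confusion.loc[y[i], pred[0]] += 1
        n_eval += 1
        if pred[0] != y[i]:
            own = post[0][m_i.class_ids.index(y[i])] if y[i] in m_i.class_ids else 0.0
            margin = float(post[0].max() - own)
            mis[taxa[i]] = (y[i], pred[0], margin)
    per_class = {}
    for c in classes:
        row = confusion.loc[c]
        tot = row.sum()
        per_class[c] = float(row[c] / tot) if tot else float("nan")
    overall = float(np.trace(confusion.values) / n_eval) if n_eval else float("nan")
    report = JackknifeReport(
        overall_rate=overall,
        per_class_rate=per_class,
        confusion=confusion,
        misclassified=mis,
        n_evaluated=n_eval,
        skipped=skipped,
    )
    return model, report


def lda_classify(model, new_scores):
    """Classify new vectors; returns (labels, posterior matrix).

    Posteriors follow the Gaussian equal-covariance rule:
    ``p(c | x) ∝ prior_c · exp(-d²_c / 2)`` with d the Mahalanobis distance
    to the class mean. Rows sum to 1.
    """
    X = np.atleast_2d(np.asarray(new_scores, dtype=float))
    p = model.class_means.shape[1]
    if X.shape[1] != p:
        raise ValueError(f"expected {p} variables, got {X.shape[1]}")
    d = X[:, None, :] - model.class_means[None, :, :]  # n x k x p
    maha = np.einsum("nkp,pq,nkq->nk", d, model._prec, d)
    logp = np.log(model.priors)[None, :] - 0.5 * maha
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    labels = [model.class_ids[i] for i in post.argmax(axis=1)]
    return labels, post
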