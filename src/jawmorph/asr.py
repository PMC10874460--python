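"""Ancestral state estimation on dated trees.

Continuous traits (functional PC scores, body size) are reconstructed under
Brownian motion by maximum likelihood — the phylogenetic-GLS conditional
mean and variance at every internal node. Discrete feeding-subgroup states
are reconstructed under Mk (continuous-time Markov) models with four rate
structures — equal rates (ER), symmetrical (SYM), all rates different
(ARD), and a two-parameter asymmetrical ordered-state model (ASYM: one
shared rate for transitions up the state order, another for transitions
down) — fitted by maximum likelihood through Felsenstein's pruning
algorithm, with marginal node probabilities from a two-pass message
scheme and an unweighted model average across rate structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .phylo import TimeTree

__all__ = [
    "ContinuousAsrResult",
    "MkFit",
    "DiscreteAsrResult",
    "asr_bm_continuous",
    "MkModel",
    "mk_fit",
    "mk_marginal_asr",
    "model_average_states",
]

MK_MODELS = ("ER", "SYM", "ARD", "ASYM")


@dataclass
class ContinuousAsrResult:
    """Per-node BM estimates with conditional variances, one set per axis."""

    axes: list
    estimates: pd.DataFrame  # node x axes
    variances: pd.DataFrame  # node x axes
    sigma2_hat: dict  # axis -> ML BM rate
    root_estimate: dict  # axis -> value

    def node_vector(self, node_id):
        return self.estimates.loc[node_id].to_numpy()


@dataclass
class MkFit:
    model: str
    states: list
    rate_matrix: np.ndarray
    log_likelihood: float
    n_params: int
    converged: bool = True
    root_prior: str = "flat"

    @property
    def aic(self):
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    def __post_init__(self):
        Q = self.rate_matrix
        k = len(self.states)
        if Q.shape != (k, k):
            raise ValueError("rate matrix shape mismatch")
        off = Q[~np.eye(k, dtype=bool)]
        if (off < -1e-12).any() or np.abs(Q.sum(axis=1)).max() > 1e-8:
            raise ValueError("invalid generator matrix")


@dataclass
class DiscreteAsrResult:
    states: list
    node_probabilities: pd.DataFrame  # node x states
    per_model: dict = field(default_factory=dict)  # model -> DataFrame
    fits: dict = field(default_factory=dict)  # model -> MkFit

    def __post_init__(self):
        s = self.node_probabilities.to_numpy().sum(axis=1)
        if np.abs(s - 1).max() > 1e-6:
            raise ValueError("node probability vectors must sum to 1")


# -- continuous (BM / GLS) -------------------------------------------------------


def asr_bm_continuous(tree, tip_values):
    """ML Brownian-motion ancestral estimates for one or more trait axes.

    ``tip_values`` may be a dict (single axis), a DataFrame (taxa x axes) or
    a Series. Estimates at internal nodes are the GLS conditional means
    given the tips; variances include the uncertainty of the root state.
    """
    for nid, bl in tree.branch_lengths().items():
        if bl <= 0:
            raise ValueError(f"non-positive branch length above node {nid}")
    if isinstance(tip_values, dict):
        tip_values = pd.Series(tip_values).to_frame("trait")
    elif isinstance(tip_values, pd.Series):
        tip_values = tip_values.to_frame(tip_values.name or "trait")
    tips = tree.tip_labels
    missing = set(tips) - set(tip_values.index)
    if missing:
        raise ValueError(f"tip values missing for {sorted(missing)}")
    Y = tip_values.loc[tips].to_numpy(dtype=float)
    axes = list(tip_values.columns)
    labels, C = tree.vcv(labels=tips)
    internals = tree.internal_ids()
    S = tree.shared_depths(internals, labels)  # m x n
    age_map = tree.node_ages
    depths = np.array([tree.root_age - age_map[nid] for nid in internals])

    Ci = np.linalg.inv(C)
    one = np.ones(len(tips))
    denom = one @ Ci @ one
    W = S @ Ci  # m x n GLS weights
    root_term = (1.0 - W @ one) ** 2 / denom
    quad = np.einsum("ij,ij->i", W, S)

    est = np.empty((len(internals), len(axes)))
    var = np.empty_like(est)
    sigma2 = {}
    root_est = {}
    for j, ax in enumerate(axes):
        y = Y[:, j]
        a = (one @ Ci @ y) / denom
        resid = y - a
        s2 = float(resid @ Ci @ resid) / len(y)
        est[:, j] = a + W @ resid
        var[:, j] = np.maximum(s2 * (depths - quad + root_term), 0.0)
        sigma2[ax] = s2
        root_est[ax] = float(a)
    return ContinuousAsrResult(
        axes=axes,
        estimates=pd.DataFrame(est, index=pd.Index(internals, name="node"),
                               columns=axes),
        variances=pd.DataFrame(var, index=pd.Index(internals, name="node"),
                               columns=axes),
        sigma2_hat=sigma2,
        root_estimate=root_est,
    )


# -- Mk machinery -----------------------------------------------------------------


def _n_params(model, k):
    return {
        "ER": 1,
        "SYM": k * (k - 1) // 2,
        "ARD": k * (k - 1),
        "ASYM": 2,
    }[model]


def build_rate_matrix(model, rates, k):
    """Generator matrix for one rate structure from its free parameters."""
    rates = np.asarray(rates, dtype=float)
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = rates[0]
    elif model == "SYM":
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                Q[i, j] = Q[j, i] = rates[idx]
                idx += 1
    elif model == "ARD":
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    elif model == "ASYM":
        up, down = rates
        for i in range(k):
            for j in range(k):
                if j > i:
                    Q[i, j] = up
                elif j < i:
                    Q[i, j] = down
    else:
        raise ValueError(f"unknown Mk model {model!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class MkModel:
    """Mk discrete-character model on a dated tree.

    ``MkModel(tree, tip_states, model).fit()`` returns an :class:`MkFit`;
    :meth:`marginal_asr` then yields per-node state probabilities.
    """

    def __init__(self, tree, tip_states, model="ER", states=None,
                 root_prior="flat"):
        if model not in MK_MODELS:
            raise ValueError(f"unknown Mk model {model!r}")
        self.tree = tree
        self.model = model
        self.tip_states = dict(tip_states)
        observed = sorted(set(self.tip_states.values()))
        self.states = list(states) if states is not None else observed
        extra = set(observed) - set(self.states)
        if extra:
            raise ValueError(f"tip states outside the state list: {sorted(extra)}")
        if len(self.states) < 2:
            raise ValueError("need at least 2 states")
        missing = set(tree.tip_labels) - set(self.tip_states)
        if missing:
            raise ValueError(f"tip states missing for {sorted(missing)}")
        self.root_prior = root_prior
        self.k = len(self.states)
        self._sidx = {s: i for i, s in enumerate(self.states)}

    # likelihood ------------------------------------------------------------

    def _prior_vector(self, Q):
        if self.root_prior == "flat":
            return np.full(self.k, 1.0 / self.k)
        # stationary distribution of the fitted generator
        w, v = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def _down_pass(self, Q):
        """Conditional likelihoods of the data below each node (scaled)."""
        down = {}
        child_msg = {}
        log_scale = 0.0
        for nd in self.tree.nodes(order="postorder"):
            if nd.is_leaf():
                vec = np.zeros(self.k)
                vec[self._sidx[self.tip_states[nd.taxon.label]]] = 1.0
                down[nd.node_id] = vec
            else:
                vec = np.ones(self.k)
                for ch in nd.child_nodes():
                    P = expm(Q * (nd.age - ch.age))
                    msg = P @ down[ch.node_id]
                    child_msg[ch.node_id] = msg
                    vec = vec * msg
                s = vec.sum()
                log_scale += np.log(s)
                down[nd.node_id] = vec / s
        return down, child_msg, log_scale

    def log_likelihood(self, Q):
        down, _, log_scale = self._down_pass(Q)
        prior = self._prior_vector(Q)
        return float(np.log(prior @ down[self.tree.root.node_id]) + log_scale)

    # fitting ----------------------------------------------------------------

    def fit(self, n_starts=5, seed=0):
        """Maximum-likelihood rates via bounded quasi-Newton, multiple
        seeded starts (rate surfaces are multimodal for rich structures)."""
        npar = _n_params(self.model, self.k)
        total_bl = sum(self.tree.branch_lengths().values())
        r0 = max(len(self.tree.tip_labels) / max(total_bl, 1e-9), 1e-4)
        rng = np.random.default_rng(seed)

        def nll(logr):
            Q = build_rate_matrix(self.model, np.exp(logr), self.k)
            try:
                return -self.log_likelihood(Q)
            except (FloatingPointError, ValueError):
                return 1e10

        best = None
        converged = False
        for s in range(n_starts):
            x0 = np.full(npar, np.log(r0))
            if s > 0:
                x0 = x0 + rng.normal(0, 1.5, size=npar)
            res = minimize(
                nll, x0, method="L-BFGS-B",
                bounds=[(-18.0, 8.0)] * npar,
            )
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success)
        Q = build_rate_matrix(self.model, np.exp(best.x), self.k)
        return MkFit(
            model=self.model,
            states=list(self.states),
            rate_matrix=Q,
            log_likelihood=-float(best.fun),
            n_params=npar,
            converged=converged,
            root_prior=self.root_prior,
        )

    # marginal reconstruction --------------------------------------------------

    def marginal_asr(self, fit):
        """Marginal per-node posterior state probabilities under a fitted
        rate matrix (down + up message passing)."""
        if list(fit.states) != list(self.states):
            raise ValueError("state spaces of fit and model differ")
        Q = fit.rate_matrix
        down, child_msg, _ = self._down_pass(Q)
        prior = self._prior_vector(Q)
        up = {self.tree.root.node_id: prior}
        probs = {}
        for nd in self.tree.nodes(order="preorder"):
            nid = nd.node_id
            marg = up[nid] * down[nid]
            probs[nid] = marg / marg.sum()
            if nd.is_leaf():
                continue
            for ch in nd.child_nodes():
                sib = up[nid].copy()
                for other in nd.child_nodes():
                    if other is not ch:
                        sib = sib * child_msg[other.node_id]
                P = expm(Q * (nd.age - ch.age))
                msg = P.T @ sib
                s = msg.sum()
                up[ch.node_id] = msg / s if s > 0 else msg
        idx = list(probs)
        table = pd.DataFrame(
            [probs[i] for i in idx], index=pd.Index(idx, name="node"),
            columns=list(self.states),
        )
        return DiscreteAsrResult(
            states=list(self.states),
            node_probabilities=table,
            per_model={fit.model: table},
            fits={fit.model: fit},
        )


def mk_fit(tree, tip_states, model="ER", states=None, root_prior="flat",
           n_starts=5, seed=0):
    """Fit one Mk rate structure by maximum likelihood."""
    return MkModel(tree, tip_states, model=model, states=states,
                   root_prior=root_prior).fit(n_starts=n_starts, seed=seed)


def mk_marginal_asr(tree, tip_states, fit, states=None):
    """Marginal ancestral state probabilities under a fitted Mk model."""
    return MkModel(tree, tip_states, model=fit.model,
                   states=states or fit.states,
                   root_prior=fit.root_prior).marginal_asr(fit)


def model_average_states(results, weights=None):
    """Average per-model node probability tables (unweighted by default).

    ``results`` is a list of :class:`DiscreteAsrResult` on identical node and
    state spaces; pass AIC-based ``weights`` for weighted averaging. Output
    vectors are renormalised against rounding drift.
    """
    if not results:
        raise ValueError("no results to average")
    ref = results[0]
    for r in results[1:]:
        if list(r.states) != list(ref.states):
            raise ValueError("disjoint or re-ordered state spaces")
        if list(r.node_probabilities.index) != list(ref.node_probabilities.index):
            raise ValueError("node sets differ")
    if weights is None:
        weights = np.full(len(results), 1.0 / len(results))
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    avg = sum(
        w * r.node_probabilities.to_numpy() for w, r in zip(weights, results)
    )
    avg = avg / avg.sum(axis=1, keepdims=True)
    per_model = {}
    fits = {}
    for r in results:
        per_model.update(r.per_model)
        fits.update(r.fits)
    return DiscreteAsrResult(
        states=list(ref.states),
        node_probabilities=pd.DataFrame(
            avg, index=ref.node_probabilities.index, columns=list(ref.states)
        ),
        per_model=per_model,
        fits=fits,
    )
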