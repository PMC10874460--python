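"""Time-scaled phylogenies: Newick I/O, minimum-branch-length (MBL) dating,
phylogenetic time-slicing, and Brownian-motion imputation of missing tip values.

Ages are in Ma before present (root maximal, tips youngest). Branch lengths
are in myr and always equal ``parent_age - child_age``. Dendropy provides the
tree container and parser; :class:`TimeTree` adds the dated-tree invariants
the downstream comparative methods rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "TimeSlice",
    "read_newick",
    "write_newick",
    "mbl_timescale",
    "time_slice",
    "bm_impute",
]


class TimeTree:
    """A rooted, dated phylogeny.

    Wraps a :class:`dendropy.Tree`. Every node carries an ``age`` (Ma) and a
    stable string identifier: tips use their taxon label, internal nodes an
    existing label or ``"node<k>"`` assigned in preorder.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with branch lengths in myr.
    tip_ranges : dict, optional
        Taxon label -> (FAD, LAD) stratigraphic range in Ma, FAD >= LAD.
    youngest_age : float
        Age (Ma) assigned to the youngest tip; other ages follow from the
        branch lengths. Ignored when ``node_ages`` is given.
    node_ages : dict, optional
        Explicit node-id -> age mapping; branch lengths are recomputed.
    """

    def __init__(self, tree, tip_ranges=None, youngest_age=0.0, node_ages=None):
        self.tree = tree
        self._label_nodes()
        if node_ages is not None:
            for nd in tree:
                nd.age = float(node_ages[nd.node_id])
            for nd in tree:
                if nd.parent_node is not None:
                    nd.edge.length = nd.parent_node.age - nd.age
        else:
            self._ages_from_branch_lengths(youngest_age)
        self.tip_ranges = dict(tip_ranges) if tip_ranges else {}
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _label_nodes(self):
        seen = set()
        k = 0
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unlabelled tip in tree")
                nd.node_id = nd.taxon.label
            elif nd.label:
                nd.node_id = nd.label
            else:
                nd.node_id = f"node{k}"
                k += 1
            if nd.node_id in seen:
                raise ValueError(f"duplicate node/tip name: {nd.node_id!r}")
            seen.add(nd.node_id)

    def _ages_from_branch_lengths(self, youngest_age):
        root = self.tree.seed_node
        root.depth = 0.0
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is not None:
                bl = nd.edge.length if nd.edge.length is not None else 0.0
                nd.depth = nd.parent_node.depth + float(bl)
        max_depth = max(nd.depth for nd in self.tree.leaf_node_iter())
        root_age = max_depth + float(youngest_age)
        for nd in self.tree:
            nd.age = root_age - nd.depth

    def _validate(self):
        for nd in self.tree:
            if not np.isfinite(nd.age) or nd.age < -1e-9:
                raise ValueError(f"node {nd.node_id}: non-finite or negative age")
            if nd.parent_node is not None and nd.parent_node.age <= nd.age - 1e-9:
                raise ValueError(
                    f"edge above {nd.node_id}: parent age {nd.parent_node.age} "
                    f"not older than child age {nd.age}"
                )
        for taxon, (fad, lad) in self.tip_ranges.items():
            if fad < lad:
                raise ValueError(f"{taxon}: FAD {fad} < LAD {lad}")

    # -- basic queries --------------------------------------------------------

    @property
    def root(self):
        return self.tree.seed_node

    @property
    def root_age(self):
        return self.tree.seed_node.age

    @property
    def tip_labels(self):
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self):
        return sum(1 for _ in self.tree.leaf_node_iter())

    def nodes(self, order="postorder"):
        it = (
            self.tree.postorder_node_iter()
            if order == "postorder"
            else self.tree.preorder_node_iter()
        )
        return list(it)

    def internal_ids(self):
        return [nd.node_id for nd in self.tree if not nd.is_leaf()]

    @property
    def node_ages(self):
        return {nd.node_id: nd.age for nd in self.tree}

    def branch_lengths(self):
        return {
            nd.node_id: nd.parent_node.age - nd.age
            for nd in self.tree
            if nd.parent_node is not None
        }

    # -- covariance machinery for BM ------------------------------------------

    def _tip_sets(self):
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                nd.tip_set = frozenset([nd.taxon.label])
            else:
                s = frozenset()
                for ch in nd.child_nodes():
                    s |= ch.tip_set
                nd.tip_set = s

    def vcv(self, labels=None):
        """Brownian-motion tip covariance structure.

        Returns ``(labels, C)`` where ``C[i, j]`` is the root-to-MRCA path
        length (myr) shared by tips i and j; the diagonal holds root-to-tip
        path lengths.
        """
        self._tip_sets()
        if labels is None:
            labels = self.tip_labels
        idx = {t: i for i, t in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        root_age = self.root_age
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            depth = root_age - nd.age
            kids = nd.child_nodes()
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for ta in kids[a].tip_set:
                        if ta not in idx:
                            continue
                        for tb in kids[b].tip_set:
                            if tb not in idx:
                                continue
                            C[idx[ta], idx[tb]] = depth
                            C[idx[tb], idx[ta]] = depth
        for lf in self.tree.leaf_node_iter():
            t = lf.taxon.label
            if t in idx:
                C[idx[t], idx[t]] = root_age - lf.age
        return labels, C

    def shared_depths(self, node_ids, labels):
        """Shared root-to-MRCA path lengths between arbitrary nodes and tips.

        Returns an ``len(node_ids) x len(labels)`` matrix used for GLS
        ancestral prediction and imputation.
        """
        self._tip_sets()
        by_id = {nd.node_id: nd for nd in self.tree}
        root_age = self.root_age
        out = np.zeros((len(node_ids), len(labels)))
        for i, nid in enumerate(node_ids):
            nd = by_id[nid]
            for j, t in enumerate(labels):
                anc = nd
                while t not in anc.tip_set:
                    anc = anc.parent_node
                out[i, j] = root_age - anc.age
        return out

    # -- serialisation ---------------------------------------------------------

    def as_newick(self):
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        )

    def clone(self):
        t = dendropy.Tree(self.tree)
        youngest = min(lf.age for lf in self.tree.leaf_node_iter())
        return TimeTree(t, tip_ranges=self.tip_ranges, youngest_age=youngest)


@dataclass
class TimeSlice:
    """Trait values of all lineages crossing one geological age."""

    age: float
    lineage_values: dict = field(default_factory=dict)  # edge (child id) -> vector
    provenance: dict = field(default_factory=dict)  # edge -> origin tag

    def matrix(self):
        if not self.lineage_values:
            return np.empty((0, 0))
        return np.asarray([self.lineage_values[k] for k in sorted(self.lineage_values)])

    def __len__(self):
        return len(self.lineage_values)


# -- I/O ----------------------------------------------------------------------


def read_newick(path, tip_ranges=None, youngest_age=0.0):
    """Read a Newick tree into a :class:`TimeTree`.

    Duplicate tip names and malformed syntax raise with the offending name /
    parser position. Polytomies are accepted.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as e:
        if "Duplicate taxon" in str(e) or "Multiple occurrences" in str(e):
            raise ValueError(f"duplicate tip names in {path}: {e}") from e
        raise
    return TimeTree(tree, tip_ranges=tip_ranges, youngest_age=youngest_age)


def write_newick(tree, path):
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


# -- MBL time-scaling ----------------------------------------------------------


def mbl_timescale(topology, first_appearances, mbl=0.1):
    """Date a tree from tip first-appearance ages with a minimum branch length.

    Tips are fixed at their FAD; one post-order pass dates each internal node
    at ``max(child age) + mbl``, which simultaneously respects the oldest
    descendant age and enforces every branch >= mbl (the branch leading to the
    oldest descendant would otherwise be zero-length).

    Parameters
    ----------
    topology : TimeTree or dendropy.Tree
        Branch lengths are ignored; only the topology is used.
    first_appearances : dict
        Taxon label -> FAD (Ma). Required for every tip.
    mbl : float
        Minimum branch duration in myr (> 0).
    """
    if mbl <= 0:
        raise ValueError("mbl must be > 0")
    tree = topology.tree if isinstance(topology, TimeTree) else topology
    tree = dendropy.Tree(tree)
    ages = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            t = nd.taxon.label
            if t not in first_appearances:
                raise ValueError(f"missing first-appearance age for taxon {t!r}")
            nd.age = float(first_appearances[t])
        else:
            nd.age = max(ch.age for ch in nd.child_nodes()) + mbl
        ages[id(nd)] = nd.age
    for nd in tree:
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age - nd.age
    youngest = min(nd.age for nd in tree.leaf_node_iter())
    return TimeTree(tree, youngest_age=youngest)


# -- time slicing ---------------------------------------------------------------


def time_slice(tree, age, node_values, model="proximity"):
    """Collect one trait vector per lineage crossing ``age``.

    Every edge whose parent is older than ``age`` and whose child is at or
    younger than ``age`` contributes exactly one vector. A tip whose
    stratigraphic range covers ``age`` contributes its observed value;
    otherwise the edge value comes from its endpoints: ``model="proximity"``
    takes the endpoint nearer in time, ``model="gradual"`` interpolates
    linearly by elapsed fraction.
    """
    if model not in ("proximity", "gradual"):
        raise ValueError(f"unknown slice model {model!r}")
    youngest = min(lf.age for lf in tree.tree.leaf_node_iter())
    if age > tree.root_age or age < youngest - 1e-12:
        warnings.warn(
            f"slice age {age} Ma outside tree span "
            f"[{youngest}, {tree.root_age}]; empty slice"
        )
        return TimeSlice(age=age)
    sl = TimeSlice(age=age)
    for nd in tree.tree.preorder_node_iter():
        par = nd.parent_node
        if par is None:
            continue
        if not (par.age > age >= nd.age - 1e-12):
            continue
        key = nd.node_id
        if nd.is_leaf() and key in tree.tip_ranges:
            fad, lad = tree.tip_ranges[key]
            if fad >= age >= lad:
                sl.lineage_values[key] = np.atleast_1d(
                    np.asarray(node_values[key], dtype=float)
                )
                sl.provenance[key] = "observed tip"
                continue
        v_par = np.atleast_1d(np.asarray(node_values[par.node_id], dtype=float))
        v_ch = np.atleast_1d(np.asarray(node_values[key], dtype=float))
        if model == "proximity":
            nearer_child = (par.age - age) >= (age - nd.age)
            sl.lineage_values[key] = v_ch if nearer_child else v_par
            sl.provenance[key] = "node value"
        else:
            span = par.age - nd.age
            frac = (par.age - age) / span if span > 0 else 1.0
            sl.lineage_values[key] = v_par + frac * (v_ch - v_par)
            sl.provenance[key] = "interpolated"
    return sl


# -- BM imputation ---------------------------------------------------------------


def _bm_ml(C, y):
    """ML root state and BM rate for observed tips with covariance C."""
    n = len(y)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Ci @ one
    a = (one @ Ci @ y) / denom
    resid = y - a
    sigma2 = (resid @ Ci @ resid) / n
    return a, sigma2, Ci, denom


def bm_impute(tree, observed_values, regime_map=None, regime_rates=None):
    """Fill missing tip values with their BM conditional expectation.

    The Brownian-motion rate and root state are fitted by maximum likelihood
    on the observed tips; each missing tip gets the phylogenetic-GLS
    conditional mean and variance given the observed tips. The conditional
    variance includes the uncertainty in the estimated root state.

    Parameters
    ----------
    observed_values : dict
        Taxon label -> value; missing taxa absent or NaN.
    regime_map, regime_rates : optional
        Clade-specific relative-rate variant: ``regime_map`` maps a node id
        (the child end of an edge) to a regime name, ``regime_rates`` maps
        regime name to a relative rate multiplying that edge's duration.
        Edges not named inherit rate 1.

    Returns
    -------
    (values, variances, sigma2_hat, root_state)
        ``values`` covers every tip (observed tips unchanged); ``variances``
        holds the conditional variance for imputed tips (0 for observed).
    """
    tips = tree.tip_labels
    obs = {
        t: float(observed_values[t])
        for t in tips
        if t in observed_values and np.isfinite(observed_values.get(t, np.nan))
    }
    missing = [t for t in tips if t not in obs]
    if len(obs) < 3:
        raise ValueError("need at least 3 observed tips for BM imputation")

    work_tree = tree
    if regime_map:
        rates = dict(regime_rates or {})
        t2 = dendropy.Tree(tree.tree)
        tt2 = TimeTree(
            t2, tip_ranges=tree.tip_ranges,
            youngest_age=min(lf.age for lf in tree.tree.leaf_node_iter()),
        )
        # stretch edge durations by their regime's relative rate, then re-date
        for nd in t2.preorder_node_iter():
            if nd.parent_node is None:
                continue
            r = rates.get(regime_map.get(nd.node_id, None), 1.0)
            nd.edge.length = (nd.parent_node.age - nd.age) * r
        work_tree = TimeTree(t2, youngest_age=0.0)

    obs_labels = list(obs)
    _, C_full = work_tree.vcv(labels=obs_labels + missing)
    no = len(obs_labels)
    C_oo = C_full[:no, :no]
    y = np.array([obs[t] for t in obs_labels])
    a, sigma2, Ci, denom = _bm_ml(C_oo, y)

    values = dict(obs)
    variances = {t: 0.0 for t in obs_labels}
    if missing:
        C_mo = C_full[no:, :no]
        C_mm = C_full[no:, no:]
        w = C_mo @ Ci  # GLS weights
        mean = a + w @ (y - a)
        one = np.ones(no)
        root_term = (1.0 - w @ one) ** 2 / denom
        cond = np.diag(C_mm) - np.einsum("ij,ij->i", w, C_mo)
        var = sigma2 * (cond + root_term)
        for t, m, v in zip(missing, mean, var):
            values[t] = float(m)
            variances[t] = float(max(v, 0.0))
    return values, variances, float(sigma2), float(a)
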