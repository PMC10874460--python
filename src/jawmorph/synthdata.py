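"""Synthetic data with known ground truth for the full analysis pipeline.

Generates dated birth-death trees with extinct (fossil) tips, Brownian-motion
continuous traits, measurement matrices with planted multi-level cluster
structure, template-deformed landmark configurations, and stratigraphic
ranges — everything the downstream morphometric, clustering and phylogenetic
stages consume, so each stage can be tested against planted truth.

Defaults emulate a late Palaeozoic carnivore study design: ~120 tips spanning
roughly 315-251 Ma, three top-level functional groups subdivided into seven
subgroups, and jaw outlines digitised as 4 fixed landmarks plus 55
semi-landmarks on 4 curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .geometry import LandmarkConfiguration
from .phylo import TimeTree

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "default_group_spec",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_measurement_groups",
    "jaw_template",
    "simulate_landmark_set",
    "simulate_dataset",
    "default_bins",
]

# Substage-style time bins (older Ma, younger Ma), Late Carboniferous-Early
# Triassic, each stage halved.
_STAGES = [
    (315.2, 307.0),  # Moscovian
    (307.0, 303.7),  # Kasimovian
    (303.7, 298.9),  # Gzhelian
    (298.9, 293.5),  # Asselian
    (293.5, 290.1),  # Sakmarian
    (290.1, 283.5),  # Artinskian
    (283.5, 273.0),  # Kungurian
    (273.0, 266.9),  # Roadian
    (266.9, 264.3),  # Wordian
    (264.3, 259.5),  # Capitanian
    (259.5, 254.1),  # Wuchiapingian
    (254.1, 251.9),  # Changhsingian
    (251.9, 249.9),  # Induan
]


def default_bins():
    """Half-stage time bins as (older, younger) Ma pairs, oldest first."""
    bins = []
    for older, younger in _STAGES:
        mid = (older + younger) / 2
        bins.append((older, mid))
        bins.append((mid, younger))
    return bins


def default_group_spec(separation=8.0, subgroup_offset=2.5, n_dims=9,
                       n_taxa=120, seed=0):
    """Planted 3-group / 7-subgroup Gaussian mixture specification.

    Top-level group centroids sit ``separation`` within-subgroup sd apart
    along distinct coordinate directions; each group's subgroups are offset
    from the group centroid by a fixed, deliberately smaller
    ``subgroup_offset``. Two design constraints keep the subgroups subtle
    relative to the groups, which is what makes top-level structure
    recoverable (and increasingly so as ``separation`` grows): the offset
    is absolute rather than proportional to ``separation``, and offset
    directions are confined to the same low-dimensional subspace as the
    group axes — per-variable standardisation downstream would otherwise
    blow subgroup-only directions up to group-level magnitude.
    """
    rng = np.random.default_rng(seed)
    layout = [("G1", 2), ("G2", 2), ("G3", 3)]  # 3 FFGs, 7 FFsGs
    n_sub = sum(k for _, k in layout)
    base = n_taxa // n_sub
    sizes = [base] * n_sub
    for i in range(n_taxa - base * n_sub):
        sizes[i] += 1
    group_dims = [g % n_dims for g in range(len(layout))]
    spec = []
    i = 0
    for g, (gid, k) in enumerate(layout):
        gdir = np.zeros(n_dims)
        gdir[group_dims[g]] = 1.0
        g_cent = separation * gdir
        for s in range(k):
            sdir = np.zeros(n_dims)
            sdir[group_dims] = rng.normal(size=len(group_dims))
            sdir /= np.linalg.norm(sdir)
            cent = g_cent + subgroup_offset * sdir
            spec.append(
                (gid, f"{gid}s{s + 1}", cent, np.eye(n_dims), sizes[i])
            )
            i += 1
    return spec


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator."""

    n_tips: int = 120
    birth_rate: float = 0.09  # per lineage-myr
    death_rate: float = 0.045
    root_age: float = 315.2  # Ma (Late Carboniferous)
    sigma2: float = 0.05  # BM rate, trait^2 / myr
    group_spec: list = None
    landmark_noise_sd: float = 0.01
    deformation_scale: float = 0.05
    missing_fraction: float = 0.3
    separation: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.death_rate >= self.birth_rate:
            raise ValueError("death_rate must be < birth_rate")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.group_spec is None:
            self.group_spec = default_group_spec(
                separation=self.separation, n_taxa=self.n_tips, seed=self.seed
            )
        if sum(s[-1] for s in self.group_spec) != self.n_tips:
            raise ValueError("group_spec taxon counts must sum to n_tips")


@dataclass
class SyntheticDataset:
    """All generated inputs keyed by one shared taxon set."""

    tree: TimeTree
    traits: pd.DataFrame  # taxon -> continuous traits (body size)
    measurements: pd.DataFrame  # taxon x raw jaw measurement columns
    true_labels: pd.DataFrame  # taxon -> (group, subgroup)
    landmarks: list  # LandmarkConfiguration per taxon
    strat_ranges: dict  # taxon -> (FAD, LAD)
    config: SimConfig = None

    def __post_init__(self):
        taxa = set(self.tree.tip_labels)
        for name, keys in [
            ("traits", set(self.traits.index)),
            ("measurements", set(self.measurements.index)),
            ("true_labels", set(self.true_labels.index)),
            ("strat_ranges", set(self.strat_ranges)),
            ("landmarks", {c.taxon_id for c in self.landmarks}),
        ]:
            if keys != taxa:
                raise ValueError(f"{name} taxon set differs from tree tips")


# -- tree simulation -----------------------------------------------------------


def simulate_tree(n_tips, birth_rate, death_rate=0.0, root_age=None, seed=0,
                  max_retries=1000):
    """Simulate a birth-death tree with exactly ``n_tips`` sampled tips.

    Forward (Gillespie) simulation from a root bifurcation; extinct lineages
    are retained as fossil tips, so the returned tree is generally
    non-ultrametric. The process stops once the total number of tips (extinct
    plus alive) reaches ``n_tips``; alive lineages are then extended by half
    of one further sampled waiting time so every terminal branch is positive.
    Replicates that go fully extinct first are retried up to ``max_retries``.

    If ``root_age`` is given (Ma), all node times are rescaled so the root
    sits at ``root_age`` and the youngest tip at 0; otherwise raw simulation
    time is kept (rates then stay calibrated, which the Yule-expectation
    tests rely on).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    total_rate = birth_rate + death_rate
    for _ in range(max_retries):
        # per-lineage records; ids -1 = root stem children 1, 2
        parent = {1: -1, 2: -1}
        btime = {1: 0.0, 2: 0.0}
        end = {}  # lineage id -> end time (split, death, or stop)
        internal = set()  # lineages that split (become internal nodes)
        extinct = set()
        alive = {1, 2}
        nxt = 3
        t = 0.0
        failed = False
        # tip count if stopped now = alive + extinct; deaths leave it fixed,
        # births raise it by one, so the loop terminates at births
        while len(alive) + len(extinct) < n_tips:
            if not alive:
                failed = True
                break
            t += rng.exponential(1.0 / (len(alive) * total_rate))
            lin = sorted(alive)[rng.integers(len(alive))]
            alive.remove(lin)
            end[lin] = t
            if rng.random() < birth_rate / total_rate:
                internal.add(lin)
                for _ in range(2):
                    parent[nxt] = lin
                    btime[nxt] = t
                    alive.add(nxt)
                    nxt += 1
            else:
                extinct.add(lin)
        if failed:
            continue
        t_stop = t + 0.5 * rng.exponential(1.0 / (len(alive) * total_rate))
        for lin in alive:
            end[lin] = t_stop
        return _build_tree(parent, btime, end, internal, t_stop, root_age)
    raise RuntimeError(
        f"birth-death simulation failed to reach {n_tips} tips in "
        f"{max_retries} attempts"
    )


def _build_tree(parent, btime, end, internal, t_stop, root_age):
    scale = 1.0 if root_age is None else root_age / t_stop
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes = {-1: tree.seed_node}
    tip_i = 0
    for k in sorted(btime, key=lambda k: (btime[k], k)):
        nd = dendropy.Node()
        nodes[parent[k]].add_child(nd)
        nd.edge.length = (end[k] - btime[k]) * scale
        nodes[k] = nd
        if k not in internal:
            tip_i += 1
            nd.taxon = taxon_ns.new_taxon(f"t{tip_i}")
    return TimeTree(tree, youngest_age=0.0)


# -- BM traits -----------------------------------------------------------------


def simulate_bm_traits(tree, sigma2, root_state=0.0, seed=0, internal=True):
    """Brownian-motion trait values for every node of a dated tree.

    Increments along a branch of duration t are Normal(0, sigma2 * t).
    Returns a dict node id -> value covering tips and, when ``internal``,
    internal nodes too.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    values = {}
    for nd in tree.nodes(order="preorder"):
        if nd.parent_node is None:
            values[nd.node_id] = float(root_state)
        else:
            bl = nd.parent_node.age - nd.age
            step = rng.normal(0.0, np.sqrt(sigma2 * bl)) if sigma2 > 0 else 0.0
            values[nd.node_id] = values[nd.parent_node.node_id] + step
    if not internal:
        tips = set(tree.tip_labels)
        values = {k: v for k, v in values.items() if k in tips}
    return values


# -- planted cluster structure ---------------------------------------------------


def simulate_measurement_groups(group_spec, taxa=None, seed=0):
    """Draw taxon vectors from a planted (group, subgroup) Gaussian mixture.

    Parameters
    ----------
    group_spec : list of (group_id, subgroup_id, centroid, covariance, n)
    taxa : list of taxon labels, optional
        Assigned to subgroups in spec order; autogenerated if omitted.

    Returns
    -------
    (measurements, labels) : (pd.DataFrame, pd.DataFrame)
    """
    rng = np.random.default_rng(seed)
    n_total = sum(s[-1] for s in group_spec)
    if taxa is None:
        taxa = [f"t{i + 1}" for i in range(n_total)]
    if len(taxa) != n_total:
        raise ValueError("taxon list length must equal total group_spec count")
    rows, labels = [], []
    i = 0
    for gid, sid, cent, cov, n in group_spec:
        cent = np.asarray(cent, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (len(cent), len(cent)):
            raise ValueError(f"subgroup {sid}: covariance shape mismatch")
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"subgroup {sid}: covariance not positive definite") from e
        draws = cent + rng.standard_normal((n, len(cent))) @ L.T
        for row in draws:
            rows.append(row)
            labels.append((taxa[i], gid, sid))
            i += 1
    cols = [f"v{j + 1}" for j in range(len(group_spec[0][2]))]
    meas = pd.DataFrame(rows, index=[l[0] for l in labels], columns=cols)
    meas.index.name = "taxon"
    lab = pd.DataFrame(
        [(g, s) for _, g, s in labels],
        index=meas.index,
        columns=["group", "subgroup"],
    )
    return meas, lab


# -- landmarks -------------------------------------------------------------------


def jaw_template():
    """Synthetic lower-jaw outline template: 4 fixed landmarks + 55
    semi-landmarks on 4 curves (dorsal anterior/posterior, ventral, coronoid).

    The outline is an elongate, asymmetric closed-ish curve qualitatively
    shaped like a carnivore mandible in lateral view; it is a synthetic
    stand-in, not a digitised specimen.
    """
    # fixed: 0 symphysis tip, 1 coronoid apex, 2 articular, 3 angular
    fixed_pts = np.array([[0.0, 0.05], [0.72, 0.28], [1.0, 0.1], [0.85, -0.08]])
    counts = [14, 14, 14, 13]  # semi-landmarks per curve (sums to 55)

    def arc(p0, p1, n, bow):
        # quadratic bow between fixed ends; interior points only
        s = np.linspace(0, 1, n + 2)[1:-1]
        mid = (p0 + p1) / 2
        d = p1 - p0
        normal = np.array([-d[1], d[0]])
        normal /= np.linalg.norm(normal)
        pts = (1 - s)[:, None] * p0 + s[:, None] * p1
        pts += (bow * np.sin(np.pi * s))[:, None] * normal
        return pts

    curves_pts = [
        arc(fixed_pts[0], fixed_pts[1], counts[0], 0.04),  # dorsal margin
        arc(fixed_pts[1], fixed_pts[2], counts[1], 0.05),  # coronoid-articular
        arc(fixed_pts[2], fixed_pts[3], counts[2], 0.03),  # posterior margin
        arc(fixed_pts[3], fixed_pts[0], counts[3], -0.06),  # ventral margin
    ]
    coords = [fixed_pts[0], fixed_pts[1], fixed_pts[2], fixed_pts[3]]
    curves = []
    idx = 4
    curve_ends = [(0, 1), (1, 2), (2, 3), (3, 0)]
    for pts, (a, b) in zip(curves_pts, curve_ends):
        ids = [a] + list(range(idx, idx + len(pts))) + [b]
        coords.extend(pts)
        curves.append(ids)
        idx += len(pts)
    coords = np.asarray(coords)
    return LandmarkConfiguration(
        taxon_id="template",
        coords=coords,
        fixed_indices=[0, 1, 2, 3],
        curves=curves,
    )


def simulate_landmark_set(template, deformation_scale, noise_sd, n, seed=0,
                          taxa=None):
    """Template + smooth low-rank deformation + i.i.d. Gaussian jitter.

    The deformation is a random linear combination of 3 smooth sinusoidal
    displacement fields evaluated at the template coordinates, giving
    low-rank, spatially coherent shape variation; jitter is independent per
    coordinate. Curve membership is inherited from the template.
    """
    if len(template.coords) != 59:
        raise ValueError("template must have exactly 59 landmarks")
    rng = np.random.default_rng(seed)
    base = template.coords
    if taxa is None:
        taxa = [f"t{i + 1}" for i in range(n)]
    # 3 fixed smooth displacement fields (deterministic given the template)
    freqs = [(1.0, 0.5), (2.0, 1.0), (0.5, 2.0)]
    fields = []
    for fx, fy in freqs:
        dx = np.sin(np.pi * fx * base[:, 0]) * np.cos(np.pi * fy * base[:, 1])
        dy = np.cos(np.pi * fx * base[:, 0]) * np.sin(np.pi * fy * base[:, 1])
        fields.append(np.stack([dx, dy], axis=1))
    configs = []
    for i in range(n):
        coefs = rng.normal(0.0, deformation_scale, size=3)
        pts = base + sum(c * f for c, f in zip(coefs, fields))
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
        configs.append(
            LandmarkConfiguration(
                taxon_id=taxa[i],
                coords=pts,
                fixed_indices=list(template.fixed_indices),
                curves=[list(c) for c in template.curves],
            )
        )
    return configs


# -- whole dataset ----------------------------------------------------------------


def _jaw_measurements_from_vectors(vectors):
    """Map planted cluster vectors onto plausible raw jaw measurements.

    The first components of each planted vector perturb, on log scale, a set
    of base jaw proportions so that the cluster structure survives into the
    functional-character ratios. Units are mm.
    """
    base = dict(
        jaw_length=200.0,
        anterior_out_lever=180.0,
        posterior_out_lever=90.0,
        closing_in_lever_a=50.0,
        closing_in_lever_b=60.0,
        opening_in_lever=25.0,
        toothrow_length=120.0,
        symphysis_length=40.0,
        symphysis_depth=20.0,
        max_depth=45.0,
        articulation_offset=5.0,
        symphyseal_angle=30.0,
    )
    cols = list(base)
    V = np.asarray(vectors, dtype=float)
    # spread planted dimensions across the measurement columns; chosen so
    # that no functional-character ratio pairs two measurements carrying the
    # same planted dimension (which would cancel the cluster signal)
    dim_of_col = [0, 1, 2, 3, 4, 5, 6, 7, 8, 4, 5, 3][: len(cols)]
    W = np.zeros((V.shape[1], len(cols)))
    for j, dim in enumerate(dim_of_col):
        W[dim % V.shape[1], j] = 1.0
    eff = V @ W * 0.06  # ~6% multiplicative effect per planted sd
    rows = []
    for e in eff:
        row = {}
        for c, b in zip(cols, base.values()):
            if c == "articulation_offset":
                row[c] = b + e[cols.index(c)] * 10.0
            elif c == "symphyseal_angle":
                row[c] = float(np.clip(b * np.exp(e[cols.index(c)]), 5.0, 175.0))
            else:
                row[c] = b * np.exp(e[cols.index(c)])
        row["toothrow_length"] = min(row["toothrow_length"], 0.95 * row["jaw_length"])
        row["symphysis_length"] = min(row["symphysis_length"], 0.5 * row["jaw_length"])
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def simulate_dataset(config=None, **kwargs):
    """Generate a complete synthetic dataset from a :class:`SimConfig`."""
    if config is None:
        config = SimConfig(**kwargs)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    tree = simulate_tree(
        config.n_tips, config.birth_rate, config.death_rate,
        root_age=config.root_age, seed=seeds[0],
    )
    taxa = tree.tip_labels
    traits = simulate_bm_traits(tree, config.sigma2, root_state=2.0, seed=seeds[1])
    trait_df = pd.DataFrame(
        {"log10_femur_mm": [traits[t] for t in taxa]}, index=pd.Index(taxa, name="taxon")
    )
    rng = np.random.default_rng(seeds[2])
    miss = rng.random(len(taxa)) < config.missing_fraction
    trait_df["log10_femur_mm_observed"] = np.where(
        miss, np.nan, trait_df["log10_femur_mm"]
    )
    vectors, labels = simulate_measurement_groups(
        config.group_spec, taxa=taxa, seed=seeds[3]
    )
    meas = _jaw_measurements_from_vectors(vectors.values)
    meas.index = pd.Index(taxa, name="taxon")
    template = jaw_template()
    landmarks = simulate_landmark_set(
        template, config.deformation_scale, config.landmark_noise_sd,
        n=len(taxa), seed=seeds[5], taxa=taxa,
    )
    bins = default_bins()
    strat = {}
    for lf in tree.tree.leaf_node_iter():
        age = lf.age
        covering = [b for b in bins if b[0] >= age >= b[1]]
        if covering:
            strat[lf.taxon.label] = covering[0]
        else:
            strat[lf.taxon.label] = (age + 1.0, max(age - 1.0, 0.0))
    tree.tip_ranges = dict(strat)
    return SyntheticDataset(
        tree=tree,
        traits=trait_df,
        measurements=meas,
        true_labels=labels,
        landmarks=landmarks,
        strat_ranges=strat,
        config=config,
    )


def write_dataset(ds, outdir):
    """Write a dataset to disk: Newick, CSV tables, TPS landmarks, JSON sidecar."""
    from pathlib import Path

    from .geometry import write_tps
    from .phylo import write_newick

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(ds.tree, out / "tree.nwk")
    ds.traits.to_csv(out / "traits.csv")
    ds.measurements.to_csv(out / "measurements.csv")
    ds.true_labels.to_csv(out / "true_labels.csv")
    pd.DataFrame(
        [(t, f, l) for t, (f, l) in sorted(ds.strat_ranges.items())],
        columns=["taxon", "fad_ma", "lad_ma"],
    ).to_csv(out / "strat_ranges.csv", index=False)
    write_tps(ds.landmarks, out / "landmarks.tps")
    cfg = {k: v for k, v in vars(ds.config).items() if k != "group_spec"}
    with open(out / "sim_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2)
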