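"""End-to-end orchestration: data in, feeding-group report out.

Stage order follows the analysis design: data (synthetic or loaded) →
functional characters → Procrustes geometry → ordination → consensus
feeding groups and subgroups → jack-knifed LDA validation → MBL
time-scaling → body-size imputation → ancestral state estimation
(continuous GLS, discrete Mk, and LDA classification of reconstructed
scores) → disparity through time with macroevolutionary model comparison →
group statistics. One master seed deterministically spawns per-stage seeds,
so a fixed (config, seed) pair reproduces every numeric output byte for
byte.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asr import MK_MODELS, asr_bm_continuous, mk_fit, mk_marginal_asr, model_average_states
from .characters import DEFAULT_CHARACTERS, compute_functional_characters, z_standardise
from .classify import lda_classify, lda_fit_jackknife
from .clustering import DEFAULT_B, DEFAULT_K_RANGE, consensus_cluster, subcluster, validate_clusters
from .disparity import DEFAULT_BOOTSTRAP, disparity_through_time, fit_series_models, series_fit_table
from .geometry import gpa_align, read_tps, slide_semilandmarks
from .ordination import pca
from .phylo import bm_impute, mbl_timescale, read_newick, write_newick
from .stats import mann_whitney_pairwise, npmanova
from .synthdata import SimConfig, default_bins, simulate_dataset, write_dataset

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

STAGES = (
    "data",
    "characters",
    "geometry",
    "ordination",
    "clustering",
    "lda",
    "timescale",
    "imputation",
    "asr",
    "disparity",
    "stats",
)


@dataclass
class PipelineConfig:
    """All inputs and stage parameters for one pipeline run."""

    outdir: str
    seed: int
    synthetic: dict = None  # SimConfig fields; None => load from paths
    measurements_csv: str = None
    landmarks_tps: str = None
    tree_newick: str = None
    taxon_table_csv: str = None
    bins_csv: str = None
    stages: dict = field(default_factory=dict)  # stage -> bool toggles
    k_range: tuple = DEFAULT_K_RANGE
    B_gap: int = DEFAULT_B
    B_boot: int = DEFAULT_BOOTSTRAP
    mbl: float = 0.1
    slice_model: str = "proximity"
    character_set: tuple = DEFAULT_CHARACTERS
    mk_models: tuple = MK_MODELS
    mk_starts: int = 5
    restarts: int = 25
    consensus_threshold: float = 2.0 / 3.0
    n_permutations: int = 999
    rarefy: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if self.synthetic is None:
            missing = [
                nm
                for nm in ("measurements_csv", "tree_newick", "taxon_table_csv")
                if getattr(self, nm) is None
            ]
            if missing:
                raise ValueError(f"non-synthetic mode requires: {missing}")
            for nm in ("measurements_csv", "landmarks_tps", "tree_newick",
                       "taxon_table_csv", "bins_csv"):
                p = getattr(self, nm)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{nm}: {p}")

    def enabled(self, stage):
        return bool(self.stages.get(stage, True))

    @classmethod
    def from_file(cls, path, **overrides):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.update(overrides)
        return cls(**raw)


@dataclass
class RunReport:
    outdir: str
    seed: int
    stages: list = field(default_factory=list)  # {name, outputs, seconds, info}
    warnings: list = field(default_factory=list)
    config_echo: dict = None
    version: str = None

    def stage_names(self):
        return [s["name"] for s in self.stages]

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "outdir": self.outdir,
                    "seed": self.seed,
                    "stages": self.stages,
                    "warnings": self.warnings,
                    "config": self.config_echo,
                },
                fh,
                indent=2,
                default=str,
            )


def _csv(df, path):
    df.to_csv(path, float_format="%.12g")
    return str(path)


def run_pipeline(config):
    """Execute all enabled stages in dependency order.

    Any stage failure raises ``RuntimeError`` naming the stage. Returns a
    :class:`RunReport` listing one entry per executed stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGES, ss.spawn(len(STAGES)))
    }
    report = RunReport(outdir=str(out), seed=config.seed, version=__version__)
    cfg_echo = asdict(config)
    cfg_echo["k_range"] = list(config.k_range)
    report.config_echo = cfg_echo
    state = {}

    for stage in STAGES:
        if not config.enabled(stage):
            continue
        t0 = time.perf_counter()
        fn = _STAGE_FNS[stage]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                outputs, info = fn(config, state, seeds[stage], out)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
        for w in caught:
            report.warnings.append(f"{stage}: {w.message}")
        report.stages.append(
            {
                "name": stage,
                "outputs": outputs,
                "seconds": round(time.perf_counter() - t0, 3),
                "seed": seeds[stage],
                "info": info,
            }
        )
    report.write(out / "run_report.json")
    return report


# -- stages ----------------------------------------------------------------------


def _stage_data(config, state, seed, out):
    if config.synthetic is not None:
        sim = dict(config.synthetic)
        sim.setdefault("seed", seed)
        ds = simulate_dataset(SimConfig(**sim))
        ddir = out / "data"
        write_dataset(ds, ddir)
        state.update(
            tree=ds.tree,
            measurements=ds.measurements,
            landmarks=ds.landmarks,
            body_size=ds.traits["log10_femur_mm_observed"],
            true_labels=ds.true_labels,
            strat=ds.strat_ranges,
            bins=default_bins(),
        )
        outputs = [str(p) for p in sorted(ddir.iterdir())]
        info = {"mode": "synthetic", "n_taxa": ds.tree.n_tips}
    else:
        meas = pd.read_csv(config.measurements_csv, index_col=0)
        taxon = pd.read_csv(config.taxon_table_csv, index_col=0)
        tree = read_newick(config.tree_newick)
        landmarks = (
            read_tps(config.landmarks_tps) if config.landmarks_tps else None
        )
        strat = {
            t: (float(r["fad_ma"]), float(r["lad_ma"]))
            for t, r in taxon.iterrows()
        }
        tree.tip_ranges = strat
        bins = (
            [
                (float(r["older_ma"]), float(r["younger_ma"]))
                for _, r in pd.read_csv(config.bins_csv).iterrows()
            ]
            if config.bins_csv
            else default_bins()
        )
        size_col = next(
            (c for c in taxon.columns if "femur" in c or "size" in c), None
        )
        body = taxon[size_col] if size_col else None
        # pre-flight: the taxon sets of all inputs must agree
        sets = {"tree": set(tree.tip_labels), "measurements": set(meas.index),
                "taxon_table": set(taxon.index)}
        if landmarks is not None:
            sets["landmarks"] = {c.taxon_id for c in landmarks}
        ref = sets["tree"]
        mismatches = {
            name: sorted(ref ^ s) for name, s in sets.items() if s != ref
        }
        if mismatches:
            raise ValueError(f"inconsistent taxon sets across inputs: {mismatches}")
        state.update(
            tree=tree, measurements=meas, landmarks=landmarks,
            body_size=body, true_labels=None, strat=strat, bins=bins,
        )
        outputs = []
        info = {"mode": "files", "n_taxa": tree.n_tips}
    return outputs, info


def _stage_characters(config, state, seed, out):
    fcm = compute_functional_characters(
        state["measurements"], character_set=config.character_set
    )
    z = z_standardise(fcm)
    state["characters"] = fcm
    state["characters_z"] = z
    path = _csv(z.to_frame(), out / "functional_characters_z.csv")
    raw = _csv(fcm.to_frame(), out / "functional_characters.csv")
    return [raw, path], {"characters": list(fcm.characters)}


def _stage_geometry(config, state, seed, out):
    if state.get("landmarks") is None:
        state["alignment"] = None
        return [], {"skipped": "no landmark data"}
    aln = gpa_align(state["landmarks"])
    slid = slide_semilandmarks(aln)
    state["alignment"] = slid
    M, order = slid.matrix()
    rows = []
    for t in order:
        for i, (x, y) in enumerate(slid.aligned[t]):
            rows.append((t, i, x, y))
    df = pd.DataFrame(rows, columns=["taxon", "landmark", "x", "y"]).set_index("taxon")
    path = _csv(df, out / "aligned_coordinates.csv")
    return [path], {
        "gpa_iterations": aln.n_iterations,
        "slide_iterations": slid.n_iterations,
        "converged": bool(aln.converged and slid.converged),
    }


def _stage_ordination(config, state, seed, out):
    taxa = list(state["characters_z"].taxa)
    fz = state["characters_z"]
    fres = pca(fz.values, taxa=taxa, variables=list(fz.characters),
               center=True, scale=False, source="function")
    state["f_pca"] = fres
    outputs = [_csv(fres.scores_frame(), out / "function_pc_scores.csv")]
    info = {
        "function_var_pc12": float(fres.variance_proportions[:2].sum()),
    }
    if state.get("alignment") is not None:
        M, order = state["alignment"].matrix(order=taxa)
        sres = pca(M, taxa=taxa, center=True, scale=False, source="shape")
        state["s_pca"] = sres
        outputs.append(_csv(sres.scores_frame(), out / "shape_pc_scores.csv"))
        info["shape_var_pc12"] = float(sres.variance_proportions[:2].sum())
    else:
        state["s_pca"] = None
    return outputs, info


def _stage_clustering(config, state, seed, out):
    z = state["characters_z"]
    ffg = consensus_cluster(
        z.values, taxa=list(z.taxa), k_range=config.k_range, B=config.B_gap,
        seed=seed, threshold=config.consensus_threshold,
        restarts=config.restarts, level="FFG",
    )
    ffsg = subcluster(
        z.values, ffg, k_range=config.k_range, B=config.B_gap, seed=seed + 1,
        threshold=config.consensus_threshold, restarts=config.restarts,
    )
    state["ffg"] = ffg
    state["ffsg"] = ffsg
    df = pd.DataFrame(
        {
            "FFG": [ffg.labels[t] for t in ffg.taxa],
            "FFsG": [ffsg.labels[t] for t in ffg.taxa],
            "silhouette_FFG": [ffg.silhouette.get(t, np.nan) for t in ffg.taxa],
        },
        index=pd.Index(ffg.taxa, name="taxon"),
    )
    for sol in ffg.per_algorithm:
        df[f"label_{sol.algorithm}"] = [sol.labels[t] for t in ffg.taxa]
    path = _csv(df, out / "feeding_groups.csv")
    info = {
        "n_ffg": len(ffg.group_members()),
        "n_ffsg": len(ffsg.group_members()),
        "agreement_rate": ffg.agreement_rate,
    }
    if state.get("true_labels") is not None:
        truth = state["true_labels"]
        info["ffg_validation"] = {
            k: v
            for k, v in validate_clusters(
                ffg, z.values, truth["group"].to_dict()
            ).items()
            if k != "silhouette"
        }
    return [path], info


def _stage_lda(config, state, seed, out):
    scores = state["f_pca"].scores_frame()
    labels = {
        t: l for t, l in state["ffsg"].labels.items() if l != "unstable"
    }
    sub = scores.loc[sorted(labels, key=list(scores.index).index)]
    model, rep = lda_fit_jackknife(sub, labels)
    state["lda_model"] = model
    path = _csv(rep.confusion, out / "lda_confusion.csv")
    return [path], {
        "jackknife_rate": rep.overall_rate,
        "n_evaluated": rep.n_evaluated,
    }


def _stage_timescale(config, state, seed, out):
    tree = state["tree"]
    fads = {t: fad for t, (fad, lad) in state["strat"].items()}
    dated = mbl_timescale(tree, fads, mbl=config.mbl)
    dated.tip_ranges = dict(state["strat"])
    state["dated_tree"] = dated
    path = out / "timescaled_tree.nwk"
    write_newick(dated, path)
    bls = dated.branch_lengths().values()
    return [str(path)], {
        "min_branch_myr": float(min(bls)),
        "root_age_ma": float(dated.root_age),
    }


def _stage_imputation(config, state, seed, out):
    body = state.get("body_size")
    if body is None:
        state["body_complete"] = None
        return [], {"skipped": "no body-size data"}
    tree = state["dated_tree"]
    values, variances, s2, root = bm_impute(tree, body.to_dict())
    df = pd.DataFrame(
        {
            "log10_femur_mm": [values[t] for t in tree.tip_labels],
            "imputation_variance": [variances[t] for t in tree.tip_labels],
            "imputed": [
                not np.isfinite(body.get(t, np.nan)) for t in tree.tip_labels
            ],
        },
        index=pd.Index(tree.tip_labels, name="taxon"),
    )
    state["body_complete"] = df["log10_femur_mm"]
    path = _csv(df, out / "body_size_imputed.csv")
    return [path], {"sigma2_hat": s2, "n_imputed": int(df["imputed"].sum())}


def _stage_asr(config, state, seed, out):
    tree = state["dated_tree"]
    scores = state["f_pca"].scores_frame()
    cont = asr_bm_continuous(tree, scores)
    state["f_asr"] = cont
    outputs = [_csv(cont.estimates, out / "ancestral_function_scores.csv")]
    info = {}
    if state.get("body_complete") is not None:
        size_asr = asr_bm_continuous(tree, state["body_complete"].to_frame("size"))
        outputs.append(_csv(size_asr.estimates, out / "ancestral_body_size.csv"))
        state["size_asr"] = size_asr
    # ancestral subgroup membership: LDA on reconstructed scores
    if state.get("lda_model") is not None:
        labels, post = lda_classify(state["lda_model"], cont.estimates.to_numpy())
        anc = pd.DataFrame(
            post, index=cont.estimates.index, columns=state["lda_model"].class_ids
        )
        anc.insert(0, "FFsG_lda", labels)
        outputs.append(_csv(anc, out / "ancestral_ffsg_lda.csv"))
        state["anc_lda"] = anc
    # discrete Mk route with model averaging; consensus-unstable taxa get
    # their LDA-predicted subgroup so the state vector is complete
    tip_states = {
        t: l for t, l in state["ffsg"].labels.items() if l != "unstable"
    }
    if state.get("lda_model") is not None:
        unstable = [t for t in state["ffsg"].labels if t not in tip_states]
        if unstable:
            vecs = scores.loc[unstable].to_numpy()
            pred, _ = lda_classify(state["lda_model"], vecs)
            tip_states.update(dict(zip(unstable, pred)))
            info["mk_lda_filled"] = len(unstable)
    if len(set(tip_states.values())) >= 2 and len(tip_states) == tree.n_tips:
        per_model = []
        for m in config.mk_models:
            fit = mk_fit(tree, tip_states, model=m, n_starts=config.mk_starts,
                         seed=seed)
            per_model.append(mk_marginal_asr(tree, tip_states, fit))
            info[f"mk_{m}_aic"] = fit.aic
        avg = model_average_states(per_model)
        state["anc_mk"] = avg
        outputs.append(
            _csv(avg.node_probabilities, out / "ancestral_ffsg_mk_averaged.csv")
        )
    elif len(set(tip_states.values())) >= 2:
        # unstable taxa leave gaps the Mk reconstruction cannot use
        info["mk_skipped"] = "unstable taxa leave the state vector incomplete"
    return outputs, info


def _stage_disparity(config, state, seed, out):
    tree = state["dated_tree"]
    scores = state["f_pca"].scores_frame()
    node_values = {t: scores.loc[t].to_numpy() for t in scores.index}
    for nid in state["f_asr"].estimates.index:
        node_values[nid] = state["f_asr"].estimates.loc[nid].to_numpy()
    curve = disparity_through_time(
        tree, node_values, state["bins"], slice_model=config.slice_model,
        B=config.B_boot, rarefy=config.rarefy, seed=seed,
    )
    state["disparity"] = curve
    outputs = [_csv(curve.to_frame().set_index("bin_older_ma"),
                    out / "disparity_function.csv")]
    info = {"n_usable_bins": int(len(curve.usable()))}
    if len(curve.usable()) >= 5:
        fits = fit_series_models(curve)
        outputs.append(
            _csv(series_fit_table(fits).set_index("model"),
                 out / "disparity_model_fits.csv")
        )
        info["best_series_model"] = fits[0].model
        info["best_weight"] = fits[0].akaike_weight
    return outputs, info


def _stage_stats(config, state, seed, out):
    scores = state["f_pca"].scores_frame()
    groups = {
        t: l for t, l in state["ffg"].labels.items() if l != "unstable"
    }
    sub = scores.loc[[t for t in scores.index if t in groups]]
    res = npmanova(sub, groups, n_permutations=config.n_permutations, seed=seed)
    outputs = []
    if res.pairwise is not None:
        outputs.append(
            _csv(res.pairwise.set_index(["group_a", "group_b"]),
                 out / "npmanova_pairwise.csv")
        )
    info = {"pseudo_F": res.pseudo_F, "p_value": res.p_value}
    body = state.get("body_complete")
    if body is not None:
        by_bin = {}
        for t, (fad, lad) in state["strat"].items():
            for older, younger in state["bins"]:
                if older >= fad > younger:
                    by_bin.setdefault((older, younger), []).append(body[t])
                    break
        mw = mann_whitney_pairwise(
            {f"{o:.2f}-{y:.2f}": v for (o, y), v in by_bin.items() if len(v) >= 2}
        )
        if len(mw):
            outputs.append(
                _csv(mw.set_index(["bin_a", "bin_b"]),
                     out / "size_mannwhitney.csv")
            )
            info["n_size_pairs"] = int(len(mw))
    return outputs, info


_STAGE_FNS = {
    "data": _stage_data,
    "characters": _stage_characters,
    "geometry": _stage_geometry,
    "ordination": _stage_ordination,
    "clustering": _stage_clustering,
    "lda": _stage_lda,
    "timescale": _stage_timescale,
    "imputation": _stage_imputation,
    "asr": _stage_asr,
    "disparity": _stage_disparity,
    "stats": _stage_stats,
}
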