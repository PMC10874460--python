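"""Non-parametric group-difference tests.

One-way NPMANOVA (PERMANOVA) on Euclidean distances over ordination scores,
with pairwise comparisons under a Bonferroni correction, and pairwise
Mann-Whitney U tests for body-size differences across time bins. The
PERMANOVA permutation loop is vectorised against a fixed squared-distance
matrix; p-values use the add-one convention
``p = (1 + #{permuted F >= observed}) / (1 + n_permutations)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = ["PermanovaResult", "npmanova", "mann_whitney_pairwise"]

DEFAULT_PERMUTATIONS = 9999


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    n_groups: int
    pairwise: pd.DataFrame = None  # group pair -> F, raw p, adjusted p
    seed: int = None


def _batch_f(D2, perms, groups_idx, n):
    """Pseudo-F for a batch of label permutations (vectorised gather)."""
    g = len(groups_idx)
    sst = D2.sum() / (2.0 * n)
    ssw = np.zeros(len(perms))
    for idx in groups_idx:
        if len(idx) < 2:
            continue
        P = perms[:, idx]  # members of this group under each permutation
        ssw += D2[P[:, :, None], P[:, None, :]].sum(axis=(1, 2)) / (2.0 * len(idx))
    with np.errstate(divide="ignore"):
        F = ((sst - ssw) / (g - 1)) / (ssw / (n - g))
    F[ssw <= 0] = np.inf
    return F


def npmanova(scores, groups, n_permutations=DEFAULT_PERMUTATIONS, seed=None,
             pairwise=True, exhaustive=False):
    """One-way NPMANOVA on Euclidean distances with label permutation.

    Parameters
    ----------
    scores : array or DataFrame, taxa x variables.
    groups : mapping or array of group labels aligned with the rows.
    n_permutations : int
        Random label permutations; the observed labelling enters through
        the add-one convention ``p = (1 + #{F* >= F}) / (1 + B)``.
    pairwise : bool
        Run all group-pair tests with Bonferroni-adjusted p-values; groups
        of size 1 are excluded with a warning.
    exhaustive : bool
        Enumerate every permutation of the labels instead of sampling
        (feasible only for tiny n); the p-value is then the exact
        proportion of permutations, identity included, with F* >= F.
    """
    if isinstance(scores, pd.DataFrame):
        X = scores.to_numpy(dtype=float)
        labels = np.asarray([groups[t] for t in scores.index])
    else:
        X = np.asarray(scores, dtype=float)
        labels = np.asarray(groups)
    n = len(X)
    cats = sorted(set(labels))
    if len(cats) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {c: int(np.sum(labels == c)) for c in cats}
    if all(s < 2 for s in sizes.values()):
        raise ValueError("every group has fewer than 2 members")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    rng = np.random.default_rng(seed)

    def perm_test(idx_all, labs):
        nn = len(idx_all)
        D2 = sq[np.ix_(idx_all, idx_all)]
        cats_l = sorted(set(labs))
        groups_idx = [np.flatnonzero(labs == c) for c in cats_l]
        f_obs = float(_batch_f(D2, np.arange(nn)[None, :], groups_idx, nn)[0])
        if exhaustive:
            if nn > 9:
                raise ValueError("exhaustive enumeration is limited to n <= 9")
            perms = np.array(list(itertools.permutations(range(nn))))
            F = _batch_f(D2, perms, groups_idx, nn)
            return f_obs, float(np.mean(F >= f_obs - 1e-12))
        perms = np.argsort(rng.random((n_permutations, nn)), axis=1)
        F = _batch_f(D2, perms, groups_idx, nn)
        count = int(np.sum(F >= f_obs - 1e-12))
        return f_obs, (1.0 + count) / (1.0 + n_permutations)

    f_obs, p = perm_test(np.arange(n), labels)

    pw = None
    if pairwise:
        eligible = [c for c in cats if sizes[c] >= 2]
        dropped = [c for c in cats if sizes[c] < 2]
        if dropped:
            warnings.warn(f"groups of size 1 excluded from pairwise tests: {dropped}")
        pairs = list(itertools.combinations(eligible, 2))
        rows = []
        for a, b in pairs:
            idx = np.flatnonzero((labels == a) | (labels == b))
            f_ab, p_ab = perm_test(idx, labels[idx])
            rows.append((a, b, f_ab, p_ab))
        m = len(pairs)
        pw = pd.DataFrame(rows, columns=["group_a", "group_b", "F", "p_raw"])
        pw["p_bonferroni"] = np.minimum(pw["p_raw"] * m, 1.0)
    return PermanovaResult(
        pseudo_F=float(f_obs), p_value=float(p),
        n_permutations=n_permutations, n_groups=len(cats),
        pairwise=pw, seed=seed,
    )


def mann_whitney_pairwise(values_by_bin, exact_max=400):
    """Pairwise Mann-Whitney U tests across time bins with Bonferroni.

    Bins with fewer than 2 values are excluded from testing. The exact null
    distribution is used when ``n1 * n2 <= exact_max`` and the samples are
    tie-free; otherwise the tie-corrected normal approximation applies.
    Fully tied pairs get p = 1 with a warning.
    """
    keys = list(values_by_bin)
    usable = [k for k in keys if len(values_by_bin[k]) >= 2]
    pairs = list(itertools.combinations(usable, 2))
    rows = []
    for a, b in pairs:
        xa = np.asarray(values_by_bin[a], dtype=float)
        xb = np.asarray(values_by_bin[b], dtype=float)
        ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
        if ties and len(np.unique(np.concatenate([xa, xb]))) == 1:
            warnings.warn(f"bins {a!r} vs {b!r}: all values tied; p = 1")
            rows.append((a, b, len(xa) * len(xb) / 2.0, 1.0))
            continue
        method = "exact" if (len(xa) * len(xb) <= exact_max and not ties) else "asymptotic"
        res = mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    m = len(rows)
    out = pd.DataFrame(rows, columns=["bin_a", "bin_b", "U", "p_raw"])
    if m:
        out["p_bonferroni"] = np.minimum(out["p_raw"] * m, 1.0)
    else:
        out["p_bonferroni"] = pd.Series(dtype=float)
    return out
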