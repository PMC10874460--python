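"""Landmark geometry: TPS I/O, generalized Procrustes analysis (GPA), and
chord-based sliding of semi-landmarks.

The landmarking scheme is 59 two-dimensional points per jaw: 4 fixed
homologous landmarks joined by 4 outline curves carrying 55 semi-landmarks in
total. GPA removes position, size and orientation; sliding then lets each
semi-landmark move along the chord through its two curve neighbours to the
position closest to the corresponding mean-shape point, iterating slide and
re-superimposition to convergence. Fixed landmarks never move.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "ProcrustesAlignment",
    "read_tps",
    "write_tps",
    "gpa_align",
    "slide_semilandmarks",
    "procrustes_distance",
]

N_LANDMARKS = 59
N_FIXED = 4
N_SEMI = 55


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark set in image units.

    ``curves`` are ordered index lists; each starts and ends at a fixed
    landmark with the interior indices being semi-landmarks on that curve.
    """

    taxon_id: str
    coords: np.ndarray  # (59, 2)
    fixed_indices: list
    curves: list
    scale: float = None
    image: str = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"{self.taxon_id}: expected {N_LANDMARKS} landmarks, "
                f"got {self.coords.shape[0]}"
            )
        fixed = set(self.fixed_indices)
        if len(fixed) != N_FIXED:
            raise ValueError(f"{self.taxon_id}: need {N_FIXED} fixed landmarks")
        semi = set()
        for c in self.curves:
            if len(c) < 3:
                raise ValueError(f"{self.taxon_id}: curve with < 3 points")
            semi.update(i for i in c if i not in fixed)
        if len(self.curves) != 4 or len(semi) != N_SEMI or semi & fixed:
            raise ValueError(
                f"{self.taxon_id}: fixed/semi-landmark partition invalid"
            )

    @property
    def semi_indices(self):
        fixed = set(self.fixed_indices)
        out = []
        for c in self.curves:
            out.extend(i for i in c if i not in fixed)
        return out

    def centroid_size(self):
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c**2).sum()))


@dataclass
class ProcrustesAlignment:
    """Superimposed coordinates in dimensionless Procrustes units."""

    aligned: dict  # taxon -> (59, 2)
    centroid_sizes: dict  # taxon -> positive scalar (pre-scaling size)
    mean_shape: np.ndarray
    n_iterations: int
    converged: bool
    curves: list = None
    fixed_indices: list = None

    def matrix(self, order=None):
        """Taxa x 118 flattened coordinate matrix (row order = ``order``)."""
        order = list(self.aligned) if order is None else order
        return np.asarray([self.aligned[t].ravel() for t in order]), order


# -- TPS I/O --------------------------------------------------------------------

_KEY_RE = re.compile(r"^\s*([A-Z]+)\s*=\s*(.*)\s*$")


def read_tps(path, fixed_indices=(0, 1, 2, 3), curves=None, expected_lm=N_LANDMARKS):
    """Parse a TPS file (LM=, coordinate rows, ID=/IMAGE=/SCALE= records).

    Curve topology is not part of the TPS dialect used here and is supplied
    via ``curves`` (defaulting to the package's jaw template layout).
    Malformed lines raise with their line number; a record whose LM count
    differs from ``expected_lm`` raises naming the specimen.
    """
    if curves is None:
        from .synthdata import jaw_template

        curves = [list(c) for c in jaw_template().curves]
    configs = []
    record = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _KEY_RE.match(line)
            if m:
                key, val = m.group(1), m.group(2)
                if key == "LM":
                    if record is not None:
                        configs.append(_finish_record(record, fixed_indices, curves))
                    record = {"lm": int(val), "pts": [], "line": ln}
                elif record is None:
                    raise ValueError(f"line {ln}: {key}= before any LM= record")
                elif key == "ID":
                    record["id"] = val
                elif key == "IMAGE":
                    record["image"] = val
                elif key == "SCALE":
                    record["scale"] = float(val)
                else:
                    raise ValueError(f"line {ln}: unknown TPS field {key!r}")
            else:
                if record is None:
                    raise ValueError(f"line {ln}: coordinates before LM= header")
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"line {ln}: malformed coordinate row {line!r}")
                try:
                    record["pts"].append((float(parts[0]), float(parts[1])))
                except ValueError as e:
                    raise ValueError(f"line {ln}: non-numeric coordinate") from e
    if record is not None:
        configs.append(_finish_record(record, fixed_indices, curves))
    for cfg in configs:
        if cfg.coords.shape[0] != expected_lm:
            raise ValueError(
                f"record {cfg.taxon_id!r}: LM={cfg.coords.shape[0]}, "
                f"expected {expected_lm}"
            )
    return configs


def _finish_record(record, fixed_indices, curves):
    n = len(record["pts"])
    if n != record["lm"]:
        raise ValueError(
            f"record starting at line {record['line']} "
            f"({record.get('id', '?')!r}): LM={record['lm']} but {n} rows"
        )
    if record["lm"] != N_LANDMARKS:
        raise ValueError(
            f"record {record.get('id', '?')!r}: LM={record['lm']}, "
            f"expected {N_LANDMARKS}"
        )
    return LandmarkConfiguration(
        taxon_id=record.get("id", record.get("image", "unnamed")),
        coords=np.asarray(record["pts"]),
        fixed_indices=list(fixed_indices),
        curves=[list(c) for c in curves],
        scale=record.get("scale"),
        image=record.get("image"),
    )


def write_tps(configs, path):
    """Write configurations in canonical TPS formatting (round-trips with
    :func:`read_tps`)."""
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={len(cfg.coords)}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.6f} {y:.6f}\n")
            if cfg.image:
                fh.write(f"IMAGE={cfg.image}\n")
            fh.write(f"ID={cfg.taxon_id}\n")
            if cfg.scale is not None:
                fh.write(f"SCALE={cfg.scale:.6f}\n")


# -- Procrustes ------------------------------------------------------------------


def _center_scale(X):
    Xc = X - X.mean(axis=0)
    size = np.sqrt((Xc**2).sum())
    if size < 1e-12:
        raise ValueError("degenerate configuration: all points coincident")
    return Xc / size, size


def _optimal_rotation(X, ref):
    """Rotation (det +1, no reflection) carrying X closest to ref."""
    H = X.T @ ref
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def procrustes_distance(A, B):
    """Ordinary (partial, two-form) Procrustes distance between two shapes."""
    Ac, _ = _center_scale(np.asarray(A, dtype=float))
    Bc, _ = _center_scale(np.asarray(B, dtype=float))
    R = _optimal_rotation(Ac, Bc)
    return float(np.sqrt(((Ac @ R - Bc) ** 2).sum()))


def gpa_align(configs, tol=1e-8, max_iter=100):
    """Generalized Procrustes superimposition.

    Translates each configuration to the origin, scales to unit centroid
    size, and iteratively rotates to the re-estimated mean shape until the
    mean moves by less than ``tol`` (Procrustes distance). Reflections are
    not allowed.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations")
    ids = [c.taxon_id for c in configs]
    sizes = {}
    shapes = []
    for c in configs:
        Xc, size = _center_scale(c.coords)
        sizes[c.taxon_id] = size
        shapes.append(Xc)
    mean = shapes[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        shapes = [X @ _optimal_rotation(X, mean) for X in shapes]
        new_mean = np.mean(shapes, axis=0)
        new_mean, _ = _center_scale(new_mean)
        delta = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if delta < tol:
            converged = True
            break
    first = configs[0]
    return ProcrustesAlignment(
        aligned={i: X for i, X in zip(ids, shapes)},
        centroid_sizes=sizes,
        mean_shape=np.mean(shapes, axis=0),
        n_iterations=it,
        converged=converged,
        curves=[list(c) for c in first.curves],
        fixed_indices=list(first.fixed_indices),
    )


def _slide_once(X, mean, curves, fixed):
    """Project the mean's semi-landmark targets onto each point's chord.

    For semi-landmark j with curve neighbours p (previous) and q (next), the
    new position is the orthogonal projection of the mean-shape point onto
    the segment p-q (clamped to the segment so curves cannot invert).
    Neighbours are taken from the configuration's current positions; fixed
    landmarks serve as neighbours at curve ends and never move themselves.
    """
    out = X.copy()
    for curve in curves:
        for k in range(1, len(curve) - 1):
            j = curve[k]
            if j in fixed:
                continue
            p = X[curve[k - 1]]
            q = X[curve[k + 1]]
            d = q - p
            L2 = float(d @ d)
            if L2 < 1e-24:
                continue
            t = float((mean[j] - p) @ d) / L2
            t = min(max(t, 0.0), 1.0)
            out[j] = p + t * d
    return out


def slide_semilandmarks(alignment, curves=None, tol=1e-8, max_iter=10):
    """Iteratively slide semi-landmarks along their chords, re-superimposing
    after each pass, until the mean shape stabilises.

    The iteration count is bounded and small by default: chord sliding
    against a re-estimated mean admits slow cumulative drift of points along
    their curves, and almost all of the fit improvement happens in the first
    few passes. Returns a new :class:`ProcrustesAlignment`; the four fixed
    landmarks are bitwise unchanged by the sliding step itself
    (superimposition still rotates whole configurations).
    """
    curves = curves if curves is not None else alignment.curves
    if curves is None:
        raise ValueError("curve topology required for sliding")
    fixed = set(alignment.fixed_indices or [])
    ids = list(alignment.aligned)
    shapes = {t: alignment.aligned[t].copy() for t in ids}
    mean = alignment.mean_shape.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        slid = {t: _slide_once(shapes[t], mean, curves, fixed) for t in ids}
        # re-superimpose (rotation only; scale/centering already standard)
        arr = []
        for t in ids:
            X = slid[t] - slid[t].mean(axis=0)
            norm = np.sqrt((X**2).sum())
            X = X / norm
            arr.append(X @ _optimal_rotation(X, mean))
        new_mean = np.mean(arr, axis=0)
        new_mean, _ = _center_scale(new_mean)
        delta = np.sqrt(((new_mean - mean) ** 2).sum())
        shapes = {t: A for t, A in zip(ids, arr)}
        mean = new_mean
        if delta < tol:
            converged = True
            break
    return ProcrustesAlignment(
        aligned=shapes,
        centroid_sizes=dict(alignment.centroid_sizes),
        mean_shape=np.mean([shapes[t] for t in ids], axis=0),
        n_iterations=it,
        converged=converged,
        curves=[list(c) for c in curves],
        fixed_indices=list(alignment.fixed_indices or []),
    )
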