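"""Standardised functional measurements (SFMs) of the lower jaw.

From raw linear jaw measurements (lever arms, lengths, depths, the
symphyseal angle) this module computes dimensionless functional characters
in the standard lower-jaw biomechanics convention:

====  =======================================  =================================
code  character                                definition
====  =======================================  =================================
MAMA  mean anterior mechanical advantage       mean over adductor attachment
                                               arms of in-lever / anterior
                                               out-lever
MPMA  mean posterior mechanical advantage      mean over arms of in-lever /
                                               posterior out-lever
OMA   opening mechanical advantage             opening in-lever / anterior
                                               out-lever
MAR   maximum aspect ratio                     max jaw depth / jaw length
RTL   relative toothrow length                 toothrow length / jaw length
RSL   relative symphyseal length               symphysis length / jaw length
SA    symphyseal angle                         degrees, used as-is
RAO   relative articulation offset             articulation offset / jaw length
SR    symphyseal robusticity                   symphysis depth / symphysis
                                               length
====  =======================================  =================================

High mechanical advantage marks bite force, low marks bite speed. The
default character set is all of the above except SR; the set is configurable
because different analyses use eight or nine of the characters. The MAMA /
MPMA averaging convention (over attachment arms, the default, or over
toothrow positions via a caller-supplied table) is also pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ALL_CHARACTERS",
    "DEFAULT_CHARACTERS",
    "RAW_COLUMNS",
    "FunctionalCharacterMatrix",
    "validate_raw_measurements",
    "compute_functional_characters",
    "z_standardise",
]

ALL_CHARACTERS = ("MAMA", "MPMA", "OMA", "MAR", "RTL", "RSL", "SA", "RAO", "SR")
DEFAULT_CHARACTERS = ("MAMA", "MPMA", "OMA", "MAR", "RTL", "RSL", "SA", "RAO")

RAW_COLUMNS = (
    "jaw_length",
    "anterior_out_lever",
    "posterior_out_lever",
    "closing_in_lever_a",
    "closing_in_lever_b",
    "opening_in_lever",
    "toothrow_length",
    "symphysis_length",
    "symphysis_depth",
    "max_depth",
    "articulation_offset",
    "symphyseal_angle",
)


@dataclass
class FunctionalCharacterMatrix:
    """Taxa x functional-character matrix, raw or z-scored."""

    taxa: list
    characters: list
    values: np.ndarray
    standardised: bool = False
    column_means: np.ndarray = None
    column_sds: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("values shape inconsistent with taxa/characters")
        if not np.isfinite(self.values).all():
            raise ValueError("functional character matrix contains missing cells")

    def to_frame(self):
        return pd.DataFrame(
            self.values, index=pd.Index(self.taxa, name="taxon"),
            columns=list(self.characters),
        )

    def inverse_transform(self):
        """Undo z-standardisation (requires stored means/sds)."""
        if not self.standardised:
            return self
        vals = self.values * self.column_sds + self.column_means
        return FunctionalCharacterMatrix(
            taxa=list(self.taxa), characters=list(self.characters), values=vals
        )


def validate_raw_measurements(raw):
    """Check a raw jaw-measurement table (one row per taxon).

    All lengths must be positive (articulation offset may take any sign),
    the toothrow and symphysis cannot exceed the jaw length, and the
    symphyseal angle must lie in (0, 180) degrees.
    """
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"raw measurement table missing columns: {missing}")
    lengths = [c for c in RAW_COLUMNS if c not in ("articulation_offset", "symphyseal_angle")]
    for c in lengths:
        bad = raw.index[raw[c] <= 0]
        if len(bad):
            raise ValueError(f"non-positive {c} for taxa {list(bad)}")
    bad = raw.index[raw["toothrow_length"] > raw["jaw_length"] * (1 + 1e-9)]
    if len(bad):
        raise ValueError(f"toothrow longer than jaw for taxa {list(bad)}")
    bad = raw.index[raw["symphysis_length"] > raw["jaw_length"] * (1 + 1e-9)]
    if len(bad):
        raise ValueError(f"symphysis longer than jaw for taxa {list(bad)}")
    ang = raw["symphyseal_angle"]
    bad = raw.index[(ang <= 0) | (ang >= 180)]
    if len(bad):
        raise ValueError(f"symphyseal angle outside (0, 180) for taxa {list(bad)}")
    return raw


def compute_functional_characters(raw, character_set=DEFAULT_CHARACTERS,
                                  ma_mean="arms", n_toothrow_positions=20):
    """Compute the functional character matrix from raw measurements.

    Parameters
    ----------
    raw : pd.DataFrame
        One row per taxon, columns as in :data:`RAW_COLUMNS`.
    character_set : sequence of character codes
        Any subset of :data:`ALL_CHARACTERS`.
    ma_mean : {"arms", "toothrow"}
        How MAMA/MPMA average: over the two adductor attachment arms at the
        anterior/posterior bite points (default), or additionally over
        ``n_toothrow_positions`` equally spaced bite points along the
        toothrow (anterior half for MAMA, posterior half for MPMA).
    """
    unknown = [c for c in character_set if c not in ALL_CHARACTERS]
    if unknown:
        raise ValueError(f"undefined characters requested: {unknown}")
    if ma_mean not in ("arms", "toothrow"):
        raise ValueError(f"unknown ma_mean convention {ma_mean!r}")
    validate_raw_measurements(raw)
    bad = raw.index[(raw["anterior_out_lever"] <= 0) | (raw["posterior_out_lever"] <= 0)]
    if len(bad):
        raise ValueError(f"zero out-lever for taxa {list(bad)}")

    def _ma(r, anterior):
        in_lever = 0.5 * (r.closing_in_lever_a + r.closing_in_lever_b)
        if ma_mean == "arms":
            out = r.anterior_out_lever if anterior else r.posterior_out_lever
            return in_lever / out
        # averaging over bite points along the relevant toothrow half
        s = np.linspace(0.0, 1.0, n_toothrow_positions)
        lo, hi = (0.5, 1.0) if anterior else (0.0, 0.5)
        frac = lo + (hi - lo) * s
        out = (
            r.posterior_out_lever.to_numpy()[:, None]
            + frac[None, :]
            * (r.anterior_out_lever - r.posterior_out_lever).to_numpy()[:, None]
        )
        ma = in_lever.to_numpy()[:, None] / out
        return pd.Series(ma.mean(axis=1), index=r.index)

    defs = {
        "MAMA": lambda r: _ma(r, anterior=True),
        "MPMA": lambda r: _ma(r, anterior=False),
        "OMA": lambda r: r.opening_in_lever / r.anterior_out_lever,
        "MAR": lambda r: r.max_depth / r.jaw_length,
        "RTL": lambda r: r.toothrow_length / r.jaw_length,
        "RSL": lambda r: r.symphysis_length / r.jaw_length,
        "SA": lambda r: r.symphyseal_angle,
        "RAO": lambda r: r.articulation_offset / r.jaw_length,
        "SR": lambda r: r.symphysis_depth / r.symphysis_length,
    }
    cols = {c: defs[c](raw) for c in character_set}
    values = np.column_stack([cols[c].to_numpy() for c in character_set])
    return FunctionalCharacterMatrix(
        taxa=list(raw.index), characters=list(character_set), values=values
    )


def z_standardise(matrix):
    """Centre each character and scale by its sample (n-1) standard deviation.

    Column means and sds are retained so the transform is invertible.
    Constant columns are rejected by name.
    """
    if matrix.standardised:
        raise ValueError("matrix already standardised")
    if len(matrix.taxa) < 2:
        raise ValueError("need at least 2 taxa to standardise")
    means = matrix.values.mean(axis=0)
    sds = matrix.values.std(axis=0, ddof=1)
    # constant up to floating-point noise counts as constant
    tol = 1e-12 * np.maximum(1.0, np.abs(means))
    const = [c for c, s, t in zip(matrix.characters, sds, tol) if s <= t]
    if const:
        raise ValueError(f"constant character column(s): {const}")
    vals = (matrix.values - means) / sds
    return FunctionalCharacterMatrix(
        taxa=list(matrix.taxa),
        characters=list(matrix.characters),
        values=vals,
        standardised=True,
        column_means=means,
        column_sds=sds,
    )
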