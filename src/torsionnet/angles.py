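"""Torsion-angle codec and periodicity-aware evaluation.

Backbone phi/psi angles live on the circle, conventionally reported in
degrees in (-180, 180].  Networks predict the four trigonometric targets
sin(phi), cos(phi), sin(psi), cos(psi); decoding uses the two-argument
arctangent so the quadrant is always recovered.  Errors are range-reduced
before averaging so that no single-residue error can exceed 180 degrees.

The first residue of a chain has no phi (no preceding C atom) and the last
has no psi; undefined angles are carried as an explicit mask and excluded
from losses and MAE.  Angle tables on disk use the ``NA`` convention for
them; a literal 360.0 (the DSSP placeholder) is also mapped to undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TorsionPair",
    "AngleTable",
    "encode_angles",
    "decode_angles",
    "wrap_error",
    "mean_absolute_error",
    "paired_t_test",
    "circular_mean_deg",
    "read_angle_table",
    "write_angle_table",
]

_DSSP_UNDEFINED = 360.0


@dataclass(frozen=True)
class TorsionPair:
    """One residue's backbone torsion angles in degrees.

    Defined angles lie in (-180, 180].  ``phi_defined`` is False for the
    first residue of a chain, ``psi_defined`` for the last.
    """

    phi_deg: float
    psi_deg: float
    phi_defined: bool = True
    psi_defined: bool = True

    def __post_init__(self) -> None:
        for value, defined, name in (
            (self.phi_deg, self.phi_defined, "phi"),
            (self.psi_deg, self.psi_defined, "psi"),
        ):
            if defined and not (-180.0 < value <= 180.0):
                raise ValueError(f"{name}={value!r} outside (-180, 180]")


@dataclass
class AngleTable:
    """Per-residue phi/psi angles for one protein chain.

    ``phi``/``psi`` are degree arrays of length L; undefined entries hold
    NaN and are flagged False in the corresponding mask.
    """

    phi: np.ndarray
    psi: np.ndarray
    phi_defined: np.ndarray
    psi_defined: np.ndarray
    aa: list[str] | None = None
    protein_id: str = ""

    def __len__(self) -> int:
        return self.phi.shape[0]

    @classmethod
    def from_arrays(cls, phi, psi, aa=None, protein_id: str = "") -> "AngleTable":
        """Build a table from degree arrays, inferring masks from NaN/360."""
        phi = np.asarray(phi, dtype=float).copy()
        psi = np.asarray(psi, dtype=float).copy()
        phi_def = np.isfinite(phi) & (phi != _DSSP_UNDEFINED)
        psi_def = np.isfinite(psi) & (psi != _DSSP_UNDEFINED)
        phi[~phi_def] = np.nan
        psi[~psi_def] = np.nan
        return cls(phi, psi, phi_def, psi_def, aa=aa, protein_id=protein_id)


def _check_range(angle_deg: float, name: str) -> None:
    if not np.isfinite(angle_deg):
        raise ValueError(f"{name} must be finite, got {angle_deg!r}")
    if not (-180.0 < angle_deg <= 180.0):
        raise ValueError(f"{name}={angle_deg!r} outside (-180, 180]")


def encode_angles(pair: TorsionPair) -> np.ndarray:
    """Encode a residue's angles as (sin phi, cos phi, sin psi, cos psi).

    Undefined angles yield NaN in their two slots; downstream losses mask
    them out.
    """
    out = np.full(4, np.nan)
    if pair.phi_defined:
        _check_range(pair.phi_deg, "phi")
        r = np.deg2rad(pair.phi_deg)
        out[0], out[1] = np.sin(r), np.cos(r)
    if pair.psi_defined:
        _check_range(pair.psi_deg, "psi")
        r = np.deg2rad(pair.psi_deg)
        out[2], out[3] = np.sin(r), np.cos(r)
    return out


def _decode_one(s: float, c: float) -> float:
    if s == 0.0 and c == 0.0:
        raise ValueError("cannot decode angle from (sin, cos) = (0, 0)")
    deg = np.rad2deg(np.arctan2(s, c))
    # atan2 returns [-180, 180]; fold the closed lower end onto +180
    if deg <= -180.0:
        deg = 180.0
    return float(deg)


def decode_angles(target) -> TorsionPair:
    """Decode a 4-vector of trig targets back to degrees in (-180, 180].

    Uses atan2(sin, cos), so the raw network outputs need not be
    normalized to the unit circle.  NaN slots decode to undefined angles.
    """
    t = np.asarray(target, dtype=float)
    if t.shape != (4,):
        raise ValueError(f"expected a 4-vector, got shape {t.shape}")
    phi_def = np.isfinite(t[0]) and np.isfinite(t[1])
    psi_def = np.isfinite(t[2]) and np.isfinite(t[3])
    phi = _decode_one(t[0], t[1]) if phi_def else np.nan
    psi = _decode_one(t[2], t[3]) if psi_def else np.nan
    return TorsionPair(phi, psi, phi_def, psi_def)


def wrap_error(pred_deg, true_deg):
    """Signed angular difference pred - true, range-reduced to (-180, 180].

    Equivalent to shifting the prediction by the multiple of 360 that
    minimises |pred + 360k - true|; the magnitude never exceeds 180.
    Accepts scalars or arrays.
    """
    p = np.asarray(pred_deg, dtype=float)
    t = np.asarray(true_deg, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(t))):
        raise ValueError("wrap_error requires finite inputs")
    d = p - t
    w = np.mod(d + 180.0, 360.0) - 180.0  # [-180, 180)
    w = np.where(w == -180.0, 180.0, w)
    if np.isscalar(pred_deg) and np.isscalar(true_deg):
        return float(w)
    return w


def mean_absolute_error(preds, trues, mask=None) -> float:
    """Wrapped MAE in degrees over unmasked residue angles."""
    p = np.asarray(preds, dtype=float)
    t = np.asarray(trues, dtype=float)
    if p.shape != t.shape:
        raise ValueError("preds and trues must have equal length")
    if mask is None:
        mask = np.ones(p.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no unmasked entries to average over")
    return float(np.mean(np.abs(wrap_error(p[mask], t[mask]))))


def paired_t_test(errors_a, errors_b) -> float:
    """Two-sided paired t-test p-value on per-residue absolute errors.

    The pairing is by residue: entry i of both series refers to the same
    residue-angle.  If every pairwise difference is exactly zero the test
    statistic is undefined; by convention p = 1 is returned (no evidence
    of a difference), so model-comparison tables never abort.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("error series must be 1-D and equally long")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if np.all(a == b):
        return 1.0
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, result in (-180, 180]."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("circular mean of empty set")
    r = np.deg2rad(a)
    return _decode_one(float(np.mean(np.sin(r))), float(np.mean(np.cos(r))))


# ---------------------------------------------------------------------------
# TSV interface: columns chain_pos (1-based), aa, phi, psi; NA for undefined.

def write_angle_table(table: AngleTable, path) -> None:
    aa = table.aa if table.aa is not None else ["X"] * len(table)
    df = pd.DataFrame(
        {
            "chain_pos": np.arange(1, len(table) + 1),
            "aa": aa,
            "phi": [f"{v:.4f}" if d else "NA" for v, d in zip(table.phi, table.phi_defined)],
            "psi": [f"{v:.4f}" if d else "NA" for v, d in zip(table.psi, table.psi_defined)],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_angle_table(path, protein_id: str = "") -> AngleTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    phi = df["phi"].to_numpy(dtype=float)
    psi = df["psi"].to_numpy(dtype=float)
    return AngleTable.from_arrays(phi, psi, aa=list(df["aa"]), protein_id=protein_id)
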