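"""Per-residue feature assembly and sliding-window extraction.

Each residue is described by 56 normalized numbers drawn from seven
sources: the PSSM profile (20), physicochemical descriptors (7), 8-state
secondary structure (8), 15-class contact-number probabilities (15),
solvent accessibility (1), disorder probability (1) and the
fragment-derived angle feature (4).  A sliding window of odd width w
concatenates the vectors of residues i-k .. i+k (k = (w-1)/2) into the
network input for residue i; positions beyond the chain ends contribute
zero vectors.

The fragment feature summarises how far the fragment-library angle guess
for a residue typically sits from the truth: for residue type r with
fragment prediction P, alpha = wrap(P - avg_r) where avg_r is the mean
signed fragment error for that type, and the emitted features are
(sin alpha + 1)/2 and (cos alpha + 1)/2 for phi and psi.  Seven residue
types (C, D, G, H, N, S, T) have error distributions too irregular to
summarise by a mean; their avg and std are fixed at zero.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import wrap_error
from .physchem import AMINO_ACIDS, AA_INDEX, PHYSCHEM_SCALED

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureLayout",
    "LAYOUT_V1",
    "FeatureMatrix",
    "ErrorDistributionTable",
    "WindowConfig",
    "ZERO_SET",
    "normalize_pssm",
    "parse_pssm",
    "estimate_error_distribution",
    "fragment_mean_angles",
    "fragment_feature",
    "build_residue_features",
    "extract_windows",
]

#: Residue types whose fragment-error distribution is treated as degenerate.
ZERO_SET = frozenset("CDGHNST")


@dataclass(frozen=True)
class FeatureLayout:
    """Ordered feature blocks and their widths; the default totals 56."""

    version: str = "v1"
    blocks: tuple[tuple[str, int], ...] = (
        ("pssm", 20),
        ("physchem", 7),
        ("ss8", 8),
        ("cn15", 15),
        ("sa", 1),
        ("disorder", 1),
        ("fragsion", 4),
    )

    @property
    def width(self) -> int:
        return sum(w for _, w in self.blocks)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.blocks)

    def block_width(self, name: str) -> int:
        for n, w in self.blocks:
            if n == name:
                return w
        raise KeyError(name)

    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, w in self.blocks:
            out[name] = slice(start, start + w)
            start += w
        return out

    def subset(self, names) -> "FeatureLayout":
        """Layout restricted to the given blocks, preserving order."""
        keep = [b for b in self.blocks if b[0] in set(names)]
        if not keep:
            raise ValueError("subset would be empty")
        return FeatureLayout(version=f"{self.version}:{'+'.join(n for n, _ in keep)}",
                             blocks=tuple(keep))


LAYOUT_V1 = FeatureLayout()


@dataclass
class FeatureMatrix:
    """L x width normalized feature grid for one protein."""

    protein_id: str
    values: np.ndarray
    layout: FeatureLayout = field(default_factory=FeatureLayout)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.layout.width:
            raise ValueError(
                f"feature matrix must be L x {self.layout.width}, got {self.values.shape}"
            )
        if not (1 <= self.values.shape[0] <= 10000):
            raise ValueError("protein length out of supported range [1, 10000]")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("feature values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class ErrorDistributionTable:
    """Per-residue-type fragment-error statistics (degrees).

    ``zero_set`` rows have avg = std = 0 by construction regardless of the
    observed errors.
    """

    avg_phi: np.ndarray
    std_phi: np.ndarray
    avg_psi: np.ndarray
    std_psi: np.ndarray
    zero_set: np.ndarray  # bool per type, AMINO_ACIDS order

    def row(self, aa: str):
        i = AA_INDEX.get(aa)
        if i is None:
            raise ValueError(f"unknown residue type {aa!r}")
        return self.avg_phi[i], self.std_phi[i], self.avg_psi[i], self.std_psi[i]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "aa": list(AMINO_ACIDS),
                "avg_phi": self.avg_phi,
                "std_phi": self.std_phi,
                "avg_psi": self.avg_psi,
                "std_psi": self.std_psi,
                "zero_set": self.zero_set.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ErrorDistributionTable":
        df = pd.read_csv(path, sep="\t").set_index("aa").loc[list(AMINO_ACIDS)]
        return cls(
            df["avg_phi"].to_numpy(float),
            df["std_phi"].to_numpy(float),
            df["avg_psi"].to_numpy(float),
            df["std_psi"].to_numpy(float),
            df["zero_set"].to_numpy(bool),
        )


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window width w (odd) with half-width k = (w-1)/2."""

    w: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.w % 2 == 0:
            raise ValueError(f"window size must be odd and >= 1, got {self.w}")

    @property
    def k(self) -> int:
        return (self.w - 1) // 2


def normalize_pssm(raw_scores) -> np.ndarray:
    """Squash integer log-odds scores into [0, 1] with the logistic function."""
    x = np.asarray(raw_scores, dtype=float)
    return 1.0 / (1.0 + np.exp(-x))


class PSSMFormatError(ValueError):
    pass


def parse_pssm(text: str):
    """Parse a PSI-BLAST ASCII PSSM into (L x 20 scores, sequence).

    Accepts the standard ``-Q`` output: a header line of residue letters
    (20 score columns, optionally followed by 20 frequency columns) and one
    row per position ``idx aa s1 .. s20 [...]``.  Columns are remapped to
    the canonical ACDEFGHIKLMNPQRSTVWY order.
    """
    lines = text.splitlines()
    header_cols = None
    header_ln = None
    for ln, line in enumerate(lines, start=1):
        toks = line.split()
        if len(toks) >= 20 and all(t in AMINO_ACIDS and len(t) == 1 for t in toks[:20]):
            header_cols = toks[:20]
            header_ln = ln
            break
    if header_cols is None:
        raise PSSMFormatError("no PSSM header row of 20 residue letters found")

    rows, seq = [], []
    for ln in range(header_ln, len(lines)):
        line = lines[ln]
        toks = line.split()
        if not toks:
            continue
        if not toks[0].lstrip("-").isdigit():
            break  # footer (statistics) section
        if len(toks) < 22 or toks[1] not in AMINO_ACIDS:
            raise PSSMFormatError(f"malformed PSSM row at line {ln + 1}: {line!r}")
        try:
            scores = [int(t) for t in toks[2:22]]
        except ValueError as exc:
            raise PSSMFormatError(f"non-integer score at line {ln + 1}") from exc
        seq.append(toks[1])
        rows.append(scores)
    if not rows:
        raise PSSMFormatError(f"no score rows after header at line {header_ln}")

    raw = np.array(rows, dtype=int)
    order = [header_cols.index(aa) for aa in AMINO_ACIDS]
    return raw[:, order], "".join(seq)


def fragment_mean_angles(fragment_sets) -> np.ndarray:
    """Circular mean per residue of a list of fragment angle sets (degrees)."""
    out = np.empty(len(fragment_sets))
    for i, angles in enumerate(fragment_sets):
        a = np.asarray(angles, dtype=float)
        if a.size == 0:
            raise ValueError(f"residue {i}: empty fragment set")
        r = np.deg2rad(a)
        deg = np.rad2deg(np.arctan2(np.mean(np.sin(r)), np.mean(np.cos(r))))
        out[i] = 180.0 if deg <= -180.0 else deg
    return out


def estimate_error_distribution(
    frag_phi, true_phi, frag_psi, true_psi, res_types
) -> ErrorDistributionTable:
    """Estimate per-residue-type fragment-error statistics.

    Errors are wrapped differences fragment-prediction minus truth; for
    each residue type the mean and standard deviation are recorded.
    Zero-set types are forced to (0, 0); a non-zero-set type with no
    observations falls back to (0, 0) with a warning.
    """
    res_types = list(res_types)
    err_phi = wrap_error(np.asarray(frag_phi, float), np.asarray(true_phi, float))
    err_psi = wrap_error(np.asarray(frag_psi, float), np.asarray(true_psi, float))
    if not (len(res_types) == err_phi.size == err_psi.size):
        raise ValueError("fragment/truth/type lists must be aligned")

    n = len(AMINO_ACIDS)
    avg_phi = np.zeros(n)
    std_phi = np.zeros(n)
    avg_psi = np.zeros(n)
    std_psi = np.zeros(n)
    zero = np.array([aa in ZERO_SET for aa in AMINO_ACIDS])
    types = np.array([AA_INDEX[t] for t in res_types])
    for i, aa in enumerate(AMINO_ACIDS):
        if zero[i]:
            continue
        sel = types == i
        if not sel.any():
            logger.warning("no fragment-error observations for %s; using (0, 0)", aa)
            continue
        avg_phi[i] = err_phi[sel].mean()
        std_phi[i] = err_phi[sel].std()
        avg_psi[i] = err_psi[sel].mean()
        std_psi[i] = err_psi[sel].std()
    return ErrorDistributionTable(avg_phi, std_phi, avg_psi, std_psi, zero)


def fragment_feature(p_phi: float, p_psi: float, res_type: str,
                     table: ErrorDistributionTable) -> np.ndarray:
    """Four [0, 1] features from fragment-predicted angles.

    alpha = wrap(P - avg) per angle; emitted as ((sin a)+1)/2, ((cos a)+1)/2
    for phi then psi.  The std column of the table flags zero-set handling
    but does not enter the emitted values.
    """
    avg_phi, _, avg_psi, _ = table.row(res_type)
    a_phi = np.deg2rad(wrap_error(float(p_phi), float(avg_phi)))
    a_psi = np.deg2rad(wrap_error(float(p_psi), float(avg_psi)))
    return np.array(
        [
            (np.sin(a_phi) + 1) / 2,
            (np.cos(a_phi) + 1) / 2,
            (np.sin(a_psi) + 1) / 2,
            (np.cos(a_psi) + 1) / 2,
        ]
    )


def build_residue_features(blocks: dict, layout: FeatureLayout = LAYOUT_V1) -> np.ndarray:
    """Concatenate per-source rows into one layout-ordered feature vector."""
    parts = []
    for name, width in layout.blocks:
        if name not in blocks:
            raise ValueError(f"missing feature block {name!r}")
        v = np.atleast_1d(np.asarray(blocks[name], dtype=float))
        if v.shape != (width,):
            raise ValueError(
                f"block {name!r} has width {v.shape[0] if v.ndim == 1 else v.shape}, "
                f"expected {width}"
            )
        parts.append(v)
    vec = np.concatenate(parts)
    if vec.min() < -1e-9 or vec.max() > 1 + 1e-9:
        raise ValueError("feature values must lie in [0, 1]")
    return vec


def extract_windows(matrix: FeatureMatrix | np.ndarray, cfg: WindowConfig) -> np.ndarray:
    """Stack each residue's w-residue neighbourhood into one row.

    Row i concatenates residues i-k .. i+k; positions outside the chain
    contribute zero vectors, so every row has length w * width.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    L, width = values.shape
    k = cfg.k
    padded = np.zeros((L + 2 * k, width))
    padded[k:k + L] = values
    return np.concatenate([padded[off:off + L] for off in range(cfg.w)], axis=1)
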