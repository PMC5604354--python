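"""Synthetic protein-like data from a Ramachandran-basin state model.

A sticky three-state Markov chain (helix, sheet, coil) walks along the
chain; each residue's phi/psi pair is its state's basin mean plus
wrapped Gaussian noise (helix near (-63, -43), sheet near (-120, 135),
coil a two-component mixture covering the polyproline-II and left-helix
regions).  Every feature block is generated with state-dependent
distributions so the angles are learnable from the features: secondary
structure concentrates on the true state, the PSSM profile and sequence
letters are drawn with state-biased residue propensities, contact-number
probabilities peak at state-typical neighbour counts, and solvent
accessibility and disorder follow state-typical rates.  Fragment
predictions are simulated as truth plus wrapped noise, from which the
error-distribution table and the fragment feature are built exactly as
for real fragment-library output.

The generator emits the same on-disk formats the pipeline reads (FASTA,
per-residue TSV, JSON manifest) and is byte-reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import AngleTable, wrap_error, write_angle_table, read_angle_table
from .features import (LAYOUT_V1, ErrorDistributionTable, FeatureMatrix,
                       build_residue_features, estimate_error_distribution,
                       fragment_feature, fragment_mean_angles)
from .physchem import AMINO_ACIDS, physchem_features

__all__ = [
    "BasinModel",
    "SyntheticProtein",
    "generate_protein",
    "generate_dataset",
    "simulate_fragment_predictions",
    "load_dataset",
]

STATES = ("helix", "sheet", "coil")
SS8_ALPHABET = "HGIEBTSC"

# residues favoured in each conformational state (propensity x4 over baseline)
_STATE_RESIDUES = {
    "helix": set("AELMQKRH"),
    "sheet": set("VIYWFTC"),
    "coil": set("GPSND"),
}
_SS8_MASS = {
    "helix": {"H": 0.70, "G": 0.08, "I": 0.02},
    "sheet": {"E": 0.70, "B": 0.10},
    "coil": {"T": 0.25, "S": 0.20, "C": 0.35},
}
_CN_TARGET = {"helix": 7, "sheet": 9, "coil": 4}
_EXPOSED_P = {"helix": 0.40, "sheet": 0.25, "coil": 0.70}
_DISORDER_MEAN = {"helix": 0.10, "sheet": 0.10, "coil": 0.50}


@dataclass
class BasinModel:
    """Ramachandran-basin state model driving the generator."""

    means: dict = field(default_factory=lambda: {
        "helix": [(-63.0, -43.0, 1.0)],
        "sheet": [(-120.0, 135.0, 1.0)],
        "coil": [(-75.0, 145.0, 0.7), (60.0, 45.0, 0.3)],
    })
    noise_sd: float = 15.0
    transition: np.ndarray = field(default_factory=lambda: np.array([
        [0.90, 0.05, 0.05],
        [0.05, 0.90, 0.05],
        [0.05, 0.05, 0.90],
    ]))

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, float)
        if self.transition.shape != (3, 3) or np.any(self.transition < 0) \
                or not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must be non-negative and sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the state chain."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()


@dataclass
class SyntheticProtein:
    protein_id: str
    sequence: str
    state_path: list[str]
    angles: AngleTable
    features: FeatureMatrix
    frag_phi: np.ndarray  # per-residue fragment-mean phi prediction
    frag_psi: np.ndarray


def _wrap(a):
    w = np.mod(np.asarray(a, float) + 180.0, 360.0) - 180.0
    return np.where(w == -180.0, 180.0, w)


def _aa_probs(state: str) -> np.ndarray:
    p = np.ones(20)
    for i, aa in enumerate(AMINO_ACIDS):
        if aa in _STATE_RESIDUES[state]:
            p[i] = 4.0
    return p / p.sum()


def simulate_fragment_predictions(truth, n_frags: int = 200,
                                  noise_sd: float = 30.0,
                                  rng: np.random.Generator | None = None,
                                  seed: int | None = None):
    """Per-residue fragment angle sets: truth plus wrapped Gaussian noise.

    ``truth`` is an AngleTable or (L x 2) degree array; undefined angles
    are treated as 0 for simulation purposes.  Returns (frag_phi,
    frag_psi) of shape (L, n_frags).
    """
    if n_frags < 1:
        raise ValueError("n_frags must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    if isinstance(truth, AngleTable):
        ang = np.column_stack([np.where(truth.phi_defined, truth.phi, 0.0),
                               np.where(truth.psi_defined, truth.psi, 0.0)])
    else:
        ang = np.atleast_2d(np.asarray(truth, float))
    L = ang.shape[0]
    frag_phi = _wrap(ang[:, [0]] + rng.normal(0, noise_sd, (L, n_frags)))
    frag_psi = _wrap(ang[:, [1]] + rng.normal(0, noise_sd, (L, n_frags)))
    return frag_phi, frag_psi


def _generate_core(protein_id: str, length: int, basin: BasinModel,
                   rng: np.random.Generator, frag_noise_sd: float,
                   n_frags: int):
    if length < 3:
        raise ValueError("protein length must be >= 3")
    trans = basin.transition
    pi = basin.stationary()
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(3, p=pi)
    for t in range(1, length):
        states[t] = rng.choice(3, p=trans[states[t - 1]])
    state_names = [STATES[s] for s in states]

    latent = np.empty((length, 2))
    for t, st in enumerate(state_names):
        comps = basin.means[st]
        weights = np.array([c[2] for c in comps])
        c = comps[rng.choice(len(comps), p=weights / weights.sum())]
        latent[t] = _wrap(np.array(c[:2]) + rng.normal(0, basin.noise_sd, 2))

    seq = "".join(AMINO_ACIDS[rng.choice(20, p=_aa_probs(st))]
                  for st in state_names)
    frag_phi, frag_psi = simulate_fragment_predictions(
        latent, n_frags=n_frags, noise_sd=frag_noise_sd, rng=rng)
    mean_phi = fragment_mean_angles(list(frag_phi))
    mean_psi = fragment_mean_angles(list(frag_psi))
    return {
        "protein_id": protein_id, "length": length, "states": state_names,
        "latent": latent, "sequence": seq,
        "frag_phi": mean_phi, "frag_psi": mean_psi,
    }


def _build_features(core: dict, table: ErrorDistributionTable,
                    rng: np.random.Generator) -> FeatureMatrix:
    rows = []
    for t in range(core["length"]):
        st = core["states"][t]
        aa = core["sequence"][t]
        # PSSM-like log-odds: favoured residues score high in this state
        raw = np.full(20, -2.0)
        for i, a in enumerate(AMINO_ACIDS):
            if a in _STATE_RESIDUES[st]:
                raw[i] = 4.0
        raw = np.clip(np.rint(raw + rng.normal(0, 2.0, 20)), -10, 10)
        pssm = 1.0 / (1.0 + np.exp(-raw))

        ss8 = rng.uniform(0.0, 0.05, 8)
        for letter, mass in _SS8_MASS[st].items():
            ss8[SS8_ALPHABET.index(letter)] += mass
        ss8 = ss8 / ss8.sum()

        kk = np.arange(15)
        cn15 = np.exp(-0.5 * ((kk - _CN_TARGET[st]) / 2.0) ** 2)
        cn15 = cn15 + rng.uniform(0, 0.02, 15)
        cn15 = cn15 / cn15.sum()

        sa = float(rng.random() < _EXPOSED_P[st])
        disorder = float(np.clip(rng.normal(_DISORDER_MEAN[st], 0.10), 0.0, 1.0))
        frag = fragment_feature(core["frag_phi"][t], core["frag_psi"][t], aa, table)
        rows.append(build_residue_features({
            "pssm": pssm, "physchem": physchem_features(aa), "ss8": ss8,
            "cn15": cn15, "sa": sa, "disorder": disorder, "fragsion": frag,
        }))
    return FeatureMatrix(core["protein_id"], np.array(rows), LAYOUT_V1)


def _angle_table(core: dict) -> AngleTable:
    phi = core["latent"][:, 0].copy()
    psi = core["latent"][:, 1].copy()
    phi[0] = np.nan   # no preceding residue: phi undefined
    psi[-1] = np.nan  # no following residue: psi undefined
    return AngleTable.from_arrays(phi, psi, aa=list(core["sequence"]),
                                  protein_id=core["protein_id"])


def generate_protein(length: int, basin: BasinModel | None = None,
                     seed: int = 0, error_table: ErrorDistributionTable | None = None,
                     frag_noise_sd: float = 30.0, n_frags: int = 200) -> SyntheticProtein:
    """Generate one synthetic protein; fully determined by the seed.

    If no fragment-error table is supplied, one is estimated from this
    protein's own simulated fragment predictions.
    """
    basin = basin or BasinModel()
    rng = np.random.default_rng(seed)
    core = _generate_core(f"synth{seed:08d}", length, basin, rng,
                          frag_noise_sd, n_frags)
    if error_table is None:
        error_table = estimate_error_distribution(
            core["frag_phi"], core["latent"][:, 0],
            core["frag_psi"], core["latent"][:, 1],
            list(core["sequence"]))
    features = _build_features(core, error_table, rng)
    return SyntheticProtein(core["protein_id"], core["sequence"],
                            core["states"], _angle_table(core), features,
                            core["frag_phi"], core["frag_psi"])


def generate_dataset(n_proteins: int, length_range=(30, 500),
                     basin: BasinModel | None = None, seed: int = 0,
                     out_dir=None, frag_noise_sd: float = 30.0,
                     n_frags: int = 200, n_calibration: int = 100):
    """Generate a dataset of independent synthetic proteins.

    The fragment-error table is estimated from the first
    ``min(n_calibration, n)`` proteins and shared by all, mirroring how
    such statistics are calibrated on a held-aside subset.  If ``out_dir``
    is given, FASTA, per-protein feature/angle TSVs, the error table and
    a JSON manifest are written there (byte-identical across runs with
    one seed).  Returns the list of SyntheticProtein objects.
    """
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    basin = basin or BasinModel()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=n_proteins)
    cores, rngs = [], []
    for i in range(n_proteins):
        rng = np.random.default_rng(int(child_seeds[i]))
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        cores.append(_generate_core(f"synth{i:04d}", length, basin, rng,
                                    frag_noise_sd, n_frags))
        rngs.append(rng)

    calib = cores[:min(n_calibration, n_proteins)]
    table = estimate_error_distribution(
        np.concatenate([c["frag_phi"] for c in calib]),
        np.concatenate([c["latent"][:, 0] for c in calib]),
        np.concatenate([c["frag_psi"] for c in calib]),
        np.concatenate([c["latent"][:, 1] for c in calib]),
        [aa for c in calib for aa in c["sequence"]])

    proteins = []
    for core, rng in zip(cores, rngs):
        features = _build_features(core, table, rng)
        proteins.append(SyntheticProtein(
            core["protein_id"], core["sequence"], core["states"],
            _angle_table(core), features, core["frag_phi"], core["frag_psi"]))

    if out_dir is not None:
        _write_dataset(Path(out_dir), proteins, table, seed)
    return proteins


def _write_dataset(out_dir: Path, proteins, table, seed: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "sequences.fasta", "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")
    table.to_tsv(out_dir / "error_table.tsv")
    layout = LAYOUT_V1
    cols = [f"{name}_{i}" for name, w in layout.blocks for i in range(w)]
    entries = []
    for p in proteins:
        feat_path = out_dir / f"{p.protein_id}.features.tsv"
        df = pd.DataFrame(p.features.values, columns=cols)
        df.insert(0, "chain_pos", np.arange(1, len(p.features) + 1))
        df.to_csv(feat_path, sep="\t", index=False, float_format="%.6f")
        ang_path = out_dir / f"{p.protein_id}.angles.tsv"
        write_angle_table(p.angles, ang_path)
        entries.append({"id": p.protein_id, "length": len(p.features),
                        "features": feat_path.name, "angles": ang_path.name})
    manifest = {"seed": seed, "layout_version": layout.version,
                "n_proteins": len(proteins), "proteins": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(in_dir):
    """Read a written dataset back as (id, FeatureMatrix, AngleTable) triples."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    out = []
    for entry in manifest["proteins"]:
        df = pd.read_csv(in_dir / entry["features"], sep="\t")
        values = df.drop(columns=["chain_pos"]).to_numpy(float)
        fm = FeatureMatrix(entry["id"], values, LAYOUT_V1)
        at = read_angle_table(in_dir / entry["angles"], protein_id=entry["id"])
        out.append((entry["id"], fm, at))
    return out
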