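"""Orchestration: build, train, evaluate and select torsion-angle models.

Datasets here are lists of proteins; each protein is either a
``SyntheticProtein`` or an ``(id, FeatureMatrix, AngleTable)`` triple.
Windowed feed-forward models treat residues as i.i.d. samples pooled
across proteins; recurrent models consume whole proteins as ordered
sequences.  All selection procedures (window sweep, memory sweep,
hidden-layer sweep, greedy forward feature selection, k-fold
cross-validation) split by protein, never by residue, and are
reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .angles import AngleTable, TorsionPair, mean_absolute_error, paired_t_test, wrap_error
from .features import LAYOUT_V1, FeatureMatrix
from .models import (CircularMeanBaseline, TorsionDNN, TorsionDRBM,
                     TorsionDRNN, TorsionDReRBM, _as_angles)

__all__ = [
    "ModelSpec",
    "EvaluationReport",
    "build_model",
    "predict_protein",
    "evaluate",
    "sweep",
    "forward_feature_selection",
    "cross_validate",
    "benchmark",
    "epochs_to_reach",
    "ARCHS",
]

#: Per-architecture default window sizes from model selection.
_DEFAULT_WINDOW = {"dnn": 11, "drbm": 7, "drnn": 7, "drerbm": 3}
ARCHS = tuple(_DEFAULT_WINDOW)
_CLASSES = {"dnn": TorsionDNN, "drbm": TorsionDRBM,
            "drnn": TorsionDRNN, "drerbm": TorsionDReRBM}


@dataclass
class ModelSpec:
    """Declarative model description mapped onto an estimator."""

    arch: str = "dnn"
    window: int | None = None
    hidden_sizes: tuple = (500, 200, 50)
    memory_length: int = 5
    epochs: int | None = None
    pretrain_epochs: int = 10
    learning_rate: float = 0.001
    seed: int = 0
    layout_version: str = "v1"

    def __post_init__(self) -> None:
        if self.arch not in _CLASSES:
            raise ValueError(f"unknown architecture {self.arch!r}; "
                             f"expected one of {sorted(_CLASSES)}")
        if self.window is None:
            self.window = _DEFAULT_WINDOW[self.arch]
        if self.window % 2 == 0:
            raise ValueError("window size must be odd")


def build_model(spec: ModelSpec):
    """Instantiate the estimator described by a ModelSpec."""
    cls = _CLASSES[spec.arch]
    kwargs = dict(window=spec.window, hidden_sizes=tuple(spec.hidden_sizes),
                  learning_rate=spec.learning_rate,
                  layout_version=spec.layout_version, random_state=spec.seed)
    if spec.arch in ("drnn", "drerbm"):
        kwargs["memory_length"] = spec.memory_length
    if spec.arch in ("drbm", "drerbm"):
        kwargs["pretrain_epochs"] = spec.pretrain_epochs
    if spec.epochs is not None:
        kwargs["epochs"] = spec.epochs
    return cls(**kwargs)


def _unpack(dataset):
    ids, X, y = [], [], []
    for item in dataset:
        if hasattr(item, "features"):  # SyntheticProtein
            ids.append(item.protein_id)
            X.append(item.features)
            y.append(item.angles)
        else:
            pid, fm, at = item
            ids.append(pid)
            X.append(fm)
            y.append(at)
    return ids, X, y


def predict_protein(model, features) -> list[TorsionPair]:
    """Predict one protein; returns per-residue TorsionPair objects."""
    pred = model.predict([features])[0]
    return [TorsionPair(float(p), float(s)) for p, s in pred]


@dataclass
class EvaluationReport:
    """Pooled and per-protein wrapped MAEs plus pairwise significance."""

    mae: pd.DataFrame                 # index model, columns mae_phi/mae_psi
    per_protein: pd.DataFrame         # model, protein, mae_phi, mae_psi
    errors: dict                      # model -> {"phi": |err| array, "psi": ...}
    pairwise_p: pd.DataFrame | None   # model_a, model_b, angle, p_value


def evaluate(models: dict, dataset) -> EvaluationReport:
    """Evaluate fitted models on a dataset of proteins with known angles."""
    ids, X, y = _unpack(dataset)
    if not ids:
        raise ValueError("empty evaluation dataset")
    rows, pp_rows, errors = [], [], {}
    for name, model in models.items():
        preds = model.predict(X)
        abs_phi, abs_psi = [], []
        for pid, pred, yi in zip(ids, preds, y):
            ang, mask = _as_angles(yi)
            e_phi = np.abs(wrap_error(pred[:, 0][mask[:, 0]], ang[:, 0][mask[:, 0]]))
            e_psi = np.abs(wrap_error(pred[:, 1][mask[:, 1]], ang[:, 1][mask[:, 1]]))
            abs_phi.append(e_phi)
            abs_psi.append(e_psi)
            pp_rows.append({"model": name, "protein": pid,
                            "mae_phi": float(e_phi.mean()),
                            "mae_psi": float(e_psi.mean())})
        errors[name] = {"phi": np.concatenate(abs_phi),
                        "psi": np.concatenate(abs_psi)}
        rows.append({"model": name,
                     "mae_phi": float(errors[name]["phi"].mean()),
                     "mae_psi": float(errors[name]["psi"].mean())})
    mae = pd.DataFrame(rows).set_index("model")

    pairwise = None
    names = list(models)
    if len(names) >= 2:
        prows = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                for angle in ("phi", "psi"):
                    p = paired_t_test(errors[a][angle], errors[b][angle])
                    prows.append({"model_a": a, "model_b": b,
                                  "angle": angle, "p_value": p})
        pairwise = pd.DataFrame(prows)
    return EvaluationReport(mae, pd.DataFrame(pp_rows), errors, pairwise)


def _fit_eval(spec: ModelSpec, train, test) -> tuple[float, float]:
    _, Xtr, ytr = _unpack(train)
    model = build_model(spec).fit(Xtr, ytr)
    rep = evaluate({spec.arch: model}, test)
    return (float(rep.mae.loc[spec.arch, "mae_phi"]),
            float(rep.mae.loc[spec.arch, "mae_psi"]))


def sweep(train, test, spec: ModelSpec, axis: str, values) -> pd.DataFrame:
    """One-axis hyperparameter sweep; rows are axis values with MAEs.

    ``axis`` is ``window`` (odd 1-17), ``memory`` ({5,10,15,20,25} for the
    recurrent models) or ``hidden_layers`` (layer-count 2-5, sizes halving
    from the first hidden width).
    """
    values = list(values)
    if not values:
        raise ValueError("empty sweep grid")
    rows = []
    for v in values:
        s = ModelSpec(**{**asdict(spec), "window": spec.window})
        if axis == "window":
            if v % 2 == 0 or not 1 <= v <= 17:
                raise ValueError("window values must be odd in [1, 17]")
            s.window = int(v)
        elif axis == "memory":
            s.memory_length = int(v)
        elif axis == "hidden_layers":
            if not 2 <= v <= 5:
                raise ValueError("hidden layer count must be in [2, 5]")
            first = spec.hidden_sizes[0]
            s.hidden_sizes = tuple(max(4, first // (2 ** i)) for i in range(int(v)))
        else:
            raise ValueError(f"unknown sweep axis {axis!r}")
        mae_phi, mae_psi = _fit_eval(s, train, test)
        row = {axis: v, "mae_phi": mae_phi, "mae_psi": mae_psi,
               "avg": (mae_phi + mae_psi) / 2}
        if axis == "window":
            row["n_features"] = v * LAYOUT_V1.width
        rows.append(row)
    return pd.DataFrame(rows)


def _subset_dataset(dataset, group_names):
    """Restrict every protein's features to the named layout blocks."""
    sub = LAYOUT_V1.subset(group_names)
    sl = LAYOUT_V1.slices()
    cols = np.concatenate([np.arange(s.start, s.stop)
                           for name, s in sl.items() if name in set(group_names)])
    ids, X, y = _unpack(dataset)
    out = []
    for pid, fm, at in zip(ids, X, y):
        values = (fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm))[:, cols]
        out.append((pid, FeatureMatrix(pid, values, sub), at))
    return out


def forward_feature_selection(train, test, spec: ModelSpec,
                              groups=None) -> pd.DataFrame:
    """Greedy forward selection over feature groups by average MAE.

    Starts from the best single group, then repeatedly adds the group
    whose inclusion minimises the mean of phi and psi MAE.  Ties break by
    the declared group order.  Returns the full selection ledger with one
    row per candidate evaluated, flagging the winner of each round.
    """
    groups = list(groups) if groups is not None else list(LAYOUT_V1.names)
    if len(groups) < 2:
        raise ValueError("need at least two feature groups")
    chosen: list[str] = []
    remaining = list(groups)
    rows = []
    for round_no in range(1, len(groups) + 1):
        best = None
        for g in remaining:  # declared order = tie-break order
            cand = chosen + [g]
            s = ModelSpec(**asdict(spec))
            s.layout_version = LAYOUT_V1.subset(cand).version
            mae_phi, mae_psi = _fit_eval(
                s, _subset_dataset(train, cand), _subset_dataset(test, cand))
            avg = (mae_phi + mae_psi) / 2
            rows.append({"round": round_no, "candidate": g,
                         "combination": "+".join(cand), "mae_phi": mae_phi,
                         "mae_psi": mae_psi, "avg": avg, "selected": False})
            if best is None or avg < best[0]:
                best = (avg, g)
        chosen.append(best[1])
        remaining.remove(best[1])
        for r in reversed(rows):
            if r["round"] == round_no and r["candidate"] == best[1]:
                r["selected"] = True
                break
    return pd.DataFrame(rows)


def epochs_to_reach(history, target: float):
    """First 1-based epoch whose loss is <= target, or None if never."""
    for i, v in enumerate(history):
        if v <= target:
            return i + 1
    return None


def benchmark(seed: int = 0, n_proteins: int = 200, length_range=(30, 120),
              hidden_sizes=(64, 32), window: int = 7, memory_length: int = 5,
              epochs_dense: int = 20, epochs_recurrent: int = 8,
              pretrain_epochs: int = 20, train_frac: float = 0.8) -> dict:
    """End-to-end synthetic benchmark of all four architectures.

    Generates a Ramachandran-basin dataset, splits it by protein, trains
    the four models plus the circular-mean baseline on the training
    portion, and evaluates everything on the held-out proteins.  The
    pre-trained variants share the fine-tuning configuration of their
    randomly initialized counterparts so their loss histories are
    directly comparable.  Returns pooled MAEs, per-model loss histories
    and the pairwise significance table.
    """
    from .synth import generate_dataset

    proteins = generate_dataset(n_proteins, length_range, seed=seed)
    n_train = int(round(train_frac * n_proteins))
    train, test = proteins[:n_train], proteins[n_train:]
    _, Xtr, ytr = _unpack(train)

    models = {}
    for arch in ARCHS:
        spec = ModelSpec(arch=arch, window=window, hidden_sizes=hidden_sizes,
                         memory_length=memory_length,
                         pretrain_epochs=pretrain_epochs, seed=seed,
                         epochs=(epochs_recurrent if arch in ("drnn", "drerbm")
                                 else epochs_dense))
        models[arch] = build_model(spec).fit(Xtr, ytr)
    models["circular_mean"] = CircularMeanBaseline().fit(Xtr, ytr)
    report = evaluate(models, test)
    return {
        "report": report,
        "mae": {name: (float(report.mae.loc[name, "mae_phi"]),
                       float(report.mae.loc[name, "mae_psi"]))
                for name in models},
        "histories": {arch: list(models[arch].loss_history_) for arch in ARCHS},
        "n_train": len(train),
        "n_test": len(test),
        "n_test_residues": int(report.errors["circular_mean"]["phi"].size),
    }


def cross_validate(dataset, spec: ModelSpec, k: int = 5,
                   seed: int = 0) -> pd.DataFrame:
    """Protein-level k-fold cross-validation; returns per-fold MAEs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids, X, y = _unpack(dataset)
    n = len(ids)
    if n < k:
        raise ValueError(f"need at least {k} proteins for {k}-fold CV")
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    rows = []
    data = list(zip(ids, X, y))
    for fold_no, fold in enumerate(folds):
        test = [data[i] for i in fold]
        train = [data[i] for i in order if i not in set(fold)]
        mae_phi, mae_psi = _fit_eval(spec, train, test)
        rows.append({"fold": fold_no, "n_test": len(fold),
                     "mae_phi": mae_phi, "mae_psi": mae_psi})
    df = pd.DataFrame(rows)
    df.attrs["mean_mae_phi"] = float(df["mae_phi"].mean())
    df.attrs["sd_mae_phi"] = float(df["mae_phi"].std())
    df.attrs["mean_mae_psi"] = float(df["mae_psi"].mean())
    df.attrs["sd_mae_psi"] = float(df["mae_psi"].std())
    return df
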