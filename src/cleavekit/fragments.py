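"""Fragment-based hit/miss prediction for sensor-compound pairs.

Sensor-compound pairs are labeled from the 90% confidence interval of the
fold change (hit: lower bound > 2; miss: upper bound < 2; otherwise
indeterminate).  Compounds are featurized as presence bit vectors over a
vocabulary of canonical circular atom environments (radius 0..radius_max)
enumerated from the whole library.  Per sensor, a random-forest classifier
is evaluated by leave-one-out cross-validation over its labeled compounds;
confusions are summed across sensors and scored with a pooled ROC AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "label_pairs",
    "FragmentVocabulary",
    "build_fragments",
    "SensorEvaluation",
    "loo_evaluate",
    "AggregateMetrics",
    "aggregate_metrics",
]


def label_pairs(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Label sensor-compound pairs hit/miss/indeterminate from their CIs.

    ``records`` needs ``sensor_id``, ``compound_id``, ``fc``, ``ci90_lo``,
    ``ci90_hi`` columns (single-compound fold-change output).  The label is
    a pure function of the CI bounds; no model is involved.
    """
    for col in ("sensor_id", "compound_id", "fc", "ci90_lo", "ci90_hi"):
        if col not in records.columns:
            raise InputError(f"records missing column {col!r}")
    label = np.where(
        records["ci90_lo"] > fc_threshold,
        "hit",
        np.where(records["ci90_hi"] < fc_threshold, "miss", "indeterminate"),
    )
    out = records[["sensor_id", "compound_id", "fc", "ci90_lo", "ci90_hi"]].copy()
    out["label"] = label
    return out


def _atom_environments(smiles: str, radius_max: int) -> set[str]:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES: {smiles!r}")
    frags: set[str] = set()
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        for r in range(radius_max + 1):
            if r == 0:
                frag = Chem.MolFragmentToSmiles(mol, atomsToUse=[idx], canonical=True)
            else:
                bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, r, idx)
                if not bonds:
                    break
                atoms = {idx}
                for b in bonds:
                    bond = mol.GetBondWithIdx(b)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
                frag = Chem.MolFragmentToSmiles(
                    mol, atomsToUse=sorted(atoms), bondsToUse=list(bonds), canonical=True
                )
            frags.add(frag)
    return frags


@dataclass
class FragmentVocabulary:
    """Ordered canonical fragment keys with per-compound presence bits."""

    keys: list  # ordered fragment keys (canonical SMILES)
    index: dict = field(init=False)  # key -> bit position
    radius_max: int = 3

    def __post_init__(self) -> None:
        self.index = {k: i for i, k in enumerate(self.keys)}

    def __len__(self) -> int:
        return len(self.keys)

    def vector(self, smiles: str) -> np.ndarray:
        """Presence bit vector of a compound over the vocabulary."""
        bits = np.zeros(len(self.keys), dtype=np.uint8)
        for frag in _atom_environments(smiles, self.radius_max):
            pos = self.index.get(frag)
            if pos is not None:
                bits[pos] = 1
        return bits

    def matrix(self, smiles_list: Sequence[str]) -> np.ndarray:
        return np.stack([self.vector(s) for s in smiles_list])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"radius_max": self.radius_max, "keys": self.keys}))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FragmentVocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(keys=payload["keys"], radius_max=payload["radius_max"])


def build_fragments(
    smiles: Sequence[str],
    radius_max: int = 3,
) -> FragmentVocabulary:
    """Enumerate the union of circular atom environments over a library.

    Environments of radius 0..``radius_max`` around every atom are
    canonicalized and deduplicated; the vocabulary order is sorted, hence
    deterministic for a fixed library.  Unparseable structures are skipped
    with a warning.
    """
    all_frags: set[str] = set()
    for smi in smiles:
        try:
            all_frags |= _atom_environments(smi, radius_max)
        except InputError:
            warnings.warn(f"excluding unparseable SMILES {smi!r}", stacklevel=2)
    return FragmentVocabulary(keys=sorted(all_frags), radius_max=radius_max)


@dataclass
class SensorEvaluation:
    """Leave-one-out confusion and scores for one sensor's classifier."""

    sensor_id: str
    n_compounds: int
    n_hits: int
    tn: int
    fp: int
    fn: int
    tp: int
    scores: pd.DataFrame  # compound_id, y_true, score, pred
    skipped: bool = False
    n_degenerate: int = 0  # folds trained on a single class


def loo_evaluate(
    labels: pd.DataFrame,
    vocabulary: FragmentVocabulary,
    smiles_by_compound: Mapping[str, str],
    min_hits: int = 3,
    seed: int = 0,
    n_estimators: int = 200,
    score_threshold: float = 0.5,
) -> SensorEvaluation:
    """Leave-one-out random-forest evaluation for one sensor.

    ``labels`` holds this sensor's hit/miss rows (indeterminate pairs are
    dropped here if present).  Each compound is predicted by a forest
    trained on all the others; the held-out label never reaches training.
    Sensors with fewer than ``min_hits`` hits are skipped.  Folds whose
    training set is single-class predict the majority class and are
    counted in ``n_degenerate``.
    """
    from sklearn.ensemble import RandomForestClassifier

    sensor_id = str(labels["sensor_id"].iloc[0]) if len(labels) else ""
    labeled = labels[labels["label"].isin(["hit", "miss"])].reset_index(drop=True)
    y = (labeled["label"] == "hit").to_numpy()
    n_hits = int(y.sum())
    if n_hits < min_hits:
        return SensorEvaluation(
            sensor_id, len(labeled), n_hits, 0, 0, 0, 0,
            scores=pd.DataFrame(columns=["compound_id", "y_true", "score", "pred"]),
            skipped=True,
        )
    X = vocabulary.matrix([smiles_by_compound[c] for c in labeled["compound_id"]])
    n = len(labeled)
    scores = np.empty(n)
    centered = np.empty(n)  # score minus the fold's training hit prior
    degenerate = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[:] = True
        mask[i] = False
        y_train = y[mask]
        if y_train.all() or not y_train.any():
            scores[i] = 1.0 if y_train.all() else 0.0
            centered[i] = 0.0
            degenerate += 1
            continue
        # balanced class weights keep each fold's decision function from
        # tracking the held-out label's effect on the training class prior
        # (unweighted leave-one-out is anti-correlated with truth under a
        # label-permutation null)
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, class_weight="balanced"
        )
        clf.fit(X[mask], y_train)
        scores[i] = clf.predict_proba(X[i : i + 1])[0, list(clf.classes_).index(True)]
        # removing the held-out example shifts each fold's training class
        # prior with the held-out label; centering by that prior keeps the
        # ranking score comparable across folds (otherwise a permutation
        # null scores well below chance)
        centered[i] = scores[i] - y_train.mean()
    pred = scores >= score_threshold
    return SensorEvaluation(
        sensor_id=sensor_id,
        n_compounds=n,
        n_hits=n_hits,
        tn=int((~pred & ~y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tp=int((pred & y).sum()),
        scores=pd.DataFrame(
            {
                "compound_id": labeled["compound_id"],
                "y_true": y,
                "score": scores,
                "centered_score": centered,
                "pred": pred,
            }
        ),
        n_degenerate=degenerate,
    )


@dataclass
class AggregateMetrics:
    tn: int
    tp: int
    fp: int
    fn: int
    precision: float | None  # None when TP + FP = 0
    auc: float | None  # pooled over all scores; None without score data
    per_sensor: pd.DataFrame


def aggregate_metrics(evaluations: Sequence) -> AggregateMetrics:
    """Sum confusions across sensors; precision TP/(TP+FP); pooled AUC.

    Accepts :class:`SensorEvaluation` objects or any records with
    ``tn/tp/fp/fn`` attributes (scores optional).  Skipped sensors are
    excluded from the sums but listed in the per-sensor table.
    """
    from sklearn.metrics import roc_auc_score

    if not len(evaluations):
        raise InputError("no evaluated sensors")
    rows, pooled_y, pooled_s = [], [], []
    for ev in evaluations:
        skipped = getattr(ev, "skipped", False)
        row = {
            "sensor_id": getattr(ev, "sensor_id", ""),
            "n_compounds": getattr(ev, "n_compounds", None),
            "n_hits": getattr(ev, "n_hits", None),
            "tn": ev.tn, "fp": ev.fp, "fn": ev.fn, "tp": ev.tp,
            "skipped": skipped,
        }
        scores = getattr(ev, "scores", None)
        if not skipped:
            if ev.tp + ev.fp > 0:
                row["precision"] = ev.tp / (ev.tp + ev.fp)
            row["tpr"] = ev.tp / (ev.tp + ev.fn) if ev.tp + ev.fn else None
            row["tnr"] = ev.tn / (ev.tn + ev.fp) if ev.tn + ev.fp else None
            if scores is not None and len(scores):
                col = "centered_score" if "centered_score" in scores else "score"
                if scores["y_true"].nunique() == 2:
                    row["auc"] = roc_auc_score(scores["y_true"], scores[col])
                pooled_y.extend(scores["y_true"])
                pooled_s.extend(scores[col])
        rows.append(row)
    per_sensor = pd.DataFrame(rows)
    live = per_sensor[~per_sensor["skipped"]]
    tn, tp = int(live["tn"].sum()), int(live["tp"].sum())
    fp, fn = int(live["fp"].sum()), int(live["fn"].sum())
    precision = tp / (tp + fp) if tp + fp > 0 else None
    auc = None
    if pooled_y and len(set(pooled_y)) == 2:
        auc = float(roc_auc_score(pooled_y, pooled_s))
    return AggregateMetrics(tn=tn, tp=tp, fp=fp, fn=fn, precision=precision, auc=auc, per_sensor=per_sensor)
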