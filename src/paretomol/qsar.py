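"""Random-forest QSAR: activity labeling, featurization and regression.

Molecules are encoded as 2067-dimensional vectors — a 2048-bit ECFP6
(Morgan radius-3) fingerprint plus 19 physicochemical descriptors —
min-max scaled to [0, 1] and fed to a 1000-tree random-forest regressor
that predicts pX (the negative log of a potency measurement, pChEMBL
style). Records without a measured activity are labeled pX = 3.99, just
below the inactive floor of 4, and down-weighted to 0.1 in the fit;
actives (pX >= 6.5) carry weight 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.preprocessing import MinMaxScaler

logger = logging.getLogger(__name__)

UNLABELED_PX = 3.99
ACTIVITY_THRESHOLD = 6.5
POSITIVE_WEIGHT = 1.0
NEGATIVE_WEIGHT = 0.1

N_FINGERPRINT_BITS = 2048
N_DESCRIPTORS = 19
N_FEATURES = N_FINGERPRINT_BITS + N_DESCRIPTORS

#: Descriptor order is part of the model contract (persisted with it).
DESCRIPTOR_NAMES = (
    "molecular_weight", "logp", "h_bond_acceptors", "h_bond_donors",
    "rotatable_bonds", "amide_bonds", "bridgehead_atoms", "heteroatoms",
    "spiro_atoms", "heavy_atoms", "fraction_csp3", "aliphatic_rings",
    "saturated_rings", "total_rings", "aromatic_rings", "heterocycles",
    "valence_electrons", "tpsa", "molar_refractivity",
)


@dataclass
class LigandRecord:
    """One compound-target activity observation."""

    compound_id: str
    smiles: str
    target_id: str
    px: float
    sample_weight: float
    comment: str = ""
    standard_type: str = ""
    standard_relation: str = ""
    #: False when px was imputed (no measured activity), True otherwise.
    measured: bool = True

    def __post_init__(self) -> None:
        if self.sample_weight not in (POSITIVE_WEIGHT, NEGATIVE_WEIGHT):
            raise ValueError("sample_weight must be 1.0 or 0.1")
        if not np.isfinite(self.px):
            raise ValueError("px must be finite")


def assign_px_labels(rows: pd.DataFrame,
                     activity_threshold: float = ACTIVITY_THRESHOLD
                     ) -> list[LigandRecord]:
    """Turn raw activity rows into weighted training records.

    Rows without a defined pX (or flagged inactive in the comment) get
    pX = 3.99 and weight 0.1. Rows with pX >= threshold get weight 1.0,
    below-threshold rows 0.1. Replicate measurements of one
    compound-target pair are aggregated by the mean of the defined pX
    values. Rows lacking a SMILES are dropped with a logged count.
    """
    df = rows.copy()
    n_dropped = int(df["smiles"].isna().sum()
                    + (df["smiles"].astype(str).str.len() == 0).sum())
    df = df[df["smiles"].notna() & (df["smiles"].astype(str).str.len() > 0)]
    if n_dropped:
        logger.info("dropped %d rows without SMILES", n_dropped)

    inactive = df.get("comment", pd.Series("", index=df.index)).astype(str)
    flagged = inactive.str.contains("not active", case=False, na=False)
    px = pd.to_numeric(df["px"], errors="coerce")
    px = px.mask(flagged, np.nan)

    records: list[LigandRecord] = []
    df = df.assign(_px=px)
    for (cid, tid), grp in df.groupby(["compound_id", "target_id"], sort=True):
        defined = grp["_px"].dropna()
        measured = bool(len(defined))
        value = float(defined.mean()) if measured else UNLABELED_PX
        weight = POSITIVE_WEIGHT if value >= activity_threshold else NEGATIVE_WEIGHT
        first = grp.iloc[0]
        records.append(LigandRecord(
            compound_id=str(cid),
            smiles=str(first["smiles"]),
            target_id=str(tid),
            px=value,
            sample_weight=weight,
            comment=str(first.get("comment", "")),
            standard_type=str(first.get("standard_type", "")),
            standard_relation=str(first.get("standard_relation", "")),
            measured=measured,
        ))
    return records


def _descriptors(mol: Chem.Mol) -> np.ndarray:
    ri = mol.GetRingInfo()
    return np.array([
        Descriptors.MolWt(mol),
        Crippen.MolLogP(mol),
        rdMolDescriptors.CalcNumHBA(mol),
        rdMolDescriptors.CalcNumHBD(mol),
        rdMolDescriptors.CalcNumRotatableBonds(mol),
        rdMolDescriptors.CalcNumAmideBonds(mol),
        rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
        rdMolDescriptors.CalcNumHeteroatoms(mol),
        rdMolDescriptors.CalcNumSpiroAtoms(mol),
        mol.GetNumHeavyAtoms(),
        rdMolDescriptors.CalcFractionCSP3(mol),
        rdMolDescriptors.CalcNumAliphaticRings(mol),
        rdMolDescriptors.CalcNumSaturatedRings(mol),
        ri.NumRings(),
        rdMolDescriptors.CalcNumAromaticRings(mol),
        rdMolDescriptors.CalcNumHeterocycles(mol),
        Descriptors.NumValenceElectrons(mol),
        rdMolDescriptors.CalcTPSA(mol),
        Crippen.MolMR(mol),
    ], dtype=np.float64)


def featurize(smiles: str) -> np.ndarray:
    """2067-dimensional unscaled feature vector for one molecule.

    First 2048 entries: ECFP6 fingerprint bits (Morgan, radius 3);
    last 19: physicochemical descriptors in :data:`DESCRIPTOR_NAMES`
    order. Raises ValueError on an invalid SMILES.
    """
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"invalid SMILES {smiles!r}")
    fp = rdMolDescriptors.GetMorganFingerprintAsBitVect(
        mol, radius=3, nBits=N_FINGERPRINT_BITS)
    vec = np.zeros(N_FEATURES)
    vec[:N_FINGERPRINT_BITS] = np.frombuffer(
        fp.ToBitString().encode(), dtype=np.uint8) - ord("0")
    vec[N_FINGERPRINT_BITS:] = _descriptors(mol)
    return vec


def featurize_many(smiles: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Featurize a batch; returns (X (n, 2067), valid mask (n,)).

    Invalid SMILES get a zero row and valid=False.
    """
    X = np.zeros((len(smiles), N_FEATURES))
    valid = np.zeros(len(smiles), dtype=bool)
    for i, smi in enumerate(smiles):
        try:
            X[i] = featurize(smi)
            valid[i] = True
        except ValueError:
            pass
    return X, valid


def fit_scaler(X: np.ndarray) -> MinMaxScaler:
    """Per-feature min-max scaler; constant features map to 0 and values
    outside the fit range are clipped into [0, 1]."""
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need at least one feature vector")
    scaler = MinMaxScaler(clip=True)
    scaler.fit(X)
    # min-max is undefined for a constant feature; pin those columns to 0
    scaler.constant_mask_ = scaler.data_range_ == 0
    return scaler


def scale(X: np.ndarray, scaler: MinMaxScaler) -> np.ndarray:
    single = X.ndim == 1
    out = scaler.transform(np.atleast_2d(X))
    constant = getattr(scaler, "constant_mask_", None)
    if constant is not None:
        out[:, constant] = 0.0
    return out[0] if single else out


@dataclass
class QsarModel:
    """Fitted random-forest regressor + scaler + provenance metadata."""

    forest: RandomForestRegressor
    scaler: MinMaxScaler
    target_id: str
    seed: int
    descriptor_names: tuple[str, ...] = DESCRIPTOR_NAMES
    oob_score: float | None = None

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        return predict_px(self, smiles)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "QsarModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a QsarModel")
        return model


def train_qsar(records: Sequence[LigandRecord],
               n_trees: int = 1000,
               seed: int = 0,
               max_features: float | str = 1.0,
               n_jobs: int = 1) -> QsarModel:
    """Fit the weighted random-forest regression QSAR model.

    Uses squared-error (variance-reduction) splitting — the natural
    criterion for a regression forest — with ``n_trees`` trees and the
    records' 1.0/0.1 sample weights. The out-of-bag R^2 is logged and
    stored on the model.
    """
    if len(records) < 20:
        raise ValueError("need at least 20 records to fit a forest")
    weights = np.array([r.sample_weight for r in records])
    if len(set(weights)) < 2:
        logger.warning("all records share one sample weight class")
    X_raw, valid = featurize_many([r.smiles for r in records])
    if not valid.all():
        raise ValueError("all training records must have valid SMILES")
    y = np.array([r.px for r in records])
    if np.allclose(y, y[0]):
        logger.warning("all labels identical; forest will be constant")
    scaler = fit_scaler(X_raw)
    X = scale(X_raw, scaler)
    forest = RandomForestRegressor(
        n_estimators=n_trees, criterion="squared_error",
        max_features=max_features, oob_score=True,
        random_state=seed, n_jobs=n_jobs)
    forest.fit(X, y, sample_weight=weights)
    oob = float(forest.oob_score_)
    logger.info("QSAR forest fitted: %d trees, OOB R^2 = %.3f", n_trees, oob)
    target = records[0].target_id
    return QsarModel(forest=forest, scaler=scaler, target_id=target,
                     seed=seed, oob_score=oob)


def predict_px(model: QsarModel, smiles: Sequence[str]) -> np.ndarray:
    """Predicted pX per molecule, NaN marking invalid SMILES.

    Invalid inputs are flagged, never raised: downstream reward code
    treats NaN as "invalid molecule" and assigns zero reward.
    """
    X_raw, valid = featurize_many(smiles)
    out = np.full(len(smiles), np.nan)
    if valid.any():
        X = scale(X_raw[valid], model.scaler)
        out[valid] = model.forest.predict(X)
    return out


def heldout_recovery_score(records: Sequence["LigandRecord"],
                           test_fraction: float = 0.25,
                           n_trees: int = 200, seed: int = 0,
                           max_features: float | str = 0.2) -> float:
    """Held-out R^2 on measured records: the parameter-recovery check.

    Fits the weighted forest on a random training split and scores it on
    the held-out records that carry a measured activity. Imputed-label
    records (pX = 3.99 stand-ins) train the model's negative range but
    are excluded from scoring, since they are not measurements.
    """
    from sklearn.model_selection import train_test_split

    X_raw, valid = featurize_many([r.smiles for r in records])
    if not valid.all():
        raise ValueError("all records must have valid SMILES")
    y = np.array([r.px for r in records])
    w = np.array([r.sample_weight for r in records])
    measured = np.array([r.measured for r in records])
    Xtr, Xte, ytr, yte, wtr, _, _, mte = train_test_split(
        X_raw, y, w, measured, test_size=test_fraction, random_state=seed)
    scaler = fit_scaler(Xtr)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features,
        random_state=seed, n_jobs=1)
    forest.fit(scale(Xtr, scaler), ytr, sample_weight=wtr)
    return float(forest.score(scale(Xte[mte], scaler), yte[mte]))


def cross_validate(records: Sequence[LigandRecord], n_splits: int = 5,
                   n_trees: int = 200, seed: int = 0,
                   max_features: float | str = 1.0) -> np.ndarray:
    """K-fold R^2 scores for the QSAR protocol on a record set."""
    X_raw, valid = featurize_many([r.smiles for r in records])
    if not valid.all():
        raise ValueError("all records must have valid SMILES")
    y = np.array([r.px for r in records])
    w = np.array([r.sample_weight for r in records])
    scores = []
    for train_idx, test_idx in KFold(n_splits, shuffle=True,
                                     random_state=seed).split(X_raw):
        scaler = fit_scaler(X_raw[train_idx])
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features=max_features,
            random_state=seed, n_jobs=1)
        forest.fit(scale(X_raw[train_idx], scaler), y[train_idx],
                   sample_weight=w[train_idx])
        scores.append(forest.score(scale(X_raw[test_idx], scaler), y[test_idx]))
    return np.array(scores)


def read_ligand_table(path: str | Path) -> pd.DataFrame:
    """Read the standard ligand CSV (compound_id, smiles, target_id, px,
    comment, standard_type, standard_relation)."""
    df = pd.read_csv(path)
    required = {"compound_id", "smiles", "target_id", "px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ligand table missing columns: {sorted(missing)}")
    return df
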