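"""Trainable regressor for mutant-allele siRNA efficacy (Eff_mut).

An epsilon-SVR with RBF kernel regresses percent inhibition (0-100) on sequence
features of the 19-nt guide.  The module provides the training-table container,
de-duplication, the evaluation harnesses (random hold-out split, 10-fold CV, and
leave-one-target-gene-out CV with pooling of small genes into an "Others" group),
all scored by Pearson correlation, plus versioned model persistence.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import encode_matrix, encoder_dim
from .sequence import GUIDE_LEN, RNA_ALPHABET, SiRNACandidate

__all__ = [
    "TrainingDataset",
    "EfficacyModel",
    "DEFAULT_HYPERPARAMS",
    "DEFAULT_GRID",
    "DEFAULT_FEATURE_SPEC",
    "deduplicate",
    "random_split",
    "train",
    "tune",
    "predict_eff_mut",
    "pcc",
    "cross_validate_10fold",
    "lotocv",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: feature recipe of the deployed regressor (mono- through tetranucleotide
#: composition plus positional one-hot; 416 dimensions)
DEFAULT_FEATURE_SPEC: tuple[str, ...] = ("m", "d", "t", "tt", "binary")

#: gamma="scale" adapts the RBF width to the feature dimensionality, so one
#: default works for the 16-dim dinucleotide recipe and the 416-dim hybrid alike
DEFAULT_HYPERPARAMS: dict[str, float] = {"C": 10.0, "gamma": "scale", "epsilon": 2.0}

#: hyperparameter grid for :func:`tune`, selected by inner 10-fold pooled PCC
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "C": (1.0, 10.0, 100.0),
    "gamma": (1e-3, 1e-2, 1e-1),
    "epsilon": (1.0, 5.0, 10.0),
}


@dataclass
class TrainingDataset:
    """Guides with measured efficacies (percent inhibition, 0-100) and gene labels.

    Wraps a DataFrame with columns ``guide``, ``efficacy``, ``gene`` and optional
    ``source``; validation happens on construction.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"guide", "efficacy", "gene"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"training table missing columns: {sorted(missing)}")
        if len(self.df) == 0:
            raise ValueError("empty training table")
        bad_len = self.df["guide"].str.len() != GUIDE_LEN
        if bad_len.any():
            raise ValueError(
                f"{int(bad_len.sum())} guides are not {GUIDE_LEN} nt"
            )
        bad_alpha = ~self.df["guide"].map(lambda g: set(g) <= RNA_ALPHABET)
        if bad_alpha.any():
            raise ValueError("guides contain non-RNA characters")
        eff = self.df["efficacy"]
        if eff.isna().any():
            raise ValueError("NaN efficacies")
        if ((eff < 0) | (eff > 100)).any():
            raise ValueError("efficacies must lie in [0, 100]")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TrainingDataset":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df)

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    def fingerprint(self) -> str:
        """SHA-256 over the sorted (guide, efficacy) pairs; identifies the data."""
        h = hashlib.sha256()
        for g, e in sorted(zip(self.df["guide"], self.df["efficacy"])):
            h.update(f"{g}\t{e:.6f}\n".encode())
        return h.hexdigest()[:16]


def deduplicate(dataset: TrainingDataset) -> tuple[TrainingDataset, pd.DataFrame]:
    """Collapse repeated guides to one record with the mean efficacy.

    Returns the non-redundant dataset and a report of collapsed groups
    (guide, n_records, efficacy_min, efficacy_max, efficacy_mean).  Gene and
    source labels take the first occurrence.
    """
    df = dataset.df
    grouped = df.groupby("guide", sort=False)
    agg = {"efficacy": "mean", "gene": "first"}
    if "source" in df.columns:
        agg["source"] = "first"
    dedup = grouped.agg(agg).reset_index()
    sizes = grouped.size()
    collapsed = sizes[sizes > 1].index
    report = (
        df[df["guide"].isin(collapsed)]
        .groupby("guide")["efficacy"]
        .agg(n_records="size", efficacy_min="min",
             efficacy_max="max", efficacy_mean="mean")
        .reset_index()
    )
    return TrainingDataset(dedup), report


def random_split(
    dataset: TrainingDataset, holdout_n: int, seed: int
) -> tuple[TrainingDataset, TrainingDataset]:
    """Random disjoint, exhaustive split into (train, validation) of sizes (n-h, h)."""
    n = len(dataset)
    if not 0 < holdout_n < n:
        raise ValueError(f"holdout_n must be in 1..{n - 1}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx = np.sort(perm[:holdout_n])
    train_idx = np.sort(perm[holdout_n:])
    return (
        TrainingDataset(dataset.df.iloc[train_idx]),
        TrainingDataset(dataset.df.iloc[val_idx]),
    )


@dataclass
class EfficacyModel:
    """A fitted efficacy regressor plus everything needed to reproduce predictions."""

    feature_spec: tuple[str, ...]
    hyperparams: dict[str, float]
    pipeline: Pipeline
    training_fingerprint: str
    n_train: int
    format_version: int = MODEL_FORMAT_VERSION

    def predict(self, guides: Sequence[str]) -> np.ndarray:
        X, _ = encode_matrix(guides, self.feature_spec)
        raw = self.pipeline.predict(X)
        return np.clip(raw, 0.0, 100.0)


def _fit_pipeline(
    guides: Sequence[str],
    efficacies: np.ndarray,
    feature_spec: Sequence[str],
    hyperparams: dict[str, float],
) -> Pipeline:
    X, _ = encode_matrix(guides, feature_spec)
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate features: zero variance in every column")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svr", SVR(kernel="rbf", **hyperparams)),
        ]
    )
    pipe.fit(X, efficacies)
    return pipe


def train(
    train_set: TrainingDataset,
    feature_spec: Sequence[str] = DEFAULT_FEATURE_SPEC,
    hyperparams: dict[str, float] | None = None,
) -> EfficacyModel:
    """Fit the epsilon-SVR (RBF kernel) on standardized features.

    Features are standardized to zero mean / unit variance using training data
    only, so large feature blocks cannot drown small ones.  Efficacies are
    regressed directly on the 0-100 percent scale.
    """
    if len(train_set) < 20:
        raise ValueError("need at least 20 training records")
    encoder_dim(feature_spec)  # validates ids
    hp = dict(DEFAULT_HYPERPARAMS if hyperparams is None else hyperparams)
    pipe = _fit_pipeline(
        train_set.df["guide"].tolist(),
        train_set.df["efficacy"].to_numpy(float),
        feature_spec,
        hp,
    )
    return EfficacyModel(
        feature_spec=tuple(feature_spec),
        hyperparams=hp,
        pipeline=pipe,
        training_fingerprint=train_set.fingerprint(),
        n_train=len(train_set),
    )


def predict_eff_mut(
    model: EfficacyModel, candidates: Sequence[SiRNACandidate | str]
) -> np.ndarray:
    """Predicted mutant-allele efficacies, clamped to [0, 100], input order preserved."""
    guides = [c.guide if isinstance(c, SiRNACandidate) else c for c in candidates]
    for g in guides:
        if len(g) != GUIDE_LEN:
            logger.warning("guide of length %d (expected %d)", len(g), GUIDE_LEN)
    return model.predict(guides)


def pcc(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson correlation coefficient between observed and predicted efficacies."""
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(a) == 0 or np.std(p) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(a, p).statistic)


def _fold_indices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Shuffle with the stated seed, deal round-robin into near-equal folds."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(perm[f::n_folds]) for f in range(n_folds)]


def cross_validate_10fold(
    dataset: TrainingDataset,
    feature_spec: Sequence[str] = DEFAULT_FEATURE_SPEC,
    hyperparams: dict[str, float] | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> tuple[float, pd.DataFrame]:
    """k-fold cross-validation scored on pooled out-of-fold predictions.

    Folds are a disjoint, exhaustive, seed-reproducible partition into near-equal
    parts; every record is predicted exactly once out-of-fold.  Returns the pooled
    PCC and a per-fold report (fold, n_test, pcc).
    """
    n = len(dataset)
    if n < 30:
        raise ValueError("need at least 30 records for cross-validation")
    folds = _fold_indices(n, n_folds, seed)
    eff = dataset.df["efficacy"].to_numpy(float)
    guides = dataset.df["guide"].tolist()
    pooled = np.empty(n)
    rows = []
    for f, test_idx in enumerate(folds):
        mask = np.ones(n, bool)
        mask[test_idx] = False
        pipe = _fit_pipeline(
            [guides[i] for i in np.flatnonzero(mask)],
            eff[mask],
            feature_spec,
            dict(DEFAULT_HYPERPARAMS if hyperparams is None else hyperparams),
        )
        X_test, _ = encode_matrix([guides[i] for i in test_idx], feature_spec)
        pred = np.clip(pipe.predict(X_test), 0.0, 100.0)
        pooled[test_idx] = pred
        try:
            fold_pcc = pcc(eff[test_idx], pred)
        except ValueError:
            fold_pcc = np.nan
        rows.append({"fold": f + 1, "n_test": len(test_idx), "pcc": fold_pcc})
    return pcc(eff, pooled), pd.DataFrame(rows)


def pool_small_genes(
    genes: Sequence[str], min_group: int = 10, pooled_label: str = "Others"
) -> pd.Series:
    """Relabel genes with fewer than ``min_group`` records into one pooled group."""
    s = pd.Series(genes, dtype=str)
    counts = s.value_counts()
    small = set(counts[counts < min_group].index)
    return s.map(lambda g: pooled_label if g in small else g)


def tune(
    dataset: TrainingDataset,
    feature_spec: Sequence[str] = DEFAULT_FEATURE_SPEC,
    grid: dict[str, tuple[float, ...]] | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> dict[str, float]:
    """Grid-search hyperparameters by inner k-fold pooled PCC; returns the best set."""
    grid = DEFAULT_GRID if grid is None else grid
    best_hp, best_score = None, -np.inf
    for C in grid["C"]:
        for gamma in grid["gamma"]:
            for epsilon in grid["epsilon"]:
                hp = {"C": C, "gamma": gamma, "epsilon": epsilon}
                score, _ = cross_validate_10fold(
                    dataset, feature_spec, hp, seed=seed, n_folds=n_folds
                )
                if score > best_score:
                    best_hp, best_score = hp, score
    logger.info("tuned hyperparameters %s (inner PCC %.3f)", best_hp, best_score)
    return best_hp


def lotocv(
    dataset: TrainingDataset,
    feature_spec: Sequence[str] = DEFAULT_FEATURE_SPEC,
    hyperparams: dict[str, float] | None = None,
    min_group: int = 10,
    seed: int = 0,
    inner_cv: bool = True,
) -> pd.DataFrame:
    """Leave-one-target-gene-out cross-validation.

    One round per gene with >= ``min_group`` records; smaller genes are pooled
    into a single "Others" round.  Each round trains on all other genes and
    reports the PCC on the held-out gene (``pcc_validation``) alongside the
    10-fold PCC within that round's training set (``pcc_10fold``, skipped when
    ``inner_cv`` is False).  Sliding 19-mers from the same gene overlap heavily,
    so this harness measures generalization to unseen genes — random k-fold CV
    cannot.
    """
    genes = pool_small_genes(dataset.df["gene"], min_group)
    rows = []
    for gene in sorted(genes.unique()):
        val_mask = (genes == gene).to_numpy()
        if val_mask.all():
            raise ValueError("a single group equals the whole dataset")
        train_ds = TrainingDataset(dataset.df[~val_mask])
        val_df = dataset.df[val_mask]
        model = train(train_ds, feature_spec, hyperparams)
        pred = model.predict(val_df["guide"].tolist())
        try:
            pcc_val = pcc(val_df["efficacy"].to_numpy(float), pred)
        except ValueError:
            pcc_val = np.nan
        pcc_inner = np.nan
        if inner_cv and len(train_ds) >= 30:
            pcc_inner, _ = cross_validate_10fold(
                train_ds, feature_spec, hyperparams, seed=seed
            )
        rows.append(
            {
                "gene": gene,
                "n_train": len(train_ds),
                "n_validation": int(val_mask.sum()),
                "pcc_10fold": pcc_inner,
                "pcc_validation": pcc_val,
                "bias": float(np.mean(pred - val_df["efficacy"].to_numpy(float))),
            }
        )
    return pd.DataFrame(rows)


def save_model(model: EfficacyModel, path: str | Path) -> None:
    """Persist a fitted model; the file is self-describing and versioned."""
    payload = {
        "format_version": model.format_version,
        "feature_spec": model.feature_spec,
        "hyperparams": model.hyperparams,
        "pipeline": model.pipeline,
        "training_fingerprint": model.training_fingerprint,
        "n_train": model.n_train,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> EfficacyModel:
    """Load a model saved by :func:`save_model`; round-trips predict bit-identically."""
    try:
        payload = joblib.load(path)
    except Exception as e:  # corrupted / not a model file
        raise ValueError(f"cannot read model file {path}: {e}") from e
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload['format_version']} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return EfficacyModel(
        feature_spec=tuple(payload["feature_spec"]),
        hyperparams=dict(payload["hyperparams"]),
        pipeline=payload["pipeline"],
        training_fingerprint=payload["training_fingerprint"],
        n_train=payload["n_train"],
        format_version=payload["format_version"],
    )
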