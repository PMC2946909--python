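"""SVM-based peptide panel classifier.

A sample is a p-dimensional vector of panel-peptide amplitudes; a linear
soft-margin support vector machine fits the maximal-margin (p-1)-dimensional
hyperplane between the two diagnostic classes, and the classifier output —
the SVM score — is the signed Euclidean distance of the sample's feature
vector to that hyperplane, (w·x + b) / ||w||. Features are log10(amplitude
+ 1) standardized with training-set mean/SD (stored in the model so scores
reproduce bit-identically); a peptide absent from a sample enters as
amplitude 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io_formats import PeptideMatrix, PanelDefinition

__all__ = ["PanelModel", "train_panel", "svm_score", "score_matrix", "cross_validate_scores"]


@dataclass
class PanelModel:
    """Trained linear-SVM panel: weights, intercept and feature transform."""

    peptide_ids: list[str]
    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    transform: str = "log10_standardize"  # or "identity"
    positive_label: str = ""
    negative_label: str = ""
    n_per_class: dict = field(default_factory=dict)
    c_reg: float = 1.0
    seed: int = 0

    def transform_features(self, amplitudes: np.ndarray) -> np.ndarray:
        x = np.asarray(amplitudes, float)
        if self.transform == "identity":
            return x
        x = np.log10(x + 1.0)
        return (x - self.feature_means) / self.feature_sds

    def to_text(self, path) -> None:
        """Serialize as a diff-able plain-text key-value + weight table."""
        with open(path, "w") as fh:
            fh.write(f"transform\t{self.transform}\n")
            fh.write(f"intercept\t{self.intercept!r}\n")
            fh.write(f"positive_label\t{self.positive_label}\n")
            fh.write(f"negative_label\t{self.negative_label}\n")
            fh.write(f"c_reg\t{self.c_reg!r}\n")
            fh.write(f"seed\t{self.seed}\n")
            fh.write("peptide_id\tweight\tfeature_mean\tfeature_sd\n")
            for pid, w, m, s in zip(
                self.peptide_ids, self.weights, self.feature_means, self.feature_sds
            ):
                fh.write(f"{pid}\t{float(w)!r}\t{float(m)!r}\t{float(s)!r}\n")

    @classmethod
    def from_text(cls, path) -> "PanelModel":
        header: dict[str, str] = {}
        ids, ws, ms, ss = [], [], [], []
        with open(path) as fh:
            in_table = False
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "peptide_id":
                    in_table = True
                    continue
                if not in_table:
                    header[parts[0]] = parts[1]
                else:
                    ids.append(parts[0])
                    ws.append(float(parts[1]))
                    ms.append(float(parts[2]))
                    ss.append(float(parts[3]))
        return cls(
            peptide_ids=ids,
            weights=np.array(ws),
            intercept=float(header["intercept"]),
            feature_means=np.array(ms),
            feature_sds=np.array(ss),
            transform=header.get("transform", "log10_standardize"),
            positive_label=header.get("positive_label", ""),
            negative_label=header.get("negative_label", ""),
            c_reg=float(header.get("c_reg", 1.0)),
            seed=int(header.get("seed", 0)),
        )


def _panel_amplitudes(matrix: PeptideMatrix, panel: PanelDefinition) -> np.ndarray:
    missing = [p for p in panel.peptide_ids if p not in matrix.amplitudes.index]
    if missing:
        raise ValueError(f"panel peptides missing from matrix: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    return matrix.amplitudes.loc[panel.peptide_ids].to_numpy(float).T  # samples x peptides


def train_panel(
    matrix: PeptideMatrix,
    panel: PanelDefinition,
    labels: pd.Series,
    c_reg: float = 1.0,
    seed: int = 0,
    transform: str = "log10_standardize",
) -> PanelModel:
    """Fit the linear soft-margin SVM on transformed panel features.

    ``labels`` maps sample_id -> one of two class labels; the
    alphabetically larger label is the positive class (positive scores).
    Deterministic for fixed inputs and seed. Raises on single-class labels
    or panel peptides absent from the matrix.
    """
    labels = labels.reindex(matrix.sample_ids).astype(str)
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = (labels == classes[1]).astype(int).to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2 or len(y) < 4:
        raise ValueError("need >= 2 samples per class and >= 4 total")
    X_raw = _panel_amplitudes(matrix, panel)
    if transform == "log10_standardize":
        Xl = np.log10(X_raw + 1.0)
        means = Xl.mean(axis=0)
        sds = Xl.std(axis=0, ddof=0)
        sds = np.where(sds == 0, 1.0, sds)
        X = (Xl - means) / sds
    elif transform == "identity":
        means = np.zeros(X_raw.shape[1])
        sds = np.ones(X_raw.shape[1])
        X = X_raw
    else:
        raise ValueError(f"unknown transform {transform!r}")
    clf = SVC(kernel="linear", C=c_reg, random_state=seed)
    clf.fit(X, y)
    return PanelModel(
        peptide_ids=list(panel.peptide_ids),
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_means=means,
        feature_sds=sds,
        transform=transform,
        positive_label=classes[1],
        negative_label=classes[0],
        n_per_class={classes[0]: int((1 - y).sum()), classes[1]: int(y.sum())},
        c_reg=c_reg,
        seed=seed,
    )


def svm_score(model: PanelModel, amplitudes) -> float:
    """Signed distance of one sample to the maximal-margin hyperplane.

    ``amplitudes`` maps peptide_id -> intensity (dict or Series); panel
    peptides absent from it are imputed as amplitude 0 before the
    transform. Positive scores lie on the positive-label side.
    """
    if isinstance(amplitudes, pd.Series):
        amplitudes = amplitudes.to_dict()
    x = np.array([float(amplitudes.get(p, 0.0)) for p in model.peptide_ids])
    feats = model.transform_features(x)
    norm = np.linalg.norm(model.weights)
    if norm == 0:
        return 0.0
    return float((model.weights @ feats + model.intercept) / norm)


def score_matrix(model: PanelModel, matrix: PeptideMatrix) -> pd.Series:
    """SVM scores for every sample of a matrix (vectorized)."""
    amp = matrix.amplitudes.reindex(model.peptide_ids).fillna(0.0).to_numpy(float).T
    feats = model.transform_features(amp)
    norm = np.linalg.norm(model.weights)
    scores = (feats @ model.weights + model.intercept) / (norm if norm else 1.0)
    return pd.Series(scores, index=matrix.sample_ids, name="svm_score")


def cross_validate_scores(
    matrix: PeptideMatrix,
    panel: PanelDefinition,
    labels: pd.Series,
    k: int = 10,
    seed: int = 0,
    c_reg: float = 1.0,
) -> pd.Series:
    """Stratified k-fold out-of-fold SVM scores.

    Every sample is scored exactly once by a model that never saw it; fold
    assignment is stratified by class and reproducible under ``seed``.
    Raises (suggesting a smaller k) when a training fold loses a class.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = labels.reindex(matrix.sample_ids).astype(str)
    y = labels.to_numpy()
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class ({counts.min()} samples); "
            "use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = pd.Series(np.nan, index=matrix.sample_ids, name="svm_score")
    sample_arr = np.array(matrix.sample_ids)
    for train_idx, test_idx in skf.split(sample_arr, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"a training fold lost a class; use a smaller k than {k}")
        sub = matrix.subset_samples(sample_arr[train_idx])
        model = train_panel(sub, panel, labels.loc[sample_arr[train_idx]], c_reg=c_reg, seed=seed)
        test = matrix.subset_samples(sample_arr[test_idx])
        scores.loc[sample_arr[test_idx]] = score_matrix(model, test).to_numpy()
    return scores
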