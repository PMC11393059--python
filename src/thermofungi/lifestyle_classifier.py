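"""Orthogroup-based thermophile/mesophile classification.

The procedure: drop low-variance orthogroups, rank each remaining
orthogroup by how well a single-feature support-vector classifier predicts
lifestyle across several fixed training subsets, keep the top features
whose point-biserial correlation with the lifestyle label is high, try
every combination of the kept features, and report the best combination,
per-genome lifestyle probabilities, and a per-feature z-score matrix
(z = (x - mu) / sigma) for heatmap export. Thermotolerant genomes never
enter training; they are scored as test items only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .formats_io import OrthogroupMatrix

logger = logging.getLogger(__name__)

THERMOPHILE, MESOPHILE = 1, 0


@dataclass
class FeatureTable:
    """Genome x orthogroup counts for labeled genomes, thermotolerant held out."""

    X: pd.DataFrame  # labeled genomes x features
    y: pd.Series  # 1 = thermophilic, 0 = mesophilic
    X_test: pd.DataFrame  # thermotolerant genomes x features

    @property
    def features(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class TrainingSubset:
    train: list[str]
    validation: list[str]


@dataclass
class ClassifierReport:
    ranked: pd.DataFrame  # feature, accuracy, correlation
    selected: list[str]
    combinations: pd.DataFrame  # combo, size, accuracy
    best_combination: tuple[str, ...]
    best_accuracy: float
    probabilities: pd.DataFrame  # genome, role, p_thermophile, p_mesophile
    zscores: pd.DataFrame
    settings: dict = field(default_factory=dict)

    def model_card(self) -> dict:
        return {
            "selected_features": list(self.selected),
            "best_combination": list(self.best_combination),
            "best_accuracy": self.best_accuracy,
            "settings": self.settings,
        }


def build_feature_table(matrix: OrthogroupMatrix, binarize: bool = False) -> FeatureTable:
    """Orient the count matrix for learning (genomes as rows).

    Requires lifestyles attached; ``binarize`` converts counts to
    presence/absence.
    """
    if matrix.lifestyles is None:
        raise ValueError("matrix has no lifestyle labels; attach metadata first")
    counts = matrix.counts.T  # genomes x orthogroups
    if binarize:
        counts = (counts >= 1).astype(int)
    ls = matrix.lifestyles
    labeled = ls[ls.isin(["thermophilic", "mesophilic"])]
    y = (labeled == "thermophilic").astype(int)
    test_genomes = ls.index[ls == "thermotolerant"]
    return FeatureTable(
        X=counts.loc[labeled.index],
        y=y,
        X_test=counts.loc[test_genomes],
    )


def variance_filter(table: FeatureTable, threshold: float = 0.1) -> FeatureTable:
    """Drop features with population variance below ``threshold`` (over the
    labeled genomes)."""
    var = table.X.var(axis=0, ddof=0)
    keep = var[var >= threshold].index
    if len(keep) == 0:
        raise ValueError("variance filter removed every feature")
    logger.info(
        "variance_filter: kept %d / %d features (threshold %.3g)",
        len(keep), table.X.shape[1], threshold,
    )
    return FeatureTable(
        X=table.X[keep], y=table.y, X_test=table.X_test[keep]
    )


def make_training_subsets(
    labels: pd.Series,
    n_subsets: int = 5,
    n_thermo: int = 20,
    n_meso: int = 30,
    seed: "int | None" = None,
) -> list[TrainingSubset]:
    """Fixed train/validation splits with exact per-class training counts.

    When a class has too few genomes the requested counts are scaled down
    proportionally (floored, reserving one genome per class for
    validation) and a warning is logged.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible subsets")
    thermo = sorted(labels.index[labels == THERMOPHILE])
    meso = sorted(labels.index[labels == MESOPHILE])
    if len(thermo) < 2 or len(meso) < 2:
        raise ValueError("each class needs at least 2 genomes")
    scale = min((len(thermo) - 1) / n_thermo, (len(meso) - 1) / n_meso, 1.0)
    nt, nm = max(1, int(n_thermo * scale)), max(1, int(n_meso * scale))
    if scale < 1.0:
        logger.warning(
            "make_training_subsets: scaled training counts down to (%d, %d)", nt, nm
        )
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_subsets):
        tr = sorted(rng.choice(thermo, size=nt, replace=False)) + sorted(
            rng.choice(meso, size=nm, replace=False)
        )
        va = sorted((set(thermo) | set(meso)) - set(tr))
        subsets.append(TrainingSubset(train=tr, validation=va))
    return subsets


def _svc(kernel: str = "linear") -> SVC:
    # maximum-margin classifier with library-default regularisation; the
    # linear kernel behaves like a weighted vote over orthogroup counts,
    # which is what the combination search relies on (RBF available too)
    return SVC(kernel=kernel, C=1.0, gamma="scale", random_state=0)


def _index_subsets(
    X: pd.DataFrame, subsets: list[TrainingSubset]
) -> list[tuple[np.ndarray, np.ndarray]]:
    pos = {g: i for i, g in enumerate(X.index)}
    return [
        (
            np.array([pos[g] for g in sub.train], dtype=int),
            np.array([pos[g] for g in sub.validation], dtype=int),
        )
        for sub in subsets
    ]


def _subset_accuracy_arrays(
    Xa: np.ndarray, ya: np.ndarray,
    idx_pairs: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    accs = []
    for tr, va in idx_pairs:
        y_tr = ya[tr]
        if len(np.unique(y_tr)) < 2 or len(va) == 0:
            logger.warning("degenerate subset skipped")
            continue
        clf = _svc()
        clf.fit(Xa[tr], y_tr)
        accs.append(float((clf.predict(Xa[va]) == ya[va]).mean()))
    if not accs:
        raise ValueError("no usable training subset")
    return float(np.mean(accs))


def _subset_accuracy(
    X: pd.DataFrame, y: pd.Series, features: "list[str] | tuple[str, ...]",
    subsets: list[TrainingSubset],
) -> float:
    return _subset_accuracy_arrays(
        X[list(features)].to_numpy(dtype=float),
        y.to_numpy(),
        _index_subsets(X, subsets),
    )


def rank_features(
    table: FeatureTable, subsets: list[TrainingSubset]
) -> pd.DataFrame:
    """Mean validation accuracy of a single-feature classifier per feature,
    plus its point-biserial correlation with the label, sorted by accuracy."""
    rows = []
    ya = table.y.to_numpy()
    Xa = table.X.to_numpy(dtype=float)
    idx_pairs = _index_subsets(table.X, subsets)
    for j, feat in enumerate(table.features):
        x = Xa[:, j]
        acc = _subset_accuracy_arrays(x[:, None], ya, idx_pairs)
        if np.std(x) == 0:
            corr = np.nan
        else:
            corr = float(stats.pointbiserialr(ya, x).statistic)
        rows.append({"feature": feat, "accuracy": acc, "correlation": corr})
    ranked = pd.DataFrame(rows).sort_values(
        ["accuracy", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    logger.info(
        "rank_features: %d features ranked, best %.3f (%s)",
        len(ranked), ranked["accuracy"].iloc[0], ranked["feature"].iloc[0],
    )
    return ranked


def select_top(
    ranked: pd.DataFrame,
    correlation_threshold: float = 0.75,
    top_k: int = 10,
) -> list[str]:
    """Features whose |point-biserial correlation| exceeds the threshold,
    capped at ``top_k`` by accuracy rank; constants (NaN correlation) are
    excluded."""
    mask = ranked["correlation"].abs() > correlation_threshold
    chosen = ranked[mask.fillna(False)]["feature"].head(top_k).tolist()
    if not chosen:
        logger.warning("select_top: no feature passed |r| > %g", correlation_threshold)
    return chosen


def combo_search(
    table: FeatureTable,
    selected: list[str],
    subsets: list[TrainingSubset],
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Evaluate every non-empty subset of the selected features.

    Best combination = highest mean validation accuracy; ties break toward
    fewer features, then lexicographic feature ids.
    """
    if not 1 <= len(selected) <= 15:
        raise ValueError(
            f"{len(selected)} selected features; need 1..15 "
            "(reduce top_k for a tractable search)"
        )
    rows = []
    sel = sorted(selected)
    col = {f: j for j, f in enumerate(sel)}
    Xsel = table.X[sel].to_numpy(dtype=float)
    ya = table.y.to_numpy()
    idx_pairs = _index_subsets(table.X, subsets)
    for size in range(1, len(sel) + 1):
        for combo in itertools.combinations(sel, size):
            cols = [col[f] for f in combo]
            acc = _subset_accuracy_arrays(Xsel[:, cols], ya, idx_pairs)
            rows.append({"combo": combo, "size": size, "accuracy": acc})
    combos = pd.DataFrame(rows)
    best_row = combos.sort_values(
        ["accuracy", "size", "combo"], ascending=[False, True, True], kind="mergesort"
    ).iloc[0]
    logger.info(
        "combo_search: %d combinations, best %.3f with %d features",
        len(combos), best_row["accuracy"], best_row["size"],
    )
    return tuple(best_row["combo"]), combos


def predict(
    table: FeatureTable, features: "tuple[str, ...] | list[str]"
) -> pd.DataFrame:
    """Per-genome lifestyle probabilities from the final model.

    The classifier is trained on all labeled genomes with the chosen
    features (Platt-calibrated probabilities); labeled genomes and held-out
    thermotolerant genomes are all scored.
    """
    missing = [f for f in features if f not in table.X.columns]
    if missing:
        raise ValueError(f"feature(s) missing from input: {missing}")
    clf = _svc()
    clf.fit(table.X[list(features)], table.y)
    # Platt calibration: logistic fit of the label on the decision values
    platt = LogisticRegression(C=1e6)
    platt.fit(clf.decision_function(table.X[list(features)])[:, None], table.y)
    rows = []
    for frame, role in ((table.X, "labeled"), (table.X_test, "test")):
        if frame.empty:
            continue
        dec = clf.decision_function(frame[list(features)])[:, None]
        proba = platt.predict_proba(dec)
        p_thermo = proba[:, list(platt.classes_).index(THERMOPHILE)]
        for genome, p in zip(frame.index, p_thermo):
            rows.append(
                {
                    "genome": genome,
                    "role": role,
                    "p_thermophile": float(p),
                    "p_mesophile": float(1.0 - p),
                }
            )
    return pd.DataFrame(rows).set_index("genome")


def zscore_matrix(
    table: FeatureTable, features: "list[str] | tuple[str, ...]"
) -> pd.DataFrame:
    """Per-feature standardisation z = (x - mu) / sigma over labeled genomes
    (population sigma), for heatmap export."""
    X = pd.concat([table.X, table.X_test])[list(features)].astype(float)
    mu = table.X[list(features)].mean(axis=0)
    sigma = table.X[list(features)].std(axis=0, ddof=0)
    if (sigma == 0).any():
        bad = sigma.index[sigma == 0].tolist()
        raise ValueError(f"zero standard deviation for feature(s) {bad}")
    return (X - mu) / sigma


def run_pipeline(
    matrix: OrthogroupMatrix,
    seed: int,
    variance_threshold: float = 0.1,
    n_subsets: int = 5,
    n_thermo: int = 20,
    n_meso: int = 30,
    correlation_threshold: float = 0.75,
    top_k: int = 10,
    binarize: bool = False,
) -> ClassifierReport:
    """Full procedure: filter, rank, select, combination search, predict."""
    table = variance_filter(
        build_feature_table(matrix, binarize=binarize), variance_threshold
    )
    subsets = make_training_subsets(
        table.y, n_subsets=n_subsets, n_thermo=n_thermo, n_meso=n_meso, seed=seed
    )
    ranked = rank_features(table, subsets)
    selected = select_top(ranked, correlation_threshold, top_k)
    if selected:
        best, combos = combo_search(table, selected, subsets)
        best_acc = float(combos.set_index("combo").loc[[best], "accuracy"].iloc[0])
    else:
        best = tuple(ranked["feature"].head(1))
        combos = pd.DataFrame(columns=["combo", "size", "accuracy"])
        best_acc = float(ranked["accuracy"].iloc[0])
    probabilities = predict(table, best)
    zscores = zscore_matrix(table, best)
    return ClassifierReport(
        ranked=ranked,
        selected=selected,
        combinations=combos,
        best_combination=best,
        best_accuracy=best_acc,
        probabilities=probabilities,
        zscores=zscores,
        settings={
            "seed": seed,
            "variance_threshold": variance_threshold,
            "n_subsets": n_subsets,
            "n_thermo": n_thermo,
            "n_meso": n_meso,
            "correlation_threshold": correlation_threshold,
            "top_k": top_k,
            "binarize": binarize,
            "kernel": "linear",
        },
    )
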