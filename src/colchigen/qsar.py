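"""QSAR activity models: pIC50 transform, correlation-threshold feature
selection, the five-method model tournament, and candidate prediction.

Activities in nM are transformed to pIC50 = 9 - log10(IC50/nM) before
modelling.  Features are the descriptor columns whose absolute Pearson
correlation with pIC50 meets a threshold; the tournament fits multiple
linear regression, a decision tree, a random forest, k-nearest neighbors
and a support-vector machine at each of the random states {15, 28, 42} and
reports Pearson R on train/test/whole-dataset plus MSE/MAE/RMSE.  The final
per-cell-line model is the configuration with the best test correlation
(ties: lower test RMSE, fewer features, then RF > DT > others).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .corpus import CellLine, MoleculeRecord, from_pic50, to_pic50
from .descriptors import DescriptorMatrix, compute_descriptors

__all__ = [
    "to_pic50", "from_pic50", "QsarConfig", "ModelReport", "FittedModel",
    "select_features", "regression_metrics", "run_tournament",
    "select_best_model", "fit_final_model", "predict_activities",
]

METHODS = ("MLR", "DT", "RF", "KNN", "SVM")
RANDOM_STATES = (15, 28, 42)
#: tie-break preference after R_test / RMSE / feature count
_METHOD_PREFERENCE = {"RF": 0, "DT": 1, "MLR": 2, "KNN": 2, "SVM": 2}


@dataclass(frozen=True)
class QsarConfig:
    method: str = "RF"
    random_state: int = 15
    correlation_threshold: float = 0.5
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must lie in (0, 1)")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")


#: Published final model configurations for the original 120-compound
#: activity library (their numeric metrics depend on that library).
PUBLISHED_FINAL_CONFIGS: dict[CellLine, QsarConfig] = {
    CellLine.A549: QsarConfig("RF", 15, 0.51),
    CellLine.BALB3T3: QsarConfig("RF", 15, 0.51),
    CellLine.LOVODX: QsarConfig("RF", 42, 0.63),
    CellLine.LOVO: QsarConfig("RF", 28, 0.54),
    CellLine.MCF7: QsarConfig("RF", 15, 0.51),
}

PUBLISHED_FEATURE_SETS: dict[CellLine, tuple[str, ...]] = {
    CellLine.A549: ("AMID_O", "EState_VSA5", "MDEO-12", "SaasC", "VSA_EState5"),
    CellLine.BALB3T3: ("AMID_O", "EState_VSA5", "GATS2c", "MDEO-12", "NdssC", "VSA_EState5"),
    CellLine.LOVODX: ("GATS2c", "MATS2c", "NdssC", "RNCG", "TopoPSA(NO)"),
    CellLine.LOVO: ("EState_VSA5", "MDEO-12"),
    CellLine.MCF7: ("AMID_O", "EState_VSA5", "MDEO-12", "EState_VSA6"),
}


def _make_estimator(config: QsarConfig):
    if config.method == "MLR":
        return LinearRegression()
    if config.method == "DT":
        return DecisionTreeRegressor(random_state=config.random_state)
    if config.method == "RF":
        return RandomForestRegressor(random_state=config.random_state)
    if config.method == "KNN":
        return KNeighborsRegressor()
    return SVR()


def select_features(
    X: DescriptorMatrix | pd.DataFrame, y: np.ndarray, threshold: float
) -> list[str]:
    """Columns with ``|Pearson r(column, pIC50)| >= threshold``, by descending |r|.

    Constant columns (undefined correlation) are skipped.  Raising the
    threshold can only shrink the selected set.
    """
    frame = X.values if isinstance(X, DescriptorMatrix) else X
    y = np.asarray(y, dtype=float)
    if len(frame) != len(y):
        raise ValueError("X and y must have matching lengths")
    if len(y) < 3:
        raise ValueError("need at least 3 samples for correlation screening")
    scored: list[tuple[float, str]] = []
    for name in frame.columns:
        col = frame[name].to_numpy(dtype=float)
        if np.ptp(col) == 0 or np.ptp(y) == 0:
            continue
        r = float(stats.pearsonr(col, y)[0])
        if np.isfinite(r) and abs(r) >= threshold:
            scored.append((abs(r), name))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [name for _, name in scored]


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """Pearson R plus MSE/MAE/RMSE of predictions against observations."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must be equal-length vectors of size >= 2")
    resid = yhat - y
    mse = float(np.mean(resid**2))
    if np.ptp(y) == 0:
        r = float("nan")  # correlation undefined for constant observations
    elif np.ptp(yhat) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(y, yhat)[0])
    return {
        "R": r,
        "MSE": mse,
        "MAE": float(np.mean(np.abs(resid))),
        "RMSE": float(np.sqrt(mse)),
    }


@dataclass
class ModelReport:
    """One tournament entry: configuration, features, and quality metrics.

    ``MSE``/``MAE``/``RMSE`` and ``R_overall`` are whole-dataset metrics (the
    final-table convention for published models); test-set metrics carry a ``_test``
    suffix and drive model selection.
    """

    config: QsarConfig
    cell_line: CellLine | None
    feature_names: list[str]
    R_train: float
    R_test: float
    R_overall: float
    MSE: float
    MAE: float
    RMSE: float
    MSE_test: float
    MAE_test: float
    RMSE_test: float

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _fit_and_report(
    frame: pd.DataFrame,
    y: np.ndarray,
    config: QsarConfig,
    features: list[str],
    cell_line: CellLine | None,
) -> tuple[ModelReport, object]:
    Xmat = frame[features].to_numpy(dtype=float)
    X_train, X_test, y_train, y_test = train_test_split(
        Xmat, y, test_size=config.test_fraction, random_state=config.random_state
    )
    if len(X_train) == 0 or len(X_test) == 0:
        raise ValueError(f"degenerate split for config {config}")
    est = _make_estimator(config)
    est.fit(X_train, y_train)
    m_train = regression_metrics(y_train, est.predict(X_train))
    m_test = regression_metrics(y_test, est.predict(X_test))
    m_all = regression_metrics(y, est.predict(Xmat))
    report = ModelReport(
        config=config,
        cell_line=cell_line,
        feature_names=list(features),
        R_train=m_train["R"],
        R_test=m_test["R"],
        R_overall=m_all["R"],
        MSE=m_all["MSE"],
        MAE=m_all["MAE"],
        RMSE=m_all["RMSE"],
        MSE_test=m_test["MSE"],
        MAE_test=m_test["MAE"],
        RMSE_test=m_test["RMSE"],
    )
    return report, est


def run_tournament(
    X: DescriptorMatrix | pd.DataFrame,
    y: np.ndarray,
    configs: list[QsarConfig],
    cell_line: CellLine | None = None,
) -> list[ModelReport]:
    """Fit every configuration and report its metrics.

    Each config screens features at its own correlation threshold, splits
    the data at its random state, fits, and is scored on train/test/whole
    data.  Deterministic for fixed inputs.
    """
    if not configs:
        raise ValueError("configs must be nonempty")
    frame = X.values if isinstance(X, DescriptorMatrix) else X
    y = np.asarray(y, dtype=float)
    reports = []
    for config in configs:
        features = select_features(frame, y, config.correlation_threshold)
        if not features:
            raise ValueError(
                f"no features pass threshold {config.correlation_threshold} for {config}"
            )
        report, _ = _fit_and_report(frame, y, config, features, cell_line)
        reports.append(report)
    return reports


def default_tournament_configs(
    correlation_threshold: float = 0.5, test_fraction: float = 0.2
) -> list[QsarConfig]:
    """The 5-method x 3-random-state grid."""
    return [
        QsarConfig(method, state, correlation_threshold, test_fraction)
        for method in METHODS
        for state in RANDOM_STATES
    ]


def select_best_model(reports: list[ModelReport]) -> tuple[QsarConfig, list[ModelReport]]:
    """Best configuration by test correlation.

    Ties break by lower test RMSE, then fewer features, then method
    preference (RF over DT over the rest).  Returns the winning config and
    the full ranking, best first.
    """
    if not reports:
        raise ValueError("reports must be nonempty")
    lines = {r.cell_line for r in reports}
    if len(lines) > 1:
        raise ValueError(f"reports mix cell lines: {lines}")
    ranked = sorted(
        reports,
        key=lambda r: (
            -r.R_test,
            r.RMSE_test,
            r.n_features,
            _METHOD_PREFERENCE[r.config.method],
            r.config.random_state,
        ),
    )
    return ranked[0].config, ranked


@dataclass
class FittedModel:
    """A final per-cell-line model: estimator plus its frozen feature list."""

    cell_line: CellLine
    config: QsarConfig
    feature_names: list[str]
    estimator: object
    report: ModelReport | None = None

    def predict_pic50(self, descriptor_rows: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(descriptor_rows[self.feature_names].to_numpy(dtype=float))


def fit_final_model(
    X: DescriptorMatrix | pd.DataFrame,
    y: np.ndarray,
    config: QsarConfig,
    cell_line: CellLine,
) -> FittedModel:
    """Fit one configuration for production prediction (train/test split kept
    for the report; the estimator is refit on the training portion only so the
    report's test metrics describe this exact estimator)."""
    frame = X.values if isinstance(X, DescriptorMatrix) else X
    y = np.asarray(y, dtype=float)
    features = select_features(frame, y, config.correlation_threshold)
    if not features:
        raise ValueError(f"no features pass threshold {config.correlation_threshold}")
    report, est = _fit_and_report(frame, y, config, features, cell_line)
    return FittedModel(
        cell_line=cell_line, config=config, feature_names=features,
        estimator=est, report=report,
    )


def predict_activities(
    final_models: dict[CellLine, FittedModel],
    candidates: list[MoleculeRecord],
) -> tuple[dict[tuple[str, CellLine], float], list[str]]:
    """Predict IC50 (nM) for every candidate under every cell-line model.

    Returns ``(predictions, excluded_ids)``: predictions are keyed by
    ``(candidate id, cell line)`` and are strictly positive by construction
    (back-transform of pIC50); candidates whose selected descriptors cannot
    be computed are excluded and reported, never silently zeroed.
    """
    needed = sorted({f for m in final_models.values() for f in m.feature_names})
    matrix = compute_descriptors(candidates, names=needed)
    excluded = list(matrix.failed_molecules)
    usable = matrix.values.dropna()
    excluded.extend(i for i in matrix.values.index if i not in usable.index)
    missing_cols = [c for c in needed if c not in usable.columns]
    if missing_cols:
        raise ValueError(f"descriptors {missing_cols} undefined across all candidates")

    predictions: dict[tuple[str, CellLine], float] = {}
    for line, model in final_models.items():
        pic50 = model.predict_pic50(usable)
        for mol_id, value in zip(usable.index, pic50):
            predictions[(mol_id, line)] = from_pic50(float(value))
    return predictions, excluded


# ---------------------------------------------------------------------------
# persistence

def save_models(models: dict[CellLine, FittedModel], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {}
    for line, model in models.items():
        tag = line.name
        joblib.dump(model.estimator, directory / f"{tag}.joblib")
        meta[tag] = {
            "cell_line": line.label,
            "config": asdict(model.config),
            "feature_names": model.feature_names,
            "metrics": None
            if model.report is None
            else {
                "R_train": model.report.R_train,
                "R_test": model.report.R_test,
                "R_overall": model.report.R_overall,
                "MSE": model.report.MSE,
                "MAE": model.report.MAE,
                "RMSE": model.report.RMSE,
            },
        }
    (directory / "models.json").write_text(json.dumps(meta, indent=1))


def load_models(directory: str | Path) -> dict[CellLine, FittedModel]:
    directory = Path(directory)
    meta = json.loads((directory / "models.json").read_text())
    models = {}
    for tag, entry in meta.items():
        line = CellLine[tag]
        models[line] = FittedModel(
            cell_line=line,
            config=QsarConfig(**entry["config"]),
            feature_names=entry["feature_names"],
            estimator=joblib.load(directory / f"{tag}.joblib"),
        )
    return models


def export_predictions(
    predictions: dict[tuple[str, CellLine], float],
    candidates: list[MoleculeRecord],
    path: str | Path,
) -> None:
    """CSV of predicted IC50 (nM) keyed by canonical SMILES."""
    by_id = {c.id: c for c in candidates}
    ids = sorted({mol_id for mol_id, _ in predictions})
    rows = []
    for mol_id in ids:
        row = {"id": mol_id, "smiles": by_id[mol_id].canonical_smiles}
        for line in CellLine:
            if (mol_id, line) in predictions:
                row[line.label] = predictions[(mol_id, line)]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
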