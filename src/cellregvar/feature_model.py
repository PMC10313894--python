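"""TSS-centered chromatin-feature layout and per-cell-cluster expression models.

A gene is represented by a grid of chromatin-feature predictions (``n_features``
tracks x ``n_bins`` sequence bins) covering a window centered on its
transcription start site.  A regularized boosted-linear model maps the
flattened grid to log expression for one cell cluster; genes on a held-out
chromosome measure generalization.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureLayout",
    "FeatureGrid",
    "TrainConfig",
    "ExpressionModel",
    "ModelEvaluation",
    "build_layout",
    "aggregate_cluster_expression",
    "normalize_chromosome",
    "split_by_chromosome",
    "train_expression_model",
    "evaluate_model",
    "lineage_fold_change_eval",
]


@dataclass(frozen=True)
class FeatureLayout:
    """Geometry of the TSS-centered feature grid.

    Parameters
    ----------
    window_bp : int
        Half-width of the genomic window around the TSS, in base pairs.
    bin_bp : int
        Width of one sequence bin, in base pairs.
    n_features : int
        Number of chromatin-feature tracks per bin (histone marks,
        TF binding, DNase hypersensitivity).
    """

    window_bp: int = 20_000
    bin_bp: int = 200
    n_features: int = 2002

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.bin_bp <= 0 or self.n_features <= 0:
            raise ValueError("layout dimensions must be positive")
        if (2 * self.window_bp) % self.bin_bp != 0:
            raise ValueError(
                f"window of {2 * self.window_bp} bp is not divisible by "
                f"bin width {self.bin_bp} bp"
            )

    @property
    def n_bins(self) -> int:
        return (2 * self.window_bp) // self.bin_bp

    @property
    def total_features(self) -> int:
        """Total model inputs per gene: n_features * n_bins."""
        return self.n_features * self.n_bins


def build_layout(window_bp: int = 20_000, bin_bp: int = 200,
                 n_features: int = 2002) -> FeatureLayout:
    """Construct and validate a :class:`FeatureLayout`."""
    return FeatureLayout(window_bp=window_bp, bin_bp=bin_bp, n_features=n_features)


@dataclass
class FeatureGrid:
    """Per-gene chromatin-feature matrix (n_features x n_bins).

    Bins are ordered 5'->3' along the annotated gene strand, so bin index is
    strand-consistent position relative to the TSS.
    """

    gene_id: str
    values: np.ndarray
    layout: FeatureLayout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.layout.n_features, self.layout.n_bins)
        if self.values.shape != expected:
            raise ValueError(
                f"grid for {self.gene_id} has shape {self.values.shape}, "
                f"layout expects {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"grid for {self.gene_id} contains non-finite values")

    def flatten(self) -> np.ndarray:
        """Flatten in layout order (feature-major)."""
        return self.values.ravel()


def aggregate_cluster_expression(cell_by_gene: pd.DataFrame,
                                 cluster_labels: pd.Series | np.ndarray,
                                 ) -> pd.DataFrame:
    """Aggregate normalized single-cell expression into per-cluster profiles.

    Per cluster, takes the mean across cells of each gene's normalized value
    and applies log(1 + x).  Returns a gene-by-cluster table.

    Parameters
    ----------
    cell_by_gene : DataFrame
        Cells in rows, genes in columns; nonnegative normalized values.
    cluster_labels : sequence
        Cluster assignment per cell, aligned with the rows.
    """
    labels = pd.Series(np.asarray(cluster_labels), index=cell_by_gene.index)
    if len(labels) != len(cell_by_gene):
        raise ValueError("cluster_labels must cover all cells")
    if (cell_by_gene.values < 0).any():
        raise ValueError("expression values must be nonnegative")
    means = cell_by_gene.groupby(labels).mean()
    return np.log1p(means).T  # genes x clusters


_CHROM_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def normalize_chromosome(chrom: str) -> str:
    """Normalize chromosome names to the 'chrN' dialect ('8' -> 'chr8')."""
    m = _CHROM_RE.match(str(chrom).strip())
    return "chr" + m.group(2)


def split_by_chromosome(gene_table: pd.DataFrame, holdout: str = "chr8",
                        ) -> tuple[list[str], list[str]]:
    """Partition genes into training and held-out test sets by chromosome.

    ``gene_table`` must have a ``gene_id`` column (or index) and a ``chrom``
    column; chromosome dialects '8' and 'chr8' are equivalent.
    """
    if "gene_id" in gene_table.columns:
        ids = gene_table["gene_id"].astype(str)
    else:
        ids = gene_table.index.astype(str)
    chroms = gene_table["chrom"].map(normalize_chromosome)
    holdout = normalize_chromosome(holdout)
    test_mask = (chroms == holdout).to_numpy()
    if not test_mask.any():
        raise ValueError(f"holdout chromosome {holdout} has no genes")
    test_ids = list(ids[test_mask])
    train_ids = list(ids[~test_mask])
    return train_ids, test_ids


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the boosted-linear trainer (gblinear contract)."""

    max_rounds: int = 40
    early_stop_rounds: int = 10
    eta: float = 0.5
    l2_lambda: float = 100.0
    validation_fraction: float = 0.1
    holdout_chromosome: str = "chr8"

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if not (0 < self.eta <= 1):
            raise ValueError("eta must lie in (0, 1]")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be nonnegative")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in [0, 1)")


@dataclass
class ExpressionModel:
    cluster_id: str
    weights: np.ndarray
    intercept: float
    rounds_used: int
    validation_loss: list[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.weights


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Closed-form L2-penalized least squares; intercept unpenalized."""
    n, p = X.shape
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    # (Xc'Xc + lam I) w = Xc'yc ; solve in the smaller of p or n dimensions
    if p <= n:
        A = Xc.T @ Xc + lam * np.eye(p)
        w = np.linalg.solve(A, Xc.T @ yc)
    else:
        # dual form: w = Xc'(Xc Xc' + lam I)^-1 yc
        K = Xc @ Xc.T + lam * np.eye(n)
        w = Xc.T @ np.linalg.solve(K, yc)
    intercept = ym - xm @ w
    return w, intercept


def train_expression_model(X: np.ndarray, y: np.ndarray,
                           config: TrainConfig = TrainConfig(),
                           seed: int = 0,
                           cluster_id: str = "cluster") -> ExpressionModel:
    """Fit a regularized boosted-linear expression model for one cell cluster.

    Each boosting round moves the weight vector a fraction ``eta`` toward the
    closed-form L2-penalized squared-error solution; rounds stop early when
    the validation loss has not improved for ``early_stop_rounds`` consecutive
    rounds.  The validation genes are a seeded random fraction of the training
    genes — never the chromosome holdout, which would leak test information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("rows of X must match length of y")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n = X.shape[0]

    rng = np.random.default_rng(seed)
    n_val = int(round(config.validation_fraction * n))
    if config.validation_fraction > 0 and n_val == 0:
        raise ValueError(
            f"{n} genes are too few for validation_fraction="
            f"{config.validation_fraction}"
        )
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if fit_idx.size < 2:
        raise ValueError("too few genes left for fitting after validation split")
    Xf, yf = X[fit_idx], y[fit_idx]
    Xv, yv = X[val_idx], y[val_idx]

    w_star, b_star = _ridge_solve(Xf, yf, config.l2_lambda)

    w = np.zeros(X.shape[1])
    b = float(yf.mean())
    best = (w.copy(), b, 0)
    best_loss = np.inf
    stall = 0
    trace: list[float] = []
    for rnd in range(1, config.max_rounds + 1):
        w = w + config.eta * (w_star - w)
        b = b + config.eta * (b_star - b)
        if n_val > 0:
            resid = yv - (b + Xv @ w)
            loss = float(np.sqrt(np.mean(resid ** 2)))
        else:
            resid = yf - (b + Xf @ w)
            loss = float(np.sqrt(np.mean(resid ** 2)))
        trace.append(loss)
        if loss < best_loss - 1e-12:
            best_loss = loss
            best = (w.copy(), b, rnd)
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_rounds:
                break
    w_best, b_best, rounds_used = best
    return ExpressionModel(cluster_id=cluster_id, weights=w_best,
                           intercept=b_best, rounds_used=rounds_used,
                           validation_loss=trace)


@dataclass
class ModelEvaluation:
    pcc: float | None
    n_test: int


def evaluate_model(model: ExpressionModel, X_test: np.ndarray,
                   y_test: np.ndarray) -> ModelEvaluation:
    """Pearson correlation between predicted and observed held-out expression.

    Returns a missing (None) PCC when either vector has zero variance.
    """
    y_test = np.asarray(y_test, dtype=float)
    pred = model.predict(X_test)
    if np.std(pred) == 0 or np.std(y_test) == 0:
        return ModelEvaluation(pcc=None, n_test=len(y_test))
    r, _ = stats.pearsonr(pred, y_test)
    return ModelEvaluation(pcc=float(r), n_test=len(y_test))


def lineage_fold_change_eval(pred: pd.DataFrame, obs: pd.DataFrame,
                             focal_cluster: str) -> dict:
    """Compare predicted vs observed cluster specificity of expression.

    The log fold change of a gene is its (log-scale) expression in the focal
    cluster minus its mean over all clusters; the returned PCC measures how
    well predicted fold changes track observed ones across genes.
    """
    if pred.shape[1] < 2 or obs.shape[1] < 2:
        raise ValueError("lineage fold change requires at least 2 clusters")
    pred, obs = pred.align(obs, join="inner")
    lfc_pred = pred[focal_cluster] - pred.mean(axis=1)
    lfc_obs = obs[focal_cluster] - obs.mean(axis=1)
    if np.std(lfc_pred) == 0 or np.std(lfc_obs) == 0:
        pcc = None
    else:
        pcc = float(stats.pearsonr(lfc_pred, lfc_obs)[0])
    return {"lfc_pred": lfc_pred, "lfc_obs": lfc_obs, "pcc": pcc}


class XgbLinearModel:
    """Thin predict-only wrapper around an xgboost gblinear booster."""

    def __init__(self, booster, cluster_id: str):
        self._booster = booster
        self.cluster_id = cluster_id

    def predict(self, X: np.ndarray) -> np.ndarray:
        import xgboost as xgb

        return self._booster.predict(xgb.DMatrix(np.asarray(X, dtype=float)))


def train_with_backend(X, y, config: TrainConfig = TrainConfig(), seed: int = 0,
                       cluster_id: str = "cluster") -> XgbLinearModel:
    """Fit the same model through the xgboost gblinear backend (optional).

    Exists as a cross-check: predictions should closely agree with the native
    trainer on well-posed problems.  Requires the ``xgboost`` extra.
    """
    import xgboost as xgb

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_val = int(round(config.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    dtrain = xgb.DMatrix(X[fit_idx], label=y[fit_idx])
    evals = []
    if n_val > 0:
        evals = [(xgb.DMatrix(X[val_idx], label=y[val_idx]), "validation")]
    params = {
        "booster": "gblinear",
        "objective": "reg:squarederror",
        "eta": config.eta,
        "lambda": config.l2_lambda,
        "alpha": 0.0,
        "updater": "coord_descent",
        "nthread": 1,
    }
    booster = xgb.train(params, dtrain, num_boost_round=config.max_rounds,
                        evals=evals,
                        early_stopping_rounds=(config.early_stop_rounds
                                               if evals else None),
                        verbose_eval=False)
    return XgbLinearModel(booster, cluster_id)
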