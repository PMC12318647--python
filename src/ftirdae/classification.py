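"""Cross-validated case-control classification workflow.

The workflow mirrors the study design: per stratified CV fold, a
multivariate Gaussian is fitted on the *training* spectra only, synthetic
spectra are sampled from it to train a fold-specific denoising autoencoder,
and a logistic-regression classifier (grid-searched regularization) is
evaluated on the untouched test fold.  Three feature arms are supported:

* ``manual``        — the manually preprocessed spectra themselves,
* ``reconstructed`` — autoencoder (decoder) output,
* ``latent``        — encoder bottleneck output after backward feature
  selection.

No stage (MVN fit, autoencoder training, feature selection, classifier fit)
ever sees test-fold samples; audit hooks let tests verify this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import autoencoder as ae
from . import synthetic_data as sd
from .latent_analysis import backward_select, correlate_latent, LatentMatrix
from .spectra_io import SpectraSet, silent_mask

__all__ = [
    "CvPlan",
    "FoldResult",
    "RocCurve",
    "AggregatedRoc",
    "WorkflowConfig",
    "make_cv_plan",
    "fit_classifier",
    "roc_auc",
    "aggregate_rocs",
    "run_cv_workflow",
    "compare_paired",
]

#: Default grid-search space: 7 log-spaced inverse-regularization strengths.
DEFAULT_C_GRID = tuple(float(c) for c in np.logspace(-3, 3, 7))

#: Audit hooks: callables invoked as hook(stage, fold_index, sample_ids)
#: whenever sample data enters a *fitting* stage. Tests use these to verify
#: that test folds never leak into training.
AUDIT_HOOKS: list = []


def _notify(stage: str, fold_index: int, sample_ids) -> None:
    for hook in AUDIT_HOOKS:
        hook(stage, fold_index, list(sample_ids))


@dataclass(frozen=True)
class CvPlan:
    n_folds: int
    fold_assignments: dict  # sample_id -> test-fold index
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_assignments.items() if f != fold]


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class AggregatedRoc:
    pooled: RocCurve
    fold_aucs: np.ndarray
    mean_auc: float
    sd_auc: float


@dataclass
class FoldResult:
    fold_index: int
    arm: str
    test_scores: np.ndarray
    test_labels: np.ndarray
    auc: float
    selected_features: list | None = None
    model_summary: str = ""


def make_cv_plan(spectra: SpectraSet, n_folds: int = 10, seed: int = 0) -> CvPlan:
    """Stratified disjoint k-fold assignment of samples to test folds."""
    labels = spectra.labels
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if spectra.n_samples < n_folds:
        raise ValueError("fewer samples than folds")
    classes = np.unique(labels[np.isfinite(labels)])
    if classes.size < 2:
        raise ValueError("stratification requires both classes present")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = {}
    for fold, (_, test_idx) in enumerate(skf.split(spectra.absorbance, labels)):
        for i in test_idx:
            assignments[spectra.sample_ids[i]] = fold
    return CvPlan(n_folds=n_folds, fold_assignments=assignments, seed=seed)


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    grid=DEFAULT_C_GRID,
    inner_cv: int = 5,
    seed: int = 0,
):
    """Standardized logistic regression with grid-searched regularization.

    Returns a fitted estimator whose ``predict_proba`` yields the
    case-probability in column 1.  A single-value grid reduces to a plain fit.
    """
    labels = np.asarray(labels)
    counts = np.unique(labels)
    if counts.size < 2:
        raise ValueError("classifier needs both classes present")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("logreg", LogisticRegression(max_iter=2000))]
    )
    grid = list(grid)
    if len(grid) == 1:
        pipe.set_params(logreg__C=grid[0])
        return pipe.fit(features, labels)
    n_min = min(np.sum(labels == c) for c in counts)
    inner = StratifiedKFold(
        n_splits=min(inner_cv, int(n_min)), shuffle=True, random_state=seed
    )
    search = GridSearchCV(
        pipe, {"logreg__C": grid}, scoring="roc_auc", cv=inner, refit=True
    )
    return search.fit(features, labels)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Empirical ROC; the AUC equals the Mann-Whitney probability with ties
    counted one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(roc_auc_score(labels, scores)))


def aggregate_rocs(folds: list[FoldResult]) -> AggregatedRoc:
    """Pool test scores across folds into one empirical ROC.

    Pooling (rather than curve averaging) is used for the aggregate; the
    per-fold AUC mean +/- sd is reported alongside so both conventions are
    visible.  Note pooling can dip below per-fold AUCs when fold score
    ranges interleave.
    """
    if not folds:
        raise ValueError("no fold results to aggregate")
    scores = np.concatenate([f.test_scores for f in folds])
    labels = np.concatenate([f.test_labels for f in folds])
    fold_aucs = np.array([f.auc for f in folds])
    return AggregatedRoc(
        pooled=roc_auc(scores, labels),
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        sd_auc=float(fold_aucs.std(ddof=1)) if fold_aucs.size > 1 else 0.0,
    )


@dataclass
class WorkflowConfig:
    """Per-fold augmentation/autoencoder/selection settings.

    ``pre_screen_k`` caps the latent features entering backward elimination
    (univariate |point-biserial| screening on the training fold) to keep the
    greedy search tractable; ``None`` disables the screen.
    """

    architecture: ae.ArchitectureSpec = field(default_factory=ae.default_architecture)
    lambda_weight: float = 1000.0
    silent_lo: float = 1800.0
    silent_hi: float = 2300.0
    train: ae.TrainConfig = field(default_factory=ae.TrainConfig)
    mvn_shrinkage: float | str = "auto"
    selection_tolerance: float = 0.005
    pre_screen_k: int | None = 32
    classifier_grid: tuple = DEFAULT_C_GRID
    inner_cv: int = 5


def _scores(clf, features: np.ndarray) -> np.ndarray:
    return clf.predict_proba(features)[:, 1]


def run_cv_workflow(
    cohort: SpectraSet,
    plan: CvPlan,
    arms: set[str] = frozenset({"manual", "reconstructed", "latent"}),
    config: WorkflowConfig | None = None,
    n_augment: int = 5000,
) -> list[FoldResult]:
    """Run the full cross-validated workflow; returns one FoldResult per
    (fold, arm).  The cohort must already be truncated and L2-normalized."""
    config = config or WorkflowConfig()
    arms = set(arms)
    unknown = arms - {"manual", "reconstructed", "latent"}
    if unknown:
        raise ValueError(f"unknown arms: {sorted(unknown)}")
    id_to_idx = {s: i for i, s in enumerate(cohort.sample_ids)}
    results: list[FoldResult] = []
    need_ae = bool(arms & {"reconstructed", "latent"})
    for fold in range(plan.n_folds):
        train_ids = plan.train_ids(fold)
        test_ids = plan.test_ids(fold)
        train_set = cohort.subset([id_to_idx[s] for s in train_ids])
        test_set = cohort.subset([id_to_idx[s] for s in test_ids])
        y_train = train_set.labels.astype(int)
        y_test = test_set.labels.astype(int)
        fold_seed = (plan.seed * 1_000 + fold) % (2**31)

        model = None
        if need_ae:
            _notify("fit_mvn", fold, train_ids)
            mvn = sd.fit_mvn(train_set, shrinkage=config.mvn_shrinkage)
            synth = sd.sample_mvn(mvn, n=n_augment, seed=fold_seed)
            mask = silent_mask(cohort.grid, config.silent_lo, config.silent_hi)
            fixed = ae.make_fixed_spectrum(train_set, mask)
            loss_cfg = ae.LossConfig(
                silent=mask, fixed_spectrum=fixed, lambda_weight=config.lambda_weight
            )
            _notify("train_autoencoder", fold, train_ids)
            model = ae.build_autoencoder(config.architecture, seed=fold_seed)
            train_cfg = ae.TrainConfig(**{**vars(config.train), "seed": fold_seed})
            ae.train_autoencoder(model, synth, loss_cfg, train_cfg)

        for arm in sorted(arms):
            if arm == "manual":
                x_train, x_test = train_set.absorbance, test_set.absorbance
                selected = None
                summary = "logistic regression on preprocessed spectra"
            elif arm == "reconstructed":
                x_train = ae.reconstruct(model, train_set).absorbance
                x_test = ae.reconstruct(model, test_set).absorbance
                selected = None
                summary = "logistic regression on autoencoder reconstructions"
            else:  # latent
                lat_train = ae.encode(model, train_set)
                lat_test = ae.encode(model, test_set)
                cols = np.arange(lat_train.n_latent)
                if config.pre_screen_k is not None and config.pre_screen_k < cols.size:
                    report = correlate_latent(
                        LatentMatrix(lat_train.values, train_ids), train_set.metadata
                    )
                    strength = np.abs(np.nan_to_num(report.table["disease_r"].to_numpy()))
                    cols = np.sort(np.argsort(strength)[::-1][: config.pre_screen_k])
                _notify("backward_select", fold, train_ids)
                kept_local = backward_select(
                    lat_train.values[:, cols],
                    y_train,
                    tolerance=config.selection_tolerance,
                    seed=fold_seed,
                )
                selected = [int(cols[i]) for i in kept_local]
                x_train = lat_train.values[:, selected]
                x_test = lat_test.values[:, selected]
                summary = f"logistic regression on {len(selected)} selected latent features"
            _notify("fit_classifier", fold, train_ids)
            clf = fit_classifier(
                x_train, y_train, grid=config.classifier_grid,
                inner_cv=config.inner_cv, seed=fold_seed,
            )
            scores = _scores(clf, x_test)
            results.append(
                FoldResult(
                    fold_index=fold,
                    arm=arm,
                    test_scores=scores,
                    test_labels=y_test,
                    auc=roc_auc(scores, y_test).auc,
                    selected_features=selected,
                    model_summary=summary,
                )
            )
    return results


def compare_paired(auc_a: np.ndarray, auc_b: np.ndarray) -> dict:
    """Two-sided paired t-test on fold-wise AUC differences."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 folds")
    diffs = a - b
    degenerate = bool(np.std(diffs, ddof=1) == 0)
    if degenerate:
        t_stat, p_val = 0.0, 1.0
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return {
        "t_statistic": t_stat,
        "p_value": p_val,
        "mean_difference": float(diffs.mean()),
        "degenerate": degenerate,
    }
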