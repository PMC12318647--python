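"""Latent-space analysis: selection, correlations, SLF marker, networks.

The encoder bottleneck yields 272 latent variables per spectrum.  Because a
separate autoencoder is trained per cross-validation fold, latent columns are
not comparable across folds — everything here operates within one fold's
model, and cross-fold reporting should use aggregates (mean +/- sd of maximum
absolute correlations) only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "LatentMatrix",
    "CorrelationReport",
    "backward_select",
    "correlate_latent",
    "reduce_disentangled",
    "select_slf",
    "correlation_network",
]


@dataclass
class LatentMatrix:
    """n_samples x n_latent encoder outputs with provenance."""

    values: np.ndarray
    sample_ids: list[str]
    fold_index: int | None = None
    model_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length != latent rows")

    @property
    def n_latent(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationReport:
    """Per-latent correlations with disease, sex (point-biserial) and age
    (Pearson), with pairwise-complete sample counts."""

    table: pd.DataFrame  # columns disease_r, sex_r, age_r, *_n, constant
    fold_index: int | None = None

    @property
    def max_abs(self) -> dict:
        return {
            var: float(np.nanmax(np.abs(self.table[f"{var}_r"])))
            for var in ("disease", "sex", "age")
        }


# ---------------------------------------------------------------------------
# Backward feature elimination on cross-validated AUC
# ---------------------------------------------------------------------------

def _cv_auc_scorer(n_splits: int = 5, seed: int = 0, C: float = 1.0):
    """Cross-validated AUC of a standardized logistic model on a feature subset."""

    def score(features: np.ndarray, labels: np.ndarray) -> float:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        aucs = []
        for tr, te in skf.split(features, labels):
            clf = make_pipeline(
                StandardScaler(), LogisticRegression(C=C, max_iter=500)
            )
            clf.fit(features[tr], labels[tr])
            aucs.append(roc_auc_score(labels[te], clf.predict_proba(features[te])[:, 1]))
        return float(np.mean(aucs))

    return score


def backward_select(
    features: np.ndarray,
    labels: np.ndarray,
    tolerance: float = 0.005,
    scorer=None,
    seed: int = 0,
) -> list[int]:
    """Greedy backward elimination on a cross-validated AUC criterion.

    At each step the feature whose removal least degrades the score is
    dropped; elimination stops when even the best removal would lower the
    current score by more than ``tolerance``, or when one feature remains.
    Ties favour keeping low-index features (the higher-index duplicate is
    removed).  Never returns an empty set.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if features.ndim != 2 or features.shape[1] < 2:
        raise ValueError("backward selection needs at least 2 features")
    scorer = scorer or _cv_auc_scorer(seed=seed)
    remaining = list(range(features.shape[1]))
    current = scorer(features, labels)
    while len(remaining) > 1:
        best_score, best_pos = -np.inf, None
        for pos in range(len(remaining)):
            cand = remaining[:pos] + remaining[pos + 1 :]
            s = scorer(features[:, cand], labels)
            if s >= best_score:  # ties remove the higher index: low indices survive
                best_score, best_pos = s, pos
        if current - best_score > tolerance:
            break
        remaining.pop(best_pos)
        current = best_score
    return remaining


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------

def _pairwise_corr(column: np.ndarray, target: np.ndarray) -> tuple[float, int, bool]:
    ok = np.isfinite(column) & np.isfinite(target)
    n = int(ok.sum())
    if n < 3:
        return np.nan, n, False
    x, y = column[ok], target[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0, n, True
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r, n, False


def _binary_coding(series: pd.Series) -> np.ndarray:
    values = series.to_numpy()
    if values.dtype == object or str(series.dtype) in ("string", "category"):
        mapping = {"M": 0.0, "F": 1.0, "m": 0.0, "f": 1.0}
        return np.array(
            [mapping.get(v, np.nan) if isinstance(v, str) else float(v) if pd.notna(v) else np.nan
             for v in values]
        )
    return series.to_numpy(dtype=float, na_value=np.nan)


def correlate_latent(latent: LatentMatrix, metadata: pd.DataFrame) -> CorrelationReport:
    """Correlate every latent column with disease status, sex and age.

    Point-biserial correlation (Pearson on the 0/1 coding) is used for the
    binary variables, Pearson for age; missing values are excluded pairwise.
    Constant latent columns get r = 0 with a ``constant`` flag.
    """
    meta = metadata.reindex(latent.sample_ids)
    targets = {
        "disease": _binary_coding(meta["label"]),
        "sex": _binary_coding(meta["sex"]),
        "age": meta["age"].to_numpy(dtype=float, na_value=np.nan),
    }
    rows = []
    for j in range(latent.n_latent):
        col = latent.values[:, j]
        row = {"latent_index": j, "constant": bool(np.nanstd(col) == 0)}
        for var, tgt in targets.items():
            r, n, flat = _pairwise_corr(col, tgt)
            row[f"{var}_r"] = 0.0 if row["constant"] else r
            row[f"{var}_n"] = n
            row["constant"] = row["constant"] or flat
        rows.append(row)
    table = pd.DataFrame(rows).set_index("latent_index")
    return CorrelationReport(table=table, fold_index=latent.fold_index)


def reduce_disentangled(report: CorrelationReport, threshold: float = 0.1) -> list[int]:
    """Keep latent features associated with exactly one of disease/sex/age.

    A feature counts as associated with a variable when |r| >= threshold;
    features crossing the threshold for two or more variables are excluded
    (entangled), as are features crossing none.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    r = report.table[["disease_r", "sex_r", "age_r"]].to_numpy()
    n_hits = (np.abs(np.nan_to_num(r)) >= threshold).sum(axis=1)
    kept = [int(i) for i in report.table.index[n_hits == 1]]
    if not kept:
        warnings.warn("no latent feature is associated with exactly one variable", stacklevel=2)
    return kept


def select_slf(report: CorrelationReport) -> int:
    """The single latent feature (SLF): argmax |disease correlation|.

    Ties break toward the lowest latent index.
    """
    if report.table["constant"].all():
        raise ValueError("all latent columns are constant")
    r = np.abs(np.nan_to_num(report.table["disease_r"].to_numpy()))
    return int(report.table.index[int(np.argmax(r))])


# ---------------------------------------------------------------------------
# Biomarker correlation network
# ---------------------------------------------------------------------------

def correlation_network(
    slf: np.ndarray,
    biomarkers: pd.DataFrame,
    edge_threshold: float = 0.3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson network over {SLF} + biomarkers.

    Biomarkers with fewer than 3 observed values are dropped with a warning
    (heavily missing markers cannot support a correlation estimate).  Returns
    an edge table (node_a, node_b, r, n) with |r| >= edge_threshold.
    """
    slf = np.asarray(slf, dtype=float)
    columns = {"SLF": slf}
    for name in biomarkers.columns:
        col = biomarkers[name].to_numpy(dtype=float, na_value=np.nan)
        if np.isfinite(col).sum() < 3:
            warnings.warn(f"biomarker {name!r} dropped: fewer than 3 observed values",
                          stacklevel=2)
            continue
        columns[name] = col
    names = list(columns)
    edges = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r, n, _ = _pairwise_corr(columns[a], columns[b])
            if np.isfinite(r) and abs(r) >= edge_threshold:
                edges.append({"node_a": a, "node_b": b, "r": r, "n": n})
    return pd.DataFrame(edges, columns=["node_a", "node_b", "r", "n"])
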