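"""Five-fold k-means cross-validation: accuracy, dispersion bias, RMSE.

Genotyped animals are clustered by k-means on the rows of their pedigree
relationship block A22, so that validation sets are as unrelated as
possible to the training sets (a harder, more honest test than random
folds). Per fold and model, validation-animal phenotypes are masked, the
model is refit, and three statistics are computed on the validation set:

accuracy  = cor(y_adj, EBV) / sqrt(h2)
slope     = regression coefficient of y_adj on EBV (1 = unbiased;
            < 1 means over-dispersed, inflated predictions)
RMSE      = sqrt(mean((y_adj - EBV)^2))

Aggregates are unweighted fold means with SE = sd / sqrt(k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .blup import MODEL_TAGS, EvalData, run_model
from .core import RelationshipMatrix, ValidationError
from .reml import VarianceComponents

#: Published per-trait dispersion slopes (regression of adjusted phenotype
#: on EBV) for ten yearling body measurements in Hanwoo cattle under the
#: four evaluation models, used as reference input for bias summaries.
#: Traits: body height, body length, chest depth, chest girth, chest
#: width, hip height, hip width, rump length, rump width, thurl width.
REFERENCE_SLOPES = pd.DataFrame(
    {
        "PBLUP_G": [0.56, 0.85, 0.76, 0.72, 0.71, 0.55, 0.01, 0.36, 0.62, 0.32],
        "PBLUP": [1.04, 1.02, 1.05, 1.05, 0.99, 1.00, 0.69, 1.01, 0.99, 0.81],
        "GBLUP": [1.17, 1.12, 1.22, 0.96, 0.99, 1.12, 0.95, 1.22, 1.43, 1.09],
        "ssGBLUP": [1.19, 1.11, 1.24, 1.05, 1.07, 1.18, 0.96, 1.17, 1.24, 1.03],
    },
    index=["BH", "BL", "CD", "CG", "CW", "HH", "HW", "RL", "RW", "TW"],
)


@dataclass
class FoldAssignment:
    """fold id (1..k) per genotyped animal."""

    fold: pd.Series
    k: int

    def __post_init__(self) -> None:
        vals = set(self.fold.unique())
        if vals != set(range(1, self.k + 1)):
            raise ValidationError(f"folds must cover 1..{self.k}; got {sorted(vals)}")

    def ids_in_fold(self, f: int) -> list[str]:
        return [str(a) for a in self.fold.index[self.fold == f]]

    def sizes(self) -> list[int]:
        return [int((self.fold == f).sum()) for f in range(1, self.k + 1)]


def kmeans_folds(A22: RelationshipMatrix, k: int = 5, seed: int = 0,
                 n_restarts: int = 10) -> FoldAssignment:
    """Cluster genotyped animals into k folds by k-means on rows of A22.

    Rows of the pedigree relationship block are the feature vectors
    (Euclidean distance); the best of ``n_restarts`` initializations by
    inertia is kept, under a fixed seed for bit-exact reproducibility.
    Unequal fold sizes are expected and allowed.
    """
    if k < 2:
        raise ValidationError("need at least k=2 folds")
    if k > A22.n:
        raise ValidationError(f"k={k} exceeds the {A22.n} genotyped animals")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(A22.dense())
    fold = pd.Series(labels + 1, index=list(A22.ids))
    return FoldAssignment(fold, k)


def _fold_metrics(y_val: np.ndarray, ebv_val: np.ndarray, h2: float) -> dict:
    rmse = float(np.sqrt(np.mean((y_val - ebv_val) ** 2)))
    if np.std(ebv_val) == 0.0 or np.std(y_val) == 0.0:
        warnings.warn("zero variance in a validation fold: slope/accuracy undefined",
                      stacklevel=2)
        return {"accuracy": np.nan, "slope": np.nan, "rmse": rmse}
    r = float(np.corrcoef(y_val, ebv_val)[0, 1])
    slope = float(np.cov(y_val, ebv_val, ddof=1)[0, 1] / np.var(ebv_val, ddof=1))
    return {"accuracy": r / np.sqrt(h2), "slope": slope, "rmse": rmse}


def run_crossval(
    data: EvalData,
    varcomp: VarianceComponents,
    folds: FoldAssignment,
    h2: float | None = None,
    models=MODEL_TAGS,
    trait: str = "trait",
) -> pd.DataFrame:
    """Cross-validated metrics per model and fold.

    Each fold's genotyped animals are the validation set: their phenotypes
    are masked during fitting, then accuracy, slope and RMSE are computed
    from their adjusted phenotypes against their predicted EBVs. ``h2``
    defaults to the heritability of ``varcomp`` (full-data estimate).
    """
    h2 = varcomp.h2 if h2 is None else h2
    if not 0.0 < h2 <= 1.0:
        raise ValidationError("h2 must be in (0, 1]")
    rows = []
    for f in range(1, folds.k + 1):
        val_ids = [a for a in folds.ids_in_fold(f) if a in data.y_adj.index]
        if not val_ids:
            raise ValidationError(f"fold {f} has no phenotyped validation animals")
        y_val = data.y_adj.loc[val_ids].to_numpy(dtype=float)
        for tag in models:
            res = run_model(tag, data, varcomp, mask_ids=val_ids)
            ebv_val = res.ebv.loc[val_ids].to_numpy(dtype=float)
            met = _fold_metrics(y_val, ebv_val, h2)
            rows.append({"trait": trait, "model": tag, "fold": f,
                         "n_val": len(val_ids), **met})
    return pd.DataFrame(rows)


def aggregate_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Unweighted fold means with SE = sd/sqrt(k), per trait and model."""
    def agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        k = len(g)
        for col in ("accuracy", "slope", "rmse"):
            out[f"{col}_mean"] = g[col].mean()
            out[f"{col}_se"] = g[col].std(ddof=1) / np.sqrt(k) if k > 1 else np.nan
        out["k"] = k
        return pd.Series(out)

    return (
        metrics.groupby(["trait", "model"], sort=False)
        .apply(agg, include_groups=False)
        .reset_index()
    )


def pooled_accuracy(
    data: EvalData,
    varcomp: VarianceComponents,
    folds: FoldAssignment,
    model: str,
    h2: float | None = None,
) -> float:
    """Accuracy from pooling all validation predictions before correlating
    (alternative to the default fold-mean aggregation)."""
    h2 = varcomp.h2 if h2 is None else h2
    ys, es = [], []
    for f in range(1, folds.k + 1):
        val_ids = [a for a in folds.ids_in_fold(f) if a in data.y_adj.index]
        res = run_model(model, data, varcomp, mask_ids=val_ids)
        ys.append(data.y_adj.loc[val_ids].to_numpy(dtype=float))
        es.append(res.ebv.loc[val_ids].to_numpy(dtype=float))
    y, e = np.concatenate(ys), np.concatenate(es)
    return float(np.corrcoef(y, e)[0, 1] / np.sqrt(h2))


def summarize_bias(slopes: pd.DataFrame) -> pd.DataFrame:
    """Per-model mean slope and mean |slope - 1| across traits, rounded to
    two decimals for reporting (rows of ``slopes`` are traits, columns are
    models)."""
    if slopes.empty:
        raise ValidationError("need at least one trait")
    out = pd.DataFrame(
        {
            "mean_slope": slopes.mean(axis=0).round(2),
            "mean_abs_dev": (slopes - 1.0).abs().mean(axis=0).round(2),
        }
    )
    out.index.name = "model"
    return out
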