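"""Marker discovery: Boruta-style shadow-feature selection on a random
forest, repeated cross-validated ROC/AUC validation of the selected set, and
Spearman + Benjamini–Hochberg screening against metabolic phenotypes.

A feature is *health-relevant* when it is both confirmed by the shadow-
feature selection (it discriminates the treatment groups) and significantly
correlated with at least one phenotype after FDR correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Boruta-style selection
# ---------------------------------------------------------------------------

@dataclass
class BorutaResult:
    """Outcome of shadow-feature selection.

    ``status`` maps each feature to confirmed / rejected / tentative;
    ``importance_history`` is (iterations x features) of Z-scores and
    ``shadow_history`` records the (min, mean, max) shadow Z per iteration.
    """

    status: pd.Series
    importance_history: pd.DataFrame
    shadow_history: pd.DataFrame
    hits: pd.Series
    n_iter: int

    @property
    def confirmed(self) -> list[str]:
        return self.status.index[self.status == "confirmed"].tolist()


def _importance_z(forest: RandomForestClassifier, n_features: int) -> np.ndarray:
    """Z-score of impurity importance over the forest's trees."""
    per_tree = np.array([t.feature_importances_ for t in forest.estimators_])
    mean = per_tree.mean(axis=0)
    sd = per_tree.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    return z[:n_features], z[n_features:]


def boruta(
    x: pd.DataFrame,
    y,
    n_iter: int = 100,
    n_trees: int = 500,
    seed=None,
    alpha: float = 0.01,
) -> BorutaResult:
    """Shadow-feature relevance selection on a random forest.

    Each iteration appends a row-permuted shadow copy of every feature and
    fits a random forest on the augmented matrix.  A real feature scores a
    *hit* when its mean-decrease-in-impurity importance exceeds the best
    shadow feature's importance in that iteration.  After each iteration a
    two-sided binomial test (success probability 0.5, Bonferroni-corrected
    across features) promotes features with significantly many hits to
    confirmed and significantly few to rejected; the rest stay tentative.
    Per-tree importance Z-scores (mean/sd over trees) are recorded for the
    real and shadow features to support the usual Boruta box plots.
    Rejected features are dropped from the model matrix (with their
    shadows), so later iterations concentrate on the undecided set.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain two classes")
    if min(np.bincount(pd.factorize(y)[0])) < 2:
        raise ValueError("need at least two samples per class")
    if n_iter < 10:
        raise ValueError("n_iter must be >= 10")
    rng = np.random.default_rng(seed)
    X = x.to_numpy(dtype=float)
    n, p = X.shape
    features = [str(c) for c in x.columns]

    hits = np.zeros(p, dtype=int)
    status = np.array(["tentative"] * p, dtype=object)
    active = np.ones(p, dtype=bool)  # confirmed + tentative stay in the model
    imp_rows, shadow_rows = [], []
    bonf_alpha = alpha / p

    for it in range(n_iter):
        cols = np.flatnonzero(active)
        Xa = X[:, cols]
        m = cols.size
        shadow = Xa[rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1).T, np.arange(m)]
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(np.hstack([Xa, shadow]), y)
        importance = forest.feature_importances_
        hits[cols] += (importance[:m] > importance[m:].max()).astype(int)
        z_real, z_shadow = _importance_z(forest, m)
        z_row = np.full(p, np.nan)
        z_row[cols] = z_real
        imp_rows.append(z_row)
        shadow_rows.append((z_shadow.min(), z_shadow.mean(), z_shadow.max()))

        trials = it + 1
        undecided = status == "tentative"
        if undecided.any():
            p_hi = stats.binom.sf(hits[undecided] - 1, trials, 0.5)
            p_lo = stats.binom.cdf(hits[undecided], trials, 0.5)
            two_hi = np.minimum(2 * p_hi, 1.0)
            two_lo = np.minimum(2 * p_lo, 1.0)
            idx = np.flatnonzero(undecided)
            status[idx[two_hi < bonf_alpha]] = "confirmed"
            rejected_now = idx[two_lo < bonf_alpha]
            status[rejected_now] = "rejected"
            active[rejected_now] = False
        if not (status == "tentative").any() or not active.any():
            break

    return BorutaResult(
        status=pd.Series(status, index=features, name="status"),
        importance_history=pd.DataFrame(imp_rows, columns=features),
        shadow_history=pd.DataFrame(shadow_rows, columns=["min", "mean", "max"]),
        hits=pd.Series(hits, index=features, name="hits"),
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# classifier validation
# ---------------------------------------------------------------------------

def classifier_auc(
    x: pd.DataFrame,
    y,
    cv_folds: int = 5,
    cv_repeats: int = 5,
    seed=None,
    n_trees: int = 500,
) -> tuple[pd.DataFrame, float]:
    """Repeated stratified cross-validated ROC curve and trapezoidal AUC.

    Out-of-fold class probabilities are pooled over every fold of every
    repeat before computing a single ROC curve.
    """
    if x.shape[1] == 0:
        raise ValueError("no features selected")
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size != 2:
        raise ValueError("binary labels required")
    if min(np.bincount(y_codes)) < cv_folds:
        raise ValueError("a class has fewer samples than cv_folds")
    rng = np.random.default_rng(seed)
    X = x.to_numpy(dtype=float)
    cv = RepeatedStratifiedKFold(
        n_splits=cv_folds, n_repeats=cv_repeats, random_state=int(rng.integers(2**31))
    )
    pooled_y, pooled_score = [], []
    for train, test in cv.split(X, y_codes):
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        forest.fit(X[train], y_codes[train])
        pooled_score.append(forest.predict_proba(X[test])[:, 1])
        pooled_y.append(y_codes[test])
    fpr, tpr, thresholds = roc_curve(np.concatenate(pooled_y), np.concatenate(pooled_score))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return roc, float(_trapezoid_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# phenotype screening
# ---------------------------------------------------------------------------

def spearman_screen(x: pd.DataFrame, phen: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho with tie-corrected p for every feature x phenotype pair,
    BH-adjusted q across the whole grid.

    Rows with a missing value in either member of a pair are dropped; pairs
    with fewer than 4 complete observations or a constant column are
    reported with missing rho/p and excluded from the BH family.
    """
    shared = x.index.intersection(phen.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between features and phenotypes")
    xs = x.loc[shared]
    ps = phen.loc[shared]
    rows = []
    for f in xs.columns:
        for ph in ps.columns:
            xv = xs[f].to_numpy(dtype=float)
            pv = ps[ph].to_numpy(dtype=float)
            ok = ~(np.isnan(xv) | np.isnan(pv))
            rho = pval = float("nan")
            if ok.sum() >= 4 and np.unique(xv[ok]).size > 1 and np.unique(pv[ok]).size > 1:
                rho, pval = stats.spearmanr(xv[ok], pv[ok])
            rows.append({"feature": str(f), "phenotype": str(ph), "rho": rho, "p": pval})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.info("spearman_screen: %d undefined pair(s) reported missing", n_dropped)
    return out


def health_relevant(
    boruta_result: BorutaResult, screen: pd.DataFrame, alpha_q: float = 0.05
) -> list[str]:
    """Features confirmed by shadow selection AND significant (q < alpha_q)
    against at least one phenotype."""
    confirmed = set(boruta_result.confirmed)
    significant = set(screen.loc[screen["q"] < alpha_q, "feature"])
    return sorted(confirmed & significant)
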