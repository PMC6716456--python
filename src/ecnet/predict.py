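"""Behavioral association and machine-learning prediction.

* Bonferroni-corrected Pearson correlations between network features and
  behavioral scores.
* Partial-least-squares regression: percent behavioral variance
  explained plus the latent-space association (R^2 and p of the first
  score pair).
* Recursive cluster elimination SVM (RCE-SVM): features are k-means
  clustered on the training data, clusters scored by within-training
  cross-validated SVM accuracy, the worst-scoring fraction eliminated,
  repeating down to two clusters; held-out accuracy is recorded at every
  step over repetitions x splits, and the *worst-case* accuracy is the
  minimum across all held-out evaluations.  Statistical significance of
  an accuracy comes from an upper-tail binomial null.
* Cross-validated linear support-vector regression of symptom scores.

Standardization, clustering and elimination are fit on training rows
only; held-out rows enter only through the recorded accuracies.  Linear
kernels with unit cost throughout (no hyperparameter optimization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC, SVR


# ---------------------------------------------------------------------------
# Feature-behavior correlations
# ---------------------------------------------------------------------------

def behavior_correlations(features: pd.DataFrame, behaviors: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r and two-sided p per feature x behavior, Bonferroni flagged.

    The Bonferroni divisor is the number of tests actually performed.
    """
    if len(features) != len(behaviors):
        raise ValueError("features and behaviors must align on rows")
    if len(features) < 10:
        raise ValueError("need >= 10 complete pairs")
    n_tests = features.shape[1] * behaviors.shape[1]
    rows = []
    for f in features.columns:
        for b in behaviors.columns:
            r, p = stats.pearsonr(features[f].to_numpy(dtype=float),
                                  behaviors[b].to_numpy(dtype=float))
            rows.append({"feature": f, "behavior": b, "r": float(r), "p": float(p),
                         "significant": bool(p < alpha / n_tests)})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_divisor"] = n_tests
    return out


# ---------------------------------------------------------------------------
# PLS regression association
# ---------------------------------------------------------------------------

@dataclass
class PLSRResult:
    n_components: int
    pct_variance_explained: float     # % of behavior-block variance explained
    x_scores: np.ndarray
    y_scores: np.ndarray
    latent_r2: float
    latent_p: float


def plsr_assoc(X: np.ndarray, Y: np.ndarray, n_components: int = 2) -> PLSRResult:
    """PLS of behaviors on features; latent-space association of the
    first score pair (R^2 and two-sided p of their linear fit)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Xs = (X - X.mean(0)) / X.std(0)
    Ys = (Y - Y.mean(0)) / Y.std(0)
    n_components = min(n_components, Xs.shape[1], Xs.shape[0] - 1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Ys)
    Yhat = pls.predict(Xs)
    sse = float(((Ys - Yhat) ** 2).sum())
    sst = float((Ys ** 2).sum())
    pct = 100.0 * (1.0 - sse / sst)
    t, u = pls.x_scores_[:, 0], pls.y_scores_[:, 0]
    fit = stats.linregress(t, u)
    return PLSRResult(
        n_components=n_components,
        pct_variance_explained=pct,
        x_scores=pls.x_scores_, y_scores=pls.y_scores_,
        latent_r2=float(fit.rvalue ** 2), latent_p=float(fit.pvalue),
    )


# ---------------------------------------------------------------------------
# RCE-SVM classification
# ---------------------------------------------------------------------------

@dataclass
class RCEConfig:
    train_frac: float = 0.8
    clusters_init: int = 40
    elim_frac: float = 0.2
    clusters_final: int = 2
    folds: int = 6                    # held-out splits per repetition
    reps: int = 100
    inner_folds: int = 3              # training-side CV for cluster scoring
    C: float = 1.0
    seed: int = 0


@dataclass
class RCEResult:
    cluster_counts: list[int]                 # per RCE step, strictly decreasing
    accuracy: np.ndarray                      # (reps, folds, steps) held-out accuracy
    correct: np.ndarray                       # (reps, folds, steps) held-out correct counts
    n_test: np.ndarray                        # (reps, folds) held-out sizes
    feature_survival: np.ndarray              # (n_features,) final-step survival counts
    feature_names: list[str]
    chance: float

    @property
    def n_evaluations(self) -> int:
        return self.accuracy.shape[0] * self.accuracy.shape[1]

    @property
    def mean_accuracy(self) -> np.ndarray:    # per step
        return self.accuracy.mean(axis=(0, 1))

    @property
    def worst_case_accuracy(self) -> np.ndarray:   # per step
        return self.accuracy.min(axis=(0, 1))

    def binomial_p(self) -> np.ndarray:
        """Upper-tail binomial p per step from pooled held-out predictions."""
        total = int(self.n_test.sum())
        return np.array([
            binomial_significance(int(self.correct[:, :, s].sum()), total, self.chance)
            for s in range(len(self.cluster_counts))
        ])


def _svm(C: float) -> SVC:
    # linear kernel, unit cost, one-vs-one multiclass (SVC default)
    return SVC(kernel="linear", C=C)


def _cluster_features(Xtr: np.ndarray, active: np.ndarray, n_clusters: int,
                      rs: int) -> list[np.ndarray]:
    """k-means on feature profiles (features as samples) of the training data."""
    prof = Xtr[:, active].T
    n_clusters = min(n_clusters, prof.shape[0])
    if n_clusters <= 1:
        return [active]
    km = KMeans(n_clusters=n_clusters, n_init=4, random_state=rs)
    lab = km.fit_predict(prof)
    return [active[lab == c] for c in range(n_clusters) if np.any(lab == c)]


def _score_cluster(Xtr: np.ndarray, ytr: np.ndarray, cols: np.ndarray,
                   inner_folds: int, C: float, rs: int) -> float:
    """Training-side stratified CV accuracy of an SVM on one cluster's features."""
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=rs)
    accs = []
    for tr, va in skf.split(Xtr, ytr):
        clf = _svm(C).fit(Xtr[np.ix_(tr, cols)], ytr[tr])
        accs.append(clf.score(Xtr[np.ix_(va, cols)], ytr[va]))
    return float(np.mean(accs))


def _rce_single_split(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                      yte: np.ndarray, cfg: RCEConfig, rs: int
                      ) -> tuple[list[float], list[int], list[np.ndarray]]:
    """One train/held-out split of the full RCE schedule.

    Returns per-step held-out accuracies, correct counts, and surviving
    feature index sets.  Everything that shapes the model (scaling,
    clustering, cluster scores, elimination) is computed from the
    training rows only.
    """
    mu, sd = Xtr.mean(0), Xtr.std(0)
    sd[sd == 0] = 1.0
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd
    active = np.arange(Xtr.shape[1])
    n_clusters = min(cfg.clusters_init, active.size)
    accs, corrects, survivors = [], [], []
    step = 0
    while True:
        clusters = _cluster_features(Xtr, active, n_clusters, rs + step)
        scores = [
            _score_cluster(Xtr, ytr, cols, cfg.inner_folds, cfg.C, rs + step)
            for cols in clusters
        ]
        clf = _svm(cfg.C).fit(Xtr[:, active], ytr)
        pred = clf.predict(Xte[:, active])
        accs.append(float(np.mean(pred == yte)))
        corrects.append(int(np.sum(pred == yte)))
        survivors.append(active.copy())
        if n_clusters <= cfg.clusters_final:
            break
        # eliminate the worst elim_frac clusters; ties keep the lower index
        n_next = max(cfg.clusters_final, n_clusters - max(1, round(cfg.elim_frac * n_clusters)))
        order = sorted(range(len(clusters)), key=lambda i: (scores[i], -i))
        n_drop = min(max(0, len(clusters) - n_next), len(clusters) - 1)
        drop = set(order[:n_drop])
        keep = [i for i in range(len(clusters)) if i not in drop]
        active = np.sort(np.concatenate([clusters[i] for i in keep]))
        n_clusters = n_next
        step += 1
    return accs, corrects, survivors


def rce_svm(features: pd.DataFrame | np.ndarray, labels: np.ndarray,
            cfg: RCEConfig | None = None) -> RCEResult:
    """Recursive cluster elimination SVM over repetitions x held-out splits."""
    cfg = cfg or RCEConfig()
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < cfg.folds:
        raise ValueError(f"every class needs >= folds={cfg.folds} members")
    chance = float(counts.max() / counts.sum())

    # probe the step schedule once to size the arrays
    n_feat = X.shape[1]
    schedule = [min(cfg.clusters_init, n_feat)]
    while schedule[-1] > cfg.clusters_final:
        n = schedule[-1]
        schedule.append(max(cfg.clusters_final, n - max(1, round(cfg.elim_frac * n))))
    n_steps = len(schedule)

    rng = np.random.default_rng(cfg.seed)
    accuracy = np.zeros((cfg.reps, cfg.folds, n_steps))
    correct = np.zeros((cfg.reps, cfg.folds, n_steps), dtype=int)
    n_test = np.zeros((cfg.reps, cfg.folds), dtype=int)
    survival = np.zeros(n_feat)
    for rep in range(cfg.reps):
        sss = StratifiedShuffleSplit(n_splits=cfg.folds, test_size=1.0 - cfg.train_frac,
                                     random_state=int(rng.integers(0, 2**31 - 1)))
        for fold, (tr, te) in enumerate(sss.split(X, y)):
            rs = int(rng.integers(0, 2**31 - 1))
            accs, corrs, survivors = _rce_single_split(X[tr], y[tr], X[te], y[te], cfg, rs)
            accuracy[rep, fold, :] = accs
            correct[rep, fold, :] = corrs
            n_test[rep, fold] = te.size
            survival[survivors[-1]] += 1
    return RCEResult(cluster_counts=schedule, accuracy=accuracy, correct=correct,
                     n_test=n_test, feature_survival=survival, feature_names=names,
                     chance=chance)


def binomial_significance(n_correct: int, n_total: int, chance: float) -> float:
    """P(X >= n_correct) under X ~ Binomial(n_total, chance)."""
    if not (0 <= n_correct <= n_total):
        raise ValueError("need 0 <= n_correct <= n_total")
    return float(stats.binom.sf(n_correct - 1, n_total, chance))


# ---------------------------------------------------------------------------
# SVR symptom prediction
# ---------------------------------------------------------------------------

@dataclass
class SVRResult:
    r2: np.ndarray                    # per-iteration pooled predicted-vs-true R^2
    mean_r2: float = field(init=False)
    sd_r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_r2 = float(np.mean(self.r2))
        self.sd_r2 = float(np.std(self.r2))


def svr_predict(features: pd.DataFrame | np.ndarray, score: np.ndarray,
                folds: int = 6, iterations: int = 1000, C: float = 1.0,
                seed: int = 0) -> SVRResult:
    """Cross-validated linear SVR of one symptom score.

    Per iteration: a random fold assignment; the model is trained on the
    other folds (features standardized on training rows) and predicts the
    held-out fold; pooled predictions give the iteration's squared
    Pearson correlation with the true scores.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    y = np.asarray(score, dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    r2 = np.empty(iterations)
    for it in range(iterations):
        assign = rng.permutation(n) % folds
        pred = np.empty(n)
        for f in range(folds):
            te = assign == f
            tr = ~te
            mu, sd = X[tr].mean(0), X[tr].std(0)
            sd[sd == 0] = 1.0
            model = SVR(kernel="linear", C=C)
            model.fit((X[tr] - mu) / sd, y[tr])
            pred[te] = model.predict((X[te] - mu) / sd)
        r = np.corrcoef(pred, y)[0, 1]
        r2[it] = r * r if np.isfinite(r) else 0.0
    return SVRResult(r2=r2)
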