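"""Sex-difference and individual-signature statistics.

The signature battery mirrors the classical bioacoustic workflow:

1. per-parameter linear mixed models for sex differences (random intercept
   per individual, because calls of one sender are not independent);
2. correlation-matrix PCA with Kaiser retention (eigenvalue > 1) to obtain
   uncorrelated components;
3. linear discriminant analysis with leave-one-out cross-validation to
   classify calls by sender (or sex);
4. a *nested permuted* DFA (pDFA): because calls are nested in individuals,
   the null distribution permutes whole individuals across the levels of
   the test factor, yielding a valid p-value and an empirical chance level;
5. per-individual exact binomial tests against the class-prior chance level;
6. Cohen's kappa and Beecher's information criterion H_s (bits of identity
   information) to compare distinctiveness across groups of different size.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger("vocalkin.signature_stats")


# ---------------------------------------------------------------------------
# PCA with Kaiser retention
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Correlation-matrix PCA: z-scored inputs, components by eigenvalue."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (n_params, n_components), orthonormal
    eigenvalues: np.ndarray  # descending
    retained_count: int

    def transform(self, X: pd.DataFrame | np.ndarray, retained_only: bool = True) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.columns].to_numpy()
        Z = (np.asarray(X, dtype=float) - self.means) / self.sds
        S = Z @ self.loadings
        return S[:, : self.retained_count] if retained_only else S


def pca_kaiser(features: pd.DataFrame | np.ndarray, columns: list[str] | None = None) -> tuple[PCAModel, np.ndarray]:
    """PCA on the correlation matrix, retaining eigenvalues greater than 1.

    Returns the fitted model and the retained-component scores of the
    training data.  The eigenvalue sum equals the number of parameters
    (trace of the correlation matrix) and scores of the training data are
    uncorrelated by construction.
    """
    if isinstance(features, pd.DataFrame):
        cols = columns or list(features.columns)
        X = features[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        cols = columns or [f"p{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 calls")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = [c for c, s in zip(cols, sds) if s == 0 or not np.isfinite(s)]
    if bad:
        raise ValueError(f"constant column(s), z-score undefined: {bad}")
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    retained = int(np.sum(eigvals > 1.0))
    if retained == 0:
        retained = 1  # degenerate isotropic data: keep the leading component
    model = PCAModel(
        columns=cols,
        means=means,
        sds=sds,
        loadings=eigvecs,
        eigenvalues=eigvals,
        retained_count=retained,
    )
    return model, model.transform(X)


# ---------------------------------------------------------------------------
# linear discriminant classification
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    labels: list[str]
    counts: np.ndarray  # [true, predicted]

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * np.trace(self.counts) / self.counts.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


class _LDA:
    """Gaussian linear discriminant with pooled within-class covariance.

    A lean implementation because the pDFA permutation loop refits it tens
    of thousands of times; cross-checked against scikit-learn in the test
    suite.  A singular pooled covariance is ridge-regularised with
    lambda = 1e-6 * trace / dim (logged).
    """

    def __init__(self, priors: str = "proportional"):
        self.priors = priors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_LDA":
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        k = len(self.classes_)
        self.means_ = np.empty((k, p))
        pooled = np.zeros((p, p))
        counts = np.bincount(y_idx, minlength=k)
        for c in range(k):
            Xc = X[y_idx == c]
            self.means_[c] = Xc.mean(axis=0)
            d = Xc - self.means_[c]
            pooled += d.T @ d
        pooled /= max(n - k, 1)
        try:
            prec = np.linalg.inv(pooled)
        except np.linalg.LinAlgError:
            lam = 1e-6 * np.trace(pooled) / p
            logger.warning("singular pooled covariance; ridge lambda=%.3g", lam)
            prec = np.linalg.inv(pooled + lam * np.eye(p))
        if self.priors == "equal":
            log_pri = np.zeros(k)
        else:
            log_pri = np.log(counts / n)
        # linear discriminant: x @ W.T + b
        self._W = self.means_ @ prec
        self._b = -0.5 * np.einsum("ij,ij->i", self._W, self.means_) + log_pri
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = X @ self._W.T + self._b
        return self.classes_[np.argmax(scores, axis=1)]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, labels: list[str]) -> ConfusionMatrix:
    pos = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(labels=list(labels), counts=counts)


def lda_loo(
    scores: np.ndarray, labels, priors: str = "proportional"
) -> tuple[ConfusionMatrix, ConfusionMatrix]:
    """DFA of calls onto labels: original and leave-one-out classification.

    The original matrix classifies every call with the model fitted on all
    calls; the cross-validated matrix refits the discriminant excluding each
    call in turn.  ``priors`` is "proportional" (to class sizes, the SPSS
    default) or "equal".
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray([str(l) for l in labels])
    uniq = sorted(set(y))
    if len(uniq) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 calls for leave-one-out")
    full = _LDA(priors).fit(X, y)
    original = _confusion(y, full.predict(X), uniq)
    loo_pred = np.empty_like(y)
    idx = np.arange(len(y))
    for i in idx:
        mask = idx != i
        loo_pred[i] = _LDA(priors).fit(X[mask], y[mask]).predict(X[i : i + 1])[0]
    return original, _confusion(y, loo_pred, uniq)


# ---------------------------------------------------------------------------
# nested permuted DFA
# ---------------------------------------------------------------------------

@dataclass
class PDFAResult:
    observed_pct: float
    chance_pct: float
    p_value: float
    n_permutations: int
    cv_observed_pct: float
    cv_chance_pct: float
    cv_p: float
    n_selections: int = 0
    n_train_per_individual: int = 0


def nested_pdfa(
    scores: np.ndarray,
    test_labels,
    control_labels,
    n_train_per_individual: int | None = None,
    n_perm: int = 1000,
    n_selections: int = 100,
    seed: int | None = None,
    priors: str = "proportional",
) -> PDFAResult:
    """Nested permuted DFA for a between-individual test factor.

    Calls are nested in individuals (the control factor) and every
    individual carries a single level of the test factor (e.g. sex).  For
    each of ``n_selections`` random splits, a DFA is trained on
    ``n_train_per_individual`` calls of every individual and the remaining
    calls are cross-classified; the observed statistics are the mean
    percentage of correctly classified training calls (resubstitution) and
    held-out calls (cross-validation).  The null distribution shuffles
    whole individuals — with all their calls — across the test-factor
    levels (preserving level sizes), one random training split per
    permutation.  p = (#{null >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 (p undefined otherwise)")
    X = np.asarray(scores, dtype=float)
    test = np.asarray([str(l) for l in test_labels])
    ctrl = np.asarray([str(l) for l in control_labels])
    rng = np.random.default_rng(seed)

    ind_ids = sorted(set(ctrl))
    ind_level = {}
    for ind in ind_ids:
        levels = set(test[ctrl == ind])
        if len(levels) != 1:
            raise ValueError(f"individual {ind} carries multiple test-factor levels")
        ind_level[ind] = levels.pop()
    level_counts = pd.Series(list(ind_level.values())).value_counts()
    if len(level_counts) < 2 or (level_counts < 2).any():
        raise ValueError("need >= 2 individuals per test-factor level to permute")

    call_idx = {ind: np.where(ctrl == ind)[0] for ind in ind_ids}
    min_calls = min(len(v) for v in call_idx.values())
    if n_train_per_individual is None:
        n_train_per_individual = min(
            math.ceil(2 * len(v) / 3) for v in call_idx.values()
        )
    if n_train_per_individual >= min_calls:
        n_train_per_individual = min_calls - 1
    if n_train_per_individual < 1:
        raise ValueError("each individual needs n_train_per_individual + 1 calls")

    levels_vec = np.array([ind_level[i] for i in ind_ids])

    def one_run(level_by_ind: np.ndarray) -> tuple[float, float]:
        train_idx, test_idx = [], []
        for k, ind in enumerate(ind_ids):
            idx = call_idx[ind]
            sel = rng.permutation(len(idx))
            train_idx.append(idx[sel[:n_train_per_individual]])
            test_idx.append(idx[sel[n_train_per_individual:]])
        tr = np.concatenate(train_idx)
        te = np.concatenate(test_idx)
        y = np.empty(len(ctrl), dtype=levels_vec.dtype)
        for k, ind in enumerate(ind_ids):
            y[call_idx[ind]] = level_by_ind[k]
        model = _LDA(priors).fit(X[tr], y[tr])
        acc_train = float(np.mean(model.predict(X[tr]) == y[tr]))
        acc_test = float(np.mean(model.predict(X[te]) == y[te]))
        return acc_train, acc_test

    obs = np.array([one_run(levels_vec) for _ in range(n_selections)])
    observed, cv_observed = obs.mean(axis=0)

    null = np.empty((n_perm, 2))
    for b in range(n_perm):
        null[b] = one_run(rng.permutation(levels_vec))

    p = (np.sum(null[:, 0] >= observed) + 1) / (n_perm + 1)
    cv_p = (np.sum(null[:, 1] >= cv_observed) + 1) / (n_perm + 1)
    return PDFAResult(
        observed_pct=100 * observed,
        chance_pct=100 * float(null[:, 0].mean()),
        p_value=float(p),
        n_permutations=n_perm,
        cv_observed_pct=100 * cv_observed,
        cv_chance_pct=100 * float(null[:, 1].mean()),
        cv_p=float(cv_p),
        n_selections=n_selections,
        n_train_per_individual=n_train_per_individual,
    )


# ---------------------------------------------------------------------------
# distinctiveness statistics
# ---------------------------------------------------------------------------

def binomial_individual_tests(
    confusion: ConfusionMatrix, chance_rule: str | float = "proportional"
) -> pd.Series:
    """One-sided exact binomial p per individual on the original classification.

    Tests whether the individual's calls are assigned to it more often than
    chance.  The default chance level is the individual's class prior
    n_i / N (class-size dependent); ``chance_rule`` may also be "uniform"
    (1 / number of classes) or an explicit probability.
    """
    row_sums = confusion.counts.sum(axis=1)
    correct = np.diag(confusion.counts)
    N = confusion.n_total
    k = len(confusion.labels)
    out = {}
    for i, label in enumerate(confusion.labels):
        n_i = int(row_sums[i])
        if n_i == 0:
            out[label] = np.nan
            continue
        if chance_rule == "proportional":
            p0 = n_i / N
        elif chance_rule == "uniform":
            p0 = 1.0 / k
        else:
            p0 = float(chance_rule)
        out[label] = stats.binomtest(int(correct[i]), n_i, p0, alternative="greater").pvalue
    return pd.Series(out, name="binomial_p")


def cohens_kappa(confusion: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement of the confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with the expected agreement p_e from the
    row/column marginal products.
    """
    counts = confusion.counts.astype(float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / n
    p_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        raise ValueError("degenerate confusion matrix: expected agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def beecher_hs(pc_scores: np.ndarray, labels) -> float:
    """Beecher's information criterion H_s in bits.

    For statistically independent components (PCA scores), the identity
    information of component i with between/within variance ratio F_i is
    log2 sqrt(F_i); H_s sums the informative components (F_i > 1 — a
    component whose between-individual variance does not exceed the within
    variance carries no identity information and contributes 0).
    """
    X = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    if X.shape[0] == len(np.asarray(labels)):
        pass
    elif X.shape[1] == len(np.asarray(labels)):
        X = X.T
    y = np.asarray([str(l) for l in labels])
    groups = sorted(set(y))
    if len(groups) < 2:
        raise ValueError("need >= 2 individuals")
    hs = 0.0
    for j in range(X.shape[1]):
        samples = [X[y == g, j] for g in groups]
        if any(len(s) < 1 for s in samples):
            raise ValueError("every individual needs at least one call")
        F = _anova_f(samples)
        if np.isfinite(F) and F > 1.0:
            hs += math.log2(math.sqrt(F))
    return hs


def _anova_f(samples: list[np.ndarray]) -> float:
    """One-way ANOVA F = between-group MS / within-group MS."""
    k = len(samples)
    ns = np.array([len(s) for s in samples])
    N = ns.sum()
    means = np.array([s.mean() for s in samples])
    grand = np.concatenate(samples).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    df_b, df_w = k - 1, N - k
    if df_w <= 0 or ss_within == 0:
        return np.inf if ss_between > 0 else np.nan
    return (ss_between / df_b) / (ss_within / df_w)


def per_individual_anova(features: pd.DataFrame, labels, columns: list[str] | None = None) -> pd.DataFrame:
    """Univariate one-way ANOVA per acoustic parameter, individual as factor.

    Returns a table with F, numerator/denominator d.f. and p per parameter;
    constant parameters are flagged with NaN.
    """
    y = np.asarray([str(l) for l in labels])
    groups = sorted(set(y))
    cols = columns or [c for c in features.columns if pd.api.types.is_numeric_dtype(features[c])]
    counts = pd.Series(y).value_counts()
    if len(groups) < 2 or (counts < 2).sum() == len(groups):
        raise ValueError("need >= 2 individuals with >= 2 calls")
    rows = []
    N = len(y)
    for c in cols:
        x = features[c].to_numpy(dtype=float)
        if np.all(x == x[0]):
            logger.warning("parameter %s constant; F undefined", c)
            rows.append({"parameter": c, "F": np.nan, "df_num": np.nan, "df_den": np.nan, "p": np.nan})
            continue
        samples = [x[y == g] for g in groups]
        F = _anova_f(samples)
        dfn, dfd = len(groups) - 1, N - len(groups)
        p = float(stats.f.sf(F, dfn, dfd)) if np.isfinite(F) else 0.0
        rows.append({"parameter": c, "F": F, "df_num": dfn, "df_den": dfd, "p": p})
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# sex-difference mixed models
# ---------------------------------------------------------------------------

def sex_difference_lmes(
    features: pd.DataFrame,
    sex_labels,
    individual_labels,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-parameter LME: parameter ~ sex + (1 | individual).

    One linear mixed model per acoustic parameter with sex as fixed effect
    and a random intercept per individual (calls of a sender are
    correlated).  Fitted by ML; reports the male-vs-female estimate, its
    standard error, t, a conservative d.f. of n_individuals - 2 and the
    two-tailed p from that t distribution.  Constant parameters are flagged
    and skipped.
    """
    sex = np.asarray([str(s) for s in sex_labels])
    ind = np.asarray([str(i) for i in individual_labels])
    if len(set(sex)) != 2:
        raise ValueError("sex must have exactly two levels")
    male = (sex == sorted(set(sex))[-1]).astype(float)  # second level coded 1
    cols = columns or [c for c in features.columns if pd.api.types.is_numeric_dtype(features[c])]
    n_ind = len(set(ind))
    df_resid = max(n_ind - 2, 1)
    exog = np.column_stack([np.ones(len(sex)), male])
    rows = []
    for c in cols:
        y = features[c].to_numpy(dtype=float)
        if np.all(y == y[0]):
            logger.warning("parameter %s constant across calls; skipped", c)
            rows.append({"parameter": c, "estimate": np.nan, "se": np.nan, "t": np.nan, "df": df_resid, "p": np.nan})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, exog, groups=ind).fit(reml=False)
        est, se = float(fit.params[1]), float(fit.bse[1])
        t = est / se if se > 0 else np.nan
        p = 2 * float(stats.t.sf(abs(t), df_resid)) if np.isfinite(t) else np.nan
        rows.append({"parameter": c, "estimate": est, "se": se, "t": t, "df": df_resid, "p": p})
    return pd.DataFrame(rows).set_index("parameter")
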