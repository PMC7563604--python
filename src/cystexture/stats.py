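"""Statistical workflow: rank tests, ROC with cutoff selection, DeLong
comparison of correlated curves, and the linear-probability prediction model.

The workflow mirrors a small-cohort radiomics study: Kruskal-Wallis across
histological subtypes, Mann-Whitney benign vs malignant per feature, ROC
analysis (empirical AUC, Youden-index cutoff, Clopper-Pearson confidence
intervals for sensitivity/specificity, DeLong variance for the AUC), paired
DeLong comparison between curves, and an "enter"-model multiple regression of
the 0/1 malignancy label on all univariately significant features (a linear-
probability model whose fitted score is itself ROC-analyzed).

No multiple-testing correction is applied by default in the univariate
screen; an optional Holm adjustment is available. The model is fit and
evaluated on the same subjects — in-sample, as small pilot studies do — so
its ROC is optimistic; see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MannWhitneyResult",
    "KruskalResult",
    "RocResult",
    "DeLongComparison",
    "LinearProbabilityModel",
    "mann_whitney_u",
    "kruskal_wallis",
    "roc_analyze",
    "delong_compare",
    "fit_prediction_model",
    "run_full_analysis",
    "truncate2",
]

#: combined sample size at or below which the exact Mann-Whitney null
#: distribution is enumerated (ties always force the normal approximation)
EXACT_MWU_MAX_N = 20


def truncate2(x: float) -> float:
    """Truncate (not round) to 2 decimals, as clinical tables often print J."""
    return math.floor(x * 100.0 + 1e-9) / 100.0


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

class MannWhitneyResult(NamedTuple):
    u: float
    p_value: float
    method: str  # "exact" | "normal-approx" | "degenerate"
    degenerate: bool = False


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample, from midrank sums."""
    nx = x.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is the first sample's statistic from midrank sums. The p-value is the
    exact permutation probability when the combined n is at most 20 and there
    are no ties; otherwise a tie-corrected normal approximation with
    continuity correction. If every value in both groups is identical the
    test is degenerate: U = nx*ny/2, p = 1, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    u = _u_statistic(x, y)

    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=u, p_value=1.0, method="degenerate", degenerate=True)

    uniq, counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(counts > 1))

    if n <= EXACT_MWU_MAX_N and not has_ties:
        # enumerate U over all C(n, nx) assignments of ranks to the first group
        mean_u = nx * ny / 2.0
        dev = abs(u - mean_u)
        hits = total = 0
        for combo in combinations(range(1, n + 1), nx):
            u_perm = sum(combo) - nx * (nx + 1) / 2.0
            total += 1
            if abs(u_perm - mean_u) >= dev - 1e-9:
                hits += 1
        return MannWhitneyResult(u=u, p_value=hits / total, method="exact")

    mean_u = nx * ny / 2.0
    tie_term = float(np.sum(counts**3 - counts))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var_u <= 0:
        return MannWhitneyResult(u=u, p_value=1.0, method="degenerate", degenerate=True)
    # continuity correction shrinks the deviation toward the mean by 1/2
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return MannWhitneyResult(u=u, p_value=p, method="normal-approx")


class KruskalResult(NamedTuple):
    h: float
    p_value: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square (k-1 df) p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KruskalResult(h=0.0, p_value=1.0)
    h, p = sps.kruskal(*arrays)
    return KruskalResult(h=float(h), p_value=float(p))


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary for one marker at its Youden-optimal cutoff."""

    auc: float
    auc_ci: tuple[float, float]
    p_vs_half: float
    youden_j: float
    cutoff_value: float
    direction: str  # "greater": positive if score > cutoff; "less_equal": <=
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    @property
    def youden_j_truncated(self) -> float:
        return truncate2(self.youden_j)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for a proportion, as (lo, hi) fractions."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: V10 per positive, V01 per negative."""
    # psi(X, Y) = 1 if X > Y, 1/2 if X == Y, 0 otherwise
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    psi = gt + 0.5 * eq
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0)


def _auc_and_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    m, n = pos.size, neg.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    # V01 stores 1 - psi-mean so its mean is 1 - auc; same variance as psi-mean
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_analyze(scores, labels, positive="malignant") -> RocResult:
    """Empirical ROC with midrank-tie AUC, oriented so AUC >= 0.5.

    The cutoff is the midpoint between adjacent sorted unique scores that
    maximizes the Youden index J = sensitivity + specificity - 1; among ties
    the cutoff with the highest specificity wins, then the lowest cutoff
    value. The AUC confidence interval uses the DeLong variance; sensitivity
    and specificity carry exact Clopper-Pearson intervals.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive if labels.dtype.kind in "OUS" else labels.astype(bool)
    pos = scores[is_pos]
    neg = scores[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    auc_raw, var_raw = _auc_and_variance(pos, neg)
    if auc_raw >= 0.5:
        direction = "greater"
        auc, var = auc_raw, var_raw
    else:
        direction = "less_equal"
        auc, var = 1.0 - auc_raw, var_raw  # variance is flip-invariant

    se = math.sqrt(var)
    if se > 0:
        auc_ci = (max(0.0, auc - 1.959963984540054 * se),
                  min(1.0, auc + 1.959963984540054 * se))
        p_vs_half = min(1.0, 2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        auc_ci = (auc, auc)
        p_vs_half = 1.0 if auc == 0.5 else 0.0

    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("all scores identical; no cutoff exists")
    cutoffs = (uniq[:-1] + uniq[1:]) / 2.0

    best = None  # (j, spec, -cutoff) lexicographic best
    for c in cutoffs:
        if direction == "greater":
            sens = float((pos > c).mean())
            spec = float((neg <= c).mean())
        else:
            sens = float((pos <= c).mean())
            spec = float((neg > c).mean())
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, j)

    _, cutoff, sens, spec, j = best
    k_sens = int(round(sens * pos.size))
    k_spec = int(round(spec * neg.size))
    return RocResult(
        auc=auc,
        auc_ci=auc_ci,
        p_vs_half=p_vs_half,
        youden_j=j,
        cutoff_value=float(cutoff),
        direction=direction,
        sensitivity=sens,
        sensitivity_ci=clopper_pearson(k_sens, pos.size),
        specificity=spec,
        specificity_ci=clopper_pearson(k_spec, neg.size),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


@dataclass(frozen=True)
class DeLongComparison:
    """Paired comparison of two correlated empirical AUCs."""

    auc_a: float
    auc_b: float
    auc_difference: float
    z_statistic: float
    p_value: float
    n: int
    zero_variance: bool = False


def delong_compare(scores_a, scores_b, labels, positive="malignant") -> DeLongComparison:
    """DeLong paired z-test on the AUC difference of two markers.

    Both score vectors must be measured on the same subjects. Scores are
    compared as given (orient beforehand if the markers run in opposite
    directions). Identical curves give difference 0 and p = 1; a zero
    estimated variance with a nonzero difference is flagged (infinite z).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    is_pos = labels == positive if labels.dtype.kind in "OUS" else labels.astype(bool)
    if is_pos.all() or (~is_pos).all():
        raise ValueError("both classes must be present")

    pos_a, neg_a = a[is_pos], a[~is_pos]
    pos_b, neg_b = b[is_pos], b[~is_pos]
    v10_a, v01_a = _placements(pos_a, neg_a)
    v10_b, v01_b = _placements(pos_b, neg_b)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    m, n = pos_a.size, neg_a.size

    def _cov(u, v):
        return float(np.cov(u, v, ddof=1)[0, 1]) if u.size > 1 else 0.0

    var = (
        (_cov(v10_a, v10_a) + _cov(v10_b, v10_b) - 2 * _cov(v10_a, v10_b)) / m
        + (_cov(v01_a, v01_a) + _cov(v01_b, v01_b) - 2 * _cov(v01_a, v01_b)) / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-15:
            return DeLongComparison(auc_a, auc_b, 0.0, 0.0, 1.0, m + n)
        return DeLongComparison(
            auc_a, auc_b, diff, math.inf if diff > 0 else -math.inf, 0.0,
            m + n, zero_variance=True,
        )
    z = diff / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return DeLongComparison(auc_a, auc_b, diff, z, p, m + n)


# ---------------------------------------------------------------------------
# linear-probability prediction model
# ---------------------------------------------------------------------------

class LinearProbabilityModel:
    """OLS "enter"-model regression of a 0/1 label on all predictors at once.

    The fitted linear predictor is the prediction-model score used for ROC
    analysis; per-predictor inference comes from OLS t-tests and collinearity
    is diagnosed with variance inflation factors (VIF_j = 1 / (1 - R2_j) of
    predictor j regressed on the co-predictors).

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : OLS coefficients.
    se_, p_values_, vif_ : per-predictor standard errors, t-test p-values, VIFs.
    r_squared_, r_squared_adj_ : coefficient of determination, adjusted.
    multiple_correlation_ : sqrt(R2).
    f_pvalue_ : overall model F-test significance level.
    fitted_scores_ : in-sample linear predictor, one value per subject.
    feature_names_in_ : predictor names when X is a DataFrame.
    """

    def __init__(self, positive="malignant"):
        self.positive = positive

    def get_params(self, deep: bool = True) -> dict:
        return {"positive": self.positive}

    def set_params(self, **params):
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    def _encode_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            return (y == self.positive).astype(float)
        return y.astype(float)

    def fit(self, X, y):
        import statsmodels.api as sm

        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim != 2:
                raise ValueError("X must be 2D")
            self.feature_names_in_ = [f"x{i}" for i in range(Xa.shape[1])]
        ya = self._encode_y(y)
        n, p = Xa.shape
        if n != ya.size:
            raise ValueError("X and y length mismatch")
        if n <= p + 2:
            raise ValueError(f"need n > n_predictors + 2 (n={n}, predictors={p})")

        # exact collinearity: grow the design column by column and name the
        # first column that adds no rank
        design = sm.add_constant(Xa, has_constant="add")
        rank = 1
        for j in range(p):
            sub = design[:, : j + 2]
            new_rank = np.linalg.matrix_rank(sub)
            if new_rank == rank:
                raise ValueError(
                    f"predictor {self.feature_names_in_[j]!r} is exactly collinear "
                    "with the preceding predictors"
                )
            rank = new_rank

        res = sm.OLS(ya, design).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.se_ = np.asarray(res.bse[1:], dtype=float)
        self.p_values_ = np.asarray(res.pvalues[1:], dtype=float)
        self.r_squared_ = float(res.rsquared)
        self.r_squared_adj_ = float(res.rsquared_adj)
        self.multiple_correlation_ = float(np.sqrt(max(res.rsquared, 0.0)))
        self.f_pvalue_ = float(res.f_pvalue) if p >= 1 and not np.isnan(res.f_pvalue) else float("nan")
        self.fitted_scores_ = np.asarray(res.fittedvalues, dtype=float)

        vifs = []
        for j in range(p):
            if p == 1:
                vifs.append(1.0)
                continue
            others = np.delete(Xa, j, axis=1)
            aux = sm.OLS(Xa[:, j], sm.add_constant(others, has_constant="add")).fit()
            r2j = min(aux.rsquared, 1.0 - 1e-12)
            vifs.append(1.0 / (1.0 - r2j))
        self.vif_ = np.asarray(vifs, dtype=float)
        return self

    def decision_function(self, X) -> np.ndarray:
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return Xa @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Linear-probability score (not thresholded, not clipped)."""
        return self.decision_function(X)

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coef_,
                "standard_error": self.se_,
                "p_value": self.p_values_,
                "vif": self.vif_,
            },
            index=self.feature_names_in_,
        )


def fit_prediction_model(
    feature_table: pd.DataFrame,
    predictors: Sequence[str],
    labels,
    positive: str = "malignant",
) -> LinearProbabilityModel:
    """Fit the enter-model linear-probability regression on named predictors."""
    if len(predictors) < 1:
        raise ValueError("need at least one predictor")
    return LinearProbabilityModel(positive=positive).fit(
        feature_table[list(predictors)], labels
    )


# ---------------------------------------------------------------------------
# full workflow
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = "1.0"


def _quartiles(v: np.ndarray) -> dict[str, float]:
    """Median and IQR with linear-interpolation (type-7) quartiles."""
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def run_full_analysis(
    feature_table: pd.DataFrame,
    alpha: float = 0.05,
    positive: str = "malignant",
    group_col: str = "group",
    subtype_col: str = "subtype",
    holm: bool = False,
) -> dict:
    """Run the complete statistical workflow on a cohort feature table.

    Steps: (1) Kruskal-Wallis per feature across subtypes; (2) Mann-Whitney
    per feature benign vs malignant with group medians/IQR for significant
    features; (3) features with p strictly below ``alpha`` enter the
    linear-probability model; (4) ROC per significant feature and for the
    model score, plus all pairwise DeLong comparisons (scores oriented so
    every AUC >= 0.5 before comparison). Returns a JSON-serializable report.
    """
    meta_cols = {c for c in ("subject_id", group_col, subtype_col) if c in feature_table}
    features = [c for c in feature_table.columns if c not in meta_cols]
    groups = feature_table[group_col].to_numpy()
    labels_bin = groups == positive
    if labels_bin.all() or (~labels_bin).all():
        raise ValueError("both groups must be present")

    subtype_tables = {
        st: df for st, df in feature_table.groupby(subtype_col, sort=True)
    }

    kw_table = {}
    for feat in features:
        res = kruskal_wallis([df[feat].to_numpy() for df in subtype_tables.values()])
        kw_table[feat] = {"h": res.h, "p": res.p_value}

    pos_df = feature_table[labels_bin]
    neg_df = feature_table[~labels_bin]
    mw_table = {}
    for feat in features:
        res = mann_whitney_u(neg_df[feat].to_numpy(), pos_df[feat].to_numpy())
        mw_table[feat] = {"u": res.u, "p": res.p_value, "method": res.method}
    if holm:
        adj = holm_adjust([mw_table[f]["p"] for f in features])
        for feat, pa in zip(features, adj):
            mw_table[feat]["p_holm"] = float(pa)

    p_key = "p_holm" if holm else "p"
    significant = [f for f in features if mw_table[f][p_key] < alpha]

    medians_table = {
        feat: {
            "benign": _quartiles(neg_df[feat].to_numpy()),
            "malignant": _quartiles(pos_df[feat].to_numpy()),
        }
        for feat in significant
    }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_subjects": int(len(feature_table)),
        "n_benign": int((~labels_bin).sum()),
        "n_malignant": int(labels_bin.sum()),
        "alpha": alpha,
        "holm": holm,
        "kruskal_wallis": kw_table,
        "mann_whitney": mw_table,
        "group_medians": medians_table,
        "significant_features": significant,
    }

    if not significant:
        report["prediction_model"] = None
        report["roc"] = {}
        report["delong"] = {}
        report["note"] = "no feature passed the univariate screen; model skipped"
        return report

    n = len(feature_table)
    model = None
    if len(significant) < n - 2:
        model = fit_prediction_model(feature_table, significant, groups, positive=positive)
    else:
        report["note"] = (
            f"{len(significant)} significant predictors with only {n} subjects; "
            "the enter-model regression is underdetermined and was skipped"
        )
    report["prediction_model"] = None if model is None else {
        "predictors": {
            name: {
                "coefficient": float(c),
                "standard_error": float(s),
                "p_value": float(p),
                "vif": float(v),
            }
            for name, c, s, p, v in zip(
                significant, model.coef_, model.se_, model.p_values_, model.vif_
            )
        },
        "intercept": model.intercept_,
        "r_squared": model.r_squared_,
        "r_squared_adjusted": model.r_squared_adj_,
        "multiple_correlation_coefficient": model.multiple_correlation_,
        "overall_significance_level": model.f_pvalue_,
    }

    marker_scores = {feat: feature_table[feat].to_numpy(dtype=float) for feat in significant}
    if model is not None:
        marker_scores["prediction_model"] = model.fitted_scores_

    roc_table = {}
    oriented = {}
    for name, sc in marker_scores.items():
        roc = roc_analyze(sc, groups, positive=positive)
        roc_table[name] = {
            "auc": roc.auc,
            "auc_ci": list(roc.auc_ci),
            "p_vs_half": roc.p_vs_half,
            "youden_j": roc.youden_j,
            "youden_j_truncated": roc.youden_j_truncated,
            "cutoff_value": roc.cutoff_value,
            "direction": roc.direction,
            "sensitivity": roc.sensitivity,
            "sensitivity_ci": list(roc.sensitivity_ci),
            "specificity": roc.specificity,
            "specificity_ci": list(roc.specificity_ci),
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
        }
        oriented[name] = sc if roc.direction == "greater" else -sc

    delong_table = {}
    names = list(marker_scores)
    for a, b in combinations(names, 2):
        cmp = delong_compare(oriented[a], oriented[b], groups, positive=positive)
        delong_table[f"{a} vs {b}"] = {
            "auc_difference": cmp.auc_difference,
            "z": cmp.z_statistic,
            "p": cmp.p_value,
        }

    report["roc"] = roc_table
    report["delong"] = delong_table
    return report
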