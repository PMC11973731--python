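"""Method-comparison statistics: concordance, agreement, discrimination.

The module provides the statistical primitives of a two-device
method-comparison study —

* Spearman correlation with a percentile-bootstrap CI (plus a Fisher-z CI
  for reference),
* covariate-adjusted Spearman correlation, operationalised as the partial
  correlation of rank-transformed variables after least-squares
  residualisation on the covariates,
* Bland-Altman agreement (mean difference and 1.96-SD limits of agreement,
  handheld-device minus oscillometry),
* an exact Wilcoxon rank-sum test (full enumeration of the rank-sum null
  by the shift algorithm for untied samples up to n = 30, tie-corrected
  normal approximation otherwise),
* a leave-one-out linear SVM confusion matrix for severity discrimination,
* the Friedman test with Bonferroni-corrected signed-rank post-hocs for the
  three cheek-hold conditions, and
* the Fisher-z a-priori sample size for detecting a correlation —

and wraps them in a statsmodels-style model object: build a
:class:`MethodComparison` from a per-participant measurement table, call
``fit()``, and read the :class:`MethodComparisonResults` (``summary()``
prints the full report).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "SpearmanResult",
    "AgreementReport",
    "ConfusionMatrix",
    "FriedmanResult",
    "spearman_ci",
    "adjusted_spearman",
    "bland_altman",
    "wilcoxon_rank_sum_exact",
    "svm_loo_confusion",
    "friedman_posthoc",
    "sample_size_correlation",
    "MethodComparison",
    "MethodComparisonResults",
    "REFERENCE_STUDY_VALUES",
]

# Benchmark values reported by the clinical method-comparison study this
# package emulates; the pipeline prints its own results next to these for
# orientation but never asserts against the participant-level ones (the
# underlying clinical data are not public).
REFERENCE_STUDY_VALUES = {
    "rho_R5_Reo_s": {"rho": 0.95, "ci": (0.81, 0.98)},
    "rho_R19_Reo_f": {"rho": 0.93, "ci": (0.79, 0.99)},
    "bland_altman_R5_Reo_s": {"mean_difference": -0.07, "loa": (-0.16, 0.03)},
    "bland_altman_R19_Reo_f": {"mean_difference": 0.08, "loa": (-0.16, 0.32)},
    "svm_misclassified": {"Reo_s": 0, "R5": 1, "Reo_f": 1, "R19": 4},
}


@dataclass
class SpearmanResult:
    rho: float
    ci_lower: float
    ci_upper: float
    p_value: float | None = None
    fisher_ci: tuple[float, float] | None = None
    degenerate: bool = False


@dataclass
class AgreementReport:
    """Concordance + agreement for one device pair (handheld minus osc)."""

    rho: float
    rho_ci: tuple[float, float]
    mean_difference: float
    loa_lower: float
    loa_upper: float

    def __post_init__(self) -> None:
        if not (self.loa_lower <= self.mean_difference <= self.loa_upper):
            raise ValueError("limits of agreement must bracket the mean difference")


@dataclass
class ConfusionMatrix:
    """2x2 counts, rows = true class, columns = predicted class."""

    labels: tuple[str, str]
    counts: np.ndarray  # shape (2, 2), non-negative ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or np.any(c < 0):
            raise ValueError("counts must be a non-negative 2x2 matrix")
        self.counts = c.astype(int)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_misclassified(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        idx = [f"true_{label}" for label in self.labels]
        col = [f"pred_{label}" for label in self.labels]
        return pd.DataFrame(self.counts, index=idx, columns=col)


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    posthoc_performed: bool
    posthoc_p: dict[str, float] | None = None


def _bootstrap_ci(pairs_fn, n: int, alpha: float, B: int, seed) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        v = pairs_fn(idx)
        if np.isfinite(v):
            vals.append(v)
    if not vals:
        return (float("nan"), float("nan"))
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def spearman_ci(x, y, alpha: float = 0.05, B: int = 2000, seed=None) -> SpearmanResult:
    """Spearman rho with percentile-bootstrap CI (B resamples over pairs).

    A Fisher-z interval is attached for reference.  Ties are handled by
    average ranks.  Raises on constant input (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need paired samples with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)

    def stat(idx):
        xs, ys = x[idx], y[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            return float("nan")
        return float(stats.spearmanr(xs, ys).statistic)

    lo, hi = (_bootstrap_ci(stat, x.size, alpha, B, seed) if B > 0
              else (float("nan"), float("nan")))
    z = stats.norm.ppf(1 - alpha / 2)
    if abs(rho) < 1:
        se = 1.0 / math.sqrt(x.size - 3)
        fz = (math.tanh(math.atanh(rho) - z * se), math.tanh(math.atanh(rho) + z * se))
    else:
        fz = (rho, rho)
    return SpearmanResult(rho=rho, ci_lower=lo, ci_upper=hi,
                          p_value=float(res.pvalue), fisher_ci=fz)


def _rank_residuals(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v)
    beta, *_ = np.linalg.lstsq(design, r, rcond=None)
    return r - design @ beta


def adjusted_spearman(x, y, covariates: pd.DataFrame, alpha: float = 0.05,
                      B: int = 2000, seed=None) -> SpearmanResult:
    """Covariate-adjusted Spearman correlation (rank-residual partial corr).

    x and y are rank-transformed, each is residualised by least squares on
    [1, covariates], and the partial coefficient is the Pearson correlation
    of the residuals.  The CI is a percentile bootstrap over participants.

    Raises
    ------
    ValueError
        If the covariate design is rank-deficient (names the collinear
        columns) or sizes mismatch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = covariates.astype(float)
    n, p = len(cov), cov.shape[1]
    if x.size != n or y.size != n:
        raise ValueError("x, y and covariates must have equal length")
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    design = np.column_stack([np.ones(n), cov.to_numpy()])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = [c for c in cov.columns
               if np.linalg.matrix_rank(design) ==
               np.linalg.matrix_rank(np.column_stack(
                   [np.ones(n), cov.drop(columns=c).to_numpy()]))]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")

    def partial(xv, yv, d):
        rx = _rank_residuals(xv, d)
        ry = _rank_residuals(yv, d)
        sx, sy = np.std(rx), np.std(ry)
        if sx < 1e-10 * max(1.0, np.std(stats.rankdata(xv))) or \
           sy < 1e-10 * max(1.0, np.std(stats.rankdata(yv))):
            return float("nan")
        return float(np.corrcoef(rx, ry)[0, 1])

    rho = partial(x, y, design)
    degenerate = not np.isfinite(rho)

    def stat(idx):
        return partial(x[idx], y[idx], design[idx])

    lo, hi = (_bootstrap_ci(stat, n, alpha, B, seed) if B > 0
              else (float("nan"), float("nan")))
    return SpearmanResult(rho=rho, ci_lower=lo, ci_upper=hi, degenerate=degenerate)


def bland_altman(handheld, oscillometry) -> tuple[float, float, float]:
    """Mean difference and 1.96-SD limits of agreement.

    Differences are handheld-device minus oscillometry.  Returns
    (mean_difference, loa_lower, loa_upper).
    """
    a = np.asarray(handheld, dtype=float)
    b = np.asarray(oscillometry, dtype=float)
    if a.size != b.size:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need n >= 2")
    d = a - b
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return md, md - 1.96 * sd, md + 1.96 * sd


def _rank_sum_pmf(n_a: int, n: int) -> np.ndarray:
    """Distribution of the rank sum of a size-n_a group among ranks 1..n,
    by the shift algorithm (dynamic program over ranks)."""
    max_sum = n_a * n
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        # iterate k downward so each rank is used at most once
        for k in range(min(n_a, r), 0, -1):
            counts[k, r:] += counts[k - 1, :-r or None]
    pmf = counts[n_a]
    return pmf / pmf.sum()


def wilcoxon_rank_sum_exact(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by full enumeration of the rank-sum null (shift algorithm) when
    the pooled sample has no ties and n_a + n_b <= 30; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    n = pooled.size
    has_ties = np.unique(pooled).size < n
    if has_ties or n > 30:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic",
                                        use_continuity=True).pvalue)
    ranks = stats.rankdata(pooled)
    w = float(np.sum(ranks[: a.size]))
    pmf = _rank_sum_pmf(a.size, n)
    sums = np.arange(pmf.size)
    p_le = pmf[sums <= w].sum()
    p_ge = pmf[sums >= w].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def svm_loo_confusion(values, labels, C: float = 1.0) -> ConfusionMatrix:
    """Leave-one-out confusion matrix of a 1-D linear soft-margin SVM.

    Each participant is predicted by an SVM (linear kernel, penalty C)
    trained on the remaining n-1 points.  Row/column order follows the
    sorted unique labels.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    preds = []
    for i in range(x.shape[0]):
        mask = np.ones(x.shape[0], dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if np.unique(ytr).size < 2:
            preds.append(ytr[0])
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(x[mask], ytr)
        preds.append(clf.predict(x[i:i + 1])[0])
    preds = np.asarray(preds)
    counts = np.zeros((2, 2), dtype=int)
    for i, ti in enumerate(classes):
        for j, pj in enumerate(classes):
            counts[i, j] = int(np.sum((y == ti) & (preds == pj)))
    return ConfusionMatrix(labels=tuple(str(c) for c in classes), counts=counts)


def friedman_posthoc(data, alpha: float = 0.05) -> FriedmanResult:
    """Friedman test across 3 repeated conditions, with post-hocs.

    ``data`` is an (n participants x 3 conditions) array with no missing
    cells.  If the main effect is significant at ``alpha``, the three
    pairwise Wilcoxon signed-rank tests are run with a Bonferroni factor
    of 3; otherwise post-hocs are reported as not performed.
    """
    d = np.asarray(data, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError("data must be n x 3")
    if np.any(~np.isfinite(d)):
        raise ValueError("missing cells are not allowed")
    if np.all(d == d[:, [0]]):
        # identical conditions: statistic 0 by convention, p = 1
        return FriedmanResult(statistic=0.0, p_value=1.0, posthoc_performed=False)
    stat, p = stats.friedmanchisquare(d[:, 0], d[:, 1], d[:, 2])
    if p >= alpha:
        return FriedmanResult(statistic=float(stat), p_value=float(p),
                              posthoc_performed=False)
    post = {}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        pw = stats.wilcoxon(d[:, i], d[:, j]).pvalue if np.any(d[:, i] != d[:, j]) else 1.0
        post[f"{i}-{j}"] = float(min(1.0, 3.0 * pw))
    return FriedmanResult(statistic=float(stat), p_value=float(p),
                          posthoc_performed=True, posthoc_p=post)


def sample_size_correlation(r_squared: float, power: float = 0.8,
                            alpha: float = 0.05) -> int:
    """A-priori n to detect a correlation with r^2 >= ``r_squared``.

    Fisher-z formula n = ceil(((z_{1-a/2} + z_{1-b}) / atanh(sqrt(r^2)))^2 + 3),
    reported with a floor of 4.
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must be in (0, 1)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n = math.ceil(((z_a + z_b) / math.atanh(math.sqrt(r_squared))) ** 2 + 3)
    return max(n, 4)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

DEFAULT_PAIRS = (("R5", "Reo_s"), ("R19", "Reo_f"))
DEFAULT_COVARIATES = ("age", "sex", "bmi", "pack_years", "severity")
MEASURE_COLUMNS = ("R5", "R19", "Reo_s", "Reo_f")


class MethodComparison:
    """Two-device method-comparison model over a per-participant table.

    Parameters
    ----------
    data : DataFrame
        One row per participant with columns ``R5, R19, Reo_s, Reo_f``
        (kPa*s/L), ``group`` (two labels, e.g. GOLD1/GOLD4), and the
        covariates ``age, sex, bmi, pack_years`` (sex coded F/M or 0/1).
        Rows with missing values among these columns are dropped (counted).
    pairs : sequence of (oscillometry, handheld) column pairs to compare.
    covariates : covariate columns for the adjusted analyses; a ``severity``
        indicator (1 = second group label in sorted order) is derived from
        ``group`` if requested and absent.
    """

    def __init__(self, data: pd.DataFrame,
                 pairs=DEFAULT_PAIRS,
                 covariates=DEFAULT_COVARIATES,
                 group_col: str = "group"):
        df = data.copy()
        self.pairs = tuple((str(a), str(b)) for a, b in pairs)
        self.group_col = group_col
        self.covariate_names = tuple(covariates)
        self.group_labels = tuple(sorted(df[group_col].astype(str).unique()))
        if len(self.group_labels) != 2:
            raise ValueError("data must contain exactly two group labels")
        if "severity" in self.covariate_names and "severity" not in df.columns:
            df["severity"] = (df[group_col].astype(str) ==
                              self.group_labels[1]).astype(float)
        if "sex" in df.columns and df["sex"].dtype == object:
            df["sex"] = (df["sex"].astype(str).str.upper() == "F").astype(float)
        needed = set(MEASURE_COLUMNS) | set(self.covariate_names) | {group_col}
        missing_cols = needed - set(df.columns)
        if missing_cols:
            raise ValueError(f"missing columns: {sorted(missing_cols)}")
        complete = df[sorted(needed)].notna().all(axis=1)
        self.n_excluded = int((~complete).sum())
        self.data = df.loc[complete].reset_index(drop=True)
        if len(self.data) < 5:
            raise ValueError("need at least 5 complete participants")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "MethodComparison":
        return cls(data, **kwargs)

    def fit(self, bootstrap: int = 2000, alpha: float = 0.05,
            seed=None) -> "MethodComparisonResults":
        """Run all comparisons; ``bootstrap=0`` skips the CIs (fast path)."""
        df = self.data
        ss = np.random.SeedSequence(entropy=seed) if seed is not None \
            else np.random.SeedSequence()
        seeds = iter(ss.spawn(4 * len(self.pairs)))
        cov = df[list(self.covariate_names)]
        agreement: dict[str, AgreementReport] = {}
        unadjusted: dict[str, SpearmanResult] = {}
        adjusted: dict[str, SpearmanResult] = {}
        for osc_col, hh_col in self.pairs:
            key = f"{osc_col}~{hh_col}"
            x, y = df[osc_col].to_numpy(), df[hh_col].to_numpy()
            unadjusted[key] = spearman_ci(x, y, alpha, bootstrap, next(seeds))
            adjusted[key] = adjusted_spearman(x, y, cov, alpha, bootstrap,
                                              next(seeds))
            md, lo, hi = bland_altman(y, x)
            adj = adjusted[key]
            agreement[key] = AgreementReport(
                rho=adj.rho, rho_ci=(adj.ci_lower, adj.ci_upper),
                mean_difference=md, loa_lower=lo, loa_upper=hi,
            )

        grp = df[self.group_col].astype(str)
        g1 = df.loc[grp == self.group_labels[0]]
        g2 = df.loc[grp == self.group_labels[1]]
        rows = []
        for m in MEASURE_COLUMNS:
            rows.append({
                "measure": m,
                f"median_{self.group_labels[0]}": float(g1[m].median()),
                f"iqr_{self.group_labels[0]}": float(g1[m].quantile(0.75)
                                                     - g1[m].quantile(0.25)),
                f"median_{self.group_labels[1]}": float(g2[m].median()),
                f"iqr_{self.group_labels[1]}": float(g2[m].quantile(0.75)
                                                     - g2[m].quantile(0.25)),
                "wilcoxon_p": wilcoxon_rank_sum_exact(g1[m], g2[m]),
            })
        group_table = pd.DataFrame(rows).set_index("measure")

        confusion = {m: svm_loo_confusion(df[m].to_numpy(), grp.to_numpy())
                     for m in MEASURE_COLUMNS}
        return MethodComparisonResults(
            model=self, agreement=agreement, unadjusted=unadjusted,
            adjusted=adjusted, group_table=group_table, confusion=confusion,
            n=len(df), n_excluded=self.n_excluded, alpha=alpha,
        )


@dataclass
class MethodComparisonResults:
    """Fitted method-comparison results; ``summary()`` renders a report."""

    model: MethodComparison
    agreement: dict[str, AgreementReport]
    unadjusted: dict[str, SpearmanResult]
    adjusted: dict[str, SpearmanResult]
    group_table: pd.DataFrame
    confusion: dict[str, ConfusionMatrix]
    n: int
    n_excluded: int
    alpha: float = 0.05

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "n_excluded": self.n_excluded,
            "pairs": {},
            "group_table": self.group_table.reset_index().to_dict("records"),
            "confusion": {m: cm.counts.tolist() for m, cm in self.confusion.items()},
            "reference_study": REFERENCE_STUDY_VALUES,
        }
        for key, rep in self.agreement.items():
            una = self.unadjusted[key]
            adj = self.adjusted[key]
            out["pairs"][key] = {
                "rho_unadjusted": una.rho,
                "rho_adjusted": adj.rho,
                "rho_adjusted_ci": [adj.ci_lower, adj.ci_upper],
                "mean_difference": rep.mean_difference,
                "loa": [rep.loa_lower, rep.loa_upper],
            }
        return out

    def summary(self) -> str:
        lines = [
            "Method comparison: handheld occlusion device vs oscillometry",
            f"participants analysed: {self.n} (excluded: {self.n_excluded})",
            "",
            "Concordance and agreement (handheld - oscillometry):",
        ]
        for key, rep in self.agreement.items():
            una = self.unadjusted[key]
            ref_key = "rho_" + key.replace("~", "_")
            ref = REFERENCE_STUDY_VALUES.get(ref_key)
            lines.append(
                f"  {key}: rho={una.rho:.3f}, adjusted rho={rep.rho:.3f} "
                f"[{rep.rho_ci[0]:.3f}, {rep.rho_ci[1]:.3f}], "
                f"mean diff={rep.mean_difference:+.3f} "
                f"(LOA {rep.loa_lower:+.3f} to {rep.loa_upper:+.3f})"
            )
            if ref is not None:
                ba = REFERENCE_STUDY_VALUES["bland_altman_" + key.replace("~", "_")]
                lines.append(
                    f"    reference study: rho={ref['rho']:.2f} "
                    f"[{ref['ci'][0]:.2f}, {ref['ci'][1]:.2f}], "
                    f"mean diff={ba['mean_difference']:+.2f} "
                    f"(LOA {ba['loa'][0]:+.2f} to {ba['loa'][1]:+.2f})"
                )
        lines += ["", "Group comparison (medians, IQRs, rank-sum p):",
                  self.group_table.to_string(float_format=lambda v: f"{v:.4g}"),
                  "", "Severity discrimination (leave-one-out SVM):"]
        for m, cm in self.confusion.items():
            ref = REFERENCE_STUDY_VALUES["svm_misclassified"].get(m)
            lines.append(f"  {m}: {cm.n_misclassified}/{cm.n} misclassified"
                         + (f" (reference study: {ref}/17)" if ref is not None else ""))
        return "\n".join(lines)
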