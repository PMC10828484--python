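"""Sex-stratified cohort statistics and synthetic cohort generation.

Implements the statistical layer applied to the per-participant variable
set: descriptive summaries (median and IQR, or counts and percentages),
sex comparisons (chi-squared for categorical variables with Yates
continuity correction on 2×2 tables only, Wilcoxon rank-sum for
continuous variables — exact when both groups have ≤ 25 observations and
there are no ties), Spearman rank correlations with Cohen effect-size
classing, and correlation matrices rendered as heatmaps.

A Gaussian-copula generator draws synthetic cohorts with specified
marginals (median, Q1, Q3, distribution family) and a target Spearman
rank-correlation structure, so the statistical layer can be exercised and
calibrated without access to the original participant data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_COHEN_BOUNDS = (0.1, 0.3, 0.5)   # small / medium / large |rho| thresholds

GRIP_CUTOFF_KG = {"M": 27.0, "F": 16.0}   # EWGSOP2 probable-sarcopenia cuts


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Participants × variables; ``sex`` column takes values "M"/"F".

    Rows play the role of participant records; ``meta`` maps variable name
    to a (units, kind) pair with kind in {"numeric", "categorical"}.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if "id" in self.df.columns and self.df["id"].duplicated().any():
            raise ValueError("participant ids must be unique")

    def kind(self, variable: str) -> str:
        if variable in self.meta:
            return self.meta[variable][1]
        return ("numeric" if pd.api.types.is_numeric_dtype(self.df[variable])
                else "categorical")

    def stratum(self, sex: str) -> pd.DataFrame:
        return self.df if sex == "all" else self.df[self.df["sex"] == sex]


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    stratum: str
    rho: float
    n: int
    effect_class: str

    def __post_init__(self):
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")


# --------------------------------------------------------------------------
# descriptive statistics and group comparisons
# --------------------------------------------------------------------------

def quartiles(values) -> tuple:
    """Median and (Q1, Q3) with linear interpolation between order
    statistics (the convention of mainstream statistics environments)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def describe(cohort: CohortTable, variable: str, stratify_by_sex: bool = True) -> dict:
    """Median (Q1, Q3) for numeric variables, counts and percentages for
    categorical ones, per sex stratum (or pooled)."""
    strata = ("M", "F") if stratify_by_sex else ("all",)
    out = {}
    for s in strata:
        vals = cohort.stratum(s)[variable]
        if cohort.kind(variable) == "numeric":
            vals = vals.dropna()
            if vals.empty:
                out[s] = {"missing": True}
                continue
            med, iqr = quartiles(vals)
            out[s] = {"median": med, "iqr": iqr, "n": int(len(vals))}
        else:
            vals = vals.dropna()
            if vals.empty:
                out[s] = {"missing": True}
                continue
            counts = vals.value_counts().to_dict()
            n = int(len(vals))
            out[s] = {"counts": counts,
                      "pct": {k: 100.0 * c / n for k, c in counts.items()},
                      "n": n}
    return out


def chi2_test(table) -> tuple:
    """Pearson chi-squared on a contingency table; Yates continuity
    correction applied iff the table is 2×2.  Returns (chi2, p, df)."""
    t = np.asarray(table, dtype=float)
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=(t.shape == (2, 2)))
    return float(chi2), float(p), int(dof)


def rank_sum_test(x, y, exact_max_n: int = 25) -> tuple:
    """Two-sided Wilcoxon rank-sum.  Exact when both samples have at most
    ``exact_max_n`` observations and there are no ties; normal
    approximation with tie and continuity correction otherwise.
    Returns (statistic U, p, method)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    exact = no_ties and len(x) <= exact_max_n and len(y) <= exact_max_n
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue), "exact" if exact else "asymptotic"


@dataclass
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p_value: float

    @property
    def p_formatted(self) -> str:
        return format_p(self.p_value)


def format_p(p: float) -> str:
    """Report to two decimals, "< 0.01" below."""
    return "< 0.01" if p < 0.005 else f"{p:.2f}"


def compare_groups(cohort: CohortTable, variable: str) -> GroupComparison:
    """Compare men and women on one variable: chi-squared (categorical) or
    Wilcoxon rank-sum (numeric)."""
    men = cohort.stratum("M")[variable].dropna()
    women = cohort.stratum("F")[variable].dropna()
    if men.empty or women.empty:
        raise ValueError(f"empty sex stratum for variable {variable!r}")
    if cohort.kind(variable) == "categorical":
        cats = sorted(set(men) | set(women))
        table = [[int((men == c).sum()) for c in cats],
                 [int((women == c).sum()) for c in cats]]
        chi2, p, _ = chi2_test(table)
        return GroupComparison(variable, "chi2", chi2, p)
    u, p, method = rank_sum_test(men, women)
    return GroupComparison(variable, f"wilcoxon-{method}", u, p)


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------

def cohen_class(rho: float) -> str:
    """Cohen's benchmarks for |rho|: < 0.1 negligible, [0.1, 0.3) small,
    [0.3, 0.5) medium, >= 0.5 large."""
    r = abs(rho)
    if r > 1 + 1e-12:
        raise ValueError("|rho| must be <= 1")
    small, medium, large = _COHEN_BOUNDS
    if r < small:
        return "negligible"
    if r < medium:
        return "small"
    if r < large:
        return "medium"
    return "large"


def spearman(x, y, var_x: str = "x", var_y: str = "y",
             stratum: str = "all") -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing values
    and average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        return CorrelationResult(var_x, var_y, stratum, float("nan"),
                                 int(len(x)), "undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(var_x, var_y, stratum, rho, int(len(x)),
                             cohen_class(rho))


def correlation_matrix(cohort: CohortTable, var_list, stratum: str = "all"):
    """Symmetric Spearman matrix over ``var_list`` within one stratum.

    Returns (DataFrame of rho, list of CorrelationResult).  Cells with
    fewer than 3 complete pairs are NaN."""
    if len(var_list) < 2:
        raise ValueError("need at least 2 variables")
    df = cohort.stratum(stratum)
    mat = pd.DataFrame(np.eye(len(var_list)), index=var_list, columns=var_list)
    results = []
    for i, vx in enumerate(var_list):
        for j in range(i + 1, len(var_list)):
            vy = var_list[j]
            try:
                r = spearman(df[vx], df[vy], vx, vy, stratum)
                mat.loc[vx, vy] = mat.loc[vy, vx] = r.rho
                results.append(r)
            except ValueError:
                mat.loc[vx, vy] = mat.loc[vy, vx] = np.nan
    return mat, results


def correlation_long(results) -> pd.DataFrame:
    """Long-format export of correlation results."""
    return pd.DataFrame(
        [{"var_x": r.var_x, "var_y": r.var_y, "stratum": r.stratum,
          "rho": r.rho, "n": r.n, "effect_class": r.effect_class}
         for r in results])


def plot_heatmap(matrix: pd.DataFrame, path=None, title: str = ""):
    """Correlation heatmap; saved to ``path`` if given, returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(0.5 * len(matrix) + 2,) * 2)
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


# --------------------------------------------------------------------------
# synthetic cohort generation (Gaussian copula)
# --------------------------------------------------------------------------

@dataclass
class MarginalSpec:
    """One variable's marginal: median and quartiles plus a family.

    Families: "normal" (location = median, scale = IQR / 1.349) and
    "lognormal" (same fit on the log scale; requires positive quartiles).
    ``lower``/``upper`` clip the draws (percentages live in [0, 100])."""

    median: float
    q1: float
    q3: float
    family: str = "normal"
    lower: float | None = None
    upper: float | None = None

    _Z_IQR = 2.0 * stats.norm.ppf(0.75)   # 1.349

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            x = stats.norm.ppf(u, loc=self.median, scale=max(self.q3 - self.q1, 1e-9) / self._Z_IQR)
        elif self.family == "lognormal":
            if self.q1 <= 0 or self.median <= 0:
                raise ValueError("lognormal marginal needs positive quartiles")
            s = (np.log(self.q3) - np.log(self.q1)) / self._Z_IQR
            x = np.exp(stats.norm.ppf(u, loc=np.log(self.median), scale=max(s, 1e-9)))
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if self.lower is not None or self.upper is not None:
            x = np.clip(x, self.lower if self.lower is not None else -np.inf,
                        self.upper if self.upper is not None else np.inf)
        return x


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Copula conversion: the latent Gaussian correlation that yields a
    given Spearman correlation after monotone marginal transforms."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def nearest_psd(mat: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping to the nearest positive semi-definite
    correlation matrix (renormalised to unit diagonal)."""
    w, v = np.linalg.eigh(np.asarray(mat, dtype=float))
    w = np.clip(w, 1e-10, None)
    out = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d)


def _sample_copula(marginals: dict, target: pd.DataFrame | None, n: int,
                   rng: np.random.Generator, repair: bool) -> pd.DataFrame:
    names = list(marginals)
    k = len(names)
    rho_s = np.eye(k)
    if target is not None:
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if a in target.index and b in target.columns:
                    rho_s[i, j] = target.loc[a, b]
    rho_p = spearman_to_pearson(rho_s)
    np.fill_diagonal(rho_p, 1.0)
    w = np.linalg.eigvalsh(rho_p)
    if w.min() < -1e-8:
        if not repair:
            raise ValueError(
                "target rank-correlation matrix is not positive semi-definite "
                "after copula conversion; pass repair=True for nearest-PSD repair")
        rho_p = nearest_psd(rho_p)
    z = rng.multivariate_normal(np.zeros(k), rho_p, size=n,
                                method="cholesky" if w.min() > 1e-8 else "eigh")
    u = stats.norm.cdf(z)
    u = np.clip(u, 1e-9, 1 - 1e-9)
    return pd.DataFrame({nm: marginals[nm].ppf(u[:, i])
                         for i, nm in enumerate(names)})


def generate_cohort(n_men: int, n_women: int, marginal_specs: dict,
                    target_rank_corr=None, seed: int = 0,
                    repair: bool = False) -> CohortTable:
    """Draw a synthetic cohort with given marginals and Spearman structure.

    ``marginal_specs`` maps sex ("M"/"F") to {variable: MarginalSpec};
    a flat {variable: MarginalSpec} dict is applied to both sexes.
    ``target_rank_corr`` is a variables × variables DataFrame of target
    Spearman correlations (or a dict per sex).  Derived fields — EWGSOP2
    category from the sex-specific grip cut-offs and BMI category from the
    <25 / 25-30 / >30 bands — are computed, never sampled.
    """
    rng = np.random.default_rng(seed)
    per_sex = ("M" in marginal_specs and isinstance(
        next(iter(marginal_specs.values())), dict))
    frames = []
    for sex, n in (("M", n_men), ("F", n_women)):
        if n == 0:
            continue
        specs = marginal_specs[sex] if per_sex else marginal_specs
        target = (target_rank_corr.get(sex)
                  if isinstance(target_rank_corr, dict) else target_rank_corr)
        df = _sample_copula(specs, target, n, rng, repair)
        df.insert(0, "sex", sex)
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", [f"P{i:03d}" for i in range(len(df))])
    if "grip_kg" in df.columns:
        cut = df["sex"].map(GRIP_CUTOFF_KG)
        df["ewgsop2"] = np.where(df["grip_kg"] < cut, "probable", "none")
    if "bmi_kgm2" in df.columns:
        df["bmi_category"] = pd.cut(
            df["bmi_kgm2"], bins=[-np.inf, 25.0, 30.0, np.inf],
            labels=["normal", "overweight", "obese"]).astype(str)
    meta = {c: ("", "numeric") for c in df.columns if c not in
            ("id", "sex", "ewgsop2", "bmi_category")}
    meta.update({"sex": ("", "categorical"), "ewgsop2": ("", "categorical"),
                 "bmi_category": ("", "categorical")})
    return CohortTable(df, meta)
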