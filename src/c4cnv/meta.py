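"""Random-effects meta-analysis of per-study log odds ratios.

DerSimonian-Laird moment estimator.  With fixed-effect weights
``w_i = 1 / se_i^2``:

    Q    = sum w_i (beta_i - beta_FE)^2
    tau2 = max(0, (Q - (k - 1)) / (sum w_i - sum w_i^2 / sum w_i))
    w*_i = 1 / (se_i^2 + tau2)
    beta = sum w*_i beta_i / sum w*_i,   se = (sum w*_i)^(-1/2)
    I2   = max(0, (Q - (k - 1)) / Q) * 100

Heterogeneity p is Q against chi-square with k-1 df.  No small-k
correction is applied (plain Wald pooling; REML is available behind a
flag but DerSimonian-Laird is the default and the tested contract).
Multiple testing across the three CNV loci uses a Bonferroni correction
with m = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MetaResult:
    pooled_beta: float
    pooled_se: float
    p: float
    q_stat: float
    df: int
    i_squared: float          # percent; NaN when k = 1
    tau_squared: float
    p_heterogeneity: float    # NaN when k = 1
    k: int
    studies: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def pooled_or(self) -> float:
        return float(np.exp(self.pooled_beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.pooled_beta - 1.96 * self.pooled_se)),
                float(np.exp(self.pooled_beta + 1.96 * self.pooled_se)))


def pool_random_effects(
    estimates, labels=None, method: str = "dl"
) -> MetaResult:
    """Pool per-study (beta, se) pairs under a random-effects model.

    ``estimates`` is a sequence of (beta_i, se_i).  A single study passes
    through unchanged with tau2 = 0 and I2 reported as not applicable
    (NaN).  ``method='reml'`` swaps in an iterative REML tau2; the default
    is the DerSimonian-Laird moment estimator.
    """
    est = [(float(b), float(s)) for b, s in estimates]
    if not est:
        raise ValueError("no study estimates supplied")
    betas = np.array([b for b, _ in est])
    ses = np.array([s for _, s in est])
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be > 0")
    k = betas.size
    if k == 1:
        tau2, q, i2, p_het = 0.0, 0.0, np.nan, np.nan
    else:
        w = 1.0 / ses**2
        beta_fe = np.sum(w * betas) / np.sum(w)
        q = float(np.sum(w * (betas - beta_fe) ** 2))
        if method == "reml":
            tau2 = _reml_tau2(betas, ses)
        else:
            denom = np.sum(w) - np.sum(w**2) / np.sum(w)
            tau2 = max(0.0, (q - (k - 1)) / denom)
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
        p_het = float(stats.chi2.sf(q, k - 1))
    w_star = 1.0 / (ses**2 + tau2)
    pooled = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(pooled / se)))
    studies = pd.DataFrame(
        {
            "study": list(labels) if labels is not None else [f"study{i+1}" for i in range(k)],
            "beta": betas,
            "se": ses,
            "weight": w_star / np.sum(w_star),
        }
    )
    return MetaResult(
        pooled_beta=pooled, pooled_se=se, p=p, q_stat=float(q), df=k - 1,
        i_squared=float(i2), tau_squared=float(tau2),
        p_heterogeneity=p_het, k=k, studies=studies,
    )


def _reml_tau2(betas: np.ndarray, ses: np.ndarray, n_iter: int = 200,
               tol: float = 1e-10) -> float:
    tau2 = max(0.0, np.var(betas, ddof=1) - np.mean(ses**2))
    for _ in range(n_iter):
        w = 1.0 / (ses**2 + tau2)
        mu = np.sum(w * betas) / np.sum(w)
        num = np.sum(w**2 * ((betas - mu) ** 2 - ses**2)) + np.sum(w**2) / np.sum(w) * tau2
        new = max(0.0, num / np.sum(w**2))
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


def bonferroni_correct(p: float, m: int = 3) -> float:
    """p_corr = min(1, m * p); m defaults to the three CNV loci tested."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p!r}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m!r}")
    return min(1.0, m * p)


def meta_grid(
    per_study: pd.DataFrame,
    group_cols: tuple[str, ...] = ("locus", "stratum"),
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Pool per-study association rows within each (locus, stratum, ...) group.

    ``per_study`` needs columns ``study, beta, se`` plus the grouping
    columns (the output of the association model grid works directly once
    the pooled rows are removed).  Rows with a nonempty ``error`` column
    are skipped.  When ``bonferroni_m`` is set, corrected p-values are
    added across the groups.
    """
    df = per_study
    if "error" in df.columns:
        df = df[df["error"].fillna("") == ""]
    df = df.dropna(subset=["beta", "se"])
    rows = []
    if "locus" in group_cols and "locus" not in df.columns and "model" in df.columns:
        df = df.assign(locus=df["model"].str.extract(r"cn\[(\w+)\]")[0])
    for key, g in df.groupby(list(group_cols)):
        key = key if isinstance(key, tuple) else (key,)
        res = pool_random_effects(
            list(zip(g["beta"], g["se"])), labels=list(g["study"])
        )
        lo, hi = res.ci95
        row = dict(zip(group_cols, key))
        row.update(
            k=res.k, pooled_beta=res.pooled_beta, pooled_se=res.pooled_se,
            pooled_or=res.pooled_or, ci_low=lo, ci_high=hi, p=res.p,
            q_stat=res.q_stat, i_squared=res.i_squared,
            tau_squared=res.tau_squared, p_heterogeneity=res.p_heterogeneity,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if bonferroni_m is not None and len(out):
        out["p_corrected"] = out["p"].apply(lambda p: bonferroni_correct(p, bonferroni_m))
    return out


def forest_table(result: MetaResult, title: str = "") -> str:
    """Plain-text forest table: one row per study, then the pooled row."""
    lines = []
    if title:
        lines.append(title)
    lines.append(f"{'study':<12} {'OR':>7} {'95% CI':>17} {'weight':>7}")
    for _, r in result.studies.iterrows():
        or_i = np.exp(r["beta"])
        lo, hi = np.exp(r["beta"] - 1.96 * r["se"]), np.exp(r["beta"] + 1.96 * r["se"])
        lines.append(
            f"{r['study']:<12} {or_i:>7.3f} [{lo:>7.3f};{hi:>7.3f}] {r['weight']:>6.1%}"
        )
    lo, hi = result.ci95
    lines.append(
        f"{'pooled (RE)':<12} {result.pooled_or:>7.3f} [{lo:>7.3f};{hi:>7.3f}] {'100.0%':>7}"
    )
    i2 = "n/a" if np.isnan(result.i_squared) else f"{result.i_squared:.1f}%"
    p_het = "n/a" if np.isnan(result.p_heterogeneity) else f"{result.p_heterogeneity:.3g}"
    lines.append(
        f"Q = {result.q_stat:.3f} (df {result.df}), I2 = {i2}, "
        f"tau2 = {result.tau_squared:.4f}, p_het = {p_het}, p = {result.p:.3g}"
    )
    return "\n".join(lines)
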