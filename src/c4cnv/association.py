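"""Case-control logistic association for C4 copy numbers.

All models code the genotype additively: the predictor is the integer
number of gene copies at C4A, C4B or total C4, so ``exp(beta)`` is the odds
ratio per additional copy.  Models are adjusted for age and sex and, where
several studies are pooled, for study; conditioning on linked SNPs adds
their allele dosages as covariates.  Fitting is maximum likelihood via
iteratively reweighted least squares with Wald standard errors from the
observed information (statsmodels).

Stratified analyses split the cohort by sex, by late-stage subtype (each
subtype's cases against all controls), or into three age bands: <71,
[71, 78], >78 years.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .calling import LOCI

AGE_BANDS = ((None, 71.0), (71.0, 78.0), (78.0, None))  # <71, [71,78], >78
AGE_LABELS = ("age<71", "age71-78", "age>78")

SUBTYPES = ("GA", "NV", "GA+NV")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclass
class AssocResult:
    term: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    model: str
    stratum: str = "all"
    term_table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - 1.96 * self.se)),
                float(np.exp(self.beta + 1.96 * self.se)))

    def to_row(self) -> dict:
        lo, hi = self.ci95
        return {
            "term": self.term, "beta": self.beta, "se": self.se,
            "or": self.or_point, "ci_low": lo, "ci_high": hi, "p": self.p,
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "model": self.model, "stratum": self.stratum,
        }


def calls_to_wide(calls: pd.DataFrame) -> pd.DataFrame:
    """Long call table -> one row per sample with cn_<locus> columns."""
    wide = calls.pivot(index="sample_id", columns="locus", values="cn")
    wide.columns = [f"cn_{c}" for c in wide.columns]
    return wide.reset_index()


def _build_frame(cohort, calls, locus, genotypes, condition_on, extra):
    df = cohort.merge(calls_to_wide(calls), on="sample_id", how="inner")
    cn_col = f"cn_{locus}"
    if cn_col not in df.columns:
        raise ValueError(f"no calls for locus {locus!r}")
    df = df.rename(columns={cn_col: "cn"})
    if condition_on:
        if genotypes is None:
            raise ValueError("conditioning requested but no genotype table given")
        df = df.merge(genotypes[["sample_id", *condition_on]], on="sample_id", how="inner")
    if extra is not None:
        df = df.merge(extra, on="sample_id", how="inner")
    return df


def fit_case_control_logistic(
    data: pd.DataFrame,
    predictor: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    extra_columns: tuple[str, ...] = (),
    model_label: str | None = None,
    stratum: str = "all",
) -> AssocResult:
    """Fit case/control status on a predictor with covariate adjustment.

    ``data`` needs a 'status' column ('case'/'control') and the predictor;
    'sex' is coded female = 1, 'study' expands to indicators with the
    largest study as reference.  Complete-case per model.  Raises
    :class:`SeparationError` on (quasi-)separation and ``ValueError`` on a
    singular design.
    """
    cols = ["status", predictor, *covariates, *extra_columns]
    df = data[cols].dropna()
    y = (df["status"] == "case").astype(float).to_numpy()
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases < 10 or n_controls < 10:
        raise ValueError(
            f"too few samples after filtering: {n_cases} cases / {n_controls} controls"
        )
    X = pd.DataFrame(index=df.index)
    X[predictor] = pd.to_numeric(df[predictor])
    for cov in covariates:
        if cov == "sex":
            X["sex_female"] = (df["sex"] == "female").astype(float)
        elif cov == "study":
            ref = df["study"].value_counts().idxmax()
            for lvl in sorted(set(df["study"]) - {ref}):
                X[f"study_{lvl}"] = (df["study"] == lvl).astype(float)
        else:
            X[cov] = pd.to_numeric(df[cov])
    for c in extra_columns:
        X[c] = pd.to_numeric(df[c])
    X = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"singular design matrix (rank {rank} < {X.shape[1]} columns "
            f"{list(X.columns)}); remove collinear covariates"
        )
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True) or np.abs(fit.params).max() > 15:
        worst = fit.params.abs().idxmax()
        raise SeparationError(
            f"diverging coefficient for term {worst!r}: complete or "
            "quasi-complete separation"
        )
    term_table = pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).reset_index(names="term")
    label = model_label or (
        f"status ~ {predictor}" + ("".join(f" + {c}" for c in X.columns[1:] if c != predictor))
    )
    return AssocResult(
        term=predictor,
        beta=float(fit.params[predictor]),
        se=float(fit.bse[predictor]),
        p=float(fit.pvalues[predictor]),
        n_cases=n_cases,
        n_controls=n_controls,
        model=label,
        stratum=stratum,
        term_table=term_table,
    )


def fit_cn_logistic(
    cohort: pd.DataFrame,
    calls: pd.DataFrame,
    locus: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    genotypes: pd.DataFrame | None = None,
    condition_on: tuple[str, ...] = (),
    stratum: tuple[str, pd.Index] | None = None,
    extra: pd.DataFrame | None = None,
    extra_columns: tuple[str, ...] = (),
) -> AssocResult:
    """Additive copy-number logistic model for one locus.

    ``condition_on`` names SNP dosage columns of ``genotypes`` to adjust
    for; ``stratum`` is a ``(label, sample_id index)`` pair restricting the
    fit; ``extra``/``extra_columns`` attach arbitrary numeric covariates
    (e.g. posterior haplotype dosages).
    """
    df = _build_frame(cohort, calls, locus, genotypes, condition_on, extra)
    label = "all"
    if stratum is not None:
        label, idx = stratum
        df = df[df["sample_id"].isin(idx)]
    spec = f"status ~ cn[{locus}]"
    if covariates:
        spec += " + " + " + ".join(covariates)
    if condition_on:
        spec += " | " + ",".join(condition_on)
    return fit_case_control_logistic(
        df, "cn", covariates,
        extra_columns=tuple(condition_on) + tuple(extra_columns),
        model_label=spec, stratum=label,
    )


def stratify_cohort(cohort: pd.DataFrame, scheme: str) -> list[tuple[str, pd.Index]]:
    """Disjoint sample strata for a stratification scheme.

    Schemes: ``age3`` (<71 / [71, 78] / >78 years), ``sex``, ``subtype``
    (each late-stage subtype's cases plus all controls), ``age3xsex``.
    Subtype strata share the controls and so overlap with each other; all
    other schemes partition the cohort.
    """
    if scheme == "age3":
        return _age_strata(cohort)
    if scheme == "sex":
        return [
            (s, pd.Index(cohort.loc[cohort["sex"] == s, "sample_id"]))
            for s in ("female", "male")
        ]
    if scheme == "subtype":
        controls = cohort.loc[cohort["status"] == "control", "sample_id"]
        out = []
        for sub in SUBTYPES:
            cases = cohort.loc[cohort["subtype"] == sub, "sample_id"]
            out.append((f"subtype:{sub}", pd.Index(pd.concat([cases, controls]))))
        return out
    if scheme == "age3xsex":
        out = []
        for (alab, aidx), sex in itertools.product(_age_strata(cohort), ("female", "male")):
            sidx = pd.Index(cohort.loc[cohort["sex"] == sex, "sample_id"])
            out.append((f"{alab},{sex}", aidx.intersection(sidx)))
        return out
    raise ValueError(f"unknown stratification scheme {scheme!r}")


def _age_strata(cohort: pd.DataFrame) -> list[tuple[str, pd.Index]]:
    if cohort["age"].isna().any():
        raise ValueError("age stratification requires ages for all samples")
    age = cohort["age"]
    masks = [age < 71.0, (age >= 71.0) & (age <= 78.0), age > 78.0]
    return [
        (lab, pd.Index(cohort.loc[m, "sample_id"]))
        for lab, m in zip(AGE_LABELS, masks)
    ]


def age_cn_correlation(cohort: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of copy number with age, per locus.

    A confounding check: copy number correlated with age in the full cohort
    would mean age adjustment alone cannot rule out longevity effects.
    """
    df = cohort.merge(calls_to_wide(calls), on="sample_id", how="inner")
    rows = []
    for locus in LOCI:
        col = f"cn_{locus}"
        if col not in df.columns:
            continue
        sub = df.dropna(subset=["age", col])
        cn = sub[col].to_numpy(float)
        if np.isclose(cn.std(), 0) or len(sub) < 3:
            rows.append({"locus": locus, "r": np.nan, "p": np.nan,
                         "n": len(sub), "testable": False})
        else:
            r, p = stats.pearsonr(sub["age"], cn)
            rows.append({"locus": locus, "r": float(r), "p": float(p),
                         "n": len(sub), "testable": True})
    return pd.DataFrame(rows)


def loo_conditioning_sets(snps: tuple[str, ...]) -> list[tuple[str, ...]]:
    """None, each leave-one-out subset, and the full set (2 + k models)."""
    sets: list[tuple[str, ...]] = [()]
    for leave in snps:
        sets.append(tuple(s for s in snps if s != leave))
    sets.append(tuple(snps))
    return sets


def run_model_grid(
    cohort: pd.DataFrame,
    calls: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    loci: tuple[str, ...] = LOCI,
    covariates: tuple[str, ...] = ("age", "sex"),
    per_study: bool = True,
    pooled: bool = True,
    strata_schemes: tuple[str, ...] = (),
    conditioning_sets: tuple[tuple[str, ...], ...] = (),
) -> pd.DataFrame:
    """Fit the full model set; one row per model, failures recorded in-place.

    Per-study crude models use ``covariates``; pooled, stratified and
    conditioned models additionally adjust for study.  A failing cell gets
    an ``error`` message instead of aborting the grid.
    """
    rows = []

    def _try(study, stratum_label, fn, model_note=""):
        try:
            res = fn()
            row = res.to_row()
            row["error"] = ""
        except (ValueError, SeparationError, RuntimeError) as exc:
            row = {"term": "cn", "model": model_note, "stratum": stratum_label,
                   "error": str(exc)}
        row["study"] = study
        rows.append(row)

    pooled_cov = covariates + (("study",) if "study" not in covariates else ())
    for locus in loci:
        if per_study:
            for study in cohort["study"].unique():
                idx = pd.Index(cohort.loc[cohort["study"] == study, "sample_id"])
                _try(study, "all",
                     lambda l=locus, i=idx: fit_cn_logistic(
                         cohort, calls, l, covariates, stratum=("all", i)),
                     f"status ~ cn[{locus}] (study {study})")
        if pooled:
            _try("pooled", "all",
                 lambda l=locus: fit_cn_logistic(cohort, calls, l, pooled_cov),
                 f"status ~ cn[{locus}] pooled")
        for scheme in strata_schemes:
            for label, idx in stratify_cohort(cohort, scheme):
                _try("pooled", label,
                     lambda l=locus, la=label, i=idx: fit_cn_logistic(
                         cohort, calls, l, pooled_cov, stratum=(la, i)),
                     f"status ~ cn[{locus}] stratum {label}")
        for cond in conditioning_sets:
            if not cond:
                continue
            _try("pooled", "all",
                 lambda l=locus, c=cond: fit_cn_logistic(
                     cohort, calls, l, pooled_cov, genotypes=genotypes,
                     condition_on=c),
                 f"status ~ cn[{locus}] | {','.join(cond)}")
    return pd.DataFrame(rows)
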