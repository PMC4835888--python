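"""Small-panel haplotype analysis: EM frequencies, per-haplotype C4A load,
haplotype association.

For a handful of SNPs (here the four CFB/C2 conditioning variants) the
classical expectation-maximization estimator for unphased multilocus
genotypes is exact and fast: the E-step computes diplotype posteriors given
current haplotype frequencies (missing genotypes are summed over), the
M-step re-estimates frequencies from expected haplotype counts.  Downstream
analyses use posterior-expected haplotype dosages (fractional counts in
[0, 2]) rather than a best-guess phase, which propagates phase uncertainty.

Because the phase of the CNV itself is hard to estimate, the C4A copies
carried per haplotype are summarized as the *average* number of copies a
haplotype contributes: a least-squares regression of diploid C4A copy
number on the haplotype dosages, without intercept over the full haplotype
basis.  Coefficient k is then the mean copies contributed per copy of
haplotype k, and frequency-weighted coefficients reproduce the population
mean diploid copy number exactly.  A simpler carrier-mean summary is
provided for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssocResult, fit_case_control_logistic, fit_cn_logistic

REPORT_FREQ_THRESHOLD = 0.01


@dataclass
class HaplotypeSet:
    snps: tuple[str, ...]
    table: pd.DataFrame                  # label, pattern, frequency, mean_c4a
    dosage: pd.DataFrame = field(repr=False)  # sample_id + expected dosage per pattern
    loglik_trace: np.ndarray = field(default=None, repr=False)
    n_iter: int = 0

    def pattern_of(self, label: str) -> str:
        row = self.table[self.table["label"] == label]
        if row.empty:
            raise KeyError(f"no haplotype labelled {label!r}")
        return row["pattern"].iat[0]

    def report(self, threshold: float = REPORT_FREQ_THRESHOLD) -> pd.DataFrame:
        """Reporting view: haplotypes below the frequency threshold are
        collapsed into an 'other' bin."""
        keep = self.table[self.table["frequency"] >= threshold].copy()
        rest = self.table[self.table["frequency"] < threshold]
        if len(rest):
            other = pd.DataFrame(
                [{"label": "other", "pattern": "-" * len(self.snps),
                  "frequency": rest["frequency"].sum(),
                  "mean_c4a": np.nan}]
            )
            keep = pd.concat([keep, other], ignore_index=True)
        return keep.reset_index(drop=True)


def _compatible_pairs(geno: tuple) -> list[tuple[int, int]]:
    """Ordered haplotype pairs (as bit patterns) compatible with one genotype."""
    site_options = []
    for g in geno:
        if g == 0:
            site_options.append(((0, 0),))
        elif g == 2:
            site_options.append(((1, 1),))
        elif g == 1:
            site_options.append(((0, 1), (1, 0)))
        else:  # missing
            site_options.append(((0, 0), (0, 1), (1, 0), (1, 1)))
    pairs = []
    for combo in itertools.product(*site_options):
        h1 = h2 = 0
        for a, b in combo:
            h1 = (h1 << 1) | a
            h2 = (h2 << 1) | b
        pairs.append((h1, h2))
    return pairs


def em_haplotype_frequencies(
    genotypes: pd.DataFrame,
    snps: tuple[str, ...] | None = None,
    max_snps: int = 8,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 1,
    seed: int = 0,
) -> HaplotypeSet:
    """Maximum-likelihood haplotype frequencies for unphased genotypes.

    ``genotypes`` holds a ``sample_id`` column and one 0/1/2 dosage column
    per SNP (NaN = missing).  Initialization is the linkage-equilibrium
    product of allele frequencies; ``n_starts > 1`` adds seeded random
    restarts and keeps the best likelihood.  Returns the full haplotype set
    labelled H1.. by descending frequency, with per-sample posterior
    expected dosages.
    """
    if snps is None:
        snps = tuple(c for c in genotypes.columns if c != "sample_id")
    if len(snps) > max_snps:
        raise ValueError(f"{len(snps)} SNPs exceeds max_snps={max_snps}")
    if len(snps) == 0:
        raise ValueError("no SNP columns found")
    G = genotypes[list(snps)].to_numpy(float)
    n, L = G.shape
    H = 1 << L
    geno_keys = [tuple(-1 if np.isnan(v) else int(v) for v in row) for row in G]
    uniq: dict[tuple, int] = {}
    counts: list[int] = []
    rows_of: list[list[int]] = []
    for i, key in enumerate(geno_keys):
        if key in uniq:
            counts[uniq[key]] += 1
            rows_of[uniq[key]].append(i)
        else:
            uniq[key] = len(counts)
            counts.append(1)
            rows_of.append([i])
    pair_sets = [
        _compatible_pairs(tuple(g if g >= 0 else None for g in key))
        for key in uniq
    ]
    counts_arr = np.array(counts, dtype=float)

    # allele frequencies (missing-aware) for the linkage-equilibrium start
    af = np.nanmean(G, axis=0) / 2.0
    monomorphic = np.all((af == 0) | (af == 1))

    def product_init() -> np.ndarray:
        f = np.ones(H)
        for h in range(H):
            for j in range(L):
                allele = (h >> (L - 1 - j)) & 1
                f[h] *= af[j] if allele else (1.0 - af[j])
        # deterministic tie-break: tiny mass everywhere avoids zero-locking
        f = f + 1e-12
        return f / f.sum()

    def run_em(f0: np.ndarray):
        f = f0.copy()
        trace = []
        for it in range(max_iter):
            expected = np.zeros(H)
            ll = 0.0
            for u, pairs in enumerate(pair_sets):
                probs = np.array([f[a] * f[b] for a, b in pairs])
                tot = probs.sum()
                if tot <= 0:
                    tot = 1e-300
                ll += counts_arr[u] * np.log(tot)
                post = probs / tot
                for (a, b), p in zip(pairs, post):
                    expected[a] += counts_arr[u] * p
                    expected[b] += counts_arr[u] * p
            trace.append(ll)
            new_f = expected / (2.0 * n)
            if it > 0 and trace[-1] - trace[-2] < tol:
                f = new_f
                break
            f = new_f
        return f, np.array(trace)

    if monomorphic:
        f, trace = product_init(), np.array([])
    else:
        f, trace = run_em(product_init())
        if n_starts > 1:
            rng = np.random.default_rng(seed)
            for _ in range(n_starts - 1):
                f0 = rng.dirichlet(np.ones(H))
                f_alt, trace_alt = run_em(f0)
                if trace_alt.size and (not trace.size or trace_alt[-1] > trace[-1]):
                    f, trace = f_alt, trace_alt

    # final E-step: per-sample expected dosages; empirical posterior
    # frequencies are exactly the dosage column means / 2
    dosage = np.zeros((n, H))
    for u, pairs in enumerate(pair_sets):
        probs = np.array([f[a] * f[b] for a, b in pairs])
        tot = probs.sum()
        if tot <= 0:
            tot = 1e-300
        post = probs / tot
        contrib = np.zeros(H)
        for (a, b), p in zip(pairs, post):
            contrib[a] += p
            contrib[b] += p
        for i in rows_of[u]:
            dosage[i] = contrib
    freqs = dosage.mean(axis=0) / 2.0

    patterns = [format(h, f"0{L}b") for h in range(H)]
    order = np.argsort(-freqs, kind="stable")
    keep = [h for h in order if freqs[h] > 1e-9]
    table = pd.DataFrame(
        {
            "label": [f"H{i+1}" for i in range(len(keep))],
            "pattern": [patterns[h] for h in keep],
            "frequency": [float(freqs[h]) for h in keep],
            "mean_c4a": np.nan,
        }
    )
    dosage_df = pd.DataFrame(dosage[:, keep], columns=[patterns[h] for h in keep])
    dosage_df.insert(0, "sample_id", genotypes["sample_id"].to_numpy())
    return HaplotypeSet(snps=tuple(snps), table=table, dosage=dosage_df,
                        loglik_trace=trace, n_iter=len(trace))


def haplotype_mean_cn(
    haps: HaplotypeSet, c4a_cn: pd.Series | pd.DataFrame,
    method: str = "regression",
) -> HaplotypeSet:
    """Fill in the average C4A copies carried per haplotype.

    ``c4a_cn`` maps sample_id to diploid C4A copy number (a Series indexed
    by sample_id, or a calls frame with sample_id/locus/cn rows).
    ``method='regression'`` (default) regresses diploid copy number on the
    expected haplotype dosages without intercept; ``method='carrier_mean'``
    takes the dosage-weighted mean of half the diploid copy number per
    haplotype.  Haplotypes never observed (zero total dosage) are reported
    as not estimable (NaN).
    """
    if isinstance(c4a_cn, pd.DataFrame):
        sub = c4a_cn[c4a_cn["locus"] == "C4A"] if "locus" in c4a_cn.columns else c4a_cn
        c4a_cn = sub.set_index("sample_id")["cn"]
    merged = haps.dosage.merge(
        c4a_cn.rename("cn"), left_on="sample_id", right_index=True, how="inner"
    )
    patterns = list(haps.table["pattern"])
    D = merged[patterns].to_numpy(float)
    y = merged["cn"].to_numpy(float)
    col_tot = D.sum(axis=0)
    estimable = col_tot > 1e-9
    means = np.full(len(patterns), np.nan)
    if method == "regression":
        coef, *_ = np.linalg.lstsq(D[:, estimable], y, rcond=None)
        means[estimable] = coef
    elif method == "carrier_mean":
        means[estimable] = (D[:, estimable] * y[:, None]).sum(axis=0) / col_tot[estimable] / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    table = haps.table.copy()
    table["mean_c4a"] = means
    return HaplotypeSet(snps=haps.snps, table=table, dosage=haps.dosage,
                        loglik_trace=haps.loglik_trace, n_iter=haps.n_iter)


def haplotype_dosage_frame(haps: HaplotypeSet, label: str) -> pd.DataFrame:
    """sample_id + one column ``hap_<label>`` of expected dosage."""
    pattern = haps.pattern_of(label)
    out = haps.dosage[["sample_id", pattern]].copy()
    out.columns = ["sample_id", f"hap_{label}"]
    return out


def haplotype_association(
    haps: HaplotypeSet,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "study"),
    threshold: float = REPORT_FREQ_THRESHOLD,
) -> list[AssocResult]:
    """Per-haplotype logistic association with disease status.

    Each haplotype's posterior-expected dosage is the predictor (all other
    haplotypes jointly form the reference), adjusted for the covariates.
    Only haplotypes at or above the reporting frequency threshold are
    tested.
    """
    results = []
    for _, row in haps.table.iterrows():
        if row["frequency"] < threshold:
            continue
        dose = haplotype_dosage_frame(haps, row["label"])
        data = cohort.merge(dose, on="sample_id", how="inner")
        col = f"hap_{row['label']}"
        res = fit_case_control_logistic(
            data, col, covariates,
            model_label=f"status ~ {col} + " + " + ".join(covariates),
        )
        results.append(res)
    return results


def cn_conditioned_on_haplotype(
    cohort: pd.DataFrame,
    calls: pd.DataFrame,
    haps: HaplotypeSet,
    label: str,
    locus: str = "C4A",
    covariates: tuple[str, ...] = ("age", "sex", "study"),
) -> AssocResult:
    """Copy-number association with one haplotype's dosage as a covariate.

    If the haplotype tags the copy-number variation, the copy-number
    estimate attenuates toward the null relative to the unconditioned
    model; an unlinked haplotype leaves it unchanged.
    """
    dose = haplotype_dosage_frame(haps, label)
    col = f"hap_{label}"
    return fit_cn_logistic(
        cohort, calls, locus, covariates,
        extra=dose, extra_columns=(col,),
    )
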