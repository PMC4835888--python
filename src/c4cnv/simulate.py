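"""Synthetic cohorts with known C4 copy-number truth.

Generates everything the downstream stages consume: a case-control cohort
with covariates, per-sample MLPA peak heights for the C4A / C4B / C4-ex30
test probes and the EP300 / CREBBP control probes, and genotypes at a small
set of SNPs whose haplotypes are correlated with C4A copy number.

The generative model mirrors the structure the analysis assumes:

* copy numbers arise per haploid genome (one CNV allele per haplotype) and
  are summed to the diploid total, so the haplotype-copy-number linkage is
  coherent by construction;
* disease status follows a logistic model additive in diploid C4A copies,
  with age, sex and study effects;
* peak heights are proportional to copy number, with a per-study batch
  scale, a per-sample run intensity, and multiplicative lognormal noise.
  Per-sample factors cancel in the control-probe ratio, which is exactly why
  the dosage normalization downstream is ratio-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TEST_PROBES = ("C4A", "C4B", "C4-ex30")
CONTROL_PROBES = ("EP300", "CREBBP")
ALL_PROBES = TEST_PROBES + CONTROL_PROBES

#: diploid copy-number ranges reported for European-ancestry cohorts
C4A_DIPLOID_RANGE = (0, 5)
C4B_DIPLOID_RANGE = (0, 4)


@dataclass(frozen=True)
class HaplotypeSpec:
    """One SNP haplotype and the C4A copies it carries.

    ``pattern`` is a string of 0/1 alleles, one per SNP in the panel.
    ``c4a_probs`` is the distribution of haploid C4A copies carried on this
    haplotype; its mean is the haplotype's expected per-copy contribution.
    """

    pattern: str
    frequency: float
    c4a_probs: tuple[float, ...]

    @property
    def mean_c4a(self) -> float:
        return float(np.dot(np.arange(len(self.c4a_probs)), self.c4a_probs))


# Synthetic allele patterns over (rs429608, rs114190211, rs204993,
# rs142511358).  The tagging structure -- one low-copy haplotype carrying
# the rs204993 alternate allele, one high-copy haplotype carrying the
# rs429608 alternate allele -- emulates the kind of CNV/SNP linkage the
# analysis must resolve; the patterns and frequencies are NOT the real ones,
# which are not published.
DEFAULT_HAPLOTYPES: tuple[HaplotypeSpec, ...] = (
    HaplotypeSpec("0000", 0.38, (0.15, 0.70, 0.15, 0.00)),
    HaplotypeSpec("0010", 0.22, (0.45, 0.50, 0.05, 0.00)),  # low-C4A, risk-tagged
    HaplotypeSpec("1000", 0.18, (0.05, 0.50, 0.35, 0.10)),  # high-C4A, protective-tagged
    HaplotypeSpec("0001", 0.10, (0.15, 0.70, 0.15, 0.00)),
    HaplotypeSpec("0100", 0.07, (0.15, 0.70, 0.15, 0.00)),
    HaplotypeSpec("1010", 0.05, (0.15, 0.70, 0.15, 0.00)),
)

DEFAULT_SNP_NAMES = ("rs429608", "rs114190211", "rs204993", "rs142511358")

# Table-1-style study composition: three studies, per-study case and control
# fractions of the full cohort.
DEFAULT_STUDIES: dict[str, tuple[float, float]] = {
    "AUS": (633 / 1536, 404 / 1109),
    "WUE": (547 / 1536, 384 / 1109),
    "MUE-TUE": (356 / 1536, 321 / 1109),
}

DEFAULT_SUBTYPE_PROBS = {"GA": 454 / 1536, "NV": 912 / 1536, "GA+NV": 170 / 1536}

DEFAULT_PROBE_SCALE = {
    "C4A": 1000.0,
    "C4B": 1000.0,
    "C4-ex30": 800.0,
    "EP300": 900.0,
    "CREBBP": 1100.0,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Copy-number frequency vectors are per *haploid* genome; diploid copy
    numbers are the sum of two haploid draws.  When ``haplotypes`` is set,
    haploid C4A copies are drawn jointly with the SNP haplotype and
    ``haploid_freqs_c4a`` must equal the marginal implied by the table.
    """

    n_cases: int = 1536
    n_controls: int = 1109
    studies: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STUDIES)
    )
    haploid_freqs_c4a: tuple[float, ...] | None = None  # derived from haplotypes if None
    haploid_freqs_c4b: tuple[float, ...] = (0.12, 0.73, 0.15)
    per_copy_log_or: float = float(np.log(0.81))
    baseline_logit: float = 0.4
    beta_age: float = 0.05       # per year, centred at age_center
    beta_sex: float = 0.10       # female vs male
    age_center: float = 72.0
    study_logits: dict[str, float] = field(default_factory=dict)
    age_mean: float = 74.0
    age_sd: float = 8.0
    female_frac: float = 0.58
    subtype_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROBS)
    )
    peak_noise_cv: float = 0.04
    sample_scale_cv: float = 0.15
    batch_scale: dict[str, float] = field(
        default_factory=lambda: {"AUS": 1.0, "WUE": 1.3, "MUE-TUE": 0.8}
    )
    probe_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROBE_SCALE)
    )
    omit_ex30_studies: tuple[str, ...] = ()
    haplotypes: tuple[HaplotypeSpec, ...] | None = DEFAULT_HAPLOTYPES
    snp_names: tuple[str, ...] = DEFAULT_SNP_NAMES
    max_draw_factor: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.peak_noise_cv < 0 or self.sample_scale_cv < 0:
            raise ValueError("noise coefficients of variation must be >= 0")
        _check_simplex(self.haploid_freqs_c4b, "haploid_freqs_c4b")
        _check_simplex(tuple(self.subtype_probs.values()), "subtype_probs")
        case_fr = [f[0] for f in self.studies.values()]
        ctrl_fr = [f[1] for f in self.studies.values()]
        _check_simplex(case_fr, "study case fractions")
        _check_simplex(ctrl_fr, "study control fractions")
        if self.haplotypes is not None:
            _check_simplex([h.frequency for h in self.haplotypes], "haplotype frequencies")
            for h in self.haplotypes:
                _check_simplex(h.c4a_probs, f"c4a_probs of haplotype {h.pattern}")
                if len(h.pattern) != len(self.snp_names):
                    raise ValueError(
                        f"haplotype pattern {h.pattern!r} does not match "
                        f"{len(self.snp_names)} SNPs"
                    )
            implied = _marginal_haploid_c4a(self.haplotypes)
            if self.haploid_freqs_c4a is None:
                self.haploid_freqs_c4a = implied
            else:
                a = np.asarray(self.haploid_freqs_c4a, float)
                b = np.asarray(implied, float)
                n = max(a.size, b.size)
                a = np.pad(a, (0, n - a.size))
                b = np.pad(b, (0, n - b.size))
                if np.max(np.abs(a - b)) > 1e-6:
                    raise ValueError(
                        "haplotype table is inconsistent with haploid_freqs_c4a: "
                        f"table marginal {tuple(np.round(b, 4))} vs "
                        f"configured {tuple(np.round(a, 4))}"
                    )
        elif self.haploid_freqs_c4a is None:
            raise ValueError("either haplotypes or haploid_freqs_c4a must be given")
        _check_simplex(self.haploid_freqs_c4a, "haploid_freqs_c4a")


def _check_simplex(probs, name: str) -> None:
    p = np.asarray(list(probs), dtype=float)
    if p.size == 0 or np.any(p < 0):
        raise ValueError(f"{name} must be a nonnegative probability vector")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")


def _marginal_haploid_c4a(haps: tuple[HaplotypeSpec, ...]) -> tuple[float, ...]:
    n = max(len(h.c4a_probs) for h in haps)
    out = np.zeros(n)
    for h in haps:
        out[: len(h.c4a_probs)] += h.frequency * np.asarray(h.c4a_probs)
    return tuple(out)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a case-control cohort by rejection from the population model.

    Individuals are drawn from the population (haplotypes, copy numbers,
    age, sex), assigned disease status from the logistic model
    ``P(case) = expit(baseline + log_or * c4a + beta_age * (age - center)
    + beta_sex * female + study_logit)``, and accepted until each study's
    case and control quotas are filled.

    Returns ``(truth, cohort)``: the truth table keeps the generated copy
    numbers and haplotype pair; the cohort table carries only what the
    analysis is allowed to observe (status, subtype, age, sex, study).
    """
    rng = np.random.default_rng(config.seed)
    quotas = _study_quotas(config)
    rows: list[dict] = []
    counter = 0
    for study in config.studies:  # insertion order: deterministic
        need_ca, need_co = quotas[study]
        got_ca = got_co = 0
        drawn = 0
        limit = config.max_draw_factor * (need_ca + need_co)
        while got_ca < need_ca or got_co < need_co:
            block = max(256, 2 * (need_ca + need_co))
            if drawn + block > limit:
                block = limit - drawn
                if block <= 0:
                    raise RuntimeError(
                        f"study {study!r}: case/control quota unreachable after "
                        f"{drawn} draws (filled {got_ca}/{need_ca} cases, "
                        f"{got_co}/{need_co} controls); the disease logits are "
                        "likely degenerate -- check baseline_logit and effect sizes"
                    )
            drawn += block
            pop = _draw_population(rng, config, study, block)
            for indiv in pop:
                is_case = indiv["status"] == "case"
                if is_case and got_ca < need_ca:
                    got_ca += 1
                elif (not is_case) and got_co < need_co:
                    got_co += 1
                else:
                    continue
                counter += 1
                indiv["sample_id"] = f"S{counter:05d}"
                rows.append(indiv)
                if got_ca >= need_ca and got_co >= need_co:
                    break
    truth = pd.DataFrame(rows)[
        ["sample_id", "study", "true_c4a", "true_c4b", "true_total",
         "hap1", "hap2", "status", "subtype", "age", "sex"]
    ]
    cohort = truth[["sample_id", "status", "subtype", "age", "sex", "study"]].copy()
    return truth.reset_index(drop=True), cohort.reset_index(drop=True)


def _study_quotas(config: SimConfig) -> dict[str, tuple[int, int]]:
    """Integer per-study quotas summing exactly to the requested totals."""
    out: dict[str, tuple[int, int]] = {}
    labels = list(config.studies)
    ca = np.array([config.studies[s][0] for s in labels]) * config.n_cases
    co = np.array([config.studies[s][1] for s in labels]) * config.n_controls
    ca_i = _round_preserving_sum(ca, config.n_cases)
    co_i = _round_preserving_sum(co, config.n_controls)
    for s, a, b in zip(labels, ca_i, co_i):
        out[s] = (int(a), int(b))
    return out


def _round_preserving_sum(x: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(x).astype(int)
    short = total - base.sum()
    order = np.argsort(-(x - base))  # largest remainders first
    base[order[:short]] += 1
    return base


def _draw_population(
    rng: np.random.Generator, config: SimConfig, study: str, n: int
) -> list[dict]:
    if config.haplotypes is not None:
        hap_freqs = np.array([h.frequency for h in config.haplotypes])
        idx1 = rng.choice(len(config.haplotypes), size=n, p=hap_freqs)
        idx2 = rng.choice(len(config.haplotypes), size=n, p=hap_freqs)
        c4a_hap1 = _draw_hap_copies(rng, config.haplotypes, idx1)
        c4a_hap2 = _draw_hap_copies(rng, config.haplotypes, idx2)
        hap1 = [config.haplotypes[i].pattern for i in idx1]
        hap2 = [config.haplotypes[i].pattern for i in idx2]
    else:
        pa = np.asarray(config.haploid_freqs_c4a)
        c4a_hap1 = rng.choice(pa.size, size=n, p=pa)
        c4a_hap2 = rng.choice(pa.size, size=n, p=pa)
        hap1 = hap2 = ["NA"] * n
    c4a = c4a_hap1 + c4a_hap2
    pb = np.asarray(config.haploid_freqs_c4b)
    c4b = rng.choice(pb.size, size=n, p=pb) + rng.choice(pb.size, size=n, p=pb)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 40.0, 100.0)
    female = rng.random(n) < config.female_frac
    logit = (
        config.baseline_logit
        + config.per_copy_log_or * c4a
        + config.beta_age * (age - config.age_center)
        + config.beta_sex * female
        + config.study_logits.get(study, 0.0)
    )
    p_case = 1.0 / (1.0 + np.exp(-logit))
    is_case = rng.random(n) < p_case
    subtype_labels = list(config.subtype_probs)
    subtype_p = np.array(list(config.subtype_probs.values()))
    subtypes = rng.choice(subtype_labels, size=n, p=subtype_p)
    out = []
    for i in range(n):
        out.append(
            {
                "study": study,
                "true_c4a": int(c4a[i]),
                "true_c4b": int(c4b[i]),
                "true_total": int(c4a[i] + c4b[i]),
                "hap1": hap1[i],
                "hap2": hap2[i],
                "status": "case" if is_case[i] else "control",
                "subtype": subtypes[i] if is_case[i] else "none",
                "age": float(np.round(age[i], 1)),
                "sex": "female" if female[i] else "male",
            }
        )
    return out


def _draw_hap_copies(rng, haps, idx) -> np.ndarray:
    out = np.empty(idx.size, dtype=int)
    for k, h in enumerate(haps):
        mask = idx == k
        if mask.any():
            p = np.asarray(h.c4a_probs)
            out[mask] = rng.choice(p.size, size=int(mask.sum()), p=p)
    return out


# ---------------------------------------------------------------------------
# peak heights
# ---------------------------------------------------------------------------

def simulate_peaks(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Raw MLPA peak heights for every sample x probe.

    ``height = probe_scale * copies * batch_scale(study) * sample_scale *
    lognormal(mean 1, cv peak_noise_cv)``; control loci EP300 and CREBBP are
    always at 2 copies.  A zero copy number yields an exactly absent peak
    (height 0).  The C4-ex30 probe is omitted for studies listed in
    ``omit_ex30_studies`` (emulating a probe failure in one batch).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(truth)
    sample_scale = _lognormal_unit_mean(rng, config.sample_scale_cv, n)
    copies = {
        "C4A": truth["true_c4a"].to_numpy(float),
        "C4B": truth["true_c4b"].to_numpy(float),
        "C4-ex30": truth["true_total"].to_numpy(float),
        "EP300": np.full(n, 2.0),
        "CREBBP": np.full(n, 2.0),
    }
    batch = truth["study"].map(lambda s: config.batch_scale.get(s, 1.0)).to_numpy(float)
    frames = []
    for probe in ALL_PROBES:
        noise = _lognormal_unit_mean(rng, config.peak_noise_cv, n)
        height = config.probe_scale[probe] * copies[probe] * batch * sample_scale * noise
        keep = np.ones(n, dtype=bool)
        if probe == "C4-ex30" and config.omit_ex30_studies:
            keep = ~truth["study"].isin(config.omit_ex30_studies).to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": truth["sample_id"].to_numpy()[keep],
                    "study": truth["study"].to_numpy()[keep],
                    "probe": probe,
                    "peak_height": np.round(height[keep], 4),
                }
            )
        )
    peaks = pd.concat(frames, ignore_index=True)
    return peaks.sort_values(["sample_id", "probe"], kind="stable").reset_index(drop=True)


def _lognormal_unit_mean(rng, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=n))


# ---------------------------------------------------------------------------
# linked SNPs
# ---------------------------------------------------------------------------

def simulate_linked_snps(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Diploid 0/1/2 allele dosages from the haplotype pair in the truth table.

    The haplotype pair was drawn jointly with haploid C4A copies in
    :func:`simulate_cohort`, so the configured haplotype-copy-number
    association holds in the output by construction.
    """
    if config.haplotypes is None:
        raise ValueError("config has no haplotype table; SNPs cannot be simulated")
    pat = {h.pattern: np.array([int(c) for c in h.pattern]) for h in config.haplotypes}
    geno = np.array([pat[a] + pat[b] for a, b in zip(truth["hap1"], truth["hap2"])])
    out = pd.DataFrame(geno, columns=list(config.snp_names))
    out.insert(0, "sample_id", truth["sample_id"].to_numpy())
    return out


def demo_config(seed: int = 0, **overrides) -> SimConfig:
    """A moderate-size configuration for demos and smoke runs."""
    base = SimConfig(n_cases=600, n_controls=450, seed=seed,
                     omit_ex30_studies=("AUS",))
    return replace(base, **overrides) if overrides else base
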