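"""End-to-end orchestration: dosages -> calls -> association -> meta ->
haplotypes, plus the cohort summary table and a consolidated text report.

Every stage reads and writes tab-separated text with fixed column orders;
a run log records per-stage input/output row counts so sample attrition is
auditable.  A second run with the same config and inputs is reproducible
byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dosage import (impute_total_c4, normalize_dosages, read_peak_table,
                     total_vs_mean_correlation)
from .calling import (CallingConfig, LOCI, call_integer_cn,
                      cn_distribution_summary, dosage_bias_qc,
                      flag_homozygous_deletions)
from .association import (age_cn_correlation, loo_conditioning_sets,
                          run_model_grid)
from .haplotypes import (cn_conditioned_on_haplotype, em_haplotype_frequencies,
                         haplotype_association, haplotype_mean_cn)
from .meta import MetaResult, bonferroni_correct, forest_table, meta_grid, pool_random_effects

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "study", "n_cases", "n_ga", "n_nv", "n_mixed", "n_controls", "n_total",
    "age_cases_mean", "age_cases_sd", "age_controls_mean", "age_controls_sd",
    "pct_female_cases", "pct_female_controls",
)

KNOWN_SUBTYPES = {"GA", "NV", "GA+NV", "none"}


@dataclass
class PipelineConfig:
    peak_tables: list[str]
    phenotype_table: str
    genotype_table: str | None = None
    batch_key: str = "study"
    calling: CallingConfig = field(default_factory=CallingConfig)
    loci: tuple[str, ...] = LOCI
    covariates: tuple[str, ...] = ("age", "sex")
    strata_schemes: tuple[str, ...] = ("age3", "sex", "subtype")
    conditioning_snps: tuple[str, ...] = ()
    bonferroni_m: int = 3
    meta_method: str = "dl"
    output_dir: str = "c4cnv_out"
    seed: int = 0

    def validate(self) -> None:
        for p in [*self.peak_tables, self.phenotype_table] + (
            [self.genotype_table] if self.genotype_table else []
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni m must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "calling" in raw and isinstance(raw["calling"], dict):
            raw["calling"] = CallingConfig(**raw["calling"])
        for key in ("loci", "covariates", "strata_schemes", "conditioning_snps"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=False)


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-study and pooled cohort characteristics (a Table-1-style view).

    Counts per subtype, mean (sd) age and percent female by status.  The
    pooled row is computed from sample-level data directly; use
    :func:`pool_summary_rows` to combine pre-aggregated per-study rows.
    """
    unknown = set(cohort["subtype"]) - KNOWN_SUBTYPES
    if unknown:
        raise ValueError(f"unknown subtype labels: {sorted(unknown)}")
    rows = [
        _summary_row(label, g)
        for label, g in [*cohort.groupby("study"), ("pooled", cohort)]
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _summary_row(label: str, g: pd.DataFrame) -> dict:
    cases = g[g["status"] == "case"]
    controls = g[g["status"] == "control"]
    return {
        "study": label,
        "n_cases": len(cases),
        "n_ga": int((cases["subtype"] == "GA").sum()),
        "n_nv": int((cases["subtype"] == "NV").sum()),
        "n_mixed": int((cases["subtype"] == "GA+NV").sum()),
        "n_controls": len(controls),
        "n_total": len(g),
        "age_cases_mean": round(cases["age"].mean(), 2) if len(cases) else np.nan,
        "age_cases_sd": round(cases["age"].std(), 2) if len(cases) > 1 else np.nan,
        "age_controls_mean": round(controls["age"].mean(), 2) if len(controls) else np.nan,
        "age_controls_sd": round(controls["age"].std(), 2) if len(controls) > 1 else np.nan,
        "pct_female_cases": round(100 * (cases["sex"] == "female").mean(), 2)
        if len(cases) else np.nan,
        "pct_female_controls": round(100 * (controls["sex"] == "female").mean(), 2)
        if len(controls) else np.nan,
    }


def pool_summary_rows(per_study: pd.DataFrame) -> pd.DataFrame:
    """Combine per-study summary rows into one pooled row.

    Counts are summed; means are combined weighted by the relevant group
    size (case counts for case columns, control counts for control
    columns).  Standard deviations are not recombined (set to NaN): they
    require sample-level data.
    """
    df = per_study[per_study["study"] != "pooled"]
    nc, nk = df["n_cases"].to_numpy(float), df["n_controls"].to_numpy(float)
    row = {
        "study": "pooled",
        "n_cases": int(nc.sum()),
        "n_ga": int(df["n_ga"].sum()),
        "n_nv": int(df["n_nv"].sum()),
        "n_mixed": int(df["n_mixed"].sum()),
        "n_controls": int(nk.sum()),
        "n_total": int(df["n_total"].sum()),
        "age_cases_mean": round(float(np.average(df["age_cases_mean"], weights=nc)), 2),
        "age_cases_sd": np.nan,
        "age_controls_mean": round(float(np.average(df["age_controls_mean"], weights=nk)), 2),
        "age_controls_sd": np.nan,
        "pct_female_cases": round(float(np.average(df["pct_female_cases"], weights=nc)), 2),
        "pct_female_controls": round(float(np.average(df["pct_female_controls"], weights=nk)), 2),
    }
    return pd.DataFrame([row], columns=SUMMARY_COLUMNS)


def _write(df: pd.DataFrame, path: Path, logname: str, lines: list[str]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    lines.append(f"{logname}: wrote {len(df)} rows -> {path.name}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to the output dir.

    Returns the in-memory bundle (dosages, calls, QC, association grid,
    meta results, haplotype report, summary, report text).  Fatal errors in
    a stage abort with the stage name; per-model failures inside the grid
    are recorded, not raised.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    loglines = [f"c4cnv {__version__}", f"seed {config.seed}", "config:"]
    loglines += ["  " + l for l in config.to_yaml().splitlines()]
    bundle: dict = {}

    # --- dosages -----------------------------------------------------------
    peaks = pd.concat(
        [read_peak_table(p) for p in config.peak_tables], ignore_index=True
    )
    loglines.append(f"peaks: {len(peaks)} rows from {len(config.peak_tables)} table(s)")
    dosages = normalize_dosages(peaks, batch_key=config.batch_key)
    n_measured = int((dosages["total_source"] == "measured").sum())
    dosages = impute_total_c4(dosages)
    loglines.append(
        f"dosage: {len(dosages)} samples; total C4 measured for {n_measured}, "
        f"imputed for {int((dosages['total_source'] == 'imputed-from-mean').sum())}"
    )
    if n_measured >= 3:
        bundle["total_vs_mean"] = total_vs_mean_correlation(dosages)
        _write(bundle["total_vs_mean"], out / "total_vs_mean_correlation.tsv",
               "dosage QC", loglines)
    _write(dosages, out / "dosages.tsv", "dosage", loglines)
    bundle["dosages"] = dosages

    # --- cohort ------------------------------------------------------------
    cohort = pd.read_csv(config.phenotype_table, sep="\t")
    summary = cohort_summary(cohort)
    _write(summary, out / "cohort_summary.tsv", "summary", loglines)
    bundle["cohort"], bundle["summary"] = cohort, summary

    # --- calling -----------------------------------------------------------
    calls = pd.concat(
        [call_integer_cn(dosages, locus, config.calling) for locus in config.loci],
        ignore_index=True,
    )
    _write(calls, out / "copy_number_calls.tsv", "calling", loglines)
    worklist = flag_homozygous_deletions(calls)
    _write(worklist, out / "homozygous_deletion_worklist.tsv", "deletion worklist",
           loglines)
    qc = dosage_bias_qc(dosages, calls, cohort, config.calling)
    _write(qc, out / "dosage_bias_qc.tsv", "bias QC", loglines)
    dist = cn_distribution_summary(calls, cohort)
    _write(dist, out / "cn_distribution.tsv", "CN distribution", loglines)
    bundle.update(calls=calls, deletion_worklist=worklist, qc=qc, cn_distribution=dist)

    # --- association -------------------------------------------------------
    genotypes = None
    conditioning_sets: tuple[tuple[str, ...], ...] = ()
    if config.genotype_table:
        genotypes = read_genotype_table(config.genotype_table)
        snps = tuple(config.conditioning_snps) or tuple(
            c for c in genotypes.columns if c != "sample_id"
        )
        conditioning_sets = tuple(s for s in loo_conditioning_sets(snps) if s)
    else:
        loglines.append("genotypes: no table configured; conditional and "
                        "haplotype stages skipped")
    grid = run_model_grid(
        cohort, calls, genotypes, loci=config.loci, covariates=config.covariates,
        strata_schemes=config.strata_schemes, conditioning_sets=conditioning_sets,
    )
    _write(grid, out / "association_results.tsv", "association", loglines)
    n_fail = int((grid["error"] != "").sum())
    if n_fail:
        loglines.append(f"association: {n_fail} grid cell(s) failed (recorded)")
    agecorr = age_cn_correlation(cohort, calls)
    _write(agecorr, out / "age_cn_correlation.tsv", "age-CN correlation", loglines)
    bundle.update(association=grid, age_cn_correlation=agecorr)

    # --- meta-analysis -----------------------------------------------------
    per_study = grid[
        (grid["study"] != "pooled") & (grid["stratum"] == "all") & (grid["error"] == "")
    ].assign(locus=lambda d: d["model"].str.extract(r"cn\[(\w+)\]")[0])
    meta = meta_grid(per_study, group_cols=("locus",), bonferroni_m=config.bonferroni_m)
    _write(meta, out / "meta_results.tsv", "meta", loglines)
    bundle["meta"] = meta

    # --- haplotypes --------------------------------------------------------
    if genotypes is not None:
        haps = em_haplotype_frequencies(genotypes, seed=config.seed)
        haps = haplotype_mean_cn(haps, calls)
        hap_assoc = haplotype_association(haps, cohort)
        hap_rows = pd.DataFrame([r.to_row() for r in hap_assoc])
        cond_rows = []
        for lab in haps.table.loc[
            haps.table["frequency"] >= 0.01, "label"
        ]:
            try:
                res = cn_conditioned_on_haplotype(cohort, calls, haps, lab)
                cond_rows.append({**res.to_row(), "conditioned_on": lab, "error": ""})
            except Exception as exc:  # per-cell failure, recorded
                cond_rows.append({"conditioned_on": lab, "error": str(exc)})
        _write(haps.table, out / "haplotypes.tsv", "haplotypes", loglines)
        _write(hap_rows, out / "haplotype_association.tsv", "haplotype assoc", loglines)
        _write(pd.DataFrame(cond_rows), out / "cn_conditioned_on_haplotype.tsv",
               "conditioned CN", loglines)
        bundle.update(haplotypes=haps, haplotype_association=hap_rows,
                      cn_conditioned=pd.DataFrame(cond_rows))

    # --- report ------------------------------------------------------------
    report = render_report(bundle)
    (out / "report.txt").write_text(report)
    bundle["report"] = report
    (out / "run.log").write_text("\n".join(loglines) + "\n")
    return bundle


def read_genotype_table(path) -> pd.DataFrame:
    """SNP allele dosages: from a TSV dosage table or a biallelic VCF.

    The dosage table needs a ``sample_id`` column plus one 0/1/2 column per
    SNP.  A ``.vcf`` file is parsed from its GT fields (biallelic records
    only); the dosage counts the alternate allele.
    """
    path = Path(path)
    if path.suffix.lower() != ".vcf":
        df = pd.read_csv(path, sep="\t")
        if "sample_id" not in df.columns:
            raise ValueError(f"genotype table {path} lacks a sample_id column")
        return df
    samples: list[str] = []
    records: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            rsid, ref, alt = parts[2], parts[3], parts[4]
            if "," in alt:
                raise ValueError(f"multiallelic VCF record {rsid} not supported")
            gt_idx = parts[8].split(":").index("GT")
            doses = []
            for cell in parts[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    doses.append(np.nan)
                else:
                    doses.append(float(sum(int(a) for a in gt.split("/"))))
            records[rsid] = doses
    out = pd.DataFrame(records)
    out.insert(0, "sample_id", samples)
    return out


def render_report(bundle: dict) -> str:
    """Consolidated plain-text report with a forest table per locus."""
    sections = ["# C4 copy-number association report", ""]
    if "summary" in bundle:
        sections += ["## Cohort summary", bundle["summary"].to_string(index=False), ""]
    if "qc" in bundle:
        pooled = bundle["qc"][bundle["qc"]["study"] == "pooled"]
        sections += ["## Differential-bias QC (modal-class dosages, cases vs controls)",
                     pooled.to_string(index=False), ""]
    assoc = bundle.get("association")
    meta = bundle.get("meta")
    if assoc is not None and meta is not None:
        sections.append("## Meta-analysis (random effects)")
        per_study = assoc[
            (assoc["study"] != "pooled") & (assoc["stratum"] == "all")
            & (assoc["error"] == "")
        ].assign(locus=lambda d: d["model"].str.extract(r"cn\[(\w+)\]")[0])
        for locus, g in per_study.groupby("locus"):
            res = pool_random_effects(list(zip(g["beta"], g["se"])),
                                      labels=list(g["study"]))
            sections += [forest_table(res, title=f"### {locus} (OR per copy)"), ""]
        if "p_corrected" in meta.columns:
            sections.append("Bonferroni-corrected p across loci:")
            for _, r in meta.iterrows():
                sections.append(f"  {r['locus']}: p = {r['p']:.3g}, "
                                f"p_corrected = {r['p_corrected']:.3g}")
            sections.append("")
    if "haplotypes" in bundle:
        sections += ["## Haplotypes (frequency >= 1%)",
                     bundle["haplotypes"].report().to_string(index=False), ""]
        if "haplotype_association" in bundle and len(bundle["haplotype_association"]):
            sections += ["## Haplotype association",
                         bundle["haplotype_association"].to_string(index=False), ""]
    else:
        sections += ["## Haplotypes", "not run (no genotype table)", ""]
    if "age_cn_correlation" in bundle:
        sections += ["## Age vs copy number",
                     bundle["age_cn_correlation"].to_string(index=False), ""]
    return "\n".join(sections)
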