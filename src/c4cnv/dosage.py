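"""Peak-table ingestion and MLPA dosage normalization.

Raw capillary-electrophoresis peak heights are turned into unitless
normalized probe dosages in two steps, per sample ``i`` and test probe
``j`` (C4A, C4B, or C4-ex30 for total C4):

    r_ij = h_ij / (h_i,EP300 + h_i,CREBBP)        control-probe ratio
    d_ij = r_ij / median_i(r_ij)                  median scaling

The ratio cancels any per-sample multiplicative factor (run intensity,
batch scale); the median rescaling places the modal copy-number class near
dosage 1.  Medians are computed within a normalization batch (the study, by
default).  Where the total-C4 probe is missing, the total dosage can be
imputed as the mean of the two isotype dosages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ALL_PROBES, CONTROL_PROBES, TEST_PROBES

log = logging.getLogger(__name__)

PEAK_COLUMNS = ("sample_id", "study", "probe", "peak_height")

#: DosageMatrix column layout
DOSAGE_COLUMNS = ("sample_id", "study", "d_c4a", "d_c4b", "d_total", "total_source")


def read_peak_table(
    path,
    probe_map: dict[str, str] | None = None,
    sep: str | None = None,
    height_column: str = "peak_height",
) -> pd.DataFrame:
    """Read and validate a peak-height export.

    Expects columns ``sample_id``, ``study``, ``probe`` and a height column
    (``peak_height`` by default; pass ``height_column="peak_area"`` to read
    areas instead).  Nonstandard probe labels are renamed through
    ``probe_map``.  Samples missing either control probe are dropped and the
    exclusion logged.  Duplicate (sample, probe) rows are an error.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.empty:
        raise ValueError(f"peak table {path} is empty")
    if height_column != "peak_height":
        if height_column not in df.columns:
            raise ValueError(f"height column {height_column!r} not found in {path}")
        df = df.rename(columns={height_column: "peak_height"})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} lacks required columns: {missing}")
    if probe_map:
        df["probe"] = df["probe"].replace(probe_map)
    unknown = sorted(set(df["probe"]) - set(ALL_PROBES))
    if unknown:
        raise ValueError(
            f"unknown probe labels {unknown}; supply probe_map to rename them"
        )
    return validate_peak_table(df)


def validate_peak_table(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce PeakTable invariants on an in-memory frame."""
    dup = df.duplicated(subset=["sample_id", "probe"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["sample_id", "probe"]].drop_duplicates()
        raise ValueError(
            "duplicate (sample, probe) rows: "
            + "; ".join(f"{s}/{p}" for s, p in offenders.itertuples(index=False))
        )
    if (df["peak_height"] < 0).any():
        bad = df.loc[df["peak_height"] < 0, "sample_id"].unique()
        raise ValueError(f"negative peak heights for samples {list(bad)}")
    by_sample = df.groupby("sample_id")["probe"].apply(set)
    lacking = by_sample[~by_sample.apply(lambda s: set(CONTROL_PROBES) <= s)]
    if len(lacking):
        for sid in lacking.index:
            log.warning("sample %s dropped: missing control probe(s) %s",
                        sid, sorted(set(CONTROL_PROBES) - by_sample[sid]))
        df = df[~df["sample_id"].isin(lacking.index)]
    if df.empty:
        raise ValueError("no samples left after control-probe QC")
    return df.reset_index(drop=True)


def normalize_dosages(peaks: pd.DataFrame, batch_key: str = "study") -> pd.DataFrame:
    """PeakTable -> DosageMatrix via control-probe ratio and median scaling.

    ``batch_key`` names the column defining a normalization batch (medians
    are computed within it).  Samples whose control-peak sum is zero are
    excluded with a logged diagnostic.  A zero test peak yields dosage 0
    exactly.  Test probes absent for a sample yield missing dosages;
    ``total_source`` records whether d_total was measured from C4-ex30.
    """
    wide = peaks.pivot(index="sample_id", columns="probe", values="peak_height")
    meta = peaks.drop_duplicates("sample_id").set_index("sample_id")
    batches = meta[batch_key]
    ctrl_sum = wide[list(CONTROL_PROBES)].sum(axis=1)
    bad = ctrl_sum <= 0
    if bad.any():
        for sid in wide.index[bad]:
            log.warning("sample %s excluded: control peak sum is 0", sid)
        wide, ctrl_sum, batches = wide[~bad], ctrl_sum[~bad], batches[~bad]
    ratios = wide.reindex(columns=list(TEST_PROBES)).div(ctrl_sum, axis=0)
    dosages = ratios.copy()
    for _, idx in batches.groupby(batches).groups.items():
        sub = ratios.loc[idx]
        med = sub.median(axis=0, skipna=True)
        dosages.loc[idx] = sub / med
    out = pd.DataFrame(
        {
            "sample_id": dosages.index,
            "study": batches.reindex(dosages.index).to_numpy(),
            "d_c4a": dosages["C4A"].to_numpy(),
            "d_c4b": dosages["C4B"].to_numpy(),
            "d_total": dosages["C4-ex30"].to_numpy(),
        }
    )
    out["total_source"] = np.where(out["d_total"].notna(), "measured", "missing")
    return out.reset_index(drop=True)


def impute_total_c4(dosages: pd.DataFrame) -> pd.DataFrame:
    """Fill missing total-C4 dosages with the mean of the isotype dosages.

    Used where the C4-ex30 probe produced no product; validated by the
    strong correlation between the measured total dosage and the isotype
    mean in batches where both exist (see total_vs_mean_correlation).
    """
    out = dosages.copy()
    todo = out["d_total"].isna() & out["d_c4a"].notna() & out["d_c4b"].notna()
    out.loc[todo, "d_total"] = (out.loc[todo, "d_c4a"] + out.loc[todo, "d_c4b"]) / 2.0
    out.loc[todo, "total_source"] = "imputed-from-mean"
    still = out["d_total"].isna()
    for sid in out.loc[still, "sample_id"]:
        log.warning("sample %s: total C4 dosage not imputable (isotype dosage missing)", sid)
    return out


def total_vs_mean_correlation(dosages: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of measured d_total with (d_c4a + d_c4b) / 2.

    Returns one row per study plus a pooled row with columns
    ``study, r, p, n``; degenerate (constant) inputs are reported with
    ``r = NaN`` rather than raising.
    """
    meas = dosages[dosages["total_source"] == "measured"].dropna(
        subset=["d_c4a", "d_c4b", "d_total"]
    )
    if len(meas) < 3:
        raise ValueError(
            f"need >= 3 samples with measured total and both isotype dosages, got {len(meas)}"
        )
    rows = []
    groups = [("pooled", meas)] + [(s, g) for s, g in meas.groupby("study")]
    for label, g in groups:
        x = (g["d_c4a"] + g["d_c4b"]) / 2.0
        y = g["d_total"]
        if len(g) < 3 or np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
            rows.append({"study": label, "r": np.nan, "p": np.nan, "n": len(g)})
        else:
            r, p = stats.pearsonr(x, y)
            rows.append({"study": label, "r": float(r), "p": float(p), "n": len(g)})
    return pd.DataFrame(rows)
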