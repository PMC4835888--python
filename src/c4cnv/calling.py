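"""Integer copy-number calling from normalized dosages, plus calling QC.

Normalized dosages cluster around equispaced values k * s (k = integer copy
number, s = dosage per copy), with the modal copy-number class sitting near
dosage 1 after median scaling.  Calling proceeds per normalization batch:

1. sort the dosages and partition them into contiguous subgroups wherever
   the gap between neighbours exceeds a fraction of the expected spacing;
2. anchor the most populous subgroup to the configured modal integer
   (2 copies for C4A and C4B, 4 for total C4);
3. estimate the per-copy spacing from the subgroup centres and assign every
   sample to the nearest point of the anchored equispaced grid.

Step 3 makes the rule deterministic and monotone and handles copy-number
classes that are empty or merge under noise.  An equispaced-mean Gaussian
mixture is available as an alternative subgrouping engine
(``CallingConfig(method="mixture")``); both engines share the anchoring and
grid-assignment contract.

Zero dosage is an absent peak: the call is 0 copies and the sample is
flagged as a suspected homozygous deletion for confirmation (MLPA can
miscall these when a polymorphism disrupts probe ligation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LOCI = ("C4A", "C4B", "totalC4")

_DOSAGE_COL = {"C4A": "d_c4a", "C4B": "d_c4b", "totalC4": "d_total"}
_CN_RANGE = {"C4A": (0, 5), "C4B": (0, 4), "totalC4": (0, 9)}

FLAG_HOMDEL = "suspected_homozygous_deletion"
FLAG_LOWCONF = "low_confidence"
FLAG_IMPUTED = "imputed_total"


@dataclass
class CallingConfig:
    modal_anchor: dict[str, int] = field(
        default_factory=lambda: {"C4A": 2, "C4B": 2, "totalC4": 4}
    )
    gap_frac: float = 0.5          # split threshold, as a fraction of spacing
    min_batch: int = 30            # calling refused below this batch size
    flag_sigma: float = 1.5        # low_confidence when the boundary is closer
                                   # than this many robust noise SDs
    min_confidence: float = 0.05   # absolute confidence floor for flagging
    method: str = "gap"            # "gap" or "mixture"


def call_integer_cn(
    dosages: pd.DataFrame, locus: str, config: CallingConfig | None = None
) -> pd.DataFrame:
    """Call integer copy numbers for one locus, batch by batch.

    Returns a frame with columns ``sample_id, study, locus, cn, dosage,
    confidence, flags`` (flags are ';'-joined).  Confidence is the distance
    of the dosage from its assignment boundary, scaled to [0, 1] (1 at a
    grid centre, 0 on a boundary).
    """
    config = config or CallingConfig()
    if locus not in LOCI:
        raise ValueError(f"unknown locus {locus!r}; expected one of {LOCI}")
    col = _DOSAGE_COL[locus]
    frames = []
    for study, g in dosages.groupby("study", sort=False):
        g = g.dropna(subset=[col])
        if len(g) < config.min_batch:
            raise ValueError(
                f"batch {study!r} has {len(g)} samples with {locus} dosage; "
                f"calling requires >= {config.min_batch}"
            )
        frames.append(_call_batch(g, locus, col, config))
    out = pd.concat(frames, ignore_index=True)
    if locus == "totalC4" and "total_source" in dosages.columns:
        imputed = set(
            dosages.loc[dosages["total_source"] == "imputed-from-mean", "sample_id"]
        )
        mask = out["sample_id"].isin(imputed)
        out.loc[mask, "flags"] = out.loc[mask, "flags"].apply(
            lambda f: _add_flag(f, FLAG_IMPUTED)
        )
    return out


def _call_batch(g: pd.DataFrame, locus: str, col: str, config: CallingConfig) -> pd.DataFrame:
    d = g[col].to_numpy(float)
    modal = config.modal_anchor[locus]
    s0 = 1.0 / modal
    centers, sizes = _gap_partition(d, config.gap_frac * s0)
    if len(centers) == 1 and (d.max() - d.min()) > 1.5 * s0:
        # dense locus: copy classes too close for visible gaps -- fit the
        # equispaced grid directly and only give up if the residuals look
        # like an unclustered smear (flat residuals have MAD s/4)
        resid_mad, spacing = _fit_grid(d, s0, modal)
        if resid_mad > 0.2 * spacing:
            raise ValueError(
                f"no discernible subgroup structure for {locus} in batch "
                f"{g['study'].iat[0]!r}: dosages span {d.min():.2f}-{d.max():.2f} "
                "with no gaps and no periodic clustering; inspect measurement noise"
            )
        anchor_center = float(np.median(d))
    else:
        anchor_center = centers[int(np.argmax(sizes))]
        spacing = _estimate_spacing(centers, s0, anchor_center, modal)
    if config.method == "mixture":
        anchor_center, spacing = _refine_mixture(d, anchor_center, spacing, modal)
    x = (d - anchor_center) / spacing
    k = modal + np.ceil(x - 0.5).astype(int)  # half-way ties go to the lower integer
    k = np.where(d == 0.0, 0, np.maximum(k, 0))
    offset = np.where(d == 0.0, 0.0, x - (k - modal))
    confidence = np.clip(1.0 - 2.0 * np.abs(offset), 0.0, 1.0)
    # low-confidence rule is noise-adaptive: flag a call when the nearest
    # assignment boundary lies within flag_sigma robust SDs of the batch's
    # residual noise, so flagging grows with noise instead of miscalls
    resid = offset[d > 0] * spacing
    sigma_hat = 1.4826 * np.median(np.abs(resid)) if resid.size else 0.0
    boundary_dist = (0.5 - np.abs(offset)) * spacing
    low_conf = (boundary_dist < config.flag_sigma * sigma_hat) | (
        confidence < config.min_confidence
    )
    lo, hi = _CN_RANGE[locus]
    out_of_range = (k < lo) | (k > hi)
    k = np.clip(k, lo, hi)
    flags = []
    for ki, lc, oor in zip(k, low_conf, out_of_range):
        f = []
        if ki == 0:
            f.append(FLAG_HOMDEL)
        if lc or oor:
            f.append(FLAG_LOWCONF)
        flags.append(";".join(f))
    return pd.DataFrame(
        {
            "sample_id": g["sample_id"].to_numpy(),
            "study": g["study"].to_numpy(),
            "locus": locus,
            "cn": k,
            "dosage": d,
            "confidence": np.round(confidence, 4),
            "flags": flags,
        }
    )


def _gap_partition(d: np.ndarray, gap_threshold: float):
    """Centres (medians) and sizes of contiguous subgroups of sorted dosages."""
    srt = np.sort(d)
    cuts = np.flatnonzero(np.diff(srt) > gap_threshold) + 1
    groups = np.split(srt, cuts)
    centers = np.array([np.median(gr) for gr in groups])
    sizes = np.array([gr.size for gr in groups])
    return centers, sizes


def _fit_grid(d: np.ndarray, s0: float, modal: int):
    """Best equispaced grid through the batch median: scan the per-copy
    spacing around its nominal value and score by robust residual size."""
    med = np.median(d)
    best_mad, best_s = np.inf, s0
    for s in np.linspace(0.75 * s0, 1.25 * s0, 101):
        k = np.round((d - med) / s)
        resid = d - (med + k * s)
        mad = float(np.median(np.abs(resid)))
        if mad < best_mad:
            best_mad, best_s = mad, float(s)
    return best_mad, best_s


def _estimate_spacing(centers, s0: float, anchor_center: float, modal: int) -> float:
    """Per-copy spacing from subgroup centres; robust to empty copy classes."""
    if len(centers) < 2:
        # single subgroup: the anchored class determines the scale
        return anchor_center / modal if anchor_center > 0 else s0
    diffs = np.diff(np.sort(centers))
    steps = np.maximum(1, np.round(diffs / s0))
    return float(np.median(diffs / steps))


def _refine_mixture(d: np.ndarray, anchor_center: float, spacing: float, modal: int,
                    n_iter: int = 100):
    """EM for a 1-D Gaussian mixture with means constrained to an equispaced grid.

    The free parameters are the grid offset/scale (via the anchor centre and
    spacing), component weights, and one shared variance.  Used only as the
    alternative subgrouping engine.
    """
    kmax = max(modal, int(np.ceil(d.max() / spacing))) + 1
    ks = np.arange(0, kmax + 1)
    w = np.full(ks.size, 1.0 / ks.size)
    sigma = max(0.25 * spacing, 1e-3)
    a, s = anchor_center, spacing
    for _ in range(n_iter):
        mu = a + (ks - modal) * s
        resp = w * np.exp(-0.5 * ((d[:, None] - mu[None, :]) / sigma) ** 2)
        tot = resp.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        resp /= tot
        w = resp.mean(axis=0)
        # weighted LS for (a, s): mu_k = a + (k - modal) * s
        z = ks - modal
        n_k = resp.sum(axis=0)
        xbar = (resp * d[:, None]).sum(axis=0)
        sw, swz, swzz = n_k.sum(), (n_k * z).sum(), (n_k * z * z).sum()
        sx, sxz = xbar.sum(), (xbar * z).sum()
        det = sw * swzz - swz * swz
        if det > 1e-12:
            a = (sx * swzz - sxz * swz) / det
            s_new = (sw * sxz - swz * sx) / det
            if s_new > 1e-6:
                s = s_new
        mu = a + z * s
        var = (resp * (d[:, None] - mu[None, :]) ** 2).sum() / len(d)
        sigma = max(np.sqrt(var), 1e-4)
    return a, s


def flag_homozygous_deletions(calls: pd.DataFrame) -> pd.DataFrame:
    """Confirmation worklist: every zero-copy call with study and dosage."""
    zero = calls[calls["cn"] == 0]
    return zero[["sample_id", "study", "locus", "dosage"]].reset_index(drop=True)


def dosage_bias_qc(
    dosages: pd.DataFrame,
    calls: pd.DataFrame,
    cohort: pd.DataFrame,
    config: CallingConfig | None = None,
) -> pd.DataFrame:
    """Case/control differential-bias QC on raw unrounded dosages.

    Restricted to modal-class carriers (diploid for C4A/C4B, tetraploid for
    total C4), compares mean dosage between cases and controls with Welch's
    two-sample t-test, pooled and per study.  Systematic batch effects that
    survive normalization would surface here as a significant shift.
    """
    config = config or CallingConfig()
    status = cohort.set_index("sample_id")["status"]
    rows = []
    for locus in LOCI:
        modal = config.modal_anchor[locus]
        sub = calls[(calls["locus"] == locus) & (calls["cn"] == modal)].copy()
        sub["status"] = sub["sample_id"].map(status)
        groups = [("pooled", sub)] + [(s, g) for s, g in sub.groupby("study")]
        for label, g in groups:
            ca = g.loc[g["status"] == "case", "dosage"].to_numpy()
            co = g.loc[g["status"] == "control", "dosage"].to_numpy()
            row = {
                "locus": locus, "modal_cn": modal, "study": label,
                "n_cases": ca.size, "n_controls": co.size,
                "mean_cases": ca.mean() if ca.size else np.nan,
                "mean_controls": co.mean() if co.size else np.nan,
            }
            if ca.size >= 2 and co.size >= 2:
                t, p = stats.ttest_ind(ca, co, equal_var=False)
                row.update(difference=row["mean_cases"] - row["mean_controls"],
                           t_stat=float(t), p=float(p), testable=True)
            else:
                row.update(difference=np.nan, t_stat=np.nan, p=np.nan, testable=False)
            rows.append(row)
    return pd.DataFrame(rows)


def cn_distribution_summary(calls: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of each integer copy number.

    Split by locus, case/control status and study (plus pooled rows), for
    comparison against published copy-number distributions.
    """
    status = cohort.set_index("sample_id")["status"]
    df = calls.copy()
    df["status"] = df["sample_id"].map(status)
    rows = []
    for (locus, st), g in df.groupby(["locus", "status"]):
        for scope, gg in [("pooled", g)] + list(g.groupby("study")):
            counts = gg["cn"].value_counts().sort_index()
            for cn, n in counts.items():
                rows.append({"locus": locus, "status": st, "study": scope,
                             "cn": int(cn), "count": int(n),
                             "proportion": n / len(gg)})
    return pd.DataFrame(rows)


def _add_flag(flags: str, new: str) -> str:
    parts = [f for f in flags.split(";") if f]
    if new not in parts:
        parts.append(new)
    return ";".join(parts)
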