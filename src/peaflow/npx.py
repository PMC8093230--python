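"""Counts -> NPX normalization, QC flagging, LOD, bridging and platform comparison.

NPX (Normalized Protein eXpression) is a relative log2-scale quantification
derived from per-assay sequencing counts in three steps: division by the
sample's extension-control count, log2 transform, and a per-plate level
adjustment driven by the plate-control (plasma pool) wells.  This module
implements that chain together with the surrounding QC machinery:
incubation-control sample flagging, limit of detection from negative
controls, bridging-sample batch normalization, cross-platform median
normalization, concordance reports and sample-control precision (CV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: default deviation (log2 units) of the incubation control from the plate
#: median beyond which a sample is flagged.
QC_FLAG_THRESHOLD = 0.3

#: pseudocount substituted for zero assay counts before the log2 ratio.
PSEUDOCOUNT = 0.5

#: added to the negative-control median when their SD is zero.
LOD_ZERO_SD_OFFSET = 0.2

COUNT_COLUMNS = ["sample_id", "assay_id", "panel", "plate_id", "batch_id", "well_type", "count"]
CONTROL_COLUMNS = ["sample_id", "plate_id", "batch_id", "control", "count"]
NPX_COLUMNS = [
    "sample_id",
    "protein_id",
    "assay_id",
    "panel",
    "plate_id",
    "batch_id",
    "well_type",
    "npx",
    "qc_flag",
]

WELL_SAMPLE = "sample"
WELL_NEGATIVE = "negative_control"
WELL_PLATE = "plate_control"
WELL_SAMPLE_CONTROL = "sample_control"


@dataclass
class CountMatrix:
    """Raw matched counts per well x assay plus per-well internal controls.

    ``counts`` is long format with :data:`COUNT_COLUMNS`; ``controls`` holds
    one row per well per internal control (extension, incubation,
    amplification) with :data:`CONTROL_COLUMNS`.  A well is keyed by
    ``(sample_id, plate_id)`` so a bridging sample re-run in a second batch
    keeps its identity.
    """

    counts: pd.DataFrame
    controls: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COUNT_COLUMNS) - set(self.counts.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class NPXMatrix:
    """Long-format NPX values with QC flags, per-assay/plate LOD and provenance."""

    data: pd.DataFrame
    lod: pd.DataFrame | None = None
    provenance: str = "ngs"
    meta: dict = field(default_factory=dict)

    def study(self, qc_pass_only: bool = True) -> pd.DataFrame:
        """Study-sample rows (control-assay rows excluded), optionally QC-pass only."""
        d = self.data[self.data["well_type"] == WELL_SAMPLE]
        if "is_control_assay" in d.columns:
            d = d[~d["is_control_assay"].astype(bool)]
        if qc_pass_only:
            d = d[d["qc_flag"] == "pass"]
        return d

    def wide(self, qc_pass_only: bool = True) -> pd.DataFrame:
        """samples x proteins matrix of study-sample NPX."""
        return self.study(qc_pass_only).pivot_table(
            index="sample_id", columns="protein_id", values="npx"
        )


@dataclass
class ConcordanceReport:
    """Cross-platform agreement: per-protein and per-sample correlations."""

    per_protein: pd.DataFrame
    per_sample: pd.DataFrame
    median_protein_pearson: float
    median_protein_spearman: float
    median_sample_pearson: float
    frac_protein_pearson_above: float
    pearson_cut: float = 0.7


def counts_to_extnpx(
    cm: CountMatrix, pseudocount: float = PSEUDOCOUNT
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Step 1+2 of NPX generation: extension-control ratio, then log2.

    Returns the long table with an ``npx`` column holding
    ``log2(count / extension_count)`` (zero counts replaced by
    ``pseudocount``) and a table of wells excluded for a missing or
    non-positive extension-control count.
    """
    ext = cm.controls[cm.controls["control"] == "extension"][["sample_id", "plate_id", "count"]]
    ext = ext.rename(columns={"count": "ext_count"})
    d = cm.counts.merge(ext, on=["sample_id", "plate_id"], how="left")
    bad = ~np.isfinite(d["ext_count"]) | (d["ext_count"] <= 0)
    excluded = (
        d.loc[bad, ["sample_id", "plate_id"]]
        .drop_duplicates()
        .assign(reason="missing_or_zero_extension_control")
    )
    d = d.loc[~bad].copy()
    num = d["count"].to_numpy(dtype=float)
    num = np.where(num <= 0, pseudocount, num)
    d["npx"] = np.log2(num / d["ext_count"].to_numpy(dtype=float))
    return d.drop(columns=["count", "ext_count"]), excluded


def flag_samples(
    extnpx: pd.DataFrame,
    controls: pd.DataFrame,
    threshold: float = QC_FLAG_THRESHOLD,
) -> pd.DataFrame:
    """Incubation-control sample QC.

    The incubation control is put on the same scale as the assays
    (log2 of its count over the extension-control count); a well whose
    value deviates from the median of the study-sample wells on its plate
    by more than ``threshold`` is flagged.  Returns one row per well with
    ``qc_flag`` in {pass, flagged} and the deviation.
    """
    piv = controls.pivot_table(
        index=["sample_id", "plate_id"], columns="control", values="count"
    ).reset_index()
    if "incubation" not in piv.columns or "extension" not in piv.columns:
        raise ValueError("incubation and extension control counts are required for QC")
    piv["inc_value"] = np.log2(
        np.where(piv["incubation"] <= 0, PSEUDOCOUNT, piv["incubation"]) / piv["extension"]
    )
    well_types = extnpx[["sample_id", "plate_id", "well_type"]].drop_duplicates()
    piv = piv.merge(well_types, on=["sample_id", "plate_id"], how="left")
    study = piv[piv["well_type"] == WELL_SAMPLE]
    plate_median = study.groupby("plate_id")["inc_value"].median()
    piv["inc_deviation"] = piv["inc_value"] - piv["plate_id"].map(plate_median)
    piv["qc_flag"] = np.where(np.abs(piv["inc_deviation"]) > threshold, "flagged", "pass")
    piv.loc[piv["well_type"] != WELL_SAMPLE, "qc_flag"] = "pass"  # control wells exempt
    piv["qc_reason"] = np.where(
        piv["qc_flag"] == "flagged", "incubation_control_deviation", ""
    )
    return piv[["sample_id", "plate_id", "inc_value", "inc_deviation", "qc_flag", "qc_reason"]]


def adjust_plate_control(extnpx: pd.DataFrame) -> pd.DataFrame:
    """Step 3 of NPX generation: per-plate level adjustment.

    For each assay, subtracts the median extension-normalized value of the
    plate-control wells on the sample's plate and adds back the assay's
    anchor — the median over all plate-control wells across plates — so
    plates are aligned without shifting the overall level.  Plates without
    a plate-control well are left unadjusted and their wells flagged.
    """
    pc = extnpx[extnpx["well_type"] == WELL_PLATE]
    if pc.empty:
        raise ValueError("no plate-control wells present; cannot adjust plate levels")
    pc_median = pc.groupby(["plate_id", "assay_id"])["npx"].median()
    anchor = pc.groupby("assay_id")["npx"].median()
    d = extnpx.copy()
    key = pd.MultiIndex.from_frame(d[["plate_id", "assay_id"]])
    shift = pc_median.reindex(key).to_numpy() - anchor.reindex(d["assay_id"]).to_numpy()
    no_control = ~np.isfinite(shift)
    d["npx"] = d["npx"] - np.where(no_control, 0.0, shift)
    d["plate_adjusted"] = ~no_control
    return d


def compute_lod(
    npx: pd.DataFrame, zero_sd_offset: float = LOD_ZERO_SD_OFFSET
) -> pd.DataFrame:
    """Limit of detection per assay per plate from negative-control wells.

    LOD = median + 3 * sample SD of the negative-control NPX; when the SD
    is zero (or a single negative control is present) a fixed offset of
    ``zero_sd_offset`` log2 units is used instead of the 3-SD term.
    """
    neg = npx[npx["well_type"] == WELL_NEGATIVE]
    if neg.empty:
        return pd.DataFrame(columns=["assay_id", "plate_id", "lod", "n_negative"])
    g = neg.groupby(["assay_id", "plate_id"])["npx"]
    out = g.agg(median="median", sd=lambda v: v.std(ddof=1), n_negative="size").reset_index()
    sd = out["sd"].fillna(0.0)
    out["lod"] = np.where(sd > 0, out["median"] + 3 * sd, out["median"] + zero_sd_offset)
    return out[["assay_id", "plate_id", "lod", "n_negative"]]


def counts_to_npx(
    cm: CountMatrix,
    design: pd.DataFrame | None = None,
    flag_threshold: float = QC_FLAG_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
) -> NPXMatrix:
    """Full counts -> NPX chain: extension ratio, QC flag, plate adjustment, LOD.

    ``design`` optionally maps assay_id to protein_id / is_control_assay
    (panel design); without it the assay id doubles as the protein id.
    Flagging happens before plate adjustment, but the adjustment itself is
    driven by plate-control wells only, so flagged study samples never
    influence other samples' values.  Values below the assay/plate LOD are
    annotated, never removed.
    """
    extnpx, excluded = counts_to_extnpx(cm, pseudocount=pseudocount)
    qc = flag_samples(extnpx, cm.controls, threshold=flag_threshold)
    adjusted = adjust_plate_control(extnpx)
    lod = compute_lod(adjusted)

    d = adjusted.merge(
        qc[["sample_id", "plate_id", "qc_flag", "qc_reason", "inc_deviation"]],
        on=["sample_id", "plate_id"],
        how="left",
    )
    d["qc_flag"] = d["qc_flag"].fillna("pass")
    d.loc[~d["plate_adjusted"], "qc_flag"] = "flagged"
    d.loc[~d["plate_adjusted"], "qc_reason"] = "no_plate_control_on_plate"
    if not excluded.empty:
        # excluded wells are retained in the QC table via meta, not in data
        pass
    if design is not None:
        d = d.merge(
            design[["assay_id", "protein_id", "is_control_assay"]], on="assay_id", how="left"
        )
        d["protein_id"] = d["protein_id"].fillna(d["assay_id"])
        d["is_control_assay"] = d["is_control_assay"].fillna(False)
    else:
        d["protein_id"] = d["assay_id"]
        d["is_control_assay"] = False
    d = d.merge(lod[["assay_id", "plate_id", "lod"]], on=["assay_id", "plate_id"], how="left")
    d["below_lod"] = d["npx"] < d["lod"]
    return NPXMatrix(
        data=d,
        lod=lod,
        provenance="ngs",
        meta={
            "pseudocount": pseudocount,
            "flag_threshold": flag_threshold,
            "excluded_wells": excluded.to_dict("records"),
        },
    )


def bridge_normalize(
    batch_a: NPXMatrix, batch_b: NPXMatrix, bridge_ids
) -> NPXMatrix:
    """Adjust batch B onto batch A's level using bridging samples.

    Per assay, the median of the paired differences (B - A) over the
    bridging samples — samples physically re-run in both batches — is
    subtracted from every batch-B value.  Requires at least two bridges.
    """
    bridge_ids = list(bridge_ids)
    a = batch_a.data[batch_a.data["sample_id"].isin(bridge_ids)]
    b = batch_b.data[batch_b.data["sample_id"].isin(bridge_ids)]
    paired = b.merge(
        a[["sample_id", "assay_id", "npx"]],
        on=["sample_id", "assay_id"],
        suffixes=("_b", "_a"),
    )
    n_bridges = paired["sample_id"].nunique()
    if n_bridges < 2:
        raise ValueError(
            f"bridge normalization needs >=2 bridging samples in both batches, got {n_bridges}"
        )
    shift = (
        paired.assign(diff=paired["npx_b"] - paired["npx_a"])
        .groupby("assay_id")["diff"]
        .median()
    )
    d = batch_b.data.copy()
    d["npx"] = d["npx"] - d["assay_id"].map(shift).fillna(0.0)
    meta = dict(batch_b.meta)
    meta["bridge_shift_median"] = float(shift.median())
    meta["n_bridges"] = int(n_bridges)
    return replace(batch_b, data=d, meta=meta)


def cross_platform_normalize(
    ngs: NPXMatrix, qpcr: NPXMatrix
) -> tuple[NPXMatrix, NPXMatrix]:
    """Median intensity normalization between two platform read-outs.

    Per protein: compute each platform's median over the shared QC-pass
    samples and the pooled median over both; the normalized value is the
    NPX value minus the platform median plus the pooled median.  After
    adjustment the two platform medians agree for every protein while all
    within-platform differences between samples are untouched.
    """
    a = ngs.study()
    b = qpcr.study()
    shared = np.intersect1d(a["sample_id"].unique(), b["sample_id"].unique())
    if shared.size == 0:
        raise ValueError("no shared samples between the two platforms")
    med_a = a[a["sample_id"].isin(shared)].groupby("protein_id")["npx"].median()
    med_b = b[b["sample_id"].isin(shared)].groupby("protein_id")["npx"].median()
    pooled = (
        pd.concat([a[a["sample_id"].isin(shared)], b[b["sample_id"].isin(shared)]])
        .groupby("protein_id")["npx"]
        .median()
    )
    da = ngs.data.copy()
    db = qpcr.data.copy()
    da["npx"] = da["npx"] - da["protein_id"].map(med_a).fillna(0.0) + da["protein_id"].map(
        pooled
    ).fillna(0.0)
    db["npx"] = db["npx"] - db["protein_id"].map(med_b).fillna(0.0) + db["protein_id"].map(
        pooled
    ).fillna(0.0)
    return replace(ngs, data=da), replace(qpcr, data=db)


def platform_concordance(
    a: NPXMatrix, b: NPXMatrix, pearson_cut: float = 0.7, min_n: int = 3
) -> ConcordanceReport:
    """Per-protein and per-sample correlations between two platforms.

    Computed over QC-pass samples present on both platforms.  Also reports
    the fraction of proteins with Pearson r above ``pearson_cut``.
    """
    wa = a.wide()
    wb = b.wide()
    samples = wa.index.intersection(wb.index)
    proteins = wa.columns.intersection(wb.columns)
    wa = wa.loc[samples, proteins]
    wb = wb.loc[samples, proteins]
    if len(samples) < min_n or len(proteins) == 0:
        raise ValueError("too few shared samples/proteins for a concordance report")

    per_protein = pd.DataFrame(
        {
            "pearson": wa.corrwith(wb, axis=0, method="pearson"),
            "spearman": wa.corrwith(wb, axis=0, method="spearman"),
            "n": wa.notna().sum(axis=0),
        }
    ).rename_axis("protein_id")
    per_sample = pd.DataFrame(
        {
            "pearson": wa.corrwith(wb, axis=1, method="pearson"),
            "n": wa.notna().sum(axis=1),
        }
    ).rename_axis("sample_id")
    return ConcordanceReport(
        per_protein=per_protein.reset_index(),
        per_sample=per_sample.reset_index(),
        median_protein_pearson=float(per_protein["pearson"].median()),
        median_protein_spearman=float(per_protein["spearman"].median()),
        median_sample_pearson=float(per_sample["pearson"].median()),
        frac_protein_pearson_above=float((per_protein["pearson"] > pearson_cut).mean()),
        pearson_cut=pearson_cut,
    )


def assay_precision(npx: NPXMatrix, linearize: bool = True) -> pd.DataFrame:
    """Intra- and inter-plate CV per assay from the sample-control wells.

    Sample controls are reference-plasma replicates on every plate.  Values
    are linearized (2**NPX) before computing CV = SD/mean.  Intra-plate CV
    is the CV across replicates within a plate, averaged over plates with
    at least two replicates; inter-plate CV is the CV across plate means.
    """
    sc = npx.data[npx.data["well_type"] == WELL_SAMPLE_CONTROL].copy()
    if sc.empty:
        raise ValueError("no sample-control wells present")
    sc["value"] = np.exp2(sc["npx"]) if linearize else sc["npx"]

    def _cv(v: pd.Series) -> float:
        m = v.mean()
        return float(v.std(ddof=1) / m) if len(v) >= 2 and m > 0 else np.nan

    intra = (
        sc.groupby(["assay_id", "plate_id"])["value"]
        .apply(_cv)
        .groupby("assay_id")
        .mean()
        .rename("intra_cv")
    )
    plate_means = sc.groupby(["assay_id", "plate_id"])["value"].mean()
    inter = plate_means.groupby("assay_id").apply(_cv).rename("inter_cv")
    n_plates = sc.groupby("assay_id")["plate_id"].nunique().rename("n_plates")
    return pd.concat([intra, inter, n_plates], axis=1).reset_index()
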