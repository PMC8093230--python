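"""Readers and writers for the pipeline's on-disk formats.

Tab-delimited long tables are the canonical interchange (missing values
written as ``NA``), genotypes travel as uncompressed VCF, configuration as
flat-key YAML, and the simulation ground truth plus a per-run provenance
block as JSON.  Every writer produces files its reader accepts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genetics import GenotypeMatrix
from .npx import CountMatrix, NPXMatrix
from .simulate import Cohort, SimConfig, SimTruth

log = logging.getLogger("peaflow")

NA = "NA"

NPX_REQUIRED = ["sample_id", "protein_id", "plate_id", "batch_id", "npx", "qc_flag"]
QC_FLAG_VALUES = {"pass", "flagged"}


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


# --- NPX long format ------------------------------------------------------

def write_npx(npx: NPXMatrix, path) -> None:
    """Write an NPX matrix as the canonical long table.

    Columns: sample_id, protein_id, assay_id, panel, plate_id, batch_id,
    well_type, npx, lod, qc_flag (plus below_lod when available).
    """
    d = npx.data.copy()
    for col in ("assay_id", "panel", "well_type"):
        if col not in d.columns:
            d[col] = NA if col != "panel" else 0
    if "lod" not in d.columns:
        d["lod"] = np.nan
    cols = [
        "sample_id",
        "protein_id",
        "assay_id",
        "panel",
        "plate_id",
        "batch_id",
        "well_type",
        "npx",
        "lod",
        "qc_flag",
    ]
    extra = [c for c in ("is_control_assay", "below_lod") if c in d.columns]
    _write_tsv(d[cols + extra], path)


def read_npx(path, provenance: str = "ngs") -> NPXMatrix:
    """Read the canonical NPX long table, validating its contract.

    Rejects missing required columns, non-numeric NPX values, unknown QC
    flags and duplicated (sample, protein, plate) rows — naming the
    offending keys.  An empty file with a valid header yields an empty
    matrix.
    """
    d = _read_tsv(path)
    missing = [c for c in NPX_REQUIRED if c not in d.columns]
    if missing:
        raise ValueError(f"NPX table {path} is missing required columns: {missing}")
    if len(d):
        npx_num = pd.to_numeric(d["npx"], errors="coerce")
        bad = npx_num.isna() & d["npx"].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric NPX values in {path} at rows {d.index[bad].tolist()[:5]}"
            )
        d["npx"] = npx_num
        unknown = set(d["qc_flag"].dropna().unique()) - QC_FLAG_VALUES
        if unknown:
            raise ValueError(f"unknown qc_flag values in {path}: {sorted(unknown)}")
        # the measurement key is the assay (control-assay proteins are
        # measured once per panel); fall back to protein when no assay column
        key = ["sample_id", "assay_id" if "assay_id" in d.columns else "protein_id", "plate_id"]
        dup = d.duplicated(key, keep=False)
        if dup.any():
            keys = d.loc[dup, key].drop_duplicates().head(5).to_records(index=False).tolist()
            raise ValueError(f"duplicated (sample, assay, plate) rows in {path}: {keys}")
    if "is_control_assay" in d.columns and len(d):
        d["is_control_assay"] = d["is_control_assay"].astype(bool)
    lod = None
    if "lod" in d.columns and len(d) and d["lod"].notna().any():
        lod = d[["assay_id", "plate_id", "lod"]].dropna().drop_duplicates()
    return NPXMatrix(data=d, lod=lod, provenance=provenance)


# --- count matrix ---------------------------------------------------------

def write_counts(cm: CountMatrix, outdir) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path = outdir / "counts.tsv"
    controls_path = outdir / "control_counts.tsv"
    _write_tsv(cm.counts, counts_path)
    _write_tsv(cm.controls, controls_path)
    return counts_path, controls_path


def read_counts(outdir) -> CountMatrix:
    outdir = Path(outdir)
    return CountMatrix(
        counts=_read_tsv(outdir / "counts.tsv"),
        controls=_read_tsv(outdir / "control_counts.tsv"),
    )


# --- cohort ---------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(cohort.subjects, outdir / "subjects.tsv")
    _write_tsv(cohort.visits, outdir / "visits.tsv")
    _write_tsv(cohort.samples, outdir / "samples.tsv")


def read_cohort(outdir) -> Cohort:
    outdir = Path(outdir)
    return Cohort(
        subjects=_read_tsv(outdir / "subjects.tsv"),
        visits=_read_tsv(outdir / "visits.tsv"),
    )


# --- VCF genotypes --------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write biallelic genotypes as an uncompressed VCF with GT calls."""
    path = Path(path)
    subjects = list(G.genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(subjects) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for vid in G.genotypes.columns:
            meta = G.variants.loc[vid]
            calls = [
                gt_map.get(g, "./.") if np.isfinite(g) else "./."
                for g in G.genotypes[vid].to_numpy(dtype=float)
            ]
            fh.write(
                f"{meta['chrom']}\t{int(meta['pos'])}\t{vid}\t{meta['ref']}\t{meta['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Read a VCF into additive allele counts via cyvcf2.

    Biallelic SNVs only; multiallelic records are skipped with a logged
    count; ``./.`` calls become NaN.  Phasing is ignored (``0|1`` counts
    as one alternate allele).
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    subjects = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    skipped_multiallelic = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            skipped_multiallelic += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = rec.gt_types.astype(float)
        counts = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        cols[vid] = counts
        maf = np.nanmean(counts) / 2.0 if np.isfinite(counts).any() else np.nan
        meta_rows.append(
            {
                "variant_id": vid,
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "maf": min(maf, 1 - maf) if np.isfinite(maf) else np.nan,
            }
        )
    if skipped_multiallelic:
        log.info("skipped %d multiallelic records in %s", skipped_multiallelic, path)
    genotypes = pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id"))
    variants = pd.DataFrame(meta_rows).set_index("variant_id") if meta_rows else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "maf"]
    )
    G = GenotypeMatrix(genotypes=genotypes, variants=variants)
    G.skipped_multiallelic = skipped_multiallelic  # type: ignore[attr-defined]
    return G


# --- TSS annotation -------------------------------------------------------

def write_tss(tss: pd.DataFrame, path) -> None:
    _write_tsv(tss.reset_index(), path)


def read_tss(path) -> pd.DataFrame:
    d = _read_tsv(path)
    for col in ("protein_id", "chrom", "tss"):
        if col not in d.columns:
            raise ValueError(f"TSS annotation {path} missing column {col!r}")
    return d.set_index("protein_id")


# --- simulation truth sidecar --------------------------------------------

def write_truth(truth: SimTruth, outdir) -> None:
    """Ground truth as a TSV (abundances) plus a JSON sidecar (parameters)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ab = truth.log_abundance.reset_index()
    _write_tsv(ab, outdir / "truth_abundance.tsv")
    sidecar = {
        "protein_means": truth.protein_means.to_dict(),
        "sex_effects": truth.sex_effects.to_dict(),
        "disease_effects": truth.disease_effects.to_dict(),
        "causal_map": {p: [list(t) for t in v] for p, v in truth.causal_map.items()},
        "responder_labels": truth.responder_labels.to_dict(),
        "responder_effects": truth.responder_effects.to_dict(),
        "plate_offsets": truth.plate_offsets.to_dict() if truth.plate_offsets is not None else None,
        "batch_offsets": truth.batch_offsets.to_dict() if truth.batch_offsets is not None else None,
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


# --- configuration & provenance ------------------------------------------

def load_sim_config(path=None, **overrides) -> SimConfig:
    """Build a SimConfig from a flat-key YAML file; kwargs override the file."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping of flat keys")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("maf_range", "responder_fractions", "age_range"):
        if key in values and isinstance(values[key], list):
            values[key] = tuple(values[key])
    return SimConfig(**values)


def write_provenance(outdir, config, seed, thresholds: dict | None = None) -> Path:
    """Echo the effective configuration, seed and version next to outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block = {
        "version": __version__,
        "seed": seed,
        "config": asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config or {}),
        "thresholds": thresholds or {},
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(block, indent=1, sort_keys=True, default=str))
    return path
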