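"""Genotype quality control and protein quantitative trait locus (pQTL) mapping.

Implements the GWAS side of the pipeline: the four-step genotype QC
(subject missingness, variant call rate, minor allele frequency,
Hardy-Weinberg equilibrium), the baseline phenotype (per-subject median
NPX across visits), covariate-adjusted linear-regression scans, the
1 Mb cis/trans classification, LD computed as squared Pearson
correlation of allele counts, and the greedy sentinel / conditional
analysis used to declare independent pQTLs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: cis window: a variant within this many bases of the gene TSS (inclusive,
#: same chromosome) is labelled cis.
CIS_WINDOW = 1_000_000

#: LD pruning threshold on r^2 against the sentinel variant.
LD_R2_THRESHOLD = 0.1

#: conditional p-value below which a non-sentinel signal is kept as independent.
CONDITIONAL_ALPHA = 0.01

#: genome-wide significance level before the per-protein Bonferroni division.
GENOME_WIDE_ALPHA = 5e-8

# default genotype QC thresholds
MAX_SUBJECT_MISSING = 0.05
MAX_VARIANT_MISSING = 0.05
MIN_MAF = 0.05
HWE_ALPHA = 0.001


@dataclass
class GenotypeMatrix:
    """Additive allele counts for a set of subjects and biallelic variants.

    Attributes
    ----------
    genotypes:
        subjects x variants DataFrame of allele counts in {0, 1, 2} with
        NaN for missing calls.
    variants:
        per-variant metadata indexed by variant id with columns
        ``chrom``, ``pos`` (1-based), ``ref``, ``alt`` and ``maf``.
    tss:
        optional protein -> gene annotation, indexed by protein id with
        columns ``chrom`` and ``tss``; required for cis/trans labelling.
    """

    genotypes: pd.DataFrame
    variants: pd.DataFrame
    tss: pd.DataFrame | None = None

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def maf(self) -> pd.Series:
        """Minor allele frequency recomputed from the current calls."""
        g = self.genotypes.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(g, axis=0) / 2.0
        return pd.Series(np.minimum(p, 1 - p), index=self.genotypes.columns, name="maf")


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Hardy-Weinberg equilibrium goodness-of-fit p-value.

    One-degree-of-freedom chi-square test of the observed genotype counts
    against the expectation at the observed allele frequency.  A
    monomorphic variant fits HWE perfectly and returns p = 1.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n <= 0:
        raise ValueError("HWE test requires at least one genotyped subject")
    p = (2 * n_hom_ref + n_het) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(g: np.ndarray) -> np.ndarray:
    """Vectorised HWE p-values for a subjects x variants array (NaN = missing)."""
    n_aa = np.nansum(g == 0, axis=0).astype(float)
    n_ab = np.nansum(g == 1, axis=0).astype(float)
    n_bb = np.nansum(g == 2, axis=0).astype(float)
    n = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_aa + n_ab) / (2 * n)
        e_aa = n * p * p
        e_ab = 2 * n * p * (1 - p)
        e_bb = n * (1 - p) ** 2
        chi2 = (
            (n_aa - e_aa) ** 2 / e_aa
            + (n_ab - e_ab) ** 2 / e_ab
            + (n_bb - e_bb) ** 2 / e_bb
        )
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.where(np.isnan(chi2), 1.0, pvals)  # monomorphic: perfect fit
    return np.where(n > 0, pvals, np.nan)


def genotype_qc(
    G: GenotypeMatrix,
    max_subject_missing: float = MAX_SUBJECT_MISSING,
    max_variant_missing: float = MAX_VARIANT_MISSING,
    min_maf: float = MIN_MAF,
    hwe_alpha: float = HWE_ALPHA,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the four genotype QC filters in order and report removals.

    Order: (1) subjects with missing rate > ``max_subject_missing``;
    (2) variants with missing rate > ``max_variant_missing``;
    (3) variants with MAF < ``min_maf`` (recomputed after the first two
    steps); (4) variants failing HWE at ``hwe_alpha``.  Statistics are
    recomputed after each step.  Raises if nothing survives.
    """
    geno = G.genotypes
    ledger: dict[str, int] = {}

    miss_subj = geno.isna().mean(axis=1)
    keep_subj = miss_subj <= max_subject_missing
    ledger["subjects_removed_missing"] = int((~keep_subj).sum())
    geno = geno.loc[keep_subj]

    miss_var = geno.isna().mean(axis=0)
    keep_var = miss_var <= max_variant_missing
    ledger["variants_removed_call_rate"] = int((~keep_var).sum())
    geno = geno.loc[:, keep_var]

    g = geno.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep_maf = maf >= min_maf
    ledger["variants_removed_maf"] = int((~keep_maf).sum())
    geno = geno.loc[:, keep_maf]

    hwe_p = _hwe_pvalues(geno.to_numpy(dtype=float))
    keep_hwe = ~(hwe_p < hwe_alpha)
    ledger["variants_removed_hwe"] = int((~keep_hwe).sum())
    geno = geno.loc[:, keep_hwe]

    if geno.shape[0] == 0 or geno.shape[1] == 0:
        raise ValueError(f"no data survived genotype QC (removals: {ledger})")

    variants = G.variants.loc[geno.columns].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p2 = np.nanmean(geno.to_numpy(dtype=float), axis=0) / 2.0
    variants["maf"] = np.minimum(p2, 1 - p2)
    return GenotypeMatrix(genotypes=geno, variants=variants, tss=G.tss), ledger


def baseline_phenotype(npx_data: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-subject baseline protein levels: median NPX across QC-pass visits.

    Parameters
    ----------
    npx_data:
        long-format NPX table with at least ``sample_id``, ``protein_id``,
        ``npx`` and ``qc_flag`` columns (study-sample rows).
    samples:
        sample annotation with ``sample_id``, ``subject_id`` and ``visit``.

    Returns a subjects x proteins DataFrame; a subject whose visits are all
    flagged for a protein is left missing there.
    """
    d = npx_data.merge(samples[["sample_id", "subject_id"]], on="sample_id")
    d = d[d["qc_flag"] == "pass"]
    return d.pivot_table(index="subject_id", columns="protein_id", values="npx", aggfunc="median")


def classify_cis_trans(
    variant_chrom: str, variant_pos: int, gene_chrom: str, tss_pos: int, window: int = CIS_WINDOW
) -> str:
    """Label a variant cis or trans for a protein's gene.

    cis when on the same chromosome and within ``window`` bases of the TSS
    (boundary inclusive); trans otherwise, including any cross-chromosome
    pair.
    """
    if str(variant_chrom) != str(gene_chrom):
        return "trans"
    return "cis" if abs(int(variant_pos) - int(tss_pos)) <= window else "trans"


def ld_r2(g1, g2) -> float:
    """LD between two variants: squared Pearson correlation of allele counts.

    Computed over pairwise-complete observations; NaN when either vector is
    constant.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _ols_genotype_t(y: np.ndarray, g: np.ndarray, covars: np.ndarray):
    """OLS of y on [1, covars, g]; returns (beta, se, p) for the g column.

    Complete-case over rows with finite y and g.  Returns NaNs when the
    genotype is constant or the system is rank deficient.
    """
    ok = np.isfinite(y) & np.isfinite(g)
    if covars.size:
        ok &= np.all(np.isfinite(covars), axis=1)
    y, g = y[ok], g[ok]
    C = covars[ok] if covars.size else np.empty((ok.sum(), 0))
    n = y.size
    if n < C.shape[1] + 3 or np.ptp(g) == 0:
        return np.nan, np.nan, np.nan
    X = np.column_stack([np.ones(n), C, g])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return np.nan, np.nan, np.nan
    resid = y - X @ coef
    dof = n - X.shape[1]
    s2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[-1, -1]))
    beta = float(coef[-1])
    p = 2 * stats.t.sf(abs(beta) / se, dof) if se > 0 else np.nan
    return beta, se, float(p)


def pqtl_scan(
    baseline: pd.DataFrame,
    G: GenotypeMatrix,
    covariates: pd.DataFrame,
    alpha: float = GENOME_WIDE_ALPHA,
    bonferroni_divisor: int | None = None,
) -> pd.DataFrame:
    """Protein x variant association scan adjusted for the given covariates.

    For each protein and variant fits ordinary least squares of the baseline
    phenotype on allele count plus covariates (age and sex in the standard
    design) and reports the two-sided t-test on the genotype coefficient.
    Effect sizes are in NPX units per alternate allele.

    The significance threshold is ``alpha`` divided by
    ``bonferroni_divisor`` (defaults to the number of proteins scanned);
    the threshold is exposed in the result attrs and rows carry a
    ``significant`` flag.  Variants with a constant genotype among a
    protein's complete cases are skipped for that protein.
    """
    subjects = baseline.index.intersection(G.genotypes.index).intersection(covariates.index)
    if len(subjects) == 0:
        raise ValueError("no shared subjects between phenotype, genotypes and covariates")
    Y = baseline.loc[subjects].to_numpy(dtype=float)
    geno = G.genotypes.loc[subjects].to_numpy(dtype=float)
    C = covariates.loc[subjects].to_numpy(dtype=float)
    n, n_prot = Y.shape
    n_var = geno.shape[1]
    divisor = bonferroni_divisor if bonferroni_divisor is not None else n_prot
    threshold = alpha / max(divisor, 1)

    # Frisch-Waugh-Lovell fast path for rows complete in every input.
    complete = np.all(np.isfinite(C), axis=1)
    rows = []
    var_index = G.variants.loc[G.genotypes.columns]
    chroms = var_index["chrom"].to_numpy()
    poss = var_index["pos"].to_numpy()
    var_ids = np.asarray(G.genotypes.columns)
    p_cov = C.shape[1] + 2  # intercept + covariates + genotype

    for j in range(n_prot):
        y = Y[:, j]
        ok = complete & np.isfinite(y)
        fast = ok & np.all(np.isfinite(geno), axis=1) if n_var else ok
        use_fast = fast.sum() == ok.sum() and ok.sum() >= p_cov + 1
        if use_fast:
            yy = y[ok]
            X0 = np.column_stack([np.ones(ok.sum()), C[ok]])
            Q, _ = np.linalg.qr(X0)
            ry = yy - Q @ (Q.T @ yy)
            RG = geno[ok] - Q @ (Q.T @ geno[ok])
            den = (RG * RG).sum(axis=0)
            const = den <= 1e-12
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = RG.T @ ry / den
                rss = ry @ ry - beta**2 * den
                dof = ok.sum() - p_cov
                s2 = rss / dof
                se = np.sqrt(s2 / den)
                tval = beta / se
            pval = 2 * stats.t.sf(np.abs(tval), dof)
            beta[const] = np.nan
            se[const] = np.nan
            pval[const] = np.nan
        else:
            beta = np.empty(n_var)
            se = np.empty(n_var)
            pval = np.empty(n_var)
            for k in range(n_var):
                beta[k], se[k], pval[k] = _ols_genotype_t(y, geno[:, k], C)
        prot = baseline.columns[j]
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": prot,
                    "variant_id": var_ids,
                    "chrom": chroms,
                    "pos": poss,
                    "beta": beta,
                    "se": se,
                    "p_value": pval,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["skipped"] = ~np.isfinite(out["p_value"])
    out["significant"] = out["p_value"] < threshold

    if G.tss is not None:
        tss = G.tss
        labels = []
        for prot, chrom, pos in zip(out["protein_id"], out["chrom"], out["pos"]):
            if prot in tss.index:
                labels.append(
                    classify_cis_trans(chrom, pos, tss.loc[prot, "chrom"], tss.loc[prot, "tss"])
                )
            else:
                labels.append("trans")
        out["cis_trans"] = labels
    out.attrs["threshold"] = threshold
    out.attrs["n_subjects"] = int(n)
    return out


def select_independent(
    results: pd.DataFrame,
    G: GenotypeMatrix,
    baseline: pd.DataFrame,
    covariates: pd.DataFrame,
    r2_threshold: float = LD_R2_THRESHOLD,
    window: int = CIS_WINDOW,
    conditional_alpha: float = CONDITIONAL_ALPHA,
) -> pd.DataFrame:
    """Greedy sentinel selection with LD pruning and conditional analysis.

    Per protein, over the significant scan hits: take the variant with the
    lowest p-value as sentinel (ties broken by chromosome then position);
    drop candidates on the same chromosome within ``window`` bases whose
    r^2 with the sentinel exceeds ``r2_threshold``; refit the remaining
    candidates with all sentinels so far as additional covariates and keep
    those with conditional p < ``conditional_alpha``; repeat until the pool
    is empty.  Returns one row per independent pQTL with the conditional
    p-value recorded for sentinels found after the first.
    """
    sig = results[results.get("significant", False) & ~results.get("skipped", False)]
    out_rows = []
    subjects = baseline.index.intersection(G.genotypes.index).intersection(covariates.index)
    C_base = covariates.loc[subjects].to_numpy(dtype=float)
    geno = G.genotypes.loc[subjects]

    for prot, grp in sig.groupby("protein_id", sort=True):
        y = baseline.loc[subjects, prot].to_numpy(dtype=float)
        pool = grp.copy()
        pool["current_p"] = pool["p_value"]
        sentinels: list[str] = []
        order_n = 0
        while not pool.empty:
            pool = pool.sort_values(["current_p", "chrom", "pos"], kind="mergesort")
            sent = pool.iloc[0]
            order_n += 1
            rec = sent.drop(labels=["current_p"]).to_dict()
            rec["sentinel"] = True
            rec["sentinel_order"] = order_n
            rec["conditional_p"] = sent["current_p"] if sentinels else np.nan
            out_rows.append(rec)
            sentinels.append(sent["variant_id"])
            pool = pool.iloc[1:]
            if pool.empty:
                break
            g_sent = geno[sent["variant_id"]].to_numpy(dtype=float)
            keep = []
            for _, row in pool.iterrows():
                same_chrom = str(row["chrom"]) == str(sent["chrom"])
                in_window = same_chrom and abs(int(row["pos"]) - int(sent["pos"])) <= window
                if in_window:
                    r2 = ld_r2(geno[row["variant_id"]].to_numpy(dtype=float), g_sent)
                    if np.isfinite(r2) and r2 > r2_threshold:
                        continue
                keep.append(row.name)
            pool = pool.loc[keep]
            if pool.empty:
                break
            C_cond = np.column_stack(
                [C_base] + [geno[s].to_numpy(dtype=float) for s in sentinels]
            )
            cond_p = []
            for _, row in pool.iterrows():
                _, _, p = _ols_genotype_t(y, geno[row["variant_id"]].to_numpy(dtype=float), C_cond)
                cond_p.append(p)
            pool = pool.assign(current_p=cond_p)
            pool = pool[pool["current_p"] < conditional_alpha]
    cols = list(results.columns) + ["sentinel", "sentinel_order", "conditional_p"]
    if not out_rows:
        return pd.DataFrame(columns=[c for c in cols if c != "current_p"])
    return pd.DataFrame(out_rows)
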