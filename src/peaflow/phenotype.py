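"""Clinical derivations, differential expression, mixed models, stratification.

Covers the phenotype side of the pipeline: HOMA-IR and BMI formulas,
Benjamini-Hochberg adjustment, ANOVA differential expression with
covariates, random-intercept mixed-model protein/clinical associations,
BMI and treatment-response stratification, and PCA/UMAP embeddings of
scaled NPX panels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

#: HOMA-IR denominator (insulin mU/L times glucose mmol/L over this constant).
HOMA_IR_CONSTANT = 22.5

#: baseline BMI above which a subject is in the obesity group.
BMI_CUTOFF = 30.0

#: FPG decrease (mmol/L, first to last visit) cut-offs for metformin response.
RESPONDER_CUT = 1.0
NON_RESPONDER_CUT = 0.1

DE_FDR = 0.05
LMM_ALPHA = 0.01


def homa_ir(insulin, glucose):
    """HOMA-IR: fasting insulin (mU/L) x fasting glucose (mmol/L) / 22.5."""
    ins = np.asarray(insulin, dtype=float)
    glu = np.asarray(glucose, dtype=float)
    if (ins < 0).any() or (glu < 0).any():
        raise ValueError("insulin and glucose must be non-negative")
    out = ins * glu / HOMA_IR_CONSTANT
    return float(out) if out.ndim == 0 else out


def bmi(weight_kg, height_m):
    """Body mass index: weight (kg) divided by height (m) squared."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if (h <= 0).any():
        raise ValueError("height must be positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        out = np.full(p.shape, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            out[ok] = multipletests(p[ok], method="fdr_bh")[1]
        return out
    return multipletests(p, method="fdr_bh")[1]


def _anova_batched(data, factor, covariates, value_col, protein_col):
    """All proteins share one design: nested-model F via a single QR.

    The F statistic for the factor fitted after the covariates equals the
    type-I (sequential) ANOVA F for the last term; computing it for every
    protein against the same design matrices avoids one formula parse and
    model fit per protein.  Returns None when the layout does not allow it
    (missing values, per-protein sample sets) so the caller can fall back
    to per-protein statsmodels fits.
    """
    import patsy
    from scipy import stats as sps

    wide = data.pivot_table(index="sample_id", columns=protein_col, values=value_col)
    if wide.isna().any().any():
        return None
    ann = data.drop_duplicates("sample_id").set_index("sample_id").loc[wide.index]
    rhs_reduced = " + ".join(list(covariates)) if covariates else "1"
    try:
        X_r = patsy.dmatrix(rhs_reduced, ann, return_type="dataframe")
        X_f = patsy.dmatrix(
            rhs_reduced + f" + C(Q('{factor}'))", ann, return_type="dataframe"
        )
    except Exception:
        return None
    if len(X_r) != len(wide) or len(X_f) != len(wide):
        return None  # rows dropped for missing covariates
    Y = wide.to_numpy(dtype=float)

    def _rss(X):
        Q, R = np.linalg.qr(X.to_numpy(dtype=float))
        if np.abs(np.diag(R)).min() < 1e-10:
            raise np.linalg.LinAlgError("rank deficient design")
        resid = Y - Q @ (Q.T @ Y)
        return (resid * resid).sum(axis=0), X.shape[1]

    try:
        rss_r, p_r = _rss(X_r)
        rss_f, p_f = _rss(X_f)
    except np.linalg.LinAlgError:
        return None
    df1 = p_f - p_r
    df2 = len(Y) - p_f
    if df1 <= 0 or df2 <= 0:
        return None
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return pd.DataFrame(
        {"F": F, "p_value": sps.f.sf(F, df1, df2)}, index=wide.columns
    )


def anova_de(
    data: pd.DataFrame,
    factor: str,
    covariates=(),
    value_col: str = "npx",
    protein_col: str = "protein_id",
    fdr: float = DE_FDR,
) -> pd.DataFrame:
    """Per-protein ANOVA differential expression for a factor with covariates.

    For each protein fits an additive linear model with the covariate
    terms first and the factor last, and reports the type-I F-test on the
    factor — for a balanced design this is the classical balanced ANOVA;
    imbalance triggers a warning, not a failure.  P-values are BH-adjusted
    across proteins and proteins with adjusted p < ``fdr`` are marked
    differentially expressed.  The log2 fold change is the difference of
    factor-level means of NPX (already log2): second level minus first in
    sorted order.
    """
    levels = sorted(data[factor].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs at least two levels, got {levels}")
    counts = data.drop_duplicates(["sample_id", factor])[factor].value_counts()
    if counts.nunique() > 1:
        warnings.warn(f"unbalanced design for factor {factor!r}: {counts.to_dict()}")
    batched = _anova_batched(data, factor, covariates, value_col, protein_col)
    rhs_reduced = " + ".join(list(covariates)) if covariates else "1"
    formula_reduced = f"Q('{value_col}') ~ " + rhs_reduced
    formula_full = formula_reduced + f" + C(Q('{factor}'))"
    rows = []
    for prot, grp in data.groupby(protein_col, sort=True):
        if batched is not None:
            fstat = float(batched.loc[prot, "F"])
            pval = float(batched.loc[prot, "p_value"])
        else:
            try:
                fit_r = smf.ols(formula_reduced, data=grp).fit()
                fit_f = smf.ols(formula_full, data=grp).fit()
                tab = sm.stats.anova_lm(fit_r, fit_f)
                fstat, pval = float(tab["F"].iloc[1]), float(tab["Pr(>F)"].iloc[1])
            except Exception:
                fstat, pval = np.nan, np.nan
        means = grp.groupby(factor)[value_col].mean()
        lfc = float(means.get(levels[1], np.nan) - means.get(levels[0], np.nan))
        rows.append(
            {
                "protein_id": prot,
                "term": factor,
                "coefficient": lfc,
                "F": fstat,
                "p_value": pval,
                "method": "anova",
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    out["de"] = out["adjusted_p"] < fdr
    out.attrs["levels"] = levels
    out.attrs["fdr"] = fdr
    return out


def lmm_association(
    data: pd.DataFrame,
    clinical: str,
    covariates=("sex", "age", "C(visit)"),
    group_col: str = "subject_id",
    value_col: str = "npx",
    protein_col: str = "protein_id",
    alpha: float = LMM_ALPHA,
) -> pd.DataFrame:
    """Mixed-effect protein/clinical association with a random intercept.

    Per protein fits ``npx ~ clinical + covariates`` with a random
    intercept per subject and reports the Wald test on the clinical term
    (a large-sample approximation in place of Kenward-Roger; see the
    package methods note).  P-values are BH-adjusted across proteins;
    associations with adjusted p < ``alpha`` are flagged significant.
    """
    formula = f"Q('{value_col}') ~ Q('{clinical}')" + "".join(f" + {c}" for c in covariates)
    rows = []
    for prot, grp in data.groupby(protein_col, sort=True):
        n_sub = grp[group_col].nunique()
        if n_sub <= len(covariates) + 2:
            raise ValueError(
                f"protein {prot}: {n_sub} subjects cannot support the fixed-effect design"
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(formula, data=grp, groups=grp[group_col]).fit(reml=True)
            term = f"Q('{clinical}')"
            coef = float(fit.params[term])
            pval = float(fit.pvalues[term])
        except Exception:
            coef, pval = np.nan, np.nan
        rows.append(
            {
                "protein_id": prot,
                "term": clinical,
                "coefficient": coef,
                "p_value": pval,
                "method": "lmm",
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["adjusted_p"] < alpha
    return out


def stratify_bmi(visits: pd.DataFrame, cutoff: float = BMI_CUTOFF) -> pd.DataFrame:
    """Split subjects into obesity / non-obesity by baseline BMI.

    Baseline is the earliest visit; BMI strictly above ``cutoff`` is
    obesity, a value exactly at the cutoff falls in the non-obesity group
    (documented boundary policy).
    """
    base = visits.sort_values("visit").groupby("subject_id").first()
    out = pd.DataFrame(
        {
            "subject_id": base.index,
            "baseline_bmi": base["bmi"].to_numpy(),
            "bmi_group": np.where(base["bmi"] > cutoff, "obesity", "non-obesity"),
        }
    ).reset_index(drop=True)
    return out


def classify_response(
    fpg_by_visit,
    responder_cut: float = RESPONDER_CUT,
    non_responder_cut: float = NON_RESPONDER_CUT,
    instability_threshold: float = 1.0,
) -> tuple[str, float]:
    """Classify one subject's FPG trajectory into a response group.

    The FPG decrease is first visit minus last visit (mmol/L): a decrease
    above ``responder_cut`` is a responder, below ``non_responder_cut`` a
    non-responder, anything between (inclusive on both ends) is
    indeterminate.  An instability override assigns indeterminate when two
    consecutive visit-to-visit changes have opposite signs and both exceed
    ``instability_threshold`` in magnitude, regardless of the net change.
    Returns (group, fpg_decrease).
    """
    vals = np.asarray(list(fpg_by_visit), dtype=float)
    if vals.size < 2:
        raise ValueError("response classification needs FPG at two visits or more")
    decrease = float(vals[0] - vals[-1])
    changes = np.diff(vals)
    for c1, c2 in zip(changes[:-1], changes[1:]):
        if (
            np.sign(c1) != 0
            and np.sign(c2) != 0
            and np.sign(c1) != np.sign(c2)
            and abs(c1) > instability_threshold
            and abs(c2) > instability_threshold
        ):
            return "indeterminate", decrease
    if decrease > responder_cut:
        return "responder", decrease
    if decrease < non_responder_cut:
        return "non-responder", decrease
    return "indeterminate", decrease


def stratify_response(
    visits: pd.DataFrame,
    treated_ids=None,
    responder_cut: float = RESPONDER_CUT,
    non_responder_cut: float = NON_RESPONDER_CUT,
    instability_threshold: float = 1.0,
) -> pd.DataFrame:
    """Treatment-response groups for (by default) every subject in ``visits``.

    Restrict with ``treated_ids`` to the treated subjects; subjects missing
    either endpoint visit are skipped.
    """
    d = visits
    if treated_ids is not None:
        d = d[d["subject_id"].isin(set(treated_ids))]
    rows = []
    for subj, grp in d.sort_values("visit").groupby("subject_id"):
        fpg = grp["fpg"].to_numpy(dtype=float)
        if len(fpg) < 2 or not np.isfinite([fpg[0], fpg[-1]]).all():
            continue
        group, dec = classify_response(
            fpg, responder_cut, non_responder_cut, instability_threshold
        )
        rows.append({"subject_id": subj, "response_group": group, "fpg_decrease": dec})
    return pd.DataFrame(rows, columns=["subject_id", "response_group", "fpg_decrease"])


def embed(
    X: pd.DataFrame,
    method: str = "pca",
    seed: int | None = None,
    n_components: int = 2,
) -> pd.DataFrame:
    """2-D embedding of samples on scaled NPX values (PCA or seeded UMAP).

    ``X`` is samples x proteins; each protein is centred and scaled to
    unit variance (constant proteins are dropped) before embedding.
    """
    if X.shape[0] < 3:
        raise ValueError("embedding needs at least three samples")
    vals = X.to_numpy(dtype=float)
    mu = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0)
    keep = sd > 0
    Z = (vals[:, keep] - mu[keep]) / sd[keep]
    Z = np.nan_to_num(Z)
    if method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=n_components, svd_solver="full").fit_transform(Z)
        cols = [f"PC{i + 1}" for i in range(n_components)]
    elif method == "umap":
        import umap

        reducer = umap.UMAP(n_components=n_components, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = reducer.fit_transform(Z)
        cols = [f"UMAP{i + 1}" for i in range(n_components)]
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=X.index, columns=cols)
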