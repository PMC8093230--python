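"""Longitudinal variance decomposition: inter- vs intra-individual CV.

For each protein the coefficient of variation (SD/mean) is computed on
linearized values (2**NPX by default, since CV is only meaningful on a
ratio scale): the inter-individual CV is the mean over visits of the CV
across individuals within that visit, the intra-individual CV the mean
over individuals of the CV across that individual's visits.  Proteins
where inter exceeds intra vary more between people than within a person
over time — the pattern expected of genetically or constitutively
determined plasma proteins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .npx import NPXMatrix


def cv(values) -> float:
    """Coefficient of variation: sample SD over mean, for positive data.

    Requires at least two values; NaN (reported as missing) when the mean
    is not positive.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def inter_intra_cv(
    npx: NPXMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    linearize: bool = True,
) -> pd.DataFrame:
    """Per-protein inter- and intra-individual CV profile.

    Parameters
    ----------
    npx:
        NPX matrix or long DataFrame with ``sample_id``, ``protein_id``,
        ``npx`` (QC-pass study rows are used).
    samples:
        sample annotation mapping ``sample_id`` to ``subject_id`` and
        ``visit``.
    linearize:
        compute CV on 2**NPX (default); set False for the log-scale
        variant, kept for comparability with conventions that stay in NPX
        units.

    Subjects with fewer than two visits are skipped for the intra CV and
    visits with fewer than two subjects for the inter CV; the counts used
    are reported per protein.
    """
    d = npx.study() if isinstance(npx, NPXMatrix) else npx
    d = d.merge(samples[["sample_id", "subject_id", "visit"]], on="sample_id")
    d = d.copy()
    d["value"] = np.exp2(d["npx"]) if linearize else d["npx"]

    def _safe_cv(v: pd.Series) -> float:
        v = v.dropna()
        if len(v) < 2 or v.mean() <= 0:
            return np.nan
        return float(v.std(ddof=1) / v.mean())

    inter = (
        d.groupby(["protein_id", "visit"])["value"]
        .apply(_safe_cv)
        .groupby("protein_id")
        .mean()
        .rename("inter_cv")
    )
    intra = (
        d.groupby(["protein_id", "subject_id"])["value"]
        .apply(_safe_cv)
        .groupby("protein_id")
        .mean()
        .rename("intra_cv")
    )
    n_ind = d.groupby("protein_id")["subject_id"].nunique().rename("n_individuals")
    n_vis = d.groupby("protein_id")["visit"].nunique().rename("n_visits")
    out = pd.concat([inter, intra, n_ind, n_vis], axis=1).reset_index()
    out["inter_gt_intra"] = out["inter_cv"] > out["intra_cv"]
    return out


def lognormal_cv(sigma_log2: float) -> float:
    """Closed-form CV of a lognormal on the linear scale.

    If log2 X ~ N(mu, sigma^2) then CV(X) = sqrt(exp(sigma^2 ln(2)^2) - 1);
    used as the analytic oracle for simulated variance components.
    """
    return float(np.sqrt(np.expm1((sigma_log2 * np.log(2)) ** 2)))
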