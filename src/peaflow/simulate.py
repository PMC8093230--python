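"""Synthetic cohorts, genotypes, true protein abundances and assay counts.

The generator emulates the statistical structure of longitudinal plasma
proteome profiling with a sequencing read-out proximity extension assay:

* two cohorts — a healthy longitudinal "wellness" cohort (default 76
  subjects, 3 visits over two years) and a newly diagnosed T2D cohort
  (default 48 subjects, 40 on metformin, visits over three months) — with
  sex, age, fasting glucose, insulin and BMI;
* per-protein log2 abundances decomposed into a protein mean, a sex
  effect for a subset of proteins, additive genetic effects of planted
  cis/trans variants, a disease effect, a subject-level random baseline
  (between-individual SD) and visit-level deviations (within-individual SD);
* genotypes in Hardy-Weinberg proportions with block LD built by copying a
  block founder haplotype with a per-variant mutation probability;
* plate layouts with the standard control wells (3 negative, 3 plate,
  2 sample controls per plate), subject visits co-located on one plate,
  batch structure and bridging samples re-run across batches;
* a negative-binomial count layer: per-well sequencing depth times
  2**(plate offset + batch offset + log2 abundance), plus spiked
  extension/incubation/amplification controls, and
* a paired second-platform (qPCR-style) read-out emitted directly on the
  NPX scale as truth plus per-protein platform offset plus noise.

Every random draw flows from ``SimConfig.seed`` through a
``numpy.random.SeedSequence`` tree, so a fixed seed reproduces the study
byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import GenotypeMatrix
from .npx import (
    CountMatrix,
    NPXMatrix,
    WELL_NEGATIVE,
    WELL_PLATE,
    WELL_SAMPLE,
    WELL_SAMPLE_CONTROL,
)

#: control wells on every plate: 3 negative, 3 plate, 2 sample controls.
N_NEGATIVE_CONTROLS = 3
N_PLATE_CONTROLS = 3
N_SAMPLE_CONTROLS = 2
CONTROL_WELLS_PER_PLATE = N_NEGATIVE_CONTROLS + N_PLATE_CONTROLS + N_SAMPLE_CONTROLS

#: QC assays replicated once per panel (real proteins measured in every panel).
CONTROL_ASSAY_PROTEINS = ("IL6", "CXCL8", "TNF")


@dataclass
class SimConfig:
    """Generator parameters; defaults encode the emulated study design.

    Log2-scale SDs: ``sigma_between`` (subject baselines), ``sigma_within``
    (visit deviations), plate/batch offsets.  Effect sizes are log2 units;
    ``genetic_beta`` is log2 units per alternate allele.  The count layer
    is negative binomial with a per-well depth (mean ``depth_mean``,
    lognormal CV ``depth_dispersion``) and quadratic overdispersion
    ``count_dispersion`` (variance = m + dispersion * m**2).  ``seed`` is
    mandatory: simulation without a seed is refused.
    """

    n_subjects: int = 76
    n_t2d_subjects: int = 48
    n_visits: int = 3
    n_proteins: int = 100
    n_panels: int = 4
    n_assays_per_panel: int = 384

    sigma_between: float = 0.4
    sigma_within: float = 0.1
    protein_mean_log2: float = 3.0
    protein_mean_sd: float = 1.0

    sex_effect_fraction: float = 0.2
    sex_effect_size: float = 0.5

    n_variants: int = 400
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 4
    ld_mutation_prob: float = 0.1
    n_causal_cis: int = 5
    n_causal_trans: int = 3
    genetic_beta: float = 1.0

    disease_effect_fraction: float = 0.1
    disease_effect_size: float = 0.8
    treated_fraction: float = 40 / 48
    responder_fractions: tuple[float, float, float] = (0.4, 0.25, 0.35)
    responder_effect_fraction: float = 0.1
    responder_effect_size: float = 1.0

    plate_offset_sd: float = 0.5
    batch_offset_sd: float = 0.4
    depth_mean: float = 20_000.0
    depth_dispersion: float = 0.3
    count_dispersion: float = 0.001
    background_log2: float = -7.0
    ext_control_log2: float = 0.0
    inc_control_log2: float = 0.0
    amp_control_log2: float = 0.0
    incubation_outlier_rate: float = 0.01
    incubation_outlier_shift: float = 1.0

    qpcr_offset_sd: float = 0.5
    qpcr_noise_sd: float = 0.15

    plexity: int = 96
    n_batches: int = 2
    n_bridge_samples: int = 8

    age_range: tuple[int, int] = (50, 65)
    male_fraction: float = 40 / 76

    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is required: simulation without a seed is refused")
        for name in ("n_subjects", "n_visits", "n_proteins", "n_panels", "n_variants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "sigma_between",
            "sigma_within",
            "plate_offset_sd",
            "batch_offset_sd",
            "count_dispersion",
            "qpcr_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_causal_cis + self.n_causal_trans > self.n_variants:
            raise ValueError("more causal variants requested than variants simulated")
        if self.n_causal_cis + self.n_causal_trans > self.n_proteins:
            raise ValueError("more causal proteins requested than proteins simulated")

    def rng_tree(self, n: int) -> list[np.random.Generator]:
        """Deterministic child generators spawned from the seed."""
        self.validate()
        return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass
class Cohort:
    """Subjects with demographics and longitudinal visit records.

    ``subjects``: subject_id, sex, age, cohort_label, treatment.
    ``visits``: subject_id, visit (1-based), date_offset_days, fpg (mmol/L),
    insulin (mU/L), bmi (kg/m2).  ``samples`` maps every sample
    (subject-visit) to its sample_id.
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame

    def __post_init__(self) -> None:
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("subject ids must be unique")
        counts = self.visits.groupby("subject_id").size()
        if (counts < 1).any() or not set(self.subjects["subject_id"]) <= set(counts.index):
            raise ValueError("every subject needs at least one visit")

    @property
    def samples(self) -> pd.DataFrame:
        s = self.visits[["subject_id", "visit"]].copy()
        s["sample_id"] = sample_id(s["subject_id"], s["visit"])
        return s[["sample_id", "subject_id", "visit"]]


@dataclass
class SimTruth:
    """Ground truth behind a simulated study, for recovery tests.

    ``log_abundance`` is indexed by (subject_id, visit) with one column per
    protein (log2 scale).  ``causal_map`` maps protein -> list of
    (variant_id, beta, cis/trans).  Plate/batch offsets are filled in by
    :func:`simulate_assay` (plate x assay, batch x assay)."""

    log_abundance: pd.DataFrame
    protein_means: pd.Series
    sex_effects: pd.Series
    disease_effects: pd.Series
    causal_map: dict[str, list[tuple[str, float, str]]]
    responder_labels: pd.Series
    responder_effects: pd.Series
    plate_control_abundance: pd.Series
    sample_control_abundance: pd.Series
    genotypes: GenotypeMatrix | None = None
    plate_offsets: pd.DataFrame | None = None
    batch_offsets: pd.DataFrame | None = None


@dataclass
class PlateLayout:
    """Well assignments: one row per well with plate, batch and content."""

    wells: pd.DataFrame

    @property
    def plates(self) -> np.ndarray:
        return self.wells["plate_id"].unique()


def sample_id(subject_id, visit):
    """Canonical sample id for a subject visit."""
    return pd.Series(subject_id).astype(str) + "_v" + pd.Series(visit).astype(str)


def _subject_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    wellness = [f"W{i + 1:03d}" for i in range(config.n_subjects)]
    t2d = [f"D{i + 1:03d}" for i in range(config.n_t2d_subjects)]
    return wellness, t2d


def protein_ids(config: SimConfig) -> list[str]:
    """Study protein ids plus the three replicated QC-assay proteins."""
    return [f"P{i + 1:04d}" for i in range(config.n_proteins)] + list(CONTROL_ASSAY_PROTEINS)


def build_panel_design(config: SimConfig) -> pd.DataFrame:
    """Assign proteins to panels; QC-assay proteins appear once per panel.

    Returns assay_id, protein_id, panel, is_control_assay.  Study proteins
    get one assay each (assay_id == protein_id); the control-assay proteins
    are replicated with panel-suffixed assay ids.
    """
    prots = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    per_panel = int(np.ceil(len(prots) / config.n_panels))
    if per_panel + len(CONTROL_ASSAY_PROTEINS) > config.n_assays_per_panel:
        raise ValueError("panel plexity too small for the requested protein count")
    rows = []
    for i, p in enumerate(prots):
        rows.append({"assay_id": p, "protein_id": p, "panel": i // per_panel + 1, "is_control_assay": False})
    for panel in range(1, config.n_panels + 1):
        for cp in CONTROL_ASSAY_PROTEINS:
            rows.append(
                {
                    "assay_id": f"{cp}_panel{panel}",
                    "protein_id": cp,
                    "panel": panel,
                    "is_control_assay": True,
                }
            )
    return pd.DataFrame(rows)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Biallelic genotypes in HWE with block LD for both cohorts' subjects.

    Variants are laid out in blocks of ``ld_block_size`` spread across 22
    chromosomes (200 kb spacing within a block, 3 Mb between block starts).
    Within a block each haplotype copies a founder allele drawn at the
    block MAF and is redrawn independently with probability
    ``ld_mutation_prob``, giving high within-block and near-zero
    between-block r^2 while each variant stays Bernoulli(MAF) per
    haplotype, hence HWE at the genotype level.
    """
    config.validate()
    (rng,) = config.rng_tree(7)[6:7]
    wellness, t2d = _subject_ids(config)
    subjects = wellness + t2d
    n = len(subjects)
    n_blocks = int(np.ceil(config.n_variants / config.ld_block_size))

    geno = np.empty((n, config.n_variants), dtype=float)
    chroms: list[str] = []
    poss: list[int] = []
    v = 0
    blocks_per_chrom = int(np.ceil(n_blocks / 22))
    for b in range(n_blocks):
        size = min(config.ld_block_size, config.n_variants - v)
        maf = rng.uniform(*config.maf_range)
        founders = rng.random((n, 2)) < maf  # one founder allele per haplotype
        for k in range(size):
            mutate = rng.random((n, 2)) < config.ld_mutation_prob
            redraw = rng.random((n, 2)) < maf
            hap = np.where(mutate, redraw, founders)
            geno[:, v] = hap.sum(axis=1)
            chrom = b // blocks_per_chrom + 1
            within = b % blocks_per_chrom
            chroms.append(str(chrom))
            poss.append(within * 3_000_000 + k * 200_000 + 1)
            v += 1

    variant_ids = [f"var{i + 1:05d}" for i in range(config.n_variants)]
    genotypes = pd.DataFrame(geno, index=pd.Index(subjects, name="subject_id"), columns=variant_ids)
    p_hat = genotypes.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": poss,
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(p_hat, 1 - p_hat).to_numpy(),
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    return GenotypeMatrix(genotypes=genotypes, variants=variants)


def simulate_cohort(
    config: SimConfig, genotypes: GenotypeMatrix | None = None
) -> tuple[Cohort, SimTruth]:
    """Generate both cohorts, clinical trajectories and true abundances.

    The log2 abundance of protein p for subject i at visit v is

        x[i,v,p] = mu_p + sex_p * 1[male] + sum_k beta_{p,k} g[i,k]
                   + disease_p * 1[T2D] + responder_p * 1[responder]
                   + b_{i,p} + e_{i,v,p}

    with b ~ N(0, sigma_between^2) and e ~ N(0, sigma_within^2).  Clinical
    values use cohort-dependent means; treated T2D subjects get an FPG
    trajectory whose total decline encodes their planted response group.
    """
    config.validate()
    rngs = config.rng_tree(7)
    r_subj, r_eff, r_abund, r_clin = rngs[0], rngs[1], rngs[2], rngs[3]

    if genotypes is None:
        genotypes = simulate_genotypes(config)

    wellness, t2d = _subject_ids(config)
    subjects = wellness + t2d
    n_sub = len(subjects)
    prots = protein_ids(config)
    n_prot = len(prots)

    sex = np.where(r_subj.random(n_sub) < config.male_fraction, "male", "female")
    age = r_subj.integers(config.age_range[0], config.age_range[1] + 1, size=n_sub)
    is_t2d = np.array([s.startswith("D") for s in subjects])
    treatment = np.where(is_t2d & (r_subj.random(n_sub) < config.treated_fraction), "metformin", "none")
    treatment[~is_t2d] = "none"
    subjects_df = pd.DataFrame(
        {
            "subject_id": subjects,
            "sex": sex,
            "age": age,
            "cohort_label": np.where(is_t2d, "T2D", "wellness"),
            "treatment": treatment,
        }
    )

    # planted effect maps
    n_sex = round(config.sex_effect_fraction * n_prot)
    sex_idx = r_eff.choice(n_prot, size=n_sex, replace=False)
    sex_eff = np.zeros(n_prot)
    sex_eff[sex_idx] = config.sex_effect_size * r_eff.choice([-1.0, 1.0], size=n_sex)

    n_dis = round(config.disease_effect_fraction * n_prot)
    dis_idx = r_eff.choice(n_prot, size=n_dis, replace=False)
    dis_eff = np.zeros(n_prot)
    dis_eff[dis_idx] = config.disease_effect_size * r_eff.choice([-1.0, 1.0], size=n_dis)

    n_resp = round(config.responder_effect_fraction * n_prot)
    resp_idx = r_eff.choice(n_prot, size=n_resp, replace=False)
    resp_eff = np.zeros(n_prot)
    resp_eff[resp_idx] = config.responder_effect_size * r_eff.choice([-1.0, 1.0], size=n_resp)

    # causal variants: distinct proteins, cis then trans
    causal_prot_idx = r_eff.choice(
        config.n_proteins, size=config.n_causal_cis + config.n_causal_trans, replace=False
    )
    variant_ids = list(genotypes.genotypes.columns)
    causal_var_idx = r_eff.choice(len(variant_ids), size=len(causal_prot_idx), replace=False)
    causal_map: dict[str, list[tuple[str, float, str]]] = {}
    genetic = np.zeros((n_sub, n_prot))
    geno_arr = genotypes.genotypes.loc[subjects].to_numpy(dtype=float)
    variants_meta = genotypes.variants
    tss_rows = {}
    for j, (pi, vi) in enumerate(zip(causal_prot_idx, causal_var_idx)):
        label = "cis" if j < config.n_causal_cis else "trans"
        prot = prots[pi]
        var = variant_ids[vi]
        beta = config.genetic_beta * float(r_eff.choice([-1.0, 1.0]))
        causal_map.setdefault(prot, []).append((var, beta, label))
        genetic[:, pi] += beta * geno_arr[:, vi]
        vchrom, vpos = variants_meta.loc[var, "chrom"], int(variants_meta.loc[var, "pos"])
        if label == "cis":
            tss_rows[prot] = (vchrom, max(1, vpos + int(r_eff.integers(-500_000, 500_001))))
        else:
            other = str(int(vchrom) % 22 + 1)  # guaranteed different chromosome
            tss_rows[prot] = (other, int(r_eff.integers(1, 50_000_000)))
    # remaining proteins: random TSS far from everything in particular
    for prot in prots:
        if prot not in tss_rows:
            tss_rows[prot] = (str(r_eff.integers(1, 23)), int(r_eff.integers(1, 50_000_000)))
    tss = pd.DataFrame.from_dict(tss_rows, orient="index", columns=["chrom", "tss"])
    tss.index.name = "protein_id"
    genotypes.tss = tss

    # responder labels among treated T2D subjects
    treated = subjects_df.loc[subjects_df["treatment"] == "metformin", "subject_id"].to_numpy()
    groups = ("responder", "indeterminate", "non-responder")
    resp_labels = pd.Series(
        r_subj.choice(groups, size=len(treated), p=config.responder_fractions), index=treated
    )

    mu = config.protein_mean_log2 + config.protein_mean_sd * r_abund.standard_normal(n_prot)
    male = (sex == "male").astype(float)[:, None]
    t2d_ind = is_t2d.astype(float)[:, None]
    resp_ind = np.array(
        [1.0 if resp_labels.get(s) == "responder" else 0.0 for s in subjects]
    )[:, None]
    base = (
        mu[None, :]
        + male * sex_eff[None, :]
        + genetic
        + t2d_ind * dis_eff[None, :]
        + resp_ind * resp_eff[None, :]
        + config.sigma_between * r_abund.standard_normal((n_sub, n_prot))
    )
    x = base[:, None, :] + config.sigma_within * r_abund.standard_normal(
        (n_sub, config.n_visits, n_prot)
    )

    idx = pd.MultiIndex.from_product(
        [subjects, range(1, config.n_visits + 1)], names=["subject_id", "visit"]
    )
    log_abundance = pd.DataFrame(x.reshape(n_sub * config.n_visits, n_prot), index=idx, columns=prots)

    # clinical trajectories
    visit_rows = []
    for i, s in enumerate(subjects):
        t2d_s = is_t2d[i]
        bmi0 = max(16.0, r_clin.normal(31.0 if t2d_s else 26.0, 5.0 if t2d_s else 3.5))
        ins0 = max(1.0, r_clin.normal(15.0 if t2d_s else 8.0, 5.0 if t2d_s else 3.0))
        fpg0 = max(3.0, r_clin.normal(9.0 if t2d_s else 5.5, 1.5 if t2d_s else 0.5))
        label = resp_labels.get(s)
        if label == "responder":
            total_dec = r_clin.uniform(1.2, 3.0)
        elif label == "indeterminate":
            total_dec = r_clin.uniform(0.15, 0.95)
        elif label == "non-responder":
            total_dec = r_clin.uniform(-0.3, 0.05)
        else:
            total_dec = 0.0
        offsets = (
            np.round(np.linspace(0, 90, config.n_visits)).astype(int)
            if t2d_s
            else np.round(np.linspace(0, 730, config.n_visits)).astype(int)
        )
        for v in range(1, config.n_visits + 1):
            frac = (v - 1) / max(config.n_visits - 1, 1)
            fpg = fpg0 - frac * total_dec + r_clin.normal(0, 0.02)
            visit_rows.append(
                {
                    "subject_id": s,
                    "visit": v,
                    "date_offset_days": int(offsets[v - 1]),
                    "fpg": max(2.5, fpg),
                    "insulin": max(0.5, ins0 + r_clin.normal(0, 0.5)),
                    "bmi": max(15.0, bmi0 + r_clin.normal(0, 0.3)),
                }
            )
    cohort = Cohort(subjects=subjects_df, visits=pd.DataFrame(visit_rows))

    pool_abund = pd.Series(mu, index=prots)  # plasma pool sits at the protein means
    ref_abund = pd.Series(
        mu + config.sigma_between * r_abund.standard_normal(n_prot), index=prots
    )
    truth = SimTruth(
        log_abundance=log_abundance,
        protein_means=pd.Series(mu, index=prots),
        sex_effects=pd.Series(sex_eff, index=prots),
        disease_effects=pd.Series(dis_eff, index=prots),
        causal_map=causal_map,
        responder_labels=resp_labels,
        responder_effects=pd.Series(resp_eff, index=prots),
        plate_control_abundance=pool_abund,
        sample_control_abundance=ref_abund,
        genotypes=genotypes,
    )
    return cohort, truth


def assign_plates(
    cohort: Cohort,
    plexity: int = 96,
    seed: int | None = None,
    n_batches: int = 1,
    bridge_ids=None,
) -> PlateLayout:
    """Randomize samples onto plates, keeping a subject's visits together.

    Each plate reserves 3 negative, 3 plate and 2 sample-control wells.
    Subjects are shuffled and packed greedily; when a subject's visits do
    not fit in the remaining capacity a new plate is started, and a subject
    with more visits than a whole plate's capacity is split with a warning
    (never dropped).  Plates are divided contiguously into ``n_batches``
    batches; samples named in ``bridge_ids`` additionally get one well in
    every other batch, spread evenly over that batch's plates.
    """
    capacity = plexity - CONTROL_WELLS_PER_PLATE
    if capacity <= 0:
        raise ValueError(
            f"plexity {plexity} leaves no sample wells after {CONTROL_WELLS_PER_PLATE} control wells"
        )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    samples = cohort.samples
    subj_order = cohort.subjects["subject_id"].to_numpy().copy()
    rng.shuffle(subj_order)
    bridge_ids = list(bridge_ids) if bridge_ids else []

    def _pack(cap: int) -> list[list[str]]:
        plates: list[list[str]] = [[]]
        for s in subj_order:
            ids = samples.loc[samples["subject_id"] == s, "sample_id"].tolist()
            if len(ids) > cap:
                warnings.warn(
                    f"subject {s} has {len(ids)} samples but plates hold {cap}; splitting across plates"
                )
                for chunk_start in range(0, len(ids), cap):
                    chunk = ids[chunk_start : chunk_start + cap]
                    if len(plates[-1]) + len(chunk) > cap:
                        plates.append([])
                    plates[-1].extend(chunk)
                continue
            if len(plates[-1]) + len(ids) > cap:
                plates.append([])
            plates[-1].extend(ids)
        return plates

    def _build(plates: list[list[str]]) -> pd.DataFrame:
        per_batch = int(np.ceil(len(plates) / n_batches))
        rows = []
        for p, plate_samples in enumerate(plates):
            plate = f"PL{p + 1:02d}"
            batch = f"B{p // per_batch + 1}"
            w = 0
            for sid in plate_samples:
                w += 1
                rows.append((plate, batch, f"W{w:03d}", WELL_SAMPLE, sid))
            for i in range(N_NEGATIVE_CONTROLS):
                w += 1
                rows.append((plate, batch, f"W{w:03d}", WELL_NEGATIVE, f"{plate}_NEG{i + 1}"))
            for i in range(N_PLATE_CONTROLS):
                w += 1
                rows.append((plate, batch, f"W{w:03d}", WELL_PLATE, f"{plate}_PC{i + 1}"))
            for i in range(N_SAMPLE_CONTROLS):
                w += 1
                rows.append((plate, batch, f"W{w:03d}", WELL_SAMPLE_CONTROL, f"{plate}_SC{i + 1}"))
        return pd.DataFrame(rows, columns=["plate_id", "batch_id", "well", "well_type", "sample_id"])

    def _place_bridges(wells: pd.DataFrame) -> pd.DataFrame | None:
        """Spread bridge re-runs evenly over each target batch's plates.

        Returns None when some plate cannot take its share without
        exceeding the plexity; the caller then repacks with a reserve.
        """
        home = wells[wells["sample_id"].isin(bridge_ids)].groupby("sample_id")["batch_id"].first()
        extra = []
        for batch in sorted(wells["batch_id"].unique()):
            batch_plates = sorted(wells.loc[wells["batch_id"] == batch, "plate_id"].unique())
            fill = {pl: int((wells["plate_id"] == pl).sum()) for pl in batch_plates}
            need = [b for b in bridge_ids if home.get(b) != batch]
            if not need:
                continue
            n_pl = len(batch_plates)
            quotas = [len(need) // n_pl + (1 if i < len(need) % n_pl else 0) for i in range(n_pl)]
            if any(fill[pl] + q > plexity for pl, q in zip(batch_plates, quotas)):
                return None
            it = iter(need)
            for pl, q in zip(batch_plates, quotas):
                for _ in range(q):
                    fill[pl] += 1
                    extra.append((pl, batch, f"W{fill[pl]:03d}", WELL_SAMPLE, next(it)))
        if extra:
            wells = pd.concat(
                [wells, pd.DataFrame(extra, columns=wells.columns)], ignore_index=True
            )
        return wells

    reserve = 0
    while True:
        if capacity - reserve < 1:
            raise ValueError("no spare wells for bridging samples; increase plexity")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            plates = _pack(capacity - reserve)
        wells = _build(plates)
        if not bridge_ids:
            break
        placed = _place_bridges(wells)
        if placed is not None:
            wells = placed
            break
        reserve += 1
    for w in caught:
        warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)

    placed_samples = set(wells.loc[wells["well_type"] == WELL_SAMPLE, "sample_id"])
    missing = set(samples["sample_id"]) - placed_samples
    if missing:
        raise AssertionError(f"samples left unplaced: {sorted(missing)[:5]}")
    return PlateLayout(wells=wells)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_assay(
    truth: SimTruth,
    design: pd.DataFrame,
    layout: PlateLayout,
    config: SimConfig,
) -> CountMatrix:
    """Generate the count read-out for every well on every plate.

    For a study well the expected count of assay a is
    ``depth * 2**(plate_offset[plate,a] + batch_offset[batch,a] + x)``
    with x the well's true log2 abundance; negative-control wells use the
    configured background abundance, plate controls a pool vector shared by
    all plates, sample controls one fixed reference vector.  Counts are
    negative binomial; spiked extension / incubation / amplification
    controls share the well depth and carry no plate or batch offset.
    Plate and batch offsets (per assay) are drawn here and recorded on the
    returned truth object.
    """
    config.validate()
    rngs = config.rng_tree(7)
    rng = rngs[4]
    wells = layout.wells.reset_index(drop=True)
    assays = design["assay_id"].to_numpy()
    assay_prot = design["protein_id"].to_numpy()
    n_wells, n_assays = len(wells), len(assays)

    plates = sorted(wells["plate_id"].unique())
    batches = sorted(wells["batch_id"].unique())
    plate_off = pd.DataFrame(
        rng.normal(0, config.plate_offset_sd, size=(len(plates), n_assays)),
        index=plates,
        columns=assays,
    )
    batch_off = pd.DataFrame(
        rng.normal(0, config.batch_offset_sd, size=(len(batches), n_assays)),
        index=batches,
        columns=assays,
    )
    if len(batches) == 1:
        batch_off.iloc[:, :] = 0.0  # a single batch has no batch effect to speak of
    truth.plate_offsets = plate_off
    truth.batch_offsets = batch_off

    # log2 abundance per well x assay
    xmat = truth.log_abundance
    abund = np.empty((n_wells, n_assays))
    for w, row in enumerate(wells.itertuples(index=False)):
        if row.well_type == WELL_SAMPLE:
            subj, visit = row.sample_id.rsplit("_v", 1)
            vec = xmat.loc[(subj, int(visit))]
            abund[w] = vec.reindex(assay_prot).to_numpy()
        elif row.well_type == WELL_NEGATIVE:
            abund[w] = config.background_log2
        elif row.well_type == WELL_PLATE:
            abund[w] = truth.plate_control_abundance.reindex(assay_prot).to_numpy()
        else:
            abund[w] = truth.sample_control_abundance.reindex(assay_prot).to_numpy()

    depth_sigma = np.sqrt(np.log1p(config.depth_dispersion**2))
    depth = config.depth_mean * np.exp(
        rng.normal(0, depth_sigma, size=n_wells) - depth_sigma**2 / 2
    )
    offsets = (
        plate_off.loc[wells["plate_id"]].to_numpy()
        + batch_off.loc[wells["batch_id"]].to_numpy()
    )
    mean = depth[:, None] * np.exp2(offsets + abund)
    counts = _nb_draw(rng, mean, config.count_dispersion)

    count_df = pd.DataFrame(
        counts, index=pd.RangeIndex(n_wells), columns=assays
    )
    long = count_df.stack().rename("count").reset_index()
    long.columns = ["well_idx", "assay_id", "count"]
    long = long.merge(
        wells[["plate_id", "batch_id", "well_type", "sample_id"]].reset_index(names="well_idx"),
        on="well_idx",
    ).drop(columns="well_idx")
    long = long.merge(design[["assay_id", "panel"]], on="assay_id")
    counts_long = long[["sample_id", "assay_id", "panel", "plate_id", "batch_id", "well_type", "count"]]

    outlier = rng.random(n_wells) < config.incubation_outlier_rate
    outlier_shift = config.incubation_outlier_shift * rng.choice([-1.0, 1.0], size=n_wells)
    ctrl_rows = []
    for name, level in (
        ("extension", config.ext_control_log2),
        ("incubation", config.inc_control_log2),
        ("amplification", config.amp_control_log2),
    ):
        lv = np.full(n_wells, level, dtype=float)
        if name == "incubation":
            lv = lv + np.where(outlier, outlier_shift, 0.0)
        c = _nb_draw(rng, depth * np.exp2(lv), config.count_dispersion)
        ctrl_rows.append(
            pd.DataFrame(
                {
                    "sample_id": wells["sample_id"],
                    "plate_id": wells["plate_id"],
                    "batch_id": wells["batch_id"],
                    "control": name,
                    "count": c,
                }
            )
        )
    controls = pd.concat(ctrl_rows, ignore_index=True)
    return CountMatrix(counts=counts_long, controls=controls)


def simulate_qpcr_readout(
    truth: SimTruth,
    config: SimConfig,
    offset_sd: float | None = None,
    noise_sd: float | None = None,
) -> NPXMatrix:
    """Paired second-platform read-out, emitted directly on the NPX scale.

    value = true log2 abundance + per-protein platform offset
    (SD ``qpcr_offset_sd``) + independent noise (SD ``qpcr_noise_sd``).
    """
    config.validate()
    rng = config.rng_tree(7)[5]
    offset_sd = config.qpcr_offset_sd if offset_sd is None else offset_sd
    noise_sd = config.qpcr_noise_sd if noise_sd is None else noise_sd
    x = truth.log_abundance
    offsets = rng.normal(0, offset_sd, size=x.shape[1]) if offset_sd > 0 else np.zeros(x.shape[1])
    noise = rng.normal(0, noise_sd, size=x.shape) if noise_sd > 0 else 0.0
    vals = x.to_numpy() + offsets[None, :] + noise
    d = pd.DataFrame(vals, index=x.index, columns=x.columns).stack().rename("npx").reset_index()
    d.columns = ["subject_id", "visit", "protein_id", "npx"]
    d["sample_id"] = sample_id(d["subject_id"], d["visit"])
    d["assay_id"] = d["protein_id"]
    d["panel"] = 0
    d["plate_id"] = "qpcr"
    d["batch_id"] = "qpcr"
    d["well_type"] = WELL_SAMPLE
    d["qc_flag"] = "pass"
    d["is_control_assay"] = d["protein_id"].isin(CONTROL_ASSAY_PROTEINS)
    cols = [
        "sample_id",
        "protein_id",
        "assay_id",
        "panel",
        "plate_id",
        "batch_id",
        "well_type",
        "npx",
        "qc_flag",
        "is_control_assay",
    ]
    return NPXMatrix(data=d[cols], provenance="qpcr", meta={"offset_sd": offset_sd, "noise_sd": noise_sd})


def truth_npx(truth: SimTruth) -> NPXMatrix:
    """Noiseless NPX table built straight from the true log2 abundances."""
    x = truth.log_abundance
    d = x.stack().rename("npx").reset_index()
    d.columns = ["subject_id", "visit", "protein_id", "npx"]
    d["sample_id"] = sample_id(d["subject_id"], d["visit"])
    d["assay_id"] = d["protein_id"]
    d["panel"] = 0
    d["plate_id"] = "truth"
    d["batch_id"] = "truth"
    d["well_type"] = WELL_SAMPLE
    d["qc_flag"] = "pass"
    d["is_control_assay"] = d["protein_id"].isin(CONTROL_ASSAY_PROTEINS)
    return NPXMatrix(data=d.drop(columns=["subject_id", "visit"]), provenance="truth")


def _truth_join(npxm: NPXMatrix, truth: SimTruth) -> pd.DataFrame:
    d = npxm.study().copy()
    x = truth.log_abundance.stack().rename("x").reset_index()
    x.columns = ["subject_id", "visit", "protein_id", "x"]
    x["sample_id"] = sample_id(x["subject_id"], x["visit"])
    d = d.merge(x[["sample_id", "protein_id", "x"]], on=["sample_id", "protein_id"])
    d["resid"] = d["npx"] - d["x"]
    return d


def plate_residuals(npxm: NPXMatrix, truth: SimTruth) -> pd.DataFrame:
    """Residual per-plate level offsets of normalized NPX against the truth.

    For each assay and plate, the median of (NPX - true log2 abundance)
    over that plate's study wells, centred per assay within its batch;
    after a successful plate adjustment these sit near zero regardless of
    the injected plate offsets.
    """
    d = _truth_join(npxm, truth)
    med = (
        d.groupby(["protein_id", "batch_id", "plate_id"])["resid"].median().rename("offset").reset_index()
    )
    med["plate_residual"] = med["offset"] - med.groupby(["protein_id", "batch_id"])["offset"].transform("mean")
    return med[["protein_id", "batch_id", "plate_id", "plate_residual"]]


def batch_residuals(npxm: NPXMatrix, truth: SimTruth, reference_batch: str) -> pd.DataFrame:
    """Residual per-batch offsets against the truth, relative to a reference batch.

    Per assay, the median of (NPX - truth) within each batch minus the same
    quantity in ``reference_batch``; after bridging these sit near zero
    regardless of the injected batch offsets.
    """
    d = _truth_join(npxm, truth)
    med = d.groupby(["protein_id", "batch_id"])["resid"].median().unstack("batch_id")
    out = med.sub(med[reference_batch], axis=0).stack().rename("batch_residual").reset_index()
    return out[out["batch_id"] != reference_batch]


@dataclass
class SimStudy:
    """A fully simulated study: cohort, truth, design, layout, counts, qPCR."""

    config: SimConfig
    cohort: Cohort
    truth: SimTruth
    design: pd.DataFrame
    layout: PlateLayout
    counts: CountMatrix
    qpcr: NPXMatrix
    bridge_ids: list[str] = field(default_factory=list)


def simulate_study(config: SimConfig) -> SimStudy:
    """End-to-end generation: cohort + genotypes + plates + counts + qPCR.

    Bridging samples (default 8) are drawn from the first batch and re-run
    in every other batch, spread evenly across that batch's plates.
    """
    config.validate()
    cohort, truth = simulate_cohort(config)
    layout0 = assign_plates(
        cohort, plexity=config.plexity, seed=config.seed, n_batches=config.n_batches
    )
    bridge_ids: list[str] = []
    if config.n_batches > 1 and config.n_bridge_samples > 0:
        first_batch = sorted(layout0.wells["batch_id"].unique())[0]
        pool = layout0.wells[
            (layout0.wells["batch_id"] == first_batch)
            & (layout0.wells["well_type"] == WELL_SAMPLE)
        ]["sample_id"].tolist()
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
        k = min(config.n_bridge_samples, len(pool))
        bridge_ids = sorted(rng.choice(pool, size=k, replace=False).tolist())
        layout = assign_plates(
            cohort,
            plexity=config.plexity,
            seed=config.seed,
            n_batches=config.n_batches,
            bridge_ids=bridge_ids,
        )
    else:
        layout = layout0
    design = build_panel_design(config)
    counts = simulate_assay(truth, design, layout, config)
    qpcr = simulate_qpcr_readout(truth, config)
    return SimStudy(
        config=config,
        cohort=cohort,
        truth=truth,
        design=design,
        layout=layout,
        counts=counts,
        qpcr=qpcr,
        bridge_ids=bridge_ids,
    )
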