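"""Genotype QC filters, HWE test vs an independent chi-square oracle,
baseline phenotype policy, scan calibration and recovery, cis/trans
boundaries, LD r^2, and greedy sentinel selection vs a brute-force
statsmodels reimplementation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import peaflow as pf
from peaflow.genetics import GenotypeMatrix, _hwe_pvalues


def make_G(geno: np.ndarray, chrom=None, pos=None, subjects=None) -> GenotypeMatrix:
    n, v = geno.shape
    subjects = subjects or [f"S{i}" for i in range(n)]
    vids = [f"v{j}" for j in range(v)]
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * v,
            "pos": pos if pos is not None else (np.arange(v) * 1000 + 1),
            "ref": "A",
            "alt": "G",
            "maf": np.nan,
        },
        index=pd.Index(vids, name="variant_id"),
    )
    return GenotypeMatrix(
        genotypes=pd.DataFrame(geno.astype(float), index=subjects, columns=vids),
        variants=variants,
    )


class TestHWE:
    def test_perfect_hwe(self):
        assert pf.hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # (30, 40, 30): chi2 = 4.0, p ~ 0.0455
        p = pf.hwe_test(30, 40, 30)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-10)
        assert p == pytest.approx(0.0455, abs=5e-4)

    def test_all_heterozygote_extreme_fails_filter(self):
        assert pf.hwe_test(0, 100, 0) < 0.001

    def test_monomorphic_fits_perfectly(self):
        assert pf.hwe_test(50, 0, 0) == 1.0

    def test_matches_scipy_chisquare_oracle_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            counts = rng.integers(0, 200, size=3)
            if counts.sum() == 0:
                continue
            n = counts.sum()
            p_hat = (2 * counts[0] + counts[1]) / (2 * n)
            mine = pf.hwe_test(*counts)
            if p_hat in (0, 1):
                assert mine == 1.0
                continue
            expected = n * np.array([p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
            oracle = stats.chisquare(counts, expected, ddof=1).pvalue
            assert mine == pytest.approx(oracle, abs=1e-8)


class TestGenotypeQC:
    def test_subject_missingness_boundary(self):
        # 50 variants: 3 missing (6%) removed, 2 missing (4%) kept
        geno = np.ones((3, 50))
        geno[0, :3] = np.nan
        geno[1, :2] = np.nan
        # keep the variants themselves alive: balanced genotypes elsewhere
        rng = np.random.default_rng(1)
        geno[2, :] = rng.integers(0, 3, 50)
        G = make_G(geno)
        miss = G.genotypes.isna().mean(axis=1)
        keep = miss <= 0.05
        assert not keep.iloc[0] and keep.iloc[1] and keep.iloc[2]

    def test_maf_boundary(self):
        # 100 subjects; alt counts 8 (MAF .04, removed) vs 12 (MAF .06, kept)
        rng = np.random.default_rng(2)
        common = rng.integers(0, 3, size=(100, 1)).astype(float)
        rare = np.zeros((100, 1))
        rare[:8, 0] = 1
        ok = np.zeros((100, 1))
        ok[:12, 0] = 1
        G = make_G(np.hstack([common, rare, ok]))
        out, ledger = pf.genotype_qc(G, hwe_alpha=0.0)
        assert ledger["variants_removed_maf"] == 1
        assert "v1" not in out.genotypes.columns and "v2" in out.genotypes.columns

    def test_each_filter_trips_once_on_constructed_matrix(self):
        # 24 variants so one missing call is 1/24 ~ 4.2% of a subject's
        # genotypes (below the 5% subject cut), letting each filter trip
        # independently in the stated order
        n = 40
        rng = np.random.default_rng(3)
        filler = rng.binomial(2, 0.5, size=(n, 20)).astype(float)  # survivors
        hwe_ok = rng.binomial(2, 0.5, size=(n, 1)).astype(float)  # survivor
        call_bad = hwe_ok.copy()
        call_bad[: int(0.1 * n)] = np.nan  # 10% missing -> call-rate filter
        maf_bad = np.zeros((n, 1))
        maf_bad[0, 0] = 1.0  # MAF 1/80
        hwe_bad = np.ones((n, 1))  # all heterozygote
        geno = np.hstack([hwe_ok, call_bad, maf_bad, hwe_bad, filler])
        # one extra subject missing two of 24 variants (8.3% > 5%)
        extra = np.concatenate([[1.0, np.nan, 0.0, 1.0, np.nan], np.ones(19)])
        geno = np.vstack([geno, extra])
        G = make_G(geno)
        out, ledger = pf.genotype_qc(G)
        assert ledger["subjects_removed_missing"] == 1
        assert ledger["variants_removed_call_rate"] == 1
        assert ledger["variants_removed_maf"] == 1
        assert ledger["variants_removed_hwe"] == 1
        assert "v0" in out.genotypes.columns
        assert out.genotypes.shape == (n, 21)

    def test_empty_result_raises(self):
        G = make_G(np.ones((40, 2)))  # all heterozygote: chi2 = n, far past HWE cut
        with pytest.raises(ValueError, match="survived"):
            pf.genotype_qc(G)


class TestBaselinePhenotype:
    def _npx(self, triples):
        rows = [
            {"sample_id": s, "protein_id": "P0", "npx": v, "qc_flag": q}
            for s, v, q in triples
        ]
        return pd.DataFrame(rows)

    def _samples(self, n=3):
        return pd.DataFrame(
            {
                "sample_id": [f"a_v{v}" for v in range(1, n + 1)],
                "subject_id": "a",
                "visit": range(1, n + 1),
            }
        )

    def test_median_of_three_visits(self):
        npx = self._npx([("a_v1", 1.0, "pass"), ("a_v2", 2.0, "pass"), ("a_v3", 9.0, "pass")])
        base = pf.baseline_phenotype(npx, self._samples())
        assert base.loc["a", "P0"] == 2.0

    def test_flagged_visit_dropped_even_count_median(self):
        npx = self._npx([("a_v1", 1.0, "flagged"), ("a_v2", 2.0, "pass"), ("a_v3", 9.0, "pass")])
        base = pf.baseline_phenotype(npx, self._samples())
        assert base.loc["a", "P0"] == pytest.approx(5.5)

    def test_all_visits_flagged_gives_missing(self):
        npx = self._npx(
            [("a_v1", 1.0, "flagged"), ("a_v2", 2.0, "flagged"), ("b_v1", 3.0, "pass")]
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["a_v1", "a_v2", "b_v1"],
                "subject_id": ["a", "a", "b"],
                "visit": [1, 2, 1],
            }
        )
        base = pf.baseline_phenotype(npx, samples)
        assert "a" not in base.index or np.isnan(base.loc["a", "P0"])


class TestCisTrans:
    @pytest.mark.parametrize(
        "dist,expected",
        [(999_999, "cis"), (1_000_000, "cis"), (1_000_001, "trans")],
    )
    def test_one_megabase_rule(self, dist, expected):
        assert pf.classify_cis_trans("7", 5_000_000 + dist, "7", 5_000_000) == expected
        assert pf.classify_cis_trans("7", 5_000_000 - dist, "7", 5_000_000) == expected

    def test_cross_chromosome_is_always_trans(self):
        assert pf.classify_cis_trans("1", 100, "2", 100) == "trans"

    def test_partition_total_and_exclusive(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            lab = pf.classify_cis_trans(
                str(rng.integers(1, 23)),
                int(rng.integers(1, 10**8)),
                str(rng.integers(1, 23)),
                int(rng.integers(1, 10**8)),
            )
            assert lab in ("cis", "trans")


class TestLD:
    def test_identical_and_flipped_vectors(self):
        g = np.array([0, 1, 2, 0, 1, 2])
        assert pf.ld_r2(g, g) == pytest.approx(1.0)
        assert pf.ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_computation_verified_brute_force(self):
        g1 = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        g2 = np.array([0, 1, 0, 1, 2, 2], dtype=float)
        # brute force: r = cov / (sd1 sd2) from first principles
        r = ((g1 - g1.mean()) * (g2 - g2.mean())).sum() / np.sqrt(
            ((g1 - g1.mean()) ** 2).sum() * ((g2 - g2.mean()) ** 2).sum()
        )
        assert pf.ld_r2(g1, g2) == pytest.approx(r**2)
        assert pf.ld_r2(g1, g2) == pytest.approx(0.5625)

    def test_constant_vector_is_nan(self):
        assert np.isnan(pf.ld_r2([1, 1, 1, 1], [0, 1, 2, 0]))

    def test_missing_pairs_dropped(self):
        g1 = np.array([0, 1, 2, np.nan, 2])
        g2 = np.array([0, 1, 2, 1, np.nan])
        assert pf.ld_r2(g1, g2) == pytest.approx(1.0)


def _scan_inputs(n=200, beta=0.0, maf=0.3, noise=0.5, n_var=1, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, size=(n, n_var)).astype(float)
    age = rng.integers(50, 66, n).astype(float)
    sex = rng.integers(0, 2, n).astype(float)
    y = beta * g[:, 0] + 0.02 * age + 0.3 * sex + rng.normal(0, noise, n)
    subjects = [f"S{i}" for i in range(n)]
    baseline = pd.DataFrame({"P0": y}, index=subjects)
    G = make_G(g, subjects=subjects)
    cov = pd.DataFrame({"age": age, "sex": sex}, index=subjects)
    return baseline, G, cov


class TestScan:
    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(10)
        n, n_var, n_prot = 200, 50, 40  # 2000 independent null tests
        g = rng.binomial(2, 0.3, size=(n, n_var)).astype(float)
        subjects = [f"S{i}" for i in range(n)]
        baseline = pd.DataFrame(
            rng.normal(0, 1, size=(n, n_prot)),
            index=subjects,
            columns=[f"P{j}" for j in range(n_prot)],
        )
        cov = pd.DataFrame(
            {"age": rng.integers(50, 66, n), "sex": rng.integers(0, 2, n)}, index=subjects
        )
        res = pf.pqtl_scan(baseline, make_G(g, subjects=subjects), cov)
        rate = (res["p_value"] < 0.05).mean()
        assert 0.04 <= rate <= 0.06

    def test_injected_beta_recovered_within_two_se(self):
        hits = 0
        for rep in range(40):
            baseline, G, cov = _scan_inputs(beta=1.0, seed=100 + rep)
            res = pf.pqtl_scan(baseline, G, cov)
            row = res.iloc[0]
            hits += abs(row["beta"] - 1.0) < 2 * row["se"]
        assert hits >= 35  # ~95% coverage

    def test_matches_statsmodels_ols_oracle(self):
        import statsmodels.api as sm

        baseline, G, cov = _scan_inputs(beta=0.8, seed=7)
        res = pf.pqtl_scan(baseline, G, cov).iloc[0]
        X = sm.add_constant(
            np.column_stack([cov["age"], cov["sex"], G.genotypes["v0"]])
        )
        fit = sm.OLS(baseline["P0"], X).fit()
        assert res["beta"] == pytest.approx(fit.params.iloc[-1], rel=1e-8)
        assert res["se"] == pytest.approx(fit.bse.iloc[-1], rel=1e-8)
        assert res["p_value"] == pytest.approx(fit.pvalues.iloc[-1], rel=1e-6)

    def test_pvalues_invariant_to_affine_phenotype_rescaling(self):
        baseline, G, cov = _scan_inputs(beta=0.5, seed=8)
        r1 = pf.pqtl_scan(baseline, G, cov)
        r2 = pf.pqtl_scan(baseline * 3.0 + 10.0, G, cov)
        np.testing.assert_allclose(r1["p_value"], r2["p_value"], rtol=1e-9)

    def test_constant_genotype_skipped_with_reason(self):
        baseline, G, cov = _scan_inputs(seed=9)
        G.genotypes["v0"] = 1.0
        res = pf.pqtl_scan(baseline, G, cov)
        assert res["skipped"].iloc[0]
        assert not res["significant"].iloc[0]

    def test_permuted_genotypes_yield_no_bonferroni_hits(self):
        baseline, G, cov = _scan_inputs(beta=1.0, n_var=20, seed=11)
        rng = np.random.default_rng(12)
        perm = G.genotypes.sample(frac=1, random_state=5).set_axis(G.genotypes.index)
        Gp = GenotypeMatrix(genotypes=perm, variants=G.variants)
        res = pf.pqtl_scan(baseline, Gp, cov)
        assert res["significant"].sum() == 0

    def test_median_bias_small_across_maf_beta_grid(self):
        biases = []
        for maf in (0.1, 0.3, 0.5):
            for beta in (0.5, 1.0):
                cell = []
                for rep in range(30):
                    baseline, G, cov = _scan_inputs(
                        beta=beta, maf=maf, seed=1000 + int(maf * 100) + rep
                    )
                    cell.append(pf.pqtl_scan(baseline, G, cov)["beta"].iloc[0] - beta)
                biases.append(np.median(cell) / beta)
        assert np.median(np.abs(biases)) <= 0.05


def oracle_select_independent(results, G, baseline, covariates, r2=0.1, window=1_000_000, alpha=0.01):
    """Brute-force reimplementation of the sentinel/conditional rules using
    statsmodels OLS fits throughout; exhaustively rescans the candidate set
    at every step."""
    import statsmodels.api as sm

    subjects = baseline.index
    out = []
    for prot in sorted(results["protein_id"].unique()):
        grp = results[(results["protein_id"] == prot) & results["significant"]].copy()
        y = baseline.loc[subjects, prot].to_numpy()
        pool = {r.variant_id: (r.chrom, r.pos, r.p_value) for r in grp.itertuples()}
        current_p = {v: pool[v][2] for v in pool}
        sentinels = []
        while pool:
            sent = min(pool, key=lambda v: (current_p[v], pool[v][0], pool[v][1]))
            out.append((prot, sent))
            sentinels.append(sent)
            del pool[sent]
            schrom, spos, _ = (
                results[(results["protein_id"] == prot) & (results["variant_id"] == sent)]
                .iloc[0][["chrom", "pos", "p_value"]]
                .tolist()
            )
            g_sent = G.genotypes.loc[subjects, sent].to_numpy()
            for v in list(pool):
                vchrom, vpos, _ = pool[v]
                if str(vchrom) == str(schrom) and abs(vpos - spos) <= window:
                    gv = G.genotypes.loc[subjects, v].to_numpy()
                    if np.corrcoef(gv, g_sent)[0, 1] ** 2 > r2:
                        del pool[v]
            survivors = {}
            for v in list(pool):
                gv = G.genotypes.loc[subjects, v].to_numpy()
                X = sm.add_constant(
                    np.column_stack(
                        [covariates.loc[subjects].to_numpy()]
                        + [G.genotypes.loc[subjects, s].to_numpy() for s in sentinels]
                        + [gv]
                    )
                )
                fit = sm.OLS(y, X).fit()
                p = fit.pvalues[-1]
                if p < alpha:
                    survivors[v] = p
            pool = {v: pool[v] for v in survivors}
            current_p = survivors
    return sorted(out)


class TestSelectIndependent:
    def test_perfectly_linked_pair_keeps_one_sentinel(self):
        rng = np.random.default_rng(20)
        n = 150
        g = rng.binomial(2, 0.4, n).astype(float)
        geno = np.column_stack([g, g])
        subjects = [f"S{i}" for i in range(n)]
        y = 1.0 * g + rng.normal(0, 0.5, n)
        baseline = pd.DataFrame({"P0": y}, index=subjects)
        cov = pd.DataFrame(
            {"age": rng.integers(50, 66, n), "sex": rng.integers(0, 2, n)}, index=subjects
        )
        G = make_G(geno, pos=[1000, 2000], subjects=subjects)
        res = pf.pqtl_scan(baseline, G, cov, alpha=0.05, bonferroni_divisor=1)
        ind = pf.select_independent(res, G, baseline, cov)
        assert len(ind) == 1

    def test_two_independent_causal_variants_both_retained(self):
        rng = np.random.default_rng(21)
        n = 300
        g1 = rng.binomial(2, 0.4, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        subjects = [f"S{i}" for i in range(n)]
        y = g1 + g2 + rng.normal(0, 0.5, n)
        baseline = pd.DataFrame({"P0": y}, index=subjects)
        cov = pd.DataFrame(
            {"age": rng.integers(50, 66, n), "sex": rng.integers(0, 2, n)}, index=subjects
        )
        G = make_G(np.column_stack([g1, g2]), pos=[1000, 2000], subjects=subjects)
        res = pf.pqtl_scan(baseline, G, cov, alpha=1e-4, bonferroni_divisor=1)
        ind = pf.select_independent(res, G, baseline, cov)
        assert len(ind) == 2
        assert set(ind["variant_id"]) == {"v0", "v1"}

    def test_never_more_loci_than_preconditional_hits(self, small_study, small_npx):
        study = small_study
        G, _ = pf.genotype_qc(study.truth.genotypes)
        baseline = pf.baseline_phenotype(small_npx.study(), study.cohort.samples)
        cov = study.cohort.subjects.set_index("subject_id")[["age", "sex"]].copy()
        cov["sex"] = (cov["sex"] == "male").astype(float)
        res = pf.pqtl_scan(baseline, G, cov, alpha=0.05)
        ind = pf.select_independent(res, G, baseline, cov)
        per_prot = res[res["significant"]].groupby("protein_id").size()
        for prot, grp in ind.groupby("protein_id"):
            assert len(grp) <= per_prot.get(prot, 0)

    def test_matches_brute_force_oracle_on_small_instances(self):
        mismatches = []
        for inst in range(25):
            rng = np.random.default_rng(3000 + inst)
            n = 120
            n_var = int(rng.integers(2, 11))
            # random LD: some variants copied with noise
            base_g = rng.binomial(2, 0.35, size=(n, n_var)).astype(float)
            for j in range(1, n_var):
                if rng.random() < 0.4:
                    src = int(rng.integers(0, j))
                    mask = rng.random(n) < 0.85
                    base_g[mask, j] = base_g[mask, src]
            subjects = [f"S{i}" for i in range(n)]
            k = int(rng.integers(1, min(3, n_var) + 1))
            causal = rng.choice(n_var, size=k, replace=False)
            y = base_g[:, causal].sum(axis=1) + rng.normal(0, 0.6, n)
            baseline = pd.DataFrame({"P0": y}, index=subjects)
            cov = pd.DataFrame(
                {"age": rng.integers(50, 66, n), "sex": rng.integers(0, 2, n)},
                index=subjects,
            )
            pos = rng.choice(np.arange(1, 3_000_000, 1000), size=n_var, replace=False)
            G = make_G(base_g, pos=pos, subjects=subjects)
            res = pf.pqtl_scan(baseline, G, cov, alpha=1e-3, bonferroni_divisor=1)
            ind = pf.select_independent(res, G, baseline, cov)
            mine = sorted((r.protein_id, r.variant_id) for r in ind.itertuples())
            oracle = oracle_select_independent(res, G, baseline, cov)
            if mine != oracle:
                mismatches.append(inst)
        assert mismatches == []
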