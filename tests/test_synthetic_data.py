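import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from famseg import synthetic_data as sd
from famseg.pedio import MISSING, read_ped, read_vcf, validate_mendelian
from famseg.phenostats import anova_oneway
from famseg.prioritize import prioritize_variants
from famseg.segregation import segregation_filter


class TestTemplate:
    def test_structure(self):
        ped = sd.four_generation_template()
        assert len(ped) == 32
        gens = {i.generation_label.split(":")[0] for i in ped.individuals}
        assert gens == {"I", "II", "III", "IV"}
        # first-cousin loop: IV-4's parents share grandparents I-1/I-2
        iv4 = ped["IV-4"]
        f, m = ped[iv4.father_id], ped[iv4.mother_id]
        def grandparents(ind):
            out = set()
            for pid in (ind.father_id, ind.mother_id):
                gp = ped[pid]
                out.update(x for x in (gp.father_id, gp.mother_id) if x)
            return out

        assert {"I-1", "I-2"} <= grandparents(f) & grandparents(m)

    def test_genotyped_subset(self):
        ped = sd.four_generation_template()
        assert len(sd.TEMPLATE_GENOTYPED) == 20
        assert set(sd.TEMPLATE_GENOTYPED) <= set(ped.ids())


class TestGeneDrop:
    def test_no_recombination_copies_parent_haplotype(self):
        ped = sd.four_generation_template()
        cfg = sd.SimulationConfig(n_variants=300, recombination=0.0, seed=2)
        matrix, truth = sd.gene_drop(cfg, ped)
        col = {s: j for j, s in enumerate(truth.sample_ids)}
        for ind in ped.individuals:
            if ind.is_founder:
                continue
            j, fj, mj = col[ind.id], col[ind.father_id], col[ind.mother_id]
            pat = truth.paternal_haplotypes[:, j]
            assert (np.array_equal(pat, truth.paternal_haplotypes[:, fj]) or
                    np.array_equal(pat, truth.maternal_haplotypes[:, fj]))
            mat = truth.maternal_haplotypes[:, j]
            assert (np.array_equal(mat, truth.paternal_haplotypes[:, mj]) or
                    np.array_equal(mat, truth.maternal_haplotypes[:, mj]))

    def test_founder_frequency_concentration(self):
        """Realised founder alt frequency concentrates on the nominal 0.3."""
        from famseg.pedio import Individual, Pedigree
        inds = [Individual(id=f"F{i}", sex="male") for i in range(500)]
        ped = Pedigree(inds)
        cfg = sd.SimulationConfig(n_variants=2000, founder_freqs=0.3, seed=3)
        matrix, truth = sd.gene_drop(cfg, ped)
        freq = truth.true_dosage().mean() / 2
        assert 0.29 < freq < 0.31

    def test_error_free_output_mendelian_clean(self):
        ped = sd.four_generation_template()
        cfg = sd.SimulationConfig(n_variants=1000, seed=4)
        matrix, _ = sd.gene_drop(cfg, ped)
        assert validate_mendelian(ped, matrix) == []

    def test_observed_consistent_with_truth_after_masking(self):
        ped = sd.four_generation_template()
        cfg = sd.SimulationConfig(n_variants=500, genotype_error_rate=0.02,
                                  genotype_missing_rate=0.05, seed=6)
        matrix, truth = sd.gene_drop(cfg, ped)
        true_d = truth.true_dosage()
        obs = matrix.genotypes
        assert np.all(obs[truth.missing_mask] == MISSING)
        clean = ~truth.missing_mask & ~truth.error_mask
        assert np.array_equal(obs[clean], true_d[clean])
        flipped = truth.error_mask & ~truth.missing_mask
        assert np.all(obs[flipped] != true_d[flipped])
        assert np.all(np.abs(obs[flipped] - true_d[flipped]) == 1)

    def test_determinism(self):
        ped = sd.four_generation_template()
        cfg = sd.SimulationConfig(n_variants=200, seed=9)
        m1, t1 = sd.gene_drop(cfg, ped)
        m2, t2 = sd.gene_drop(cfg, ped)
        assert np.array_equal(m1.genotypes, m2.genotypes)
        assert np.array_equal(t1.paternal_haplotypes, t2.paternal_haplotypes)


class TestAffection:
    def drop(self, seed=0):
        ped = sd.four_generation_template()
        cfg = sd.SimulationConfig(n_variants=11, causal_index=5, seed=seed)
        return sd.gene_drop(cfg, ped)

    def test_deterministic_penetrance(self):
        matrix, truth = self.drop()
        aff = sd.assign_affection(truth, (0.0, 1.0), 5, seed=1)
        dosage = truth.true_dosage()[5]
        for j, sid in enumerate(truth.sample_ids):
            assert (aff[sid] == "affected") == (dosage[j] >= 1)

    def test_null_model_independent_of_genotype(self):
        """With f1 = f0 affection carries no genotype signal: carrier and
        noncarrier affection rates match across seeds."""
        rates = {True: [0, 0], False: [0, 0]}  # carrier -> [affected, total]
        for seed in range(40):
            matrix, truth = self.drop(seed)
            aff = sd.assign_affection(truth, (0.5, 0.5), 5, seed=seed)
            dosage = truth.true_dosage()[5]
            for j, sid in enumerate(truth.sample_ids):
                carrier = dosage[j] >= 1
                rates[carrier][0] += aff[sid] == "affected"
                rates[carrier][1] += 1
        r_car = rates[True][0] / rates[True][1]
        r_non = rates[False][0] / rates[False][1]
        assert abs(r_car - 0.5) < 0.06
        assert abs(r_non - 0.5) < 0.06

    def test_template_calibrated_to_40pct_affected(self):
        """At f1=0.9 / f0=0.05 the template yields ~40% affected on
        average (the study family's diagnosed fraction)."""
        fracs = []
        for seed in range(400):
            cfg = sd.study_config(seed=seed, n_variants=15)
            ped, _, _ = sd.simulate_family(cfg)
            fracs.append(len(ped.members("affected")) / len(ped))
        assert 0.35 <= np.mean(fracs) <= 0.45


class TestCohort:
    def test_null_or_equal_freqs(self):
        cfg = sd.SimulationConfig(true_or=1.0, control_risk_freq=0.38,
                                  n_cases=30000, n_controls=30000, seed=5)
        dosages, status = sd.simulate_cohort(cfg)
        st = np.asarray(status)
        p_case = dosages[st == "case"].mean() / 2
        p_ctrl = dosages[st == "control"].mean() / 2
        assert abs(p_case - p_ctrl) < 0.01

    def test_odds_transform_closed_form(self):
        p0, theta = 0.38, 1.579
        p1 = theta * p0 / (1 - p0 + theta * p0)
        assert p1 == pytest.approx(0.59989 / 1.21989, abs=1e-4)
        cfg = sd.SimulationConfig(n_cases=50000, n_controls=100, seed=7)
        dosages, status = sd.simulate_cohort(cfg)
        st = np.asarray(status)
        p_hat = dosages[st == "case"].mean() / 2
        assert abs(p_hat - p1) < 0.01

    def test_group_sizes(self):
        cfg = sd.SimulationConfig(seed=1)
        dosages, status = sd.simulate_cohort(cfg)
        assert status.count("case") == 141
        assert status.count("control") == 130
        assert len(dosages) == 271


class TestPhenotypes:
    def test_noiseless_equals_group_mean(self):
        model = {"feno_ppb": {"GG": (20.0, 0.0), "GC": (15.0, 0.0),
                              "CC": (10.0, 0.0)}}
        df = sd.simulate_phenotypes(phenotype_model=model, seed=1)
        for grp, mean in (("GG", 20.0), ("GC", 15.0), ("CC", 10.0)):
            vals = df.loc[df["genotype_group"] == grp, "feno_ppb"]
            assert np.allclose(vals, mean)

    def test_age_moments_replicate_null_finding(self):
        """Groups drawn at the cohort's age moments are a null: ANOVA
        rarely rejects."""
        model = {"age_months": sd.COHORT_PHENOTYPE_MODEL["age_months"]}
        nonsig = 0
        n_rep = 120
        for seed in range(n_rep):
            df = sd.simulate_phenotypes(phenotype_model=model, seed=seed)
            groups = [g["age_months"].to_numpy()
                      for _, g in df.groupby("genotype_group")]
            nonsig += anova_oneway(groups).p > 0.05
        assert nonsig / n_rep >= 0.90

    def test_planted_one_sd_effect_high_power(self):
        model = {"x": {"GG": (0.0, 1.0), "GC": (1.0, 1.0), "CC": (0.0, 1.0)}}
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            df = sd.simulate_phenotypes(phenotype_model=model, seed=seed)
            groups = [g["x"].to_numpy() for _, g in df.groupby("genotype_group")]
            hits += anova_oneway(groups).p < 0.05
        assert hits / n_rep > 0.9

    def test_negative_sd_rejected(self):
        model = {"x": {"GG": (0.0, -1.0), "GC": (0, 1), "CC": (0, 1)}}
        with pytest.raises(ValueError):
            sd.simulate_phenotypes(phenotype_model=model, seed=0)

    def test_covariate_effects_enter_linearly(self):
        model = {"x": {"GG": (0.0, 0.0), "GC": (0.0, 0.0), "CC": (0.0, 0.0)}}
        df = sd.simulate_phenotypes(phenotype_model=model, seed=3,
                                    covariate_effects={"x": {"age": 2.0}})
        assert np.allclose(df["x"], 2.0 * df["age"], atol=1e-6)


class TestFixture:
    def test_fixture_parses_and_recovers_causal(self, tmp_path):
        """The study-shaped bundle round-trips through the readers and the
        segregate -> prioritize path keeps the planted variant at tier 1."""
        cfg = sd.study_config(seed=5, n_variants=801)
        cfg.penetrance_f0, cfg.penetrance_f1 = 0.0, 1.0
        paths = sd.make_fixture(cfg, tmp_path / "fx")
        ped = read_ped(paths["family_ped"])
        matrix = read_vcf(paths["family_vcf"])
        truth = json.loads(paths["truth_json"].read_text())
        res = segregation_filter(matrix, ped)
        seg = [r for r in res if r.status == "segregating"]
        assert truth["causal_index"] in {r.variant_index for r in seg}
        known = set(paths["known_genes"].read_text().split())
        assert truth["causal_gene"] not in known
        calls = prioritize_variants(seg, matrix, known)
        tier1 = {c.variant_index for c in calls if c.tier == 1}
        assert truth["causal_index"] in tier1

    def test_fixture_deterministic(self, tmp_path):
        cfg = sd.study_config(seed=21, n_variants=101)
        p1 = sd.make_fixture(cfg, tmp_path / "a")
        p2 = sd.make_fixture(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_cohort_files_consistent(self, tmp_path):
        cfg = sd.study_config(seed=2, n_variants=101)
        paths = sd.make_fixture(cfg, tmp_path / "fx")
        cohort = read_vcf(paths["cohort_vcf"])
        status = pd.read_csv(paths["status_csv"])
        assert cohort.sample_ids == status["sample_id"].tolist()
        assert cohort.n_variants == 1
        assert cohort.variants[0].rsid == "rs10839616"


class TestEndToEndSensitivity:
    def test_filter_sensitivity_one_under_full_penetrance(self):
        for seed in range(6):
            cfg = sd.study_config(seed=seed, n_variants=301)
            cfg.penetrance_f0, cfg.penetrance_f1 = 0.0, 1.0
            ped, matrix, truth = sd.simulate_family(cfg)
            res = segregation_filter(matrix, ped)
            assert res[truth.causal_index].status == "segregating"

    def test_specificity_improves_with_more_unaffected(self):
        """Fixing the causal signal, the number of background variants
        passing the filter shrinks as the unaffected panel grows."""
        from conftest import make_matrix, nuclear_pedigree
        passed = []
        for n_unaff in (3, 6, 9):
            ped = nuclear_pedigree(5, n_unaff)
            total = 0
            for seed in range(3):
                rng = np.random.default_rng(100 + seed)
                geno = rng.binomial(2, 0.25,
                                    size=(500, 5 + n_unaff)).astype(np.int8)
                samples = [f"A{i}" for i in range(5)] + \
                          [f"U{i}" for i in range(n_unaff)]
                res = segregation_filter(
                    make_matrix(geno, sample_ids=samples), ped)
                total += sum(r.status == "segregating" for r in res)
            passed.append(total)
        assert passed[0] >= passed[1] >= passed[2]
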