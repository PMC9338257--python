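"""Synthetic breeding-program generator: gene dropping, pedigree consistency,
inbreeding decay and exact phenotype variance shares."""

import numpy as np
import pytest

import cottongp as cg


class TestConfigValidation:
    def test_bad_shares(self):
        with pytest.raises(ValueError):
            cg.TraitConfig(h2=0.7, year_share=0.2, experiment_share=0.2)
        with pytest.raises(ValueError):
            cg.TraitConfig(h2=0.0)
        with pytest.raises(ValueError):
            cg.TraitConfig(n_qtl=0, h2=0.5)

    def test_too_many_crosses(self):
        with pytest.raises(ValueError, match="crosses"):
            cg.SimConfig(n_founders=3, n_families=10)

    def test_qtl_exceeding_markers(self):
        cfg = cg.SimConfig(
            n_founders=10,
            n_families=4,
            offspring_per_family=4,
            n_markers=50,
            traits={"t": cg.TraitConfig(n_qtl=200, h2=0.5)},
        )
        with pytest.raises(ValueError, match="n_qtl"):
            cg.simulate_study(cfg)


class TestGeneDropping:
    def test_reproducible(self):
        cfg = cg.SimConfig(
            n_founders=12,
            n_families=5,
            offspring_per_family=6,
            n_markers=100,
            seed=3,
            traits={"trait": cg.TraitConfig(n_qtl=40, h2=0.5)},
        )
        s1 = cg.simulate_study(cfg)
        s2 = cg.simulate_study(cfg)
        np.testing.assert_array_equal(s1.genotypes.dosages, s2.genotypes.dosages)
        assert s1.phenotypes.data.equals(s2.phenotypes.data)

    def test_layout(self):
        cfg = cg.SimConfig(
            n_founders=12,
            n_families=5,
            offspring_per_family=6,
            n_markers=100,
            n_years=3,
            seed=3,
        )
        s = cg.simulate_breeding_program(cfg)
        assert s.genotypes.n_lines == 30
        assert len(s.families) == 5
        assert all(len(v) == 6 for v in s.families.values())
        # families round-robin over year cohorts
        meta = s.line_meta
        fam_year = meta.drop_duplicates("family").set_index("family")["year"]
        years = sorted(fam_year.unique())
        assert len(years) == 3
        assert fam_year["FAM001"] == fam_year["FAM004"] == years[0]
        assert fam_year["FAM002"] == fam_year["FAM005"] == years[1]

    def test_pedigree_records_selfing_chain(self):
        cfg = cg.SimConfig(
            n_founders=6,
            n_families=2,
            offspring_per_family=3,
            selfing_generations=3,
            n_markers=50,
            seed=1,
        )
        s = cg.simulate_breeding_program(cfg)
        parents = s.pedigree.parents
        # line <- S3 <- S2 <- F1 <- founders
        lid = "FAM001_L01"
        s3 = parents[lid][0]
        assert s3 == f"{lid}_S3" and parents[lid] == (s3, s3)
        s2 = parents[s3][0]
        assert s2 == f"{lid}_S2"
        f1 = parents[s2][0]
        assert f1 == "FAM001_F1"
        p1, p2 = parents[f1]
        assert p1.startswith("P") and p2.startswith("P")

    def test_f1_offspring_are_distinct_full_sibs(self):
        cfg = cg.SimConfig(
            n_founders=6,
            n_families=1,
            offspring_per_family=8,
            selfing_generations=0,
            n_markers=400,
            seed=2,
        )
        s = cg.simulate_breeding_program(cfg)
        X = s.genotypes.dosages
        # siblings must not be genetically identical copies of one F1
        assert not np.array_equal(X[0], X[1])
        # every line's parents are the two founders of the cross
        for lid in s.families["FAM001"]:
            p1, p2 = s.pedigree.parents[lid]
            assert p1.startswith("P") and p2.startswith("P")

    def test_explicit_crosses_respected(self):
        cfg = cg.SimConfig(
            n_founders=5,
            n_families=2,
            offspring_per_family=3,
            n_markers=50,
            crosses=[(0, 1), (0, 2)],
            seed=4,
        )
        s = cg.simulate_breeding_program(cfg)
        f1_parents = {
            fam: s.pedigree.parents[f"{fam}_F1"] for fam in ("FAM001", "FAM002")
        }
        assert f1_parents["FAM001"] == ("P001", "P002")
        assert f1_parents["FAM002"] == ("P001", "P003")

    def test_heterozygosity_decays_by_half_per_selfing(self):
        # E[het] at generation F(1+g) is mean_j 2 p_j (1-p_j) * (1/2)^g
        cfg = cg.SimConfig(
            n_founders=30,
            n_families=20,
            offspring_per_family=10,
            selfing_generations=3,
            n_markers=2000,
            seed=5,
            traits={},
        )
        s = cg.simulate_breeding_program(cfg)
        het = (s.genotypes.dosages == 1.0).mean()
        expected = float(np.mean(2 * s.founder_freqs * (1 - s.founder_freqs))) * 0.5**3
        assert het == pytest.approx(expected, rel=0.1)

    def test_genotypes_consistent_with_pedigree(self):
        # realized G and expected A must correlate strongly across line pairs
        cfg = cg.SimConfig(
            n_founders=10,
            n_families=6,
            offspring_per_family=8,
            selfing_generations=1,
            n_markers=1500,
            seed=6,
            traits={},
        )
        s = cg.simulate_breeding_program(cfg)
        g = cg.filter_markers(s.genotypes, 0.0, 0.025)
        G = cg.compute_grm(g, allele_freq=None)
        A = cg.compute_nrm(s.pedigree, ids=list(G.ids))
        iu = np.triu_indices(G.n, k=1)
        assert np.corrcoef(G.values[iu], A.values[iu])[0, 1] > 0.8


class TestPhenotypes:
    def test_exact_variance_shares(self):
        cfg = cg.SimConfig(
            n_founders=20,
            n_families=10,
            offspring_per_family=10,
            n_markers=500,
            n_years=3,
            experiments_per_year=2,
            seed=7,
            traits={"t": cg.TraitConfig(n_qtl=100, h2=0.4, year_share=0.2,
                                        experiment_share=0.1, mean=5.0)},
        )
        s = cg.simulate_study(cfg)
        truth = s.truth["t"]
        tbv = truth["tbv"].to_numpy()
        assert np.var(tbv) == pytest.approx(0.4, abs=1e-10)
        assert truth["shares"]["residual"] == pytest.approx(0.3)
        y = s.phenotypes.data["t"].to_numpy()
        assert y.mean() == pytest.approx(5.0, abs=0.2)
        # components are scaled independently, so total variance is near 1
        assert np.var(y) == pytest.approx(1.0, abs=0.35)

    def test_single_year_share_forced_to_zero(self):
        cfg = cg.SimConfig(
            n_founders=20,
            n_families=8,
            offspring_per_family=6,
            n_markers=300,
            n_years=1,
            experiments_per_year=1,
            seed=8,
            traits={"t": cg.TraitConfig(n_qtl=50, h2=0.5, year_share=0.2,
                                        experiment_share=0.1)},
        )
        s = cg.simulate_study(cfg)
        shares = s.truth["t"]["shares"]
        assert shares["year"] == 0.0
        assert shares["experiment"] == 0.0
        assert shares["residual"] == pytest.approx(0.5)

    def test_tbv_predicts_phenotype_at_h2(self):
        cfg = cg.SimConfig(
            n_founders=40,
            n_families=40,
            offspring_per_family=8,
            n_markers=800,
            n_years=1,
            experiments_per_year=1,
            seed=9,
            traits={"t": cg.TraitConfig(n_qtl=150, h2=0.5, year_share=0.0,
                                        experiment_share=0.0)},
        )
        s = cg.simulate_study(cfg)
        y = s.phenotypes.data.set_index("line_id")["t"]
        tbv = s.truth["t"]["tbv"]
        r2 = np.corrcoef(tbv.loc[y.index], y)[0, 1] ** 2
        assert r2 == pytest.approx(0.5, abs=0.1)

    def test_epistatic_trait_generated(self):
        cfg = cg.SimConfig(
            n_founders=20,
            n_families=8,
            offspring_per_family=6,
            n_markers=200,
            seed=10,
            traits={"t": cg.TraitConfig(n_qtl=20, h2=0.4, epistatic_pairs=5)},
        )
        s = cg.simulate_study(cfg)
        assert np.isfinite(s.phenotypes.data["t"]).all()
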