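import numpy as np
import pytest

from reefadmix.dstat import QuartetHypothesis, count_patterns, d_statistic
from reefadmix.snp_io import read_vcf
from reefadmix.synthetic_data import (
    ABBA,
    BABA,
    SimulationConfig,
    emit_popmap,
    emit_vcf,
    expected_d,
    pattern_probabilities,
    popmap,
    simulate_site_patterns,
)

from oracles import oracle_pattern_probabilities

H = QuartetHypothesis("H1", "P1", "P2", "P3", "O")
CLEAN = dict(het_rate=0.0, missing_rate=0.0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sites": 0},
            {"gamma": 1.5},
            {"internal_branch_T": -1.0},
            {"admix_pair": ("P1", "P1")},
            {"admix_pair": ("P1", "O")},
            {"qual_range": (0.0, 10.0)},
            {"mutation_weighting": "uniform"},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestLimitCases:
    def test_no_ils_no_admixture_gives_no_discordance(self):
        cfg = SimulationConfig(n_sites=5000, internal_branch_T=50.0, gamma=0.0,
                               seed=3, **CLEAN)
        _, m = simulate_site_patterns(cfg)
        c = count_patterns(m, H)
        assert c.n_abba == 0 and c.n_baba == 0

    def test_pure_ils_d_within_mc_error_of_zero(self):
        cfg = SimulationConfig(n_sites=50_000, internal_branch_T=1.0, gamma=0.0,
                               seed=5, **CLEAN)
        _, m = simulate_site_patterns(cfg)
        c = count_patterns(m, H)
        d, _, _ = d_statistic(c)
        se = 1.0 / np.sqrt(c.n_abba + c.n_baba)  # binomial MC error on D
        assert abs(d) <= 3 * se

    def test_admixture_d_matches_enumeration_oracle(self):
        cfg = SimulationConfig(n_sites=50_000, internal_branch_T=1.0, gamma=0.3,
                               admix_pair=("P1", "P3"), seed=7, **CLEAN)
        _, m = simulate_site_patterns(cfg)
        c = count_patterns(m, H)
        d, _, _ = d_statistic(c)
        d_exp = expected_d(cfg)
        assert d_exp < 0
        se = 1.0 / np.sqrt(c.n_abba + c.n_baba)
        assert d == pytest.approx(d_exp, abs=3 * se)


class TestDeterminismAndEmission:
    def test_identical_seed_identical_output(self):
        cfg = SimulationConfig(n_sites=500, seed=9)
        p1, m1 = simulate_site_patterns(cfg)
        p2, m2 = simulate_site_patterns(cfg)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(m1.genotypes, m2.genotypes)
        assert [s.qual for s in m1.sites] == [s.qual for s in m2.sites]

    def test_vcf_round_trip_and_qual_range(self, tmp_path):
        cfg = SimulationConfig(n_sites=300, seed=2, missing_rate=0.2, het_rate=0.1)
        _, m = simulate_site_patterns(cfg)
        path = tmp_path / "sim.vcf"
        emit_vcf(m, path)
        back = read_vcf(path)
        assert back.sample_ids == m.sample_ids
        np.testing.assert_array_equal(back.genotypes, m.genotypes)
        quals = [s.qual for s in back.sites]
        assert all(cfg.qual_range[0] <= q <= cfg.qual_range[1] for q in quals)

    def test_masked_genotypes_serialize_as_missing(self, tmp_path):
        cfg = SimulationConfig(n_sites=200, seed=4, missing_rate=0.5)
        _, m = simulate_site_patterns(cfg)
        path = tmp_path / "sim.vcf"
        emit_vcf(m, path)
        assert "./." in path.read_text()

    def test_popmap_emission(self, tmp_path):
        cfg = SimulationConfig(n_sites=10, samples_per_lineage=3)
        path = tmp_path / "pm.tsv"
        emit_popmap(popmap(cfg), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 12
        assert lines[0] == "P1_1\tP1"

    def test_multi_sample_lineages_share_underlying_allele(self):
        cfg = SimulationConfig(n_sites=100, samples_per_lineage=4, seed=6, **CLEAN)
        pats, m = simulate_site_patterns(cfg)
        assert m.n_samples == 16
        # without noise every sample of a lineage is homozygous for its allele
        for k in range(4):
            block = m.genotypes[4 * k : 4 * (k + 1)]
            assert (block == block[0]).all()


class TestPatternDistribution:
    def test_probabilities_sum_to_one(self):
        cfg = SimulationConfig(gamma=0.25, internal_branch_T=0.7)
        assert sum(pattern_probabilities(cfg).values()) == pytest.approx(1.0)

    @pytest.mark.parametrize("gamma", [0.0, 0.3])
    def test_matches_independent_enumeration(self, gamma):
        cfg = SimulationConfig(gamma=gamma, internal_branch_T=1.2,
                               admix_pair=("P2", "P3"))
        ours = pattern_probabilities(cfg)
        theirs = oracle_pattern_probabilities(1.2, gamma, "P2", "P3")
        assert set(ours) == set(theirs)
        for pat, p in theirs.items():
            assert ours[pat] == pytest.approx(p)

    def test_empirical_frequencies_within_3_mc_se(self):
        cfg = SimulationConfig(n_sites=100_000, gamma=0.2, internal_branch_T=0.8,
                               seed=13, **CLEAN)
        pats, _ = simulate_site_patterns(cfg)
        probs = pattern_probabilities(cfg)
        n = cfg.n_sites
        observed = {}
        for row in pats:
            key = tuple(int(x) for x in row)
            observed[key] = observed.get(key, 0) + 1
        for pat, p in probs.items():
            freq = observed.get(pat, 0) / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) <= 3 * se + 1e-12, pat

    def test_exchangeability_p1_p2_symmetric_under_pure_ils(self):
        cfg = SimulationConfig(gamma=0.0, internal_branch_T=0.9)
        probs = pattern_probabilities(cfg)
        assert probs[ABBA] == pytest.approx(probs[BABA])
        swapped = {(b, a, c, o): p for (a, b, c, o), p in probs.items()}
        for pat, p in probs.items():
            assert swapped[pat] == pytest.approx(p)

    def test_expected_abs_d_nondecreasing_in_gamma(self):
        vals = [
            abs(expected_d(SimulationConfig(gamma=g, admix_pair=("P1", "P3"))))
            for g in (0.0, 0.1, 0.3, 0.5)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] > vals[0]

    def test_length_weighting_still_normalised_and_symmetric(self):
        cfg = SimulationConfig(gamma=0.0, internal_branch_T=1.0,
                               mutation_weighting="length")
        probs = pattern_probabilities(cfg)
        assert sum(probs.values()) == pytest.approx(1.0)
        assert probs[ABBA] == pytest.approx(probs[BABA])


class TestMsprimeCrossCheck:
    def test_gene_flow_direction_agrees_with_independent_coalescent_simulator(self):
        """An msprime model with a P1<->P3 pulse must give BABA excess (D<0)."""
        msprime = pytest.importorskip("msprime")
        from reefadmix.snp_io import SiteRecord, SnpMatrix

        Ne = 1000
        demography = msprime.Demography()
        for name in ("P1", "P2", "P3", "O", "A12", "A123", "ROOT"):
            demography.add_population(name=name, initial_size=Ne)
        demography.add_mass_migration(time=50, source="P3", dest="P1", proportion=0.4)
        demography.add_population_split(time=1000, derived=["P1", "P2"], ancestral="A12")
        demography.add_population_split(time=2000, derived=["A12", "P3"], ancestral="A123")
        demography.add_population_split(time=6000, derived=["A123", "O"], ancestral="ROOT")
        ts = msprime.sim_ancestry(
            samples={"P1": 1, "P2": 1, "P3": 1, "O": 1},
            demography=demography,
            sequence_length=400_000,
            recombination_rate=1e-7,
            random_seed=20,
        )
        ts = msprime.sim_mutations(ts, rate=2e-7, random_seed=21)
        gm = ts.genotype_matrix()  # sites x haplotypes (2 per sample)
        biallelic = np.array([len(v.alleles) == 2 for v in ts.variants()])
        gm = gm[biallelic]
        geno = (gm[:, 0::2] + gm[:, 1::2]).T.astype(np.int8)  # samples x sites
        sites = [
            SiteRecord("m", i + 1, "A", ("G",), 60.0) for i in range(geno.shape[1])
        ]
        m = SnpMatrix(["P1", "P2", "P3", "O"], sites, geno)
        c = count_patterns(m, H)
        d, _, p = d_statistic(c)
        assert d < 0
        assert p < 0.01
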