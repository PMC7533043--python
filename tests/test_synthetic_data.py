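import json

import numpy as np
import pytest

from facsex.degeneracy_filter import build_site_table, filter_complete_sites
from facsex.dfe import StepDemography
from facsex.diversity import diversity_from_matrix
from facsex.io_formats import AlignedGenomes
from facsex.polarize import build_derived_matrix, polarize_all
from facsex.synthetic_data import (
    SimulationTruth,
    effective_rates,
    forward_wright_fisher,
    simulate_population,
    simulate_sfs,
    simulate_two_lineages,
)


def four_gamete_violations(geno):
    """Count pairs of variant columns showing all four gametes."""
    n_viol = 0
    m = geno.shape[1]
    for i in range(m):
        for j in range(i + 1, m):
            pairs = {(a, b) for a, b in zip(geno[:, i], geno[:, j])}
            if len(pairs) == 4:
                n_viol += 1
    return n_viol


class TestEffectiveRates:
    def test_identities(self):
        theta, rho = effective_rates(u=1e-9, r=1e-8, N=1e6, F=0.98, S=0.001)
        assert theta == pytest.approx(4e6 * 1e-9 / 1.98)
        assert rho == pytest.approx(4e6 * 1e-8 * 0.001 * 0.02)

    def test_invalid_F(self):
        with pytest.raises(ValueError):
            effective_rates(1e-9, 1e-8, 1e6, 1.0, 0.001)


class TestSimulatePopulation:
    def test_zero_theta_identical_haplotypes(self):
        ps = simulate_population(6, 1000, 0.0, seed=1)
        assert (ps.matrix == ps.matrix[0]).all()
        assert ps.genotypes.shape[1] == 0

    def test_no_recombination_passes_four_gamete_test(self):
        ps = simulate_population(12, 20_000, 0.005, 0.0, seed=5)
        assert ps.genotypes.shape[1] > 10
        assert four_gamete_violations(ps.genotypes) == 0

    def test_recombination_produces_four_gamete_violations(self):
        ps = simulate_population(12, 50_000, 0.005, 0.01, seed=5)
        assert four_gamete_violations(ps.genotypes) > 0

    def test_mean_pi_matches_theta(self):
        """E[pi] = theta under the neutral coalescent."""
        pis = []
        for seed in range(1, 41):
            ps = simulate_population(20, 20_000, 0.01, seed=seed)
            pis.append(diversity_from_matrix(ps.matrix)[0])
        assert np.mean(pis) == pytest.approx(0.01, rel=0.05)

    def test_deterministic_given_seed(self):
        a = simulate_population(8, 5000, 0.01, 0.002, seed=42)
        b = simulate_population(8, 5000, 0.01, 0.002, seed=42)
        assert (a.matrix == b.matrix).all()
        assert (a.positions == b.positions).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_population(1, 100, 0.01)
        with pytest.raises(ValueError):
            simulate_population(5, 100, -0.01)


class TestSimulateTwoLineages:
    def test_outputs_validate_downstream_contracts(self, two_lineage):
        g = two_lineage.genomes
        # AlignedGenomes invariants enforced in the constructor; re-run them
        AlignedGenomes(matrix=g.matrix, strain_ids=g.strain_ids,
                       population=g.population, subgroup=g.subgroup,
                       latitude=g.latitude, chrom_map=g.chrom_map)
        assert set(g.outgroup_ids) == {"NA_OUT", "SC_OUT"}
        for gene in two_lineage.models:
            assert gene.cds_length % 3 == 0

    def test_no_shared_polymorphism(self, two_lineage):
        g = two_lineage.genomes
        table = filter_complete_sites(
            build_site_table(g, two_lineage.models), g
        )
        rows_a = g.rows_for_population("EU")
        rows_b = g.rows_for_population("FE")
        shared = 0
        for c in np.flatnonzero(table.complete):
            a = set(g.matrix[rows_a, c])
            b = set(g.matrix[rows_b, c])
            if len(a) > 1 and len(b) > 1:
                shared += 1
        assert shared == 0

    def test_rate_multiplier_shifts_mean_divergence(self):
        """Population A's stem rate multiplier surfaces as proportionally
        more DAs per strain (averaged over replicates)."""
        ratios = []
        for seed in (1, 2, 3, 4):
            ds = simulate_two_lineages(
                seed=seed, n_a=8, n_b=8, rate_multiplier_a=1.5,
                rate_multiplier_b=1.0, theta_a=0.0, theta_b=0.0,
                n_chromosomes=2, genes_per_chromosome=8, codons_per_gene=150,
            )
            ratios.append(ds.truth.extra["n_stem_a"] / ds.truth.extra["n_stem_b"])
        assert np.mean(ratios) == pytest.approx(1.5, rel=0.2)

    def test_latitude_effect_creates_negative_correlation(self):
        from facsex.individual_variation import covariate_correlation

        rs = []
        for seed in (3, 4, 5):
            ds = simulate_two_lineages(seed=seed, latitude_effect=4e-5)
            g = ds.genomes
            table = filter_complete_sites(build_site_table(g, ds.models), g)
            pol = polarize_all(g, table, "EU", "FE")
            dm = build_derived_matrix(pol, g, "EU", "FE")
            totals = dm.strain_totals("EU")
            lat = [g.latitude[s] for s in totals.index]
            rs.append(covariate_correlation(totals.to_numpy(), lat)["r"])
        assert np.mean(rs) < -0.3

    def test_deterministic_given_seed(self):
        a = simulate_two_lineages(seed=7, n_a=5, n_b=5, n_chromosomes=2,
                                  genes_per_chromosome=4, codons_per_gene=60)
        b = simulate_two_lineages(seed=7, n_a=5, n_b=5, n_chromosomes=2,
                                  genes_per_chromosome=4, codons_per_gene=60)
        assert (a.genomes.matrix == b.genomes.matrix).all()
        assert a.truth.strain_mutation_counts == b.truth.strain_mutation_counts


class TestTruthRoundTrip:
    def test_json_round_trip(self, tmp_path, two_lineage):
        truth = two_lineage.truth
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SimulationTruth.from_json(path)
        assert back == truth
        # file is plain JSON
        json.loads(path.read_text())


class TestSimulateSFS:
    def test_zero_sites_empty_spectrum(self):
        sfs, _ = simulate_sfs(StepDemography(), 8, (0, 0), seed=1)
        assert sfs.neutral.sum() == 0 and sfs.selected.sum() == 0

    def test_dfe_shifts_mass_toward_singletons(self):
        sfs, _ = simulate_sfs(StepDemography(), 12, (400_000, 400_000),
                              dfe=(0.23, 347.0), seed=6)
        neu, sel = sfs.neutral, sfs.selected
        ratio_neu = neu[1] / neu[2:11].sum()
        ratio_sel = sel[1] / sel[2:11].sum()
        assert ratio_sel > ratio_neu

    def test_deterministic_given_seed(self):
        a, _ = simulate_sfs(StepDemography(2, 0.5), 10, (1000, 1000), dfe=(0.3, 10), seed=3)
        b, _ = simulate_sfs(StepDemography(2, 0.5), 10, (1000, 1000), dfe=(0.3, 10), seed=3)
        assert (a.neutral == b.neutral).all() and (a.selected == b.selected).all()


class TestForwardWrightFisher:
    def test_neutral_diversity_scale(self):
        """Forward simulation cross-validates the coalescent scaling:
        E[pi] ~ 2 N u per site for haploids."""
        N, L, u = 100, 2000, 2e-5
        pis = []
        for seed in (1, 2, 3, 4, 5, 6):
            sample = forward_wright_fisher(N, L, u, n_sample=20, seed=seed)
            p = sample.mean(axis=0)
            pi = float(np.mean(2 * p * (1 - p) * 20 / 19))
            pis.append(pi)
        expected = 2 * N * u
        assert np.mean(pis) == pytest.approx(expected, rel=0.5)

    def test_large_N_rejected(self):
        with pytest.raises(ValueError):
            forward_wright_fisher(1000, 10, 1e-6)
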