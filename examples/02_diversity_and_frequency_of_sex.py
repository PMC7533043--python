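"""Nucleotide diversity, Tajima's D and the frequency of sex.

Computes 4-fold-site diversity for both simulated populations, then shows
the frequency-of-sex estimator on the published genome-wide summaries of
the two wild yeast populations (theta from 4-fold pi, rho from LDhat runs
normalised by the reference length, F = 0.98).
"""

from facsex import (
    annotate_degeneracy,
    build_ancestral_sequence,
    build_site_table,
    diversity_stats,
    filter_complete_sites,
    polarize_all,
    sex_frequency,
    simulate_two_lineages,
)

ds = simulate_two_lineages(seed=7)
g = ds.genomes
table = filter_complete_sites(build_site_table(g, ds.models), g)
pol = polarize_all(g, table, "EU", "FE")
table = annotate_degeneracy(build_ancestral_sequence(pol, g), ds.models, table)

for pop in ("EU", "FE"):
    s = diversity_stats(g, table, pop, "4fold")
    print(f"{pop}: n={s.n_strains}  pi4={s.pi:.5f}  theta_w={s.theta_w:.5f}  "
          f"Tajima's D={s.tajimas_d:+.2f}")
# pi approximates the per-bp scaled mutation rate of each population;
# lineage A was simulated with twice the polymorphism of lineage B.

# Frequency of sex from the published summaries: S = (rho/theta)(u/r)/[(1+F)(1-F)].
# u/r is calibrated from the European values; 1/S is the number of mitotic
# generations per sexual generation.
F = 0.98
pi = {"EU": 0.0021, "FE": 0.0011}
rho = {"EU": 0.000815, "FE": 0.000133}
u_over_r = 0.000621 * (1 + F) * (1 - F) * pi["EU"] / rho["EU"]
print(f"\ncalibrated u/r = {u_over_r:.3e}")
for pop in ("EU", "FE"):
    S, gens = sex_frequency(pi[pop], rho[pop], u_over_r, 1.0, F)
    print(f"{pop}: S = {S:.6f}  -> one sexual generation every {gens:,.0f} mitoses")
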