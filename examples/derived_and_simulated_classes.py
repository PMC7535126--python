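"""Build the two proxy variant classes from a toy genome pair.

Derived variants are positions where the reference differs from the
inferred ancestor (plus near-fixed segregating sites); simulated de novo
variants are drawn from windowed substitution rates estimated between the
same two genomes.
"""

from chcadd import simulator, synthetic, variants

world = synthetic.make_world(seed=3)

derived = variants.extract_derived_sites(world.reference, world.ancestor,
                                         world.population)
n_fixed = sum(s.source == "fixed-difference" for s in derived.sites)
n_highfreq = len(derived) - n_fixed
print(f"derived class: {len(derived):,} sites "
      f"({n_fixed:,} fixed differences, {n_highfreq:,} near-fixed "
      f"segregating at derived frequency > 90%)")

tables = simulator.estimate_rates(world.ancestor, world.reference,
                                  window_size=100_000)
sim = simulator.simulate_variants(tables, world.ancestor,
                                  n_target=len(derived), seed=3)
print(f"simulated class: {len(sim):,} de novo variants drawn from "
      f"{len(tables)} windowed rate tables")

balanced_d, balanced_s = variants.balance_classes(derived.sites,
                                                  sim.variants, seed=0)
print(f"balanced training classes: {len(balanced_d):,} vs {len(balanced_s):,}")
print("\nThe derived set is depleted of deleterious variants (it survived "
      "selection); the simulated set is not - that contrast is what the "
      "classifier learns.")
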