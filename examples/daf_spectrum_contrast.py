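"""Polarize population SNPs against the ancestral genome and contrast the
derived allele frequency (DAF) spectrum inside vs outside constrained
regions.

Mutation-rate differences do not shift allele frequencies; selection does.
An excess of rare derived alleles (DAF <= 10%) inside constrained regions
is the signature of purifying selection still acting on them.
"""

from chcadd import synthetic, variants

world = synthetic.make_world(seed=9)

cons_starts = [(r.start, r.end) for r in world.constrained_regions]


def constrained(pos0):
    return any(s <= pos0 < e for s, e in cons_starts)


inside, outside = [], []
rejected = 0
for rec in world.population:
    pv = variants.polarize(rec, world.ancestor)
    if isinstance(pv, variants.RejectionReason):
        rejected += 1
        continue
    (inside if constrained(rec.pos - 1) else outside).append(pv)

print(f"polarized {len(inside) + len(outside):,} SNPs "
      f"({rejected} rejected: ancestral state unusable)")
for name, group in (("constrained", inside), ("unconstrained", outside)):
    s = variants.daf_spectrum(group, cutoff=0.10)
    print(f"  {name:>13}: {s['n']:>6,} SNPs, "
          f"rare (DAF<=10%) fraction {s['rare_fraction']:.2f}")
print("\nThe higher rare fraction inside constrained regions mirrors the "
      "selection-driven spectrum shift seen in real conserved elements.")
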