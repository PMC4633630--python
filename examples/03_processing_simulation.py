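"""Simulate Dicer- vs Ago2-dependent maturation and Ago partitioning.

Three scenarios on the same 21-nt target: a ribozyme-enhanced saiRNA
(Ago2 route, guide only), the C75U dead-ribozyme control (long U-tail
overhang blocks Ago2 loading) and a classical 21-bp shRNA (Dicer route,
guide + passenger into all four Ago paralogues).
"""

from sairna import (
    NucSeq,
    SimOptions,
    TargetSite,
    build_sairna,
    build_shrna_classic,
    simulate,
)

window = NucSeq("AACUUCAGGGUCAGCUUGCCG", "RNA")
site = TargetSite("demo", 1, window, window.gc_fraction())

scenarios = [
    ("saiRNA-RZ (wild-type ribozyme)", build_sairna(site), SimOptions(ribozyme="WT")),
    ("saiRNA-mRZ (C75U, no cleavage)", build_sairna(site), SimOptions(ribozyme="C75U")),
    ("classical 21-bp shRNA", build_shrna_classic(site), SimOptions(ribozyme="NONE")),
]

for label, design, opts in scenarios:
    out = simulate(design, opts)
    print(f"\n=== {label} ===")
    print(f"category: {out.category.value}   precursor 3' overhang: {out.loading.overhang3} nt"
          f"   Ago2 load: {out.loading.ago2_load_weight:.2f}")
    for name, w in sorted(out.species_weights().items()):
        print(f"  {name:16s} weight {w:.3f}")
    print("Ago association (rows Ago1-4, weight per species):")
    print(out.ago_table.to_string())
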