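"""Design saiRNA hairpins against a target mRNA.

Scans every 21-nt window (17-bp stem + 4-nt loop), applies GC and
homopolymer filters, builds a guide-in-5'-arm hairpin per window and
ranks candidates by duplex-end asymmetry; prints the top designs with
ready-to-anneal cloning oligos for the H1 pSilencer-style vector.
"""

import random

from sairna import (
    DesignConstraints,
    NucSeq,
    SeqRecord,
    build_sairna,
    make_cloning_oligos,
    rank_candidates,
    scan_target_sites,
)

rng = random.Random(42)
mrna = SeqRecord("demo_mRNA", NucSeq("".join(rng.choice("ACGU") for _ in range(300)), "RNA"))

constraints = DesignConstraints(stem_len=17, loop_len=4)
sites = scan_target_sites(mrna, constraints)
print(f"{len(sites)} candidate windows pass the GC/homopolymer filters")

designs = [build_sairna(s, 17, 4) for s in sites]
for rank, r in enumerate(rank_candidates(designs)[:3], start=1):
    d = r.design
    print(f"\n#{rank}  window @ {d.site.start}  (GC {d.site.gc:.2f})")
    print(f"  guide   5'-{d.guide}-3'   (position 1 fixed as A)")
    print(f"  hairpin {d.arm5}|{d.loop}|{d.arm3}")
    print(f"  asymmetry ΔΔG = {r.subscores['asymmetry']:+.2f} kcal/mol "
          "(negative: guide 5' end less stable -> guide retained)")
    try:
        oligos = make_cloning_oligos(d, "H1_pSilencer")
        print(f"  top oligo    5'-{oligos.top}-3'")
        print(f"  bottom oligo 5'-{oligos.bottom}-3'")
    except Exception as e:
        print(f"  (not cloneable into this vector: {e})")
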