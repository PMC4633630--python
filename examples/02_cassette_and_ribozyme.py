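"""Model the expression cassette and HDV-ribozyme 3'-end homogenization.

A pol III transcript carries a ragged 4-6-U tail; fusing a self-cleaving
HDV ribozyme behind a 2-nt spacer trims the 3' end to a uniform 2-nt
overhang bearing a 2',3'-cyclic phosphate.  The C75U point mutant never
cleaves, leaving the long fusion transcript intact.
"""

from sairna import (
    NucSeq,
    TargetSite,
    attach_ribozyme,
    build_sairna,
    fold_hairpin,
    pnk_dephosphorylate,
    ribozyme_cleave,
    transcribe_pol3,
)

window = NucSeq("AACUUCAGGGUCAGCUUGCCG", "RNA")  # a real 21-nt siRNA target
site = TargetSite("demo", 1, window, window.gc_fraction())
design = build_sairna(site, stem_len=17, loop_len=4)
print(f"saiRNA core ({len(design.core)} nt): {design.core}")

for variant in ("WT", "C75U"):
    cassette = attach_ribozyme(design, variant)
    print(f"\n--- HDV ribozyme {variant} ---")
    for t in transcribe_pol3(cassette):
        res = ribozyme_cleave(t, cassette.ribozyme)
        if res.occurred:
            p = fold_hairpin(res.upstream, design)
            print(
                f"tail U{t.u_tail_len}: cleaved -> {len(res.upstream.seq)}-nt precursor, "
                f"3' overhang {p.overhang3} nt, 3' end {res.upstream.ends.three_prime}"
            )
        else:
            p = fold_hairpin(res.upstream, design)
            print(
                f"tail U{t.u_tail_len}: NOT cleaved -> {len(res.upstream.seq)}-nt fusion, "
                f"3' overhang {p.overhang3} nt"
            )

# the cyclic phosphate converts to a hydroxyl under ATP-free T4 PNK
cassette = attach_ribozyme(design, "WT")
t = transcribe_pol3(cassette)[0]
upstream = ribozyme_cleave(t, cassette.ribozyme).upstream
print(f"\nPNK: 3' {upstream.ends.three_prime} -> {pnk_dephosphorylate(upstream).ends.three_prime}")
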