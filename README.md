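# sairna

Design and in-silico processing of **ribozyme-enhanced saiRNA** and shRNA
gene-silencing constructs.

## The problem

Short-hairpin RNAs (shRNAs) expressed from pol III promoters are the
workhorse of stable RNAi, but Dicer-made siRNA duplexes load both strands
into all four Argonaute paralogues: the passenger strand and the
non-nucleolytic Ago1/3/4 drive miRNA-like off-target repression, and
abundant shRNA competes with endogenous miRNA biogenesis.

A **saiRNA** (single-stranded, Ago2-processed interfering RNA) sidesteps
this. It is a short hairpin with a 16–18 bp stem, a 5′ arm carrying the
guide strand, a loop complementary to the target, a fixed 5′ adenosine
and an engineered C/A mismatch opposite guide position 1. It is matured
not by Dicer but by Ago2, which slices the 3′ arm opposite guide
positions 10/11; the retained 5′ product is 3′-trimmed into mature
guides, and **the passenger strand is destroyed** — so passenger-seed
off-targets and antisense-transcript cleavage are structurally
impossible, and mature guides reside in Ago2 only.

The catch is the 3′ end: pol III termination leaves a 4–6-uridine tail,
and Ago2 only loads hairpins with a short (≈2 nt) 3′ overhang. Fusing a
self-cleaving **hepatitis delta virus (HDV) ribozyme** to the 3′ end
fixes this: the ribozyme cleaves immediately 5′ of its own sequence,
independent of upstream context, leaving a uniform 2-nt overhang with a
2′,3′-cyclic phosphate. The C75U point mutation abolishes catalysis and
serves as the negative control.

Stem length alone dictates the processing route:

| stem (bp) | category   | fate |
|-----------|------------|------|
| ≥ 21      | DICER      | 21–24-nt siRNA duplexes, both strands, all four Agos |
| 19–20     | dead zone  | Ago2-sliced intermediate > 30 nt; no mature siRNA |
| 16–18     | AGO2_SAI   | Ago2 slice + 3′ trimming; single-stranded guide, Ago2 only |
| < 16      | suboptimal | bound but unproductive |

This package implements the full reagent life cycle as a library:
target-window scanning and hairpin construction with duplex-end
asymmetry ranking (`sairna.designer`), expression-cassette and ribozyme
chemistry (`sairna.cassette`), deterministic processing simulation with
overhang-gated Ago2 loading and Ago partitioning (`sairna.processing`),
seed (guide positions 2–7) off-target scanning with a planted-truth
synthetic transcriptome (`sairna.offtarget`), and a desk-scale
small-RNA-seq profiler with a synthetic read generator
(`sairna.profiler`). A thin `sairna` CLI wraps the library.

## Worked example

```python
from sairna import (NucSeq, TargetSite, SimOptions, build_sairna,
                    attach_ribozyme, transcribe_pol3, ribozyme_cleave,
                    fold_hairpin, simulate)

window = NucSeq("AACUUCAGGGUCAGCUUGCCG", "RNA")   # 21-nt target site
site = TargetSite("demo", 1, window, window.gc_fraction())
design = build_sairna(site, stem_len=17, loop_len=4)
print(design.core)   # AGGCAAGCUGACCCUGAAGUUUCAGGGUCAGCUUGCCC (38 nt)

cassette = attach_ribozyme(design, "WT")          # + 2-nt spacer + HDV ribozyme
for t in transcribe_pol3(cassette):               # U4/U5/U6 tail ensemble
    p = fold_hairpin(ribozyme_cleave(t, cassette.ribozyme).upstream, design)
    print(t.u_tail_len, p.overhang3)              # 4 2 / 5 2 / 6 2
```

The guide is `AGGCAAGCUGACCCUGAAGUU`: a fixed 5′ A followed by the
reverse complement of the first 20 window nucleotides, so positions 2–21
pair the target while the 3′ arm ends in the engineered C mismatch.
Whatever the U-tail length, ribozyme scission leaves a 40-nt precursor
with a **2-nt 3′ overhang** and a cyclic-phosphate 3′ end — the form
Ago2 loads fully.

```python
out = simulate(design, SimOptions(ribozyme="WT"))
print(out.category.value, out.species_weights())
# AGO2_SAI {'intermediate': 0.2, 'mature_guide': 0.8}
```

The simulation emits the 28-nt Ago2-slicing intermediate
(stem + loop + (stem − 10) = 17 + 4 + 7) and 21–24-nt mature
single-stranded guides; no passenger species exists, and the Ago table
assigns mature guides to Ago2 alone. With the C75U ribozyme the
uncleaved precursor keeps its ~90-nt 3′ extension, the loading gate
closes, and mature guides all but vanish (weight ≤ 0.05) — the
dead-ribozyme control. A classical 21-bp shRNA instead returns Dicer
duplexes with guide *and* passenger reaching all four Agos.

See `examples/` for runnable scripts covering design, cassette
chemistry, processing, off-target attribution and library profiling.

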