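# Methods

This note documents the models behind the `sairna` package: what is
computed, under which assumptions, with which defaults, and what the
synthetic-data generators do and do not emulate.

## Coordinates, alphabets, end chemistry

All coordinates are 1-based and inclusive on the 5′→3′ strand of the
molecule under discussion; guide positions always number the guide 5′
end as 1 (so "seed = positions 2–7" reads off directly). Designs are
reported in the RNA alphabet and cloning oligos in DNA; U↔T conversion
is lossless and applied at module boundaries. IUPAC ambiguity codes are
rejected by default (a permissive read skips such records, which are
never eligible as design windows). Terminal chemistry is tracked as a
pair (5′: PPP/P/OH; 3′: OH/CyclicP/P): nascent transcripts carry 5′ PPP,
ribozyme-cleaved upstream products carry a 2′,3′-cyclic phosphate until
explicitly converted by the ATP-free T4 PNK step. End chemistry is
bookkeeping only — it does not alter loading or stability in the model,
matching the observation that cyclic-phosphate and hydroxyl 3′ ends
behave equivalently in silencing.

## Hairpin construction

A design consumes a target *window* of `stem_len + loop_len` nt (21 for
the canonical 17+4 saiRNA). The guide is a fixed 5′ A followed by the
reverse complement of window positions 1..n−1; pairing of guide position
1 with the target is not required (5′ A/U maximizes Ago loading and pol
III H1 initiation). The 5′ arm is the first `stem_len` guide
nucleotides, the loop the next `loop_len` (target-complementary for
saiRNA), and the 3′ arm the reverse complement of the 5′ arm with its
3′-terminal residue replaced by C (or A) so the 5′ A stays unpaired —
that engineered mismatch biases guide-strand retention. The mismatched
terminal position still counts toward the stated stem length. For
guide-in-5′-arm shRNAs with stems above 21 bp the window simply extends
into the mRNA context downstream of the canonical 21-nt target, since
the scanner takes windows directly from the transcript. Classical
shRNAs are built sense-arm-5′ / guide-arm-3′ with a fixed non-
complementary loop (default: the 6-nt TRC/pLKO.1 loop `CUCGAG`).

Window filters: GC fraction within [0.25, 0.75] by default (a
conventional designability band; configurable), and no homopolymer run
longer than 3 nt in the guide — which in particular rejects guides with
≥4 consecutive U, an internal pol III terminator.

## Duplex-end asymmetry

Strand retention follows the thermodynamic asymmetry rule: the strand
whose 5′ end is less stably paired is retained. The score sums
Watson–Crick nearest-neighbour stacking free energies (ΔG°37, Xia et
al. 1998 parameters embedded as constants) over the terminal 4-bp window
at each duplex end, with mismatched positions contributing zero, and
reports the guide-end minus passenger-end difference on the unwinding
(positive-stability) scale. Negative scores therefore favour guide
retention, and the score negates exactly under a strand swap. Candidate
ranking combines this with GC deviation from 0.5, guide homopolymer
length and an optional off-target load, under user weights; ties break
toward the 5′-most target position and the sort is stable.

## Expression cassette and ribozyme

The cassette is promoter (H1/U6 pol III or T7) + hairpin + spacer
(default `UU`, configurable 0–5 nt) + optional HDV ribozyme + poly-T
terminator (default 6 T, ≥5 required for pol III). The embedded default
ribozyme is the standard 84-nt HDV self-cleaving sequence with its
catalytic C at position 75; the C75U substitution flags it inactive.
Because published constructs use engineered ribozyme variants, the
ribozyme sequence, catalytic position and cleavage offset are fully
user-overridable.

Pol III transcription returns a weighted ensemble — insert plus a 4, 5
or 6-U tail, uniform weights by default (the tail-length *range* is well
established, its distribution is not; weights are configurable) — rather
than sampling, so default pipelines are deterministic. T7 transcription
returns the single full-length run-off product. Cleavage occurs
immediately 5′ of ribozyme nucleotide 1 regardless of upstream sequence
(HDV ribozymes need no upstream base pairing), conserving sequence:
upstream ⧺ downstream = input. The upstream product's 3′ overhang after
folding therefore equals the spacer length — 2 nt by default.

Folding is template-directed, not free-energy-based: the stem pairs are
the design's declared pairs, and the overhangs are the unpaired terminal
runs measured on the actual transcript. Predicting alternative folds is
out of scope; the designed hairpin is assumed to dominate.

## Processing model

Classification is piecewise-constant in stem length with breakpoints at
16, 19 and 21 (suboptimal < 16 ≤ saiRNA ≤ 18 < dead zone ≤ 20 < Dicer).

**Dicer route** (stem ≥ 21): duplexes with strand lengths 21–24 nt
(weights default 0.4/0.4/0.1/0.1, clipped to what the stem affords) and
2-nt 3′ overhangs; both strands are emitted as RISC cargo.

**Ago2 route** (stem 16–20): the 3′ arm is sliced between the residues
paired to guide positions 11 and 10 — the canonical Ago2 slicer
register, adopted as a fixed modelling choice since the register is only
characterized for the central cut. The retained 5′ product has length
`stem + loop + (stem − 10)`: 28 nt for 17+4, 32 nt for 19+4. For 16–18
bp stems the intermediate is 3′-trimmed into mature guides of
21..min(24, intermediate) nt (uniform weights by default; heterogeneity
is observed but unquantified), all sharing the precursor 5′ end. For
19–20 bp stems the intermediate (> 30 nt) is too stable to unwind and
trim: it is emitted as-is with no matures, and a diagnostic flag records
that such precursors are bound by both Dicer and Ago2. Passenger
species are structurally absent on this route. At steady state 20 % of
the processed flux is shown as intermediate and 80 % as matures — a
display convention for the co-existing pools, not a kinetic claim.

**Loading gate.** Ago2 loading is a step function of the precursor 3′
overhang: full at ≤ 2 nt, half at 3 nt, zero at ≥ 4 nt. The two
observed anchor states are a 2-nt overhang (binds) and a 4–6-nt U tail
(does not); the 3-nt half-weight point is a declared interpolation.
An un-loadable precursor still matures at a small leak rate (default
0.05), representing the minor 3′-trimmed short isoform of full-length
saiRNA seen on long exposures.

**Ago partitioning.** Dicer duplexes load guide and passenger into all
four Agos with equal weight (Ago4 down-weightable, as it is often below
detection). Ago2-route outcomes place intermediate and mature guide on
Ago2 only; Ago1/3/4 bind the unprocessed precursor. An optional Ago3
residual-slicer weight (default 0) and an Ago2-knockout switch (which
also abolishes all Ago2-route products) cover the perturbation
scenarios.

## Off-target model

The seed is the exact hexamer at strand positions 2–7; a UTR site is an
exact reverse-complement match, counted with overlaps. 7mer-m8/7mer-A1
site classes, conservation and context scores are deliberately out of
scope. Attribution filters genes at control FPKM ≥ 10, classifies
up/down at treated/control ratio ≥ 1.5 (ties included; no pseudocount by
default, since the FPKM floor removes zeros), and intersects the
downregulated set with seed-site presence independently per strand —
for saiRNA the passenger row is NA because the species does not exist.
Genes lacking UTR records count in up/down but are excluded from
attribution, with a logged count. When processing yields several mature
isoforms, the seed comes from the highest-weight one.

The synthetic transcriptome plants truth for recovery tests: background
UTRs (uniform-random, default 200–1200 nt) are rejection-sampled to be
seed-site-free, target genes receive 1–3 planted sites and a fixed fold
change, and baseline FPKM is log-normal (median ≈ e⁴ ≈ 55) floored at
the filter. Noise modes allow chance background sites and
seed-independent background downregulation, with site collisions
logged. It emulates site presence and fold changes only — not count
noise, isoform structure, 3′-UTR base composition or correlated
expression — so recovery tests validate the attribution logic, not
RNA-seq inference.

## Small-RNA profiler

Preprocessing clips each read at the first exact occurrence of the
adaptor's leading 6 nt, discards unclippable reads and clipped inserts
shorter than 19 nt, and collapses to unique sequences with
multiplicities. Classification assigns each unique read to the first
matching class in the fixed order construct → miRNA → tRNA → rRNA →
snoRNA → other → unmapped, where matching is exact (0-mismatch)
substring containment in the class's reference sequences — a desk-scale
equivalent of 0-mismatch genome alignment that preserves its semantics
on the supplied references; within-class multi-hits count once. miRNA
counting is 5′-anchored: the read must start exactly at the annotated
mature 5′ site, end within ±2 nt of the mature 3′ end, and any 3′
additions must be templated by the precursor (untemplated tailing is not
counted by default). Normalization is counts per million miRNA reads at
full precision. End-heterogeneity tabulates (5′, 3′) end pairs of reads
mapping inside the construct, assigns strands by the arm containing the
read 5′ end, and scores 5′ homogeneity as the modal-5′-position
fraction.

The read generator samples multinomially from simulated species
weights, optionally trims read ends with given probabilities
(extensions are not modelled — a sampled species has no flanking
context) and appends the adaptor, so libraries round-trip through the
profiler; proportions are recovered within binomial error.

## Numerical and degenerate-input choices

All ensembles are weight-normalized and asserted to sum to 1; nothing in
a default pipeline is sampled, and every sampling entry point takes an
explicit integer seed (numpy `default_rng`). Empty FASTA files parse to
empty collections; an empty UTR set yields an empty report; zero-depth
libraries are empty; a zero miRNA total is an error rather than a NaN.
Problem sizes in tests and the acceptance script are desk-scale by
design: windows of a few hundred nt, transcriptomes of 40–120 genes,
libraries of 10⁵ reads — large enough for 3σ binomial checks, small
enough to run in seconds.

## Known limitations

No kinetics anywhere (ribozyme cleavage, Dicer/Ago2 turnover and PARN
trimming are endpoint rules, not rate models); no free-energy folding of
precursors or targets; the slice register is fixed at guide 10/11 for
all stems although it is only established for canonical substrates; the
loading gate is a step function standing in for an unknown smooth
dependence; efficacy prediction (beyond end asymmetry and simple
filters) and chemical modification design are out of scope.
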