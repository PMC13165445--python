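# msapclade

Dominant-marker analysis for cultivar panels: **MSAP methylation typing**,
**Nei–Li / neighbor-joining clustering** with locus bootstrap, **parsimony
mapping** of binary morphological characters onto the resulting tree, and
**flow-cytometry ploidy / genome-size estimation**.

The package targets the common study design in ornamental-plant and crop
systematics where a panel of clonally propagated cultivars is fingerprinted
with AFLP and its methylation-sensitive variant MSAP, clustered, and then
compared against morphology and cytology. Because raw gel matrices are
rarely deposited, a first-class synthetic-panel generator reproduces the
statistical structure of such panels (two differentiated clades, planted
clade-private fragments, known methylation-type proportions, known character
step counts, known 2C values) so that every stage of the pipeline is
testable end to end against planted ground truth.

## The methods

**MSAP typing.** HpaII and MspI both cut 5′-CCGG but differ in methylation
sensitivity, so the presence pattern of a band across the paired
EcoRI/HpaII and EcoRI/MspI digests classifies its site: (1,1) → type I
(non-methylated), (0,1) → type II (fully methylated internal cytosines),
(1,0) → type III (hemimethylated), (0,0) → type IV (fully methylated).
Per-sample indices over the amplified panel of *n* loci:

    MSAP% = 100 · (I_ms + II + III + IV) / n
    fully methylated % = 100 · (II + IV) / n

where I_ms is the methylation-sensitive subset of type-I bands (those whose
locus carries a different type in at least one other sample).

**Clustering.** Dominant bands carry no information in shared absence, so
pairwise dissimilarity is the Nei–Li / Dice band-sharing form
`D = 1 − 2a/(2a + b + c)` (a = shared presences, b, c = private presences).
Trees are built by Saitou–Nei neighbor joining (exact on additive
distances), rooted on a designated outgroup, and internal branches are
assigned bootstrap percentages by resampling loci with replacement.

**Character mapping.** Binary morphological characters are optimized on the
fixed molecular tree under unordered (Fitch) parsimony — Hartigan's
generalization, so polytomies are handled exactly — and classified by step
count and the outgroup-polarized derived state: plesiomorphic (0 steps),
autapomorphy (1 step, one tip), synapomorphy (1 step, a clade), homoplastic
(>1 step).

**Cytometry.** With an internal standard of known genome size co-stained in
each run (default *Pisum sativum* 'Ctirad', 2C = 9.09 pg), the DNA index is
the ratio of the sample to the standard G1 peak mean; 2C (pg) = index ×
standard 2C; 1C (Mbp) = 2C/2 × 978; ploidy is the nearest integer multiple
of a known-diploid reference 2C.

## Worked example

```python
import msapclade as mc

cfg = mc.PanelConfig(seed=42)           # 2 + 12 cultivars + outgroup
aflp, hpa, msp, truth = mc.simulate_marker_panel(cfg)

m = mc.filter_monomorphic(aflp)         # 549 loci -> 292 polymorphic
tree = mc.bootstrap_supports(m, n_reps=1000, seed=42)
print(mc.support_for_clade(tree, truth.clade_a))   # 99.9
rooted = mc.root_with_outgroup(tree, "Outgroup")

print(mc.profile_all(hpa, msp).head(1))
#   sample  type_I  type_I_ms  type_II  type_III  type_IV  total_amplified  msap_pct  fully_methylated_pct
# cladeA_1     240        124      210       168       49              667     82.61                 38.83

tally = mc.clade_fragment_tally(
    hpa, msp, (list(truth.clade_a), list(truth.clade_b) + ["Outgroup"]))
print({t.value: v for t, v in tally.shared_all.items()})
# {'I': 116, 'II': 84, 'III': 77, 'IV': 0}

cm, ct = mc.simulate_characters(rooted, 2, 1, 7, seed=42, outgroup="Outgroup")
print(mc.total_steps(rooted, cm))       # 17  (= planted 2·1 + 1 + 7·2)

h = mc.simulate_histogram(2.92, 9.09, cv=0.03, n_events=20000, seed=42)
(s, _), (std, _) = mc.find_peaks(h, 2)
two_c = mc.estimate_2c(mc.dna_index(s, std))
print(round(two_c, 2), mc.genome_size_mbp(two_c))  # 2.92 1427
```

Reading of the output: the 2-vs-12 clade split planted by the generator is
recovered with 99.9% bootstrap support; the planted shared-fragment counts
(116 type I, 84 type II, 77 type III) are recovered exactly by the clade
tally; the planted 17 parsimony steps are recovered exactly; and the
simulated 2.92 pg genome is recovered to the published rounding (2.92 pg,
~1427 Mbp, diploid).

The same operations are available from the shell via the `msapclade`
console script (`msapclade simulate panel`, `msapclade tree build`,
`msapclade msap type`, `msapclade charmap`, `msapclade ploidy`; see
`msapclade --help`).

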