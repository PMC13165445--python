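# Methods notes

This note records the models implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical conventions used throughout.

## Band matrices

A `BandMatrix` is a samples × loci table over {present = 1, absent = 0,
missing}. The canonical file orientation is gel-like (rows are loci,
columns are samples), with a flag for the transpose; missing cells are
written `?`. Labels are case-sensitive and whitespace-trimmed. Missing data
are excluded pairwise in distances; a locus with missing cells still counts
as *variable* when at least two observed states remain — a conservative
retention rule, since dropping such loci would discard real signal.

`filter_monomorphic` (retain loci with ≥2 distinct observed states) is the
standard pre-clustering step for dominant markers and is idempotent.
`merge_matrices` aligns rows by sample label, prefixes locus labels with
the source marker system, and produces a `COMBINED` matrix for
joint-dataset clustering.

## MSAP typing

The type map from paired digest states is fixed by enzyme chemistry:
(HpaII, MspI) = (1,1) → I, (0,1) → II, (1,0) → III, (0,0) → IV. Two
conventions needed a decision:

* **The type-IV panel problem.** A band absent from both digests in every
  sample is indistinguishable from a locus that does not exist, a known
  MSAP limitation. The locus panel is therefore the union of loci amplified
  in at least one sample/digest, and "absent in both digests" is scored IV
  only inside that panel. This reproduces the structure of published
  per-cultivar tables, where type-IV counts are reported against a common
  panel.
* **Methylation-sensitive type I.** The literature computes MSAP% over
  "total methylated bands" including a methylation-sensitive subset of
  type-I bands but rarely states the subset rule. Here a type-I site is
  methylation-sensitive when its locus carries a different observed type in
  at least one other sample (i.e. the locus is methylation-polymorphic).
  The predicate is a pluggable argument of `profile_sample` so
  intensity-based or other definitions can be substituted.
* **Fully-methylated ratio.** Published per-cultivar tables that print both
  the counts and the ratio are reproduced by (II + IV)/total, not by the
  occasionally stated IV/total; (II + IV)/total is therefore the default
  and `full_methylation_mode="IV"` is kept as a documented alternative.

Indices are reported rounded half-up to two decimals, the convention of the
printed tables (`round_half_up`, since Python's builtin rounds to even).

## Distances, neighbor joining, bootstrap

The Nei–Li / Dice form `D = 1 − 2a/(2a+b+c)` is the standard band-sharing
dissimilarity for dominant markers; shared absences carry no signal, and a
pair whose usable loci are all shared absences gets D = 0 by convention.
The restriction-fragment variant of the original formulation (which models
fragment-length evolution) is not implemented: for anonymous bands the
Dice form is what mainstream phylogenetics software applies.

Neighbor joining follows the standard Saitou–Nei Q-criterion agglomeration
and is exact on additive matrices (verified in tests against an all-pairs
path-length oracle on random trees of up to 8 taxa, and cross-checked
against an independent NJ implementation). Two deterministic conventions:
ties in Q break on the lowest taxon-index pair in the current order, and
negative estimated branch lengths are clamped to zero with the deficit
transferred to the sibling branch — the usual correction, which preserves
the pair's summed length. The result is an unrooted tree with a
trifurcating root node; `root_with_outgroup` bisects the outgroup's pendant
edge, preserving all leaf-to-leaf path lengths.

Bootstrap supports resample loci with replacement to the original count,
rebuild the tree with the identical pipeline per replicate, and attach to
each internal branch of the full-data tree the percentage of replicates
containing its bipartition (bipartitions are canonicalized relative to the
lexicographically smallest taxon, making them rooting-invariant). Supports
are mapped onto the full-data tree rather than a consensus topology, the
way published phylograms present them. The default replicate count is
1000 — source analyses in this area quote anywhere from 10,000 to 50,000
replicates, the choice carries no canonical value, and 1000 resolves
supports to 0.1% which is ample for the ≥95% decision the pipeline's
validation makes. A single seeded generator drives all replicates.

Newick output writes branch lengths to five decimals with supports as
internal node labels.

## Character mapping

Characters are binary (absent/present) with missing states treated as
wildcards that force no changes. Step counting uses Hartigan's
generalization of Fitch parsimony (node state-set = states attaining the
maximal child count; steps += children − max count), which is exact for
minimum-change counting on binary characters including polytomies; tests
verify equality with exhaustive minimization over all internal labelings on
trees of up to 8 leaves. Unordered symmetric costs are used because that is
the default of mainstream ancestral-state software for categorical data and
nothing in the study design motivates asymmetry.

Classification polarizes by the outgroup state (which must be observed):
invariant → plesiomorphic; 1 step with the derived state on one ingroup
tip → autapomorphy; 1 step on ≥2 tips (necessarily a clade) →
synapomorphy; >1 step → homoplastic. Where published figures distinguish
"paraphyletic status" from homoplasy the operational rule is undefined, so
this package reports all >1-step characters under the single homoplastic
label — a declared convention. When multiple optimal internal labelings
exist, one is reported deterministically (down-pass preferring state 0 on
ties) and flagged `ambiguous`.

## Cytometry

Peak finding is deliberately non-parametric: counts are smoothed with a
5-channel moving average, local maxima are ranked by prominence, and each
peak statistic is the count-weighted mean/SD of raw counts within ±20% of
the peak mode. For well-separated G1 peaks with CV of a few percent the
±20% window covers ≳6 SD, so truncation bias is negligible; no Gaussian fit
is needed at that accuracy, keeping the estimator free of convergence
failures on noisy histograms.

Defaults: the internal standard's 2C is a configuration input defaulting to
9.09 pg (*Pisum sativum* 'Ctirad', the standard literature value);
pg → Mbp uses 978 Mbp/pg; pg and index round half-up to two decimals, Mbp
to an integer. `ploidy_call` rounds `2 × 2C / reference-2C` to the nearest
integer and flags the call inconclusive when the ratio is farther than
`rel_tol` from that integer. The default `rel_tol = 0.15` tolerates the
±5% spread in 2C typical of a cultivar panel measured against its own
median (at 0.10 the most divergent members of a realistic panel would be
flagged despite being unambiguous diploids); pass a stricter tolerance for
calibrated instruments. No significance test across samples is
implemented, only descriptive mean ± SD over replicates (n−1).

## Synthetic generator: what it emulates, and what not

The generator's defaults are the study conditions of the panel this
pipeline was designed around: clades of 2 and 12 cultivars plus one
outgroup; 549 AFLP loci with 292 polymorphic; 667 MSAP loci; planted
shared-type counts 116/84/77 (types I/II/III) and clade-private counts
39 vs 51 (I), 20 vs 22 (II), 21 vs 25 (III); per-sample type proportions
(0.31, 0.31, 0.23, 0.15), inside the published per-cultivar ranges.
Values the printed record does not fix are package choices: 30 + 37 AFLP
clade-diagnostic loci (so the clade split carries ~23% of the polymorphic
variation, matching the published share), within-clade presence probability
0.5, and an independent outgroup presence probability of 0.35 (a distant
outgroup whose band sharing with the ingroup is low, yielding the strongly
supported ingroup monophyly such panels show).

Generation details that matter for exactness guarantees:

* MSAP sites are generated as *types* and then split into the HpaII/MspI
  pair through the inverse of the classification map, so typing round-trips
  by construction.
* Within-clade polymorphic AFLP columns are redrawn if constant, so the
  polymorphic locus count is exact by construction (hence 549 → 292 after
  filtering, deterministically).
* The non-carrier side of a planted private MSAP locus is redrawn if it
  lands uniformly in a single other type, which would otherwise register as
  a spurious private fragment of the opposite clade; planted private counts
  are therefore exact in panels without background loci, and lower bounds
  in the default panel (background loci can only add).
* Characters are planted with true step counts 1 (synapomorphy on an
  internal clade), 1 (autapomorphy) and 2 (derived state on two non-sister
  tips); the outgroup always keeps the ancestral state.
* Histograms are two-Gaussian mixtures on unit channels (standard peak at
  channel 300), events split evenly, with binomial/Poisson-like counting
  noise; peaks closer than 4 combined SD set an `overlapping_peaks` flag.

What the generator does **not** emulate: gel scoring artifacts (band
co-migration, size homoplasy, intensity variation), linkage between loci,
within-cultivar variation (clonally propagated panels have essentially
none), debris/G2 peaks and stain stoichiometry drift in histograms.
Passing tests therefore demonstrate the correctness of the computations and
the recoverability of planted structure — not robustness to scoring error
in real gels.

## Problem sizes

The validation suite runs the full default panel (15 samples × 549/667
loci), 1000 bootstrap replicates, brute-force parsimony oracles to 8
leaves and 20,000-event histograms; the complete suite takes a few seconds
on one core, so these sizes are comfortable for routine re-runs while
remaining at the scale of the study design they mirror.

## Known limitations

* MSAP cannot distinguish a truly absent site from full methylation
  (type IV); counts inherit that ambiguity.
* Nei–Li distances treat bands as independent, homologous loci; AFLP size
  homoplasy violates this in real data.
* Bootstrap supports are attached to the full-data topology only; splits
  absent from it are counted in replicates but not reported.
* The published per-cultivar tables this package ships contain a few
  internally inconsistent rows (type counts not summing to the printed
  total, and two Mbp cells off by 1–3 from their own 2C values); the
  calculators always report computed values and make no attempt to
  reproduce arithmetic that conflicts with its own inputs.
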