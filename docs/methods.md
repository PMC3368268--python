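# Methods

`ctcf-repeatscape` re-implements, at desk scale, the comparative analysis by
which CTCF binding is shown to spread through mammalian genomes via
retrotransposon expansions.  Real six-species ChIP-seq is replaced by a
synthetic multi-species cohort with planted truth, so every stage of the
analysis — motif scanning, cross-species sharing, motif-word statistics,
repeat association and dating, chromatin barriers, transcriptional
insulation — is testable end to end without downloads.

## The Poisson ChIP model

The genome is divided into N non-overlapping bins; a fraction f of bins carry
the feature and are enriched e-fold.  With R total aligned reads, bin counts
are Poisson with mean eM in feature bins and M elsewhere, where

    M = R / (N · (e·f + (1 − f))).

The printed formula is typographically ambiguous ("R/N(ef+(1−f))"); the
division reading above is the only one that reproduces the worked example of
75 reads per feature bin before knockdown and 85 after halving f (R = 2×10⁷,
e = 30, 500 bp bins on a 3.1 Gb genome, so N = 6.2×10⁶; the genome size is
back-calculated, as it is not printed).  The model's counter-intuitive
consequence — knocking down a factor *raises* the expected count at the
surviving sites — is exposed as a strict monotonicity property.  Normalized
ChIP signal follows the quoted form ((sum(ChIP)+1)/(sum(Input)+1))·n with
n = total(ChIP)/total(Input); a depth-correcting variant that divides by n is
available but not the default.

## Synthetic cohort

**Tree and neutral evolution.**  Six species (human, macaque, mouse, rat,
dog, opossum) on a fixed topology ((human, macaque), (mouse, rat), dog) with
opossum as outgroup; branch lengths are in substitutions per neutral site
(human–macaque 0.08, mouse–rat 0.12, human–dog 0.28, human–opossum 0.59 in
path length).  Each branch applies the exact Jukes–Cantor substitution
probability 3/4·(1 − e^(−4b/3)) per site with a uniform choice among the
three alternative bases, so corrected leaf–leaf distances are additive and
testable in closed form.  Evolution is substitution-only: there are no indels
inside alignment blocks, which keeps cross-species projection exact integer
arithmetic.  Repeat insertions enter as new, species-restricted blocks.

**Motif geometry.**  M1 is 20 bp with 14 informative columns (8 sharp at
p = 0.85, 6 degenerate at p = 0.70) and 6 near-uniform columns; M2 is 9 bp,
all columns at p = 0.85.  A site's footprint is M1 alone or M1 plus M2 at a
center-to-center spacing of 20 or 21 bp (half each by default).  Motif
centers are taken floor(L/2) bases from the motif's 5′ end; this convention
is strand-symmetric, which a fixed genome-coordinate center is not for
even-length motifs (it would shift minus-strand spacings by +1 bp and smear
the planted 20/21 modes).

**Word pool and hierarchy.**  2,000 ancestral sites draw a 14-mer word from a
50-word pool with Zipf(1.3) weights; pool words differ from the consensus
word by at most two substitutions confined to the degenerate informative
columns, so every planted word scores above the −10 bit study cutoff.  A
word's probability of seeding a conserved (all-species-bound) site increases
with its usage weight, planting the frequency-vs-conservation hierarchy; the
overall conserved fraction is 0.30.  Conserved sites are purified (rate ×
0.1 at motif bases) on every branch; species-specific sites only along the
path to the species where they are bound, so their motifs stay intact where
binding is planted and decay elsewhere.

**Repeat expansions.**  Defaults emulate the study's lineage expansions at
desk scale: a rodent-shared B2-like SINE (300 copies, 5% divergence, M1+M2 at
20 bp spacing), a mouse-specific B2 (300 copies, 3%), a dog SINEC-like family
(200 copies, 5%, M1 only), an opossum MIR-like family (200 copies, 6%, M1
only), and a motif-free decoy family (300 copies) for the association
negative control.  Each expansion's consensus carries a lineage word that
differs from the pool consensus by one substitution at a sharp column — by
construction disjoint from the pool and still detectable at −10 bits.
Copies draw their substitutions once, at insertion, at the family's
divergence mean; they are not further evolved down the tree, so the planted
divergence is exactly what the clock estimator (age = divergence / rate;
2.2×10⁻⁹ /bp/yr for mammals, 4.5×10⁻⁹ for rodents) must recover.
Divergences of 3–6% correspond to ages of 7–27 My — recent, lineage-specific
activity on the two clocks.

**Binding events, domains, genes.**  Bound sites and bound repeat copies
(60% of copies by default) become 400 bp events with ChIP-like scores that
increase with word weight.  In the barrier species (mouse), 5% of events in
each of four truth classes (five-way conserved, species-specific
repeat-associated, lineage-shared repeat-associated, all other) receive an
H2AK5ac domain (4–30 kb) whose boundary falls within min(l/10, 1 kb) of the
event summit — about one event in twenty acts as a barrier, the frequency
reported for liver CTCF; 20 background domains and Poisson coverage (rates 1
and 8 per 100 bp bin) complete the track.  In the expression species
(mouse), 200 tandem gene pairs straddle an isolated event summit and 200
control pairs sit in event-free stretches; genes are 1 kb, gaps 0.5–1.8 kb
per side, strands alternate between neighboring pairs so no spurious
cross-pair adjacencies arise.  Expression is log2-scale with two replicates;
insulated pairs receive a divergence shift of 1.0 (Manhattan units) away
from zero, so the planted median shift equals the configured value.

**What the generator does not emulate.**  Realistic repeat superfamilies,
indel evolution, CpG hypermutability, chromosome-scale genomes, read-level
ChIP noise at binding events (scores are drawn, not re-estimated from
simulated reads), and expression quantification upstream of log2 estimates.
Passing tests therefore demonstrate correctness of the analysis pipeline
under the stated generative model, not performance on real alignments or
real ChIP libraries.

## Analysis conventions and numerical choices

* Scanning is bits-suboptimal (0.0 = perfect match), both strands, windows
  with non-ACGT bases skipped; PWMs carry a pseudocount (default 0.5 when
  estimated from seeded sites) so no cell is ever zero.  Cutoffs: −10 for
  bound motif instances, −15 for conservation profiling (the published
  values).  The M2 cutoff is not stated in the source analysis; the package
  default is −6, because a 9 bp matrix at −15 accepts nearly every window.
* Spacing uses, per M1, the closest downstream same-strand M2 within
  12–42 bp; the background is the per-distance median over 100 re-draws of
  the M1 positions uniformly over the scanned sequence.
* Sharing codes are ordered (human, macaque, mouse, rat, dog); "11111" is
  five-way shared, "00110" mouse–rat only.  Overlap means ≥ 1 bp after
  projection; by default events that project into no other species are
  excluded (the aligned-regions restriction), with a flag to keep them.
  Pairwise percentages average the two anchoring directions.
* nocc = occ / (total bound bases / 10⁶), exactly; group nocc pools
  occurrences and factors.  The malformed printed expression
  "ln(nocc(S))/nocc(R)) > 2" is read as ln(nocc(S)/nocc(R)) > 2, with
  nocc(R) = 0 treated as +∞ (included) since absence elsewhere is the
  strongest specificity signal.  Hierarchy: words bound ≥ 5 times in any
  species, 25 bins by default (a bin-size-100 variant is a parameter).
* Fisher enrichment is the exact hypergeometric upper tail; Bonferroni is
  reported within each repeat hierarchy level but never silently applied.
  The event/repeat binomial background places size-matched regions uniformly
  within the gaps between events, rejecting gap-crossing placements, and
  takes the median overlap fraction across randomizations.
* Barrier rule: distance from the event summit to the nearest boundary of
  the nearest domain, compared to min(l/10, 1000 bp) without rounding;
  events equidistant from two domains resolve to the domain with the smaller
  start.  Controls: unrelated-TF sets (with an optional <1 kb-to-CTCF
  exclusion), summits shifted by a uniform 2–100 kb with random sign
  (reflected at the ends), and size/count-matched random regions.
* Tandem pairs: same-strand genomic neighbors with 0 < gap < 10 kb;
  "CTCF-separated" requires an event summit strictly inside the open gap;
  category precedence five-way > repeat-associated > all-other.  Category
  comparisons use the two-sided Wilcoxon rank-sum test: the compared
  categories contain different, unmatched pairs, so the paired signed-rank
  variant mentioned in one place in the source description is not defined
  here.
* Conservation is an observed/expected substitution ratio on the synthetic
  alignment (per column: species bases differing from the anchor base,
  normalized by the flank mean over ±50 bp by default); an adapter accepts
  externally computed per-base constraint scores (e.g. GERP) for real data.
  "Unchanged" is measured against the anchor base, not an inferred ancestor.
  The length/IC-vs-conservation Spearman test uses an exact permutation p
  for n ≤ 9 and the asymptotic p above that.

## Problem sizes

Default study conditions: 5 Mb × 6 species, 2,000 planted sites, 300-copy
rodent expansions (plus 200-copy dog/opossum families and a 300-copy decoy).
Cohort generation takes a few seconds and genome-wide scanning ~15 s on one
CPU; the full test suite, including parameter-recovery runs on the default
cohort and 100-seed null calibrations, completes in a few minutes.  Unit
tests use smaller cohorts (0.2–1.5 Mb) chosen so that closed-form
expectations (Jukes–Cantor additivity, binomial divergence, geometric
boundary-capture probabilities) have adequate power at 3σ tolerances.

## Known limitations

* Projection assumes the no-indel block model; the liftOver/chain reader is
  a stub for real data and is untested against real chains.
* At desk scale the nocc > 8 lineage-word threshold is a low absolute bar
  (bound-base factors around 0.3–1), so mutated repeat copies can promote
  variant words into the lineage-specific set alongside the planted
  consensus word; the truth tables record realized per-copy words so tests
  compare against the rule applied to the generated truth.
* The domain caller is a threshold/gap-merge caller for synthetic coverage,
  not a peak-caller replacement for real histone ChIP.
* GERP itself, de novo motif discovery, and real-alignment projection are
  out of scope; the corresponding inputs are either synthetic or supplied
  externally.
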