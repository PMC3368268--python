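# ctcf-repeatscape

Comparative analysis of CTCF-binding evolution through retrotransposon
expansions, runnable end to end on synthetic multi-species cohorts.

CTCF is the 11-zinc-finger protein that organizes vertebrate chromatin into
insulated domains.  Comparing its binding across mammals reveals a striking
pattern: a deeply conserved core of binding events sits alongside large
lineage-specific expansions carried by SINE retrotransposons (B2 in rodents,
SINEC/Lys in dog, MIR-family elements in opossum).  This package implements
the quantitative machinery of that comparison for researchers who want to
study or extend it:

* a **two-part motif model** — the canonical 20 bp M1 plus a 9 bp M2 at a
  preferred center-to-center spacing of 20–21 bp — with bits-suboptimal PWM
  scanning (0.0 = perfect match) and a randomized-background spacing test;
* **cross-species sharing** via exact interval projection through alignment
  blocks, with binary sharing codes over (human, macaque, mouse, rat, dog):
  `11111` = five-way shared, `00110` = mouse–rat only;
* **motif-word statistics**: each bound motif is read as a 14-mer at the most
  informative M1 positions; per species, a word's normalized occurrence is
  `nocc = occ / (bound bases / 10⁶)`, and lineage-specific words satisfy
  `ln(nocc(S)/nocc(R)) > 2` and `nocc(S) > 8`;
* **repeat association and dating**: one-sided Fisher (hypergeometric tail)
  tests of word/repeat association, a gap-randomized binomial test of
  event/repeat overlap, and molecular-clock ages
  `age = divergence / rate` (2.2×10⁻⁹ /bp/yr mammalian, 4.5×10⁻⁹ rodent);
* **chromatin barriers**: an event with summit x is a barrier of an H2AK5ac
  domain of length l iff its distance to the domain boundary is at most
  `min(l/10, 1000 bp)`, compared against shifted-event and random-region
  controls;
* **transcriptional insulation**: tandem gene pairs (same strand, gap
  < 10 kb) split by whether a CTCF summit lies in the inter-gene gap, and
  compared by the Manhattan distance of log2 expression (Wilcoxon rank-sum);
* the **Poisson ChIP enrichment model** `M = R/(N(ef+(1−f)))` that explains
  why knockdown *increases* coverage at surviving sites;
* a **synthetic cohort generator** that plants all of the above — species
  tree, purifying selection on bound motifs, word-usage hierarchy, repeat
  expansions with recorded per-copy substitutions, barrier domains, and
  insulated gene pairs — with full truth tables.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from ctcf_repeatscape.chip_model import ChipModelParams, expected_read_means
from ctcf_repeatscape.cohort import SimulationConfig, simulate_cohort
from ctcf_repeatscape.ortho_sharing import sharing_codes, five_way_fraction

# Poisson enrichment model: 20M reads, 500 bp bins on 3.1 Gb, 30x enrichment
before = expected_read_means(ChipModelParams(2e7, 6_200_000, 30.0, 0.01))
after = expected_read_means(ChipModelParams(2e7, 6_200_000, 30.0, 0.005))
print(round(before["feature_mean"]), round(after["feature_mean"]))

# a small synthetic cohort and its cross-species sharing
cohort = simulate_cohort(SimulationConfig(seed=7, genome_length=600_000,
                                          n_sites=250, expansions=(),
                                          n_insulated_pairs=0, n_control_pairs=0))
codes = sharing_codes(cohort.events["human"], cohort.events,
                      cohort.block_map, anchor="human")
sites = cohort.truth.sites
planted = sites[sites["bound_species"].str.contains("human")]["conserved"].mean()
print(f"{five_way_fraction(codes):.2f} {planted:.2f}")
```

prints

```
75 85
0.71 0.71
```

— the per-feature-bin read means before and after a knockdown that halves the
bound-bin fraction (coverage at surviving sites *rises* from 75 to 85 because
the same read budget concentrates on fewer enriched bins), then the five-way
shared fraction measured by projection and sharing codes (0.71) against the
planted conserved fraction among human-bound sites (0.71): the sharing
machinery recovers the planted truth exactly on this cohort.  (The fraction
exceeds the 30% of ancestral sites planted as conserved because conserved
sites are bound in every species, while each species-specific site is bound
in just one.)

A full pipeline run (simulate → scan → share → words → repeats → barriers →
insulate → conserve) on a scaled-down cohort:

```bash
ctcf-repeatscape run --seed 7 --genome-length 1000000 --n-sites 400 --out results/run7
```

which writes versioned TSV/BED outputs and a machine-readable
`summary.json` (spacing modes, five-way fraction, lineage-specific word
counts, repeat-association p-values, barrier fractions, insulation medians
and p-values).

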