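# Methods

## Community structure

A replicate group holds exactly 42 species: 33 bacteria, 6 archaea and
3 fungi. Thirty-six prokaryotes are organised into 12 taxonomic triplets;
each triplet lives in one (phylum, family) and splits 2 + 1 by genus: the
two congeners supply the reference and the "very closely related" partner,
the remaining species is the "closely related" partner (same family,
different genus). The decomposition 42 = 12 × 3 + 3 special-topology
bacteria + 3 fungi is the only one consistent with the domain census and
the rule that triplets exclude fungi and bacteria with linear or
multi-replicon genomes, so the validator enforces it: the eligible
prokaryotes must partition into exactly 12 families of three with a 2 + 1
genus split.

Reference selection within a family is a seeded uniform draw between the
two congeners, making `build_triplets` a deterministic function of
(group, seed). Species matching everywhere is case-insensitive on the
first two name tokens ("Genus epithet"); abbreviations are not expanded.

## Abundance distributions

No closed functional form is canonical for "logarithmic decay" and
"exponential decay" rank-abundance curves, so the package uses the
simplest shapes matching the names:

* exponential: aᵢ ∝ r^(i−1) with 0 < r < 1;
* logarithmic: aᵢ ∝ C − ln i with C > ln n.

Both are normalized and the free parameter is solved by bracketed root
finding (Brent, |min − floor| ≤ 1e−10) so the lowest rank sits exactly at
the floor. The default floor is 0.009 relative abundance — the smallest
abundance used in the benchmark design — and must satisfy
0 < floor < 1/n; outside that range the shape is infeasible and the
calibration raises. The minimum of the normalized vector is monotone in
the parameter for both forms, so the root is unique.

Plateau variants place consecutive rank pairs at a shared level: the
level curve is the same decay shape over n/2 levels calibrated at twice
the floor, duplicated pairwise and renormalized, which leaves the
post-normalization minimum exactly at the floor. Plateau profiles
therefore require even n. An explicit abundance vector can be supplied to
replay an externally specified design verbatim.

## Factorial design and read budgets

`enumerate_design` emits the 23 profiles per group in a fixed order with
per-profile seeds derived from a master seed through numpy's
`SeedSequence`, keeping the entire design a pure function of
(group label, master seed). Depth counts **read pairs**; the total
individual reads in a library is R = 2 × depth, and R is the denominator
used for relative abundance so that numerator and denominator share
units.

Rank arrangements encode the relatedness intent:

* *ordered* — triplets in listed order, then specials, then fungi;
* *random* — seeded uniform shuffle;
* *very_close* / *close* — each triplet's (reference, partner) pair at
  adjacent ranks (pair orientation randomized), remaining species
  interleaved by seeded shuffle so pairs spread over the whole ranking;
* *not_close* — the ranking is cut into thirds and triplet members are
  placed one per third at matching offsets, guaranteeing every
  within-triplet rank distance is at least n/3.

Fungi and special-topology bacteria fill unconstrained ranks by seeded
shuffle in all arrangements. Integer read budgets are the
largest-remainder rounding of depth × aᵢ (ties to the lower rank), which
conserves the depth exactly.

## Read simulation

Fragments are 180 bp, mates 125 bp — mate 1 is the fragment head, mate 2
the reverse complement of the tail, so mates overlap by 70 bp; these are
implemented literally from the stated library geometry. Fragment starts
are uniform per replicon, replicons chosen per read by effective-length
weighting (circular: full length, with wrap-around across the origin;
linear: length − fragment + 1). Linear replicons shorter than one
fragment are skipped with a warning and their weight reallocated to the
species' other replicons; a species with no usable replicon is an error.
Coordinates are 0-based half-open on the forward strand and carried in
the read header together with species, replicon, and strand, so
evaluation can count mapped reads from truth tags instead of re-mapping.

The error model is a uniform i.i.d. per-base substitution rate
(default 0). Truth-tracked benchmarking does not require a realistic
error profile; the knob exists for robustness experiments. Quality
strings are constant ('I', Phred 40). No indels, GC bias, duplicates, or
assembly are simulated.

## Evaluation

The quality filter keeps bins with completeness − 5 × contamination
**strictly** above 50. TP is counted at unique-species level (one species
with five passing bins is one TP); FP is reported both per bin and per
unique off-roster species, and accuracy TP/(TP+FP) × 100 defaults to the
species-level FP count with a switch for the bin-level count — both
denominators are legitimate readings and both are exposed. Bins without
an assigned taxonomy are tallied separately and never counted as FP.
Accuracy and pair recovery are NaN (missing), not zero, when their
denominators are empty. Pair recovery for a relatedness class is the
fraction of its (reference, partner) pairs with both members recovered as
TP in the same community. Detection-limit summaries report the minimum
TP and maximum FP relative abundance and fold coverage per
(profile, pipeline), with species names.

## Statistics

Pairwise comparisons use the classic equal-variance two-sample t-test,
two-sided, with Bonferroni correction over all level pairs within one
(factor, metric) call, significance at adjusted p < 0.05. The three
replicate groups supply the observations per level; a level with fewer
than two observations raises rather than silently degrading. The
complementary route is one-way ANOVA followed by Tukey's HSD
(statsmodels). When the between-level sum of squares is exactly zero the
F statistic is reported as 0 with p = 1 (the ratio is otherwise 0/0 for
all-constant input). Summaries report mean ± sample sd (ddof = 1; 0 for
singletons).

## Synthetic data

`gen_taxonomy` fabricates rosters with pronounceable but fictional
binomials and guaranteed structure; labels are collision-checked, and
fabricated genera mean off-roster sibling names always exist for the mock
binner's false-positive modes. Genome lengths on the roster default to
realistic ranges (2–6 Mb bacteria, 1.5–3.5 Mb archaea, 10–40 Mb fungi)
and drive coverage computations; `gen_genomes` writes actual sequences at
a test-scale default of 0.1–1 Mb so simulation stays fast — real genome
sizes are a parameter, not a limit.

The mock binner emulates binning outcomes, not mechanics: it operates on
the community spec (design truth) rather than on reads. Per species it
detects with probability `p_detect` — optionally gated on truth fold
coverage L × 2 × budget / G against a detection threshold — and emits one
or more bins whose completeness/contamination are truncated-normal draws
(defaults ≈ 97 % / ≈ 1 %, matching curated MAG sets, so most bins pass the
quality filter) and whose mapped reads sum to the species' full budget.
With probability `p_fp` it adds an off-roster bin labelled as a fabricated
same-genus sibling, same-family sibling, or arbitrary label. FP labels are
unique per emitting species, so species-level FP counts equal FP
emissions and configured probabilities are recoverable from evaluated
panels — the module's core acceptance property.

## Problem sizes and numerical choices

Tests and examples run the design at reduced depths (tens of thousands of
read pairs) and test-scale genomes; all structural results (census,
calibration, conservation, round-trips) are exact at any scale, and the
package's own choice is to keep the default suite desk-scale. Stochastic
checks fix seeds and use 3–4 standard-error tolerances. What passing
mock-binner tests show is that the evaluation layer faithfully recovers
configured behaviour; they do not show how real assemblers and binners
behave on real communities — the mock binner has no composition signal,
no inter-species sequence similarity, and no assembly artifacts.

## Known limitations

* Synthetic genomes are i.i.d. random sequence; sibling species share
  labels, not sequence similarity, so taxonomic misclassification
  pressure is not emulated at the sequence level.
* The plateau floor calibration and the log-decay functional form are
  package conventions; externally specified abundance tables can be
  replayed through the explicit-vector path when exact curves matter.
* "Depth" is interpreted as read pairs throughout; libraries quoted in
  individual reads should be halved before use.
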