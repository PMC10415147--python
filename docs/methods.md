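# Methods

## Coordinate and orientation conventions

All genomic intervals are 0-based, half-open, on the forward strand, with
an explicit strand flag (the BED convention). A site's `spacer_seq` and
`pam4` are reported on the protospacer strand: for a `-` site the interval
[start, end) still addresses forward-strand bases, the sequence is
reverse-complemented, and the PAM lies 5′ of the interval in forward
coordinates. On circular genomes windows may wrap the origin; such a site
keeps `start` in [0, L) and `end = start + spacer_len`, read modulo L.
Distances in the priming analysis are never wrapped, even on circular
genomes: they are reported in the linear coordinate frame, matching how
genomic-position histograms are drawn.

New spacers integrate at the leader end of a CRISPR array, so the
leader-proximal spacer in a read is the most recently acquired. The package
fixes this as a convention constant: in a double-acquisition read, the
*first*-acquired spacer is the leader-distal one. Amplicon reads are
orientation-normalised before extraction, so the convention is independent
of sequencing direction.

## PAM classification

A 4-nt PAM (the four bases immediately 3′ of the protospacer, no gap — the
NAGG "slip" is part of the motif, not a spacer) is classified with the
precedence NGG → NAGG → NNGG_other → other. A PAM such as `AGGG` is
canonical NGG first, because canonical targeting dominates biologically;
`NAGG` requires A at position 2 with GG at 3–4; any other `..GG` is
NNGG_other. The four classes partition all 256 PAMs (16 / 4 / 8 / 228).

## Site scanning and the shifted counterpart

`scan_pam_sites` matches an IUPAC motif downstream of every protospacer
window on both strands (regex with lookahead, so overlapping occurrences
all count), requiring enough flank for both the motif and the 4-nt PAM. On
linear genomes windows that would run off an end are excluded; windows
containing non-ACGT bases are skipped and counted when N-masking is
enabled. The implementation is checked exactly against a quadratic-time
brute-force oracle on hundreds of random genomes, and against strand
symmetry (scanning the reverse complement gives the mirrored site set).

`shifted_counterpart` advances an NAGG site's window one base in the
5′→3′ direction of the protospacer strand, so the former N becomes the
protospacer's 3′-terminal base and the new PAM begins AGG. Counterparts
inherit the site name with a `*` suffix. A shift that runs a linear
genome's end off is rejected with a warning rather than an error, since it
is a property of the site, not a misuse of the function.

`count_motif_sites` counts motif occurrences only (no protospacer window),
which makes the circular identity count(NGG) = count(NNGG) exact: on a
circle every GG has exactly one upstream base.

## Spacer calling

Repeats are located by mismatch-tolerant sliding comparison (default ≤ 2
mismatches over the full repeat, leftmost-greedy non-overlapping). The
tolerance default is a deliberate middle ground: strict enough that a
36-nt repeat is essentially never found spuriously, loose enough to absorb
occasional sequencing errors. Reads with repeats in both orientations are
discarded as chimeric; reads with fewer than two repeat matches yield no
spacers. Inter-repeat segments of 28–32 nt (target 30) are accepted;
engineered pre-existing spacers are removed via a user denylist.

Mapping is exact full-length matching on both strands, because the
tabulation is defined over unique spacer sequences matching the genome;
sequencing errors then drop a read out of its planted spacer's count rather
than contaminating a neighbour's. Multi-locus spacers are retained in
counts but flagged ambiguous and excluded from site-level analyses
(priming, per-site rates). Frequencies are computed over mapped spacer
occurrences — a double-acquisition read contributes two — with unmapped
spacers tallied separately and excluded from the denominator by default
(a flag includes them). Frequency normalization (sum = 1 ± 1e-9) is
asserted on every table construction.

## Enrichment, paired fitness and partitions

The enrichment ratio of a spacer is its read frequency in the infected
sample divided by its frequency in the uninfected sample, computed only for
spacers present (count ≥ 1) in both; absent spacers are listed as dropped,
with no pseudocounts by default. Complete-case filtering across ≥ 2 tables
reproduces an "appeared in all experiments" criterion and is monotone in
the number of tables.

Paired fitness is f = ER_NAGG / (ER_NAGG + ER_AGG): 0.5 means the NAGG
spacer performs exactly as well as its shifted canonical counterpart. The
definition is scale-invariant and complementary (f(a,b) + f(b,a) = 1). A
frequency-based variant (infected-sample frequencies instead of enrichment
ratios) is available behind a flag; the enrichment-ratio form is the
default because it is the form that is internally normalised against the
uninfected library composition. Partition boundaries are strict
inequalities: "above" means f > 0.5, "below" means f < 0.1, so boundary
values fall in the middle band.

## Nucleotide-preference testing

Spacers are grouped by the first PAM base, by the protospacer's 3′-terminal
("seed-last") base, or by the seed-last + PAM-N dinucleotide. The default
test is an intersection-union design: a group is called preferred or
disfavored only if its mean enrichment ratio differs from *every* other
group's (two-sided Welch t-tests; the group's p-value is the maximum of its
pairwise p-values), Holm-adjusted across groups. This design was chosen
over the more obvious group-vs-complement t-test after the complement
design failed a basic power requirement: when one group is strongly
shifted, it contaminates every other group's complement and drags all
groups to significance, so a single deviant nucleotide could never be
isolated. The intersection-union test flags exactly the shifted group in
simulation (≥ 95% power at 25 spacers/group for a large shift) while
holding the family-wise error at or below nominal under label permutation.
The complement Welch test and a label-permutation test remain available as
`method="complement"` and `method="permutation"`. Groups with fewer than
two members are flagged skipped. Enrichment ratios are summarised on the
raw scale (means, standard deviations) and are best plotted on log10; the
heavy right tail is why the permutation variant exists.

## Priming analysis

Double-acquisition events are paired as (first-acquired, second-acquired)
targets; both spacers must map uniquely, and the first must belong to the
configured PAM class (NAGG by default; `None` accepts any). "Unique events"
are deduplicated on the ordered (first, second) sequence pair. Distances
default to signed start-coordinate differences; absolute values and
midpoint anchors are options. Histograms bin by floor division (bin 0 is
[0, bin_width)), and the locality report tests the within-one-bin count
against the uniform null p = 2·bin_width/L with a one-sided binomial test.
At 400 events this cleanly separates an exponential kernel from uniform
second-target placement.

## The synthetic generator

The generator emulates the experimental structure end to end, with every
draw flowing from one integer seed through `numpy.random.Generator`
(integer categorical draws; no platform-dependent reduction orders):

- **Genome**: i.i.d. bases, default 30 kb at GC 0.33 — the size and base
  composition of a staphylococcal lytic phage. 30 kb gives ~1,600 NGG and
  ~550 NAGG sites, matching the density regime of a real phage target
  while keeping the full-atlas scan fast.
- **Acquisition**: each event's first spacer is drawn over the complete
  protospacer atlas with probability proportional to its PAM-class weight;
  default NGG:NAGG:NNGG_other = 1 : 10^-2.5 : 10^-2.5 (the observed two-to-
  three orders of magnitude of bias, at its midpoint), "other" 0. With
  probability p_double = 0.1 a second spacer is drawn with probability
  proportional to class weight × exp(−|Δ|/500 bp) (or uniform over sites
  under the no-priming null). The 500 bp scale puts ~86% of second targets
  within 1 kb, the regime where most second spacers sit in one histogram
  bin. The class weights apply to second draws too: priming modulates
  locality, not PAM recognition.
- **Selection**: single-round multinomial resampling — uninfected counts
  from a uniform library, infected counts proportional to per-spacer
  protection s_i ∈ (0, 1]. This is the simplest model whose expectation
  gives ER_i = s_i / mean(s); growth dynamics are deliberately omitted, so
  the generator makes no claims about time courses or multiplicity of
  infection.
- **Reads**: repeat + spacer (+ repeat + spacer) + repeat with uniform
  substitution errors (default 10^-3/base) and a fixed Q40 quality string.
  No indels, no quality modelling, no PCR duplicates, and at most two new
  spacers per read.

What passing tests on this generator do **not** show: robustness to indels
or quality-dependent errors, to non-uniform library composition before
selection, to real repeat polymorphism, or to genome repeats longer than a
spacer (real phage genomes have them; random sequence essentially does
not). The exact-match mapping policy in particular is only as good as the
per-base error rate is low.

## Problem sizes and numerical choices

The integration tests and the acceptance script use a 30 kb genome with
100,000 acquisition events (≈ 100 NAGG-first events at the planted bias,
enough for ±0.2 recovery of the log10 bias), a 1,000-spacer neutral
library at 2,000,000 reads per sample (deep enough that the small-count
inflation of E[1/X] in the ratio denominator is negligible against the
3-SE band), and 250 spacer pairs at 50,000 reads per sample. Recovery
tolerances are pre-registered: ±0.2 in log10 for the acquisition bias,
3 SE for the neutral mean, binomial 3σ for partition fractions and the
within-1-kb priming fraction, 0.03 absolute for mean pair fitness.

Tie-breaks and degenerate inputs: scanning returns sites sorted by
(start, strand) with each key at most once; tables sort by read count
(stable); zero mapped spacers yield an empty table with a warning rather
than an error; an empty motif, a degenerate GC content, out-of-range
probabilities and protection values, and hi ≤ lo partition thresholds all
raise configuration errors before any computation.

## Known limitations

- Exact-match mapping discards error-bearing reads instead of rescuing
  them; a substitution-only rescue (`map_spacer(..., max_mismatches=1)`)
  exists behind a flag, off by default, and does not handle indels.
- The library designer does not check cloning feasibility (internal BsaI
  sites, GC clamps) — scaffold segments are caller-supplied configuration.
- The paired-fitness denominator requires both members of a pair to have
  positive enrichment ratios; pairs with a zero-count member are dropped,
  which biases partitions if dropout correlates with fitness.
- Whether the uninfected-frequency denominator should include unmapped
  spacer reads is configurable because it changes enrichment ratios
  uniformly; the default excludes them.
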