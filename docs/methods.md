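# Methods

## Genome model and identity structure

The toy genome is the minimal structure that reproduces the mapping problem
posed by an LTR-retrotransposon family: `n_full` full-length copies that are
sequence-identical to one another (default length 5918 bp, the size of a
full Ty1 element), each carrying identical ~334 bp LTRs at both ends (the 3′
LTR is a byte-for-byte copy of the 5′ LTR), plus `n_solo` solo-LTR remnants
drawn as prefixes of the canonical LTR with lengths uniform on
[150, `ltr_len`] — echoing the observation that nearly all genomic delta
elements are shorter than 350 bp. Copies are placed on the chromosome(s)
with random strand and a minimum gap of one maximum fragment length (500 bp)
between elements and from chromosome edges, by distributing the free slack
randomly between elements in a single pass (no rejection loop over
intervals).

Sequence identity is recorded as *identity groups*: a body group mapping the
full canonical element into every full copy, and an LTR group mapping the
canonical LTR into the 5′ and 3′ LTR of every full copy and into every solo.
A fragment's candidate-locus list is derived purely from these groups: a
fragment wholly inside a shared interval lists the corresponding position in
every other copy of that interval; a fragment crossing an element/background
junction is unique. For this to be the *complete* truth, the random
background must share no fragment-length subsequence with the element. The
generator enforces this with an exact screen at k = 32 using 2-bit-packed
k-mers (a 32-mer fits a uint64 exactly): if no 32-mer is shared, no k-mer at
any k ≥ 32 — in particular at the 200 bp minimum fragment length — can be
shared, and the screen is orders of magnitude cheaper than hashing 200-mers.
A failing chromosome draw is regenerated (bounded retries); with random
sequence the rejection probability is negligible.

Divergence between copies is deliberately not modeled: with identical
copies the candidate lists are exact, so every downstream claim about
multimapper handling is checked against ground truth rather than against a
heuristic aligner. How an aligner's random assignment interacts with slight
inter-copy divergence is outside what this package can decide.

## Fragment simulation

ChIP fragments are intervals only — no read sequences or base-call errors,
since alignment is out of scope. Centers are drawn from a mixture of a
genome-wide uniform background and per-element enrichment components;
each component is a symmetric triangular window (default half-width 50 bp)
around a fixed element-relative offset, a deliberately simple stand-in for a
promoter-proximal occupancy peak of no particular shape. Fragment lengths
are uniform on [200, 500] bp, the size range of sonicated chromatin.
Components are applied to full-length copies only: solo LTRs receive signal
exclusively through candidate-list ambiguity, which isolates the
read-assignment artifact (Ty1-TSS signal mirrored into 3′ LTRs and solos)
from any directly injected solo signal. The untagged control is the same
simulator with only the background component.

## Processing order: dedup before assignment

Duplicates are defined by fragment endpoints — identical length and
identical candidate *set* — matching paired-end duplicate marking on
unstranded fragments. Deduplication runs before random assignment: PCR
duplicates of one molecule share identical mapping ambiguity, and
deduplicating on the post-assignment locus would stochastically retain
duplicates that landed on different copies. The alternative order is
available (`order="assign-first"`) for comparison. Assignment is uniform
over candidates (candidates are equally good by construction), seeded and
reproducible. Coverage is a fragment pileup (each fragment adds 1 over its
whole interval), so the raw track sum always equals the summed assigned
fragment lengths — an invariant the tests assert.

Control normalization scales both tracks to coverage per million fragments
and forms the per-bp ratio `(ip + ε) / (control + ε)` with ε = 0.5
per-million units by default. A ratio (rather than subtraction, which is
offered behind a flag) is the convention implied by metaprofiles whose
background sits at a flat constant baseline; the pseudocount regularizes
zero-coverage control positions and a zero pseudocount with a zero-coverage
control base pair is an error, not a silent infinity.

## Metaprofile layout and averaging

The profile window runs from 2 kb upstream of the TSS to 2 kb downstream of
the TES. Within the element, TSS→TSS+1 kb and TES−1 kb→TES are kept per-bp —
the only reading under which fixed promoter offsets (+238, +1000) remain
addressable — and the interior is rescaled into 100 bins by an even integer
partition (remainder base pairs assigned to the leading bins: deterministic
and order-independent). TES defaults to the element end. Minus-strand
elements are flipped so all profiles read 5′→3′; positions beyond a
chromosome end are masked (NaN) and averaging is per-position mask-aware.
All full copies are averaged with equal weight; per-element profiles are not
a primary output because family members are indistinguishable by
construction. Anchoring on element start instead of the TSS is available as
a switch (`anchor="start"`) for plots whose x-axis begins at the element.

Peak localization deserves a note: piling up 200–500 bp fragments turns a
narrow source into a flat-topped plateau roughly one fragment length wide,
so the single highest base pair wanders tens of bp between replicates.
`profile_peaks` therefore smooths lightly (31 bp moving average), finds
local maxima, and reports each peak as the midpoint of its half-maximum
region — standard summit refinement — which localizes the simulated
promoter peaks to within a few base pairs at 100k fragments.

The promoter-balance statistic is the ratio of mean normalized occupancy in
±100 bp windows around the internal TSS and the element TSS. A zero or fully
masked element-TSS window returns an explicit undefined flag rather than a
NaN.

## Mobility assay arithmetic

Whole-culture CFU from a plate is `colonies × dilution × (culture volume /
plated volume)`; a permissive plate with zero colonies is an error (density
unmeasurable), while zero selective colonies is a valid observation of zero
events. Per-culture frequency is the CFU ratio. Technical cultures (default
4 per biological replicate, emulating dilution in quadruplicate) are
averaged within each biological replicate before the cross-replicate mean;
dispersion is the sample s.d. for n ≥ 3 biological replicates and the range
for n = 2. Pooling all 12 cultures directly is offered as an option since
the replicate structure of the s.d. is a convention, not a law. When every
culture shows zero events the strain is censored with upper limit 1 /
(summed whole-culture permissive CFU over all replicates); by that literal
formula, differences in selective plating volume do not enter the limit —
a documented limitation, since plating less than the whole culture assays
fewer cells than the limit assumes. Fold changes against a censored strain
are reported as lower bounds (`> x`); two censored strains have an undefined
fold.

The simulator draws per-culture totals as Poisson around 2×10⁸ CFU, events
as Binomial(total, p), and plate counts as binomial subsamples at the plated
fraction. At the default geometry (1 μL of a 1:1000 dilution on permissive
plates, whole culture on selective plates) the estimator is unbiased to
within sampling noise; the calibration test recovers p = 10⁻⁶ to well within
10% over 200 replicates.

## RT-PCR and densitometry

The semi-quantitative RT-PCR estimate multiplies two factors: the per-cycle
amplification factor (fixed at 2, i.e. perfect doubling — a conservative
choice, since real efficiencies below 2 would imply a larger true ratio)
raised to the observed cycle offset, and a molar correction equal to the
target/reference amplicon length ratio (equal mass signal of a 3 kb and a
200 bp amplicon means a 15-fold molar excess of the short species). The
genomic-DNA control that anchors the cycle comparison is a qualitative
validity gate, not a numeric correction. Densitometry is
`(target/loading) ÷ (reference target/reference loading)` with positive
signals required.

## Problem sizes and what the tests show

Profiling checks run on an 8-copy genome with 100,000 IP + 100,000 control
fragments (a few seconds each), mobility calibration on 200 simulated
replicates of 3×4 cultures, and the sequence-level checks on 2-copy toys;
these sizes give comfortable statistical margins for every asserted
property while keeping the whole suite under a minute. Passing tests show
that the implementation is internally correct under the generator's
idealizations — identical copies, triangular peaks, uniform fragment
lengths, Poisson/binomial colony statistics. They do not show robustness to
features the generator omits: inter-copy sequence divergence, GC- or
mappability-dependent coverage bias, fragment-length distributions with
tails, chromatin-dependent sonication bias, or aligner-specific multimapper
behavior.
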