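# Methods

## Scope and data model

The package analyses TCRβ repertoires of sorted lymph-node T cells, one
clonotype table per sample. A clonotype is a CDR3 amino-acid sequence with
optional nucleotide sequence and V/J gene calls, a read count and a
frequency. Samples carry metadata (mouse, vaccine group, lymph-node side,
T-cell subset, sorted cell count). All amino-acid-level analyses key
clonotypes either by CDR3aa alone (the pooling default) or by
(CDR3aa, V, J); tables may contain CDR3aa duplicates (nucleotide-level
variants), which are preserved on I/O.

## Preprocessing

**Detection filter.** Clones with frequency strictly above 2.5×10⁻⁵ are
kept and the survivors' frequencies renormalized to 1; read counts are
untouched. The threshold is motivated by a single-cell argument: with
~7.5×10⁴ sorted cells and ~10⁶ on-target reads, the smallest credible clone
(one cell) is ~25 reads, i.e. 2.5×10⁻⁵. The companion consistency rule
checks exactly this: total reads divided by the smallest clone's reads must
stay below the sorted cell count, otherwise sub-cell-sized clones (noise)
remain. `choose_threshold` scans a k×10⁻⁶ grid for the smallest threshold
that satisfies the rule; passing at a threshold implies passing at any
larger one because filtering only raises the smallest retained clone.

**Pooling.** Same-group samples are pooled by key; a key's cumulative
frequency is the *sum* of its per-sample frequencies (so the 5×10⁻⁵
cumulative cutoff reads literally), and the per-sample breakdown is kept
for enrichment analyses. The representative V/J of a pooled key is the
frequency-weighted modal call among contributors. Cross-group exclusion
removes keys present in both groups' pools; the reported overlap fraction
is clone-count-based (shared keys over pool size), not frequency-weighted.

## Clonality

Clonality is 1 − H/ln N with H = −Σ fᵢ ln fᵢ over clones with f > 0 and
N their number: 0 for a perfectly even repertoire, 1 in the monoclonal
limit (the N = 1 case is defined as 1). The normalization makes the value
base-invariant. Zero-frequency clones are excluded from N, matching
post-filter use. V-segment usage is reported both frequency-weighted and
clonotype-count-weighted; statements like "TRBV17 in 24% of clonotypes" use
the count weighting.

## Generative background and convergence scan

**Background model.** The null for the convergence scan is a factorized
amino-acid CDR3 model:

    Pgen(s) = P(L) × Π_i P(s_i | bin(i, L))

with five anchor bins (the first three positions — the conserved C-A-S
region — and the last two — the F/W motif region) plus one pooled interior
bin. Bins are anchored to both sequence ends, so a single emission table
serves all lengths; unseen lengths score 0. `fit_background` estimates all
tables by counting with an additive pseudocount (default 1 per bin×letter),
which keeps every single-substitution variant's Pgen strictly positive.
The default mouse-like model spans lengths 12–17 (mode 14) with a
near-uniform, mildly G/S/L-tilted interior and realistic anchor
conservation; TRBV usage makes TRBV17 rare (~2%), matching its usage in
unselected mouse repertoires. The model deliberately ignores
nucleotide-level recombination mechanics; every downstream use needs only a
self-consistent Pgen/sampler pair (expected neighbor counts, null
sampling). A Pgen table computed externally by a full V(D)J recombination
model can replace the factorized model through `TabularPgen`.

**Scan.** For each pooled clonotype the observed statistic is the number of
distinct pooled keys at Hamming distance exactly 1 (same length, self and
identical-CDR3 keys excluded); in linked mode neighbors must also share the
representative V and J. Counting uses positional mask buckets (two
sequences are Hamming-1 iff they share exactly one masked pattern), which
is O(total sequence length) and is verified in tests against a brute-force
all-pairs oracle. The null expectation is

    E = Σ_{s ∈ neighbors} [1 − (1 − π(s))^N]

with π(s) = Pgen(s), N the scanned cloneset size, and the linear shortcut
N·Σπ when N·max π < 10⁻³. In linked mode π(s) additionally carries the
background probability of the key's V (and J): the observed count is
V/J-restricted, so the expectation must be restricted identically or the
test is mis-calibrated; segments unknown to the model contribute no
reduction, which errs conservative. Observed counts are tested with a
Poisson upper tail (neighbor presences are rare, nearly independent
Bernoulli events), and p-values are Benjamini–Hochberg adjusted over all
scanned keys of one pooled cloneset (one family per group per linkage
mode). A hit needs at least one observed neighbor and adjusted p below
5×10⁻⁵; the published replication setting (p < 10⁻⁴, no V linking) is a
flag away.

**Clustering.** Hits are assembled into connected components of the
Hamming-1 (optionally V/J-linked) graph; components of size ≥ 2 are
reported as clusters, ranked by member count, then cumulative frequency,
then consensus string; singletons are retained separately. All members of a
component share one CDR3 length by construction, so the per-position
majority consensus (uniform or frequency-weighted; ties to the smallest
letter) is well defined, and the full position-frequency matrix is emitted
so a sequence logo can be regenerated externally. Graph export follows the
one-node-per-(clonotype, sample) convention used for Cytoscape figures,
with same-clonotype occurrences chained so each clonotype stays connected.

## Enrichment

Enrichment compares frequency sums over dLN samples against ndLN samples
(summed, not averaged, matching the cumulative-frequency convention). A
side summing to zero is replaced by the detection-threshold floor
2.5×10⁻⁵ — the smallest retainable frequency — and flagged. Ratios are
computed per clone, per cluster (summing members), and per specificity
label (mean ± SD over matched clones, SD with the n−1 denominator,
SEM = SD/√n). Swapping every sample's side maps un-floored ratios r → 1/r,
and ratios are invariant to common rescaling of both sides; both are
property-tested.

## Specificity matching

A repertoire clonotype matches a database TCR when gene-level TRBV calls
are equal and the CDR3s align within the edit budget. The default
("combined") budget allows at most one substitution and at most one indel
simultaneously: equal lengths with Hamming distance ≤ 1, or lengths
differing by one where deleting a single position from the longer leaves
Hamming distance ≤ 1 (computed in O(L) with prefix/suffix mismatch arrays).
A strict mode (substitution XOR indel) is provided because the narrower
reading is also defensible; length differences ≥ 2 never match, and indels
may sit at the termini. Per sample and label, matched clones contribute
their frequency once per label even when they match several records of that
label. Equivalence with an enumeration oracle (all ≤1-substitution,
≤1-indel variants) is tested exhaustively on a reduced alphabet.

## Synthetic studies

The generator emulates the sequencing scale of sorted lymph-node CTL
samples: per sample 1.4×10⁴ clonotypes and 10⁶ on-target reads from
7.5×10⁴ sorted cells, with log-normal clone sizes (σ = 1.5, the standard
heavy-tail model for repertoire abundances). The background pool —
sequences and clone weights — is drawn once per mouse and shared by that
mouse's dLN and ndLN samples: both nodes sample one animal's T-cell
compartment, which is what makes the within-mouse dLN/ndLN comparison
paired. Reads are multinomial at the configured depth (optional
Dirichlet-multinomial overdispersion), so realized frequencies carry
binomial noise around intended values; zero-read clones drop out.

Planted structure, identical in intended frequency across a group's mice:

* **Convergent clusters** — a seed CDR3 drawn from the background model
  plus k−1 distinct single-substitution variants (uniform without
  replacement over the 19L substitution space), all sharing the seed's V/J.
  Each cluster mirrors a real convergent response: the seed is dominant
  (`seed_dominance` = 0.4 of the cluster's mass, ~10⁻³ at defaults) with
  low-frequency variants, and every member's intended dLN frequency is
  ρ × its ndLN frequency (default ρ = 3).
* **Bystanders** — expanded single clonotypes (~10⁻³ at defaults) without
  sequence neighbors, with their own dLN enrichment factor.
* **Public clones** — planted at equal frequency on both sides and emitted
  as an exactly matching specificity database with cycling labels.

Planted sizes sit well above the detection threshold on both sides, and
intended dLN/ndLN ratios equal ρ exactly (only the background is rescaled
to fill the remaining mass), so ground truth is sufficient to recover the
enrichment factor before read sampling — an internal consistency assertion.
What the generator does **not** emulate: nucleotide-level sequencing error,
PCR amplification bias, shared public background clones between mice, and
real V(D)J generation-probability structure. Passing tests therefore show
the chain's statistical behavior under its declared null and planted
alternatives, not performance on real sequencing artifacts.

## Numerical choices and problem sizes

Poisson tails use the survival function (never 1 − CDF). BH adjustment is
the textbook step-up, cross-checked against an independent brute-force
oracle and statsmodels. Integer percentages round half away from zero.
Ranking ties break deterministically (cumulative frequency, then
lexicographic CDR3), and every stochastic component takes an explicit seed;
identical seeds reproduce studies bit-exactly.

Test-suite problem sizes are chosen to exercise each property at the scale
where it is informative while keeping the default run fast: type-I control
uses 20 null clonesets of 5,000 clonotypes; planted-cluster recovery runs
the full default-scale study (4 samples × 1.4×10⁴ clonotypes × 10⁶ reads)
on fixed seeds; the clonality contrast uses 20 seeded one-mouse studies at
default per-sample scale (at strongly reduced clonotype numbers planted
clones land near the background's mean clone size and no longer constitute
expansions, so the contrast is not probed there); exhaustive oracle
comparisons use a 4-letter alphabet up to length 5 plus randomized
length-6 pairs.

## Known limitations

* The factorized background underestimates the true sequence-space
  concentration of V(D)J recombination (real Pgen distributions are far
  more skewed), so absolute expected-neighbor counts are not comparable to
  a recombination-model null; the scan's calibration is with respect to the
  declared background.
* Cluster ranking for "top-k" summaries (member count, then cumulative
  frequency) is one reasonable convention; the choice is recorded in output
  metadata.
* Enrichment ratios use pooled sums across same-side samples rather than
  per-mouse averaging; with balanced designs the two agree in expectation.
* The label-set of sample metadata is extensible but validated
  (`dLN`/`ndLN`/`NA` sides; `CTL`/`Treg`/`other` subsets).
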