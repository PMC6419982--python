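# Methods

## The model of an OTU

`pairtax` treats an OTU as an exact unique pair of sub-reads — the first
`read_len` payload bases of the forward mate and of the reverse mate
(default 70 each, so ~140 nt of information per amplicon).  No clustering
radius is applied; instead, artifacts are controlled by three mechanisms
that each have a precise, testable definition: a per-sample minimum
relative-abundance filter, one-mismatch rescue of filtered reads, and a
parent-abundance chimera rule.  This buys determinism: the whole pipeline
is a pure function of its inputs and configuration, and byte-identical
reruns are asserted in the test suite.

## Demultiplexing

A mapping entry binds a sample to (forward barcode, reverse barcode,
forward primer, reverse primer, linker length).  Acceptance of a read
pair requires, on each mate, an exact barcode match at the 5′ end and a
zero-mismatch IUPAC match of the primer after skipping the linker bases.
Design choices:

* **The linker is skipped, not matched.**  It is a spacer chosen to be
  non-complementary to the target and identical across samples; matching
  it would add nothing to sample identification.
* **No barcode error correction.**  The zero-tolerance contract is what
  makes the partition property (assigned + rejected + too-short = input)
  and the cross-sample chimera rejection exact.  The simulator's
  `technical_error_rate` exists to verify the contract, and corrupts a
  primer base only to a base *outside* the IUPAC expansion at that
  position (an in-expansion substitution is not an observable error).
* **Orientation is fixed**: the forward FASTQ carries the forward
  barcode/primer, the reverse FASTQ the reverse ones.  No read-flipping
  heuristics.
* Reads whose payload after technical-sequence stripping is shorter than
  `read_len` are discarded and counted; base-call qualities are carried
  through and never consulted.

## OTU picking, rescue, chimera rule

The abundance threshold (default 0.001 = 0.1%) is applied per sample:
`count / reads_entering_picking >= threshold`.  Accepted OTUs are ordered
by descending count with lexicographic tie-breaks and named
`<sample>_OTU<rank>` for reproducible output.

**Rescue** assigns each discarded unique pair lying at Hamming distance
≤ 1 from an accepted OTU (over the 2·`read_len` concatenation — one
substitution total across both mates, matching a substitution-dominated
Illumina error model; indels are not considered) to the most abundant
such OTU, ties broken lexicographically.  Rescue adds to a separate
`rescued` field and can never change acceptance or exact counts, so the
result is independent of processing order.  Since one total mismatch
implies one mate matches exactly, the implementation indexes accepted
OTUs by each mate instead of scanning all pairs; a brute-force all-pairs
scan is the test oracle.

**Chimera flagging**: C is flagged iff accepted records A ≠ C and B ≠ C
exist with `A.fwd == C.fwd`, `B.rev == C.rev` and both counts ≥
`chimera_fold × C.count` (default fold 2; "at least twice" is read as ≥).
Abundance here is the pre-rescue exact count, which keeps flags stable
whether or not rescue ran.  Because (fwd, rev) keys are unique within a
sample, no single record can parent both ends of a distinct C, so the
"A and B may coincide" and "A and B must differ" readings flag identical
tables; both are exposed via `require_distinct_parents`.  Flagged records
are retained with the flag and excluded from profiles.  An exhaustive
triple-loop enumeration is the test oracle.

## Taxonomy

References are full-length 16S sequences with 6-slot lineages
(domain…genus, empty = unresolved).  On load, sequences are uppercased,
U→T, and alignment gap characters removed.  Each reference is trimmed to
the amplified region by locating the best forward-primer and
reverse-primer sites under IUPAC matching with ≤ `max_primer_mismatch`
mismatches (default 1 — references may contain isolated errors; reads,
by contrast, get zero tolerance).  Ambiguous equally good sites resolve
to the 5′-most forward and 3′-most reverse site, bounding the widest
amplicon.  Entries without both sites, or with an inter-primer region
shorter than `read_len`, are rejected and counted.

**Identity** is `1 − d/max(|a|,|b|)` with `d` the Levenshtein distance
(unit costs, end-to-end, computed with edlib).  This equals
matches/columns for a gap-minimal optimal alignment, is symmetric, and —
unlike a match count read off one particular optimal path — does not
depend on alignment tie-breaking.  For the dominant case (equal-length
fragments differing by substitutions) it is exactly the Hamming match
fraction, e.g. 69/70 for one substitution in a 70-mer.

**Combined identity** of an OTU against a trimmed reference is the mean
of the forward-fragment and reverse-fragment identities.  For end-to-end
alignments of equal-length halves this equals identity on the
concatenation while keeping the two fragments' alignments independent.
The OTU's reverse read is in read orientation, so the amplicon-oriented
reverse fragment is reverse-complemented once before comparison.

**Consensus rule.**  Hits are collected at six nested thresholds
(1.00, 0.98, 0.97, 0.95, 0.92, 0.90).  Let T be the highest populated
level.  The genus modal label at T is accepted iff its specificity
(percentage of genus-labelled hits at T sharing it) is ≥ `min_spec`
(default 50%) and the modal genus at every lower populated level agrees;
failing genus, the same test runs at family; failing both, the deepest
lineage prefix shared by all hits at T is emitted.  Hits with an empty
label at a rank count toward neither numerator nor denominator at that
rank (so a genus-less lineage still informs family statistics).  The rule
is one consistent formalisation of "deepest concordant rank"; the exact
tie between specificity and concordance is a design choice of this
package and is deliberately explicit in the code.

## Profiles and the weighted difference

A profile maps labels at one rank to fractions summing to 1 over the
non-chimeric OTUs of a sample; rescued reads are included by default, and
OTUs assigned shallower than the requested rank contribute to a reserved
`unassigned` label rather than being renormalised away — poor
classification should cost distance.

The weighted difference between profiles x and y is
`Σᵢ (xᵢ − yᵢ)² / ((xᵢ + yᵢ)/2)` over the union of labels (absent = 0;
taxa absent from both contribute 0).  The per-taxon denominator is the
two-profile mean of that taxon's abundances — the only reading of a
per-taxon weighting factor that scales a fixed absolute difference up for
rare taxa and down for common ones.  It is symmetric, non-negative and
zero exactly on equal profiles; it is a divergence, with no triangle
inequality claimed.  Degenerate bound: two disjoint singleton profiles
give 2 + 2 = 4.

## The simulator

`synth_references` emulates a set of Sanger-quality full-length
phylotypes: random padding + a concrete IUPAC expansion of the forward
primer + a random insert (default 253 nt, V4-like) + the
reverse-complemented reverse primer + padding.  Genus structure is
imposed on the inserts — genus seeds are re-drawn until all between-genus
identities are < 0.90, and within-genus members mutate ≤ 3 seed positions
(pairwise identity ≥ 0.97 at the default insert length).  Lineages share
domain/phylum/class/order and split into per-genus families and genera.

`simulate_reads` draws template assignments from the design's
multinomial, recombines two distinct templates with probability
`chimera_rate` (at the mate boundary by default — the case the chimera
rule can see; `chimera_breakpoint="uniform"` places the breakpoint
anywhere in the concatenation to quantify the rule's blind spot), applies
i.i.d. substitutions at `error_rate` to payload bases only, and emits
constant-quality FASTQ with intact technical prefixes unless
`technical_error_rate` fires.  All randomness comes from one
`random.Random(seed)`, so a fixed seed gives byte-identical FASTQ.

Preset designs: mc1 (17 members, equimolar, 10,000 pairs), mc2 (55,
equimolar, 50,000), mc3 (55, log-staggered over three decades, 50,000 —
a gut-like rank-abundance curve), mc4 (50 members from 0.001% to 2.49%,
including members at exactly 0.1%, 0.01% and 0.001%; with the 2.49% cap
the remaining 47 members are linearly spaced near 2% so the design sums
to 1; 20,000 pairs).  mc4 at 20,000 reads places the 0.01% and 0.001%
members (expected 2 and 0.2 reads) hopelessly below the 20-read
acceptance bar, which is precisely the rare-taxon cost of abundance
filtering that the test suite documents.

**What the simulator does not model** — and hence what passing tests do
not show about real data: PCR-cycle-dependent amplification bias, indels
and quality-correlated error profiles, chimera breakpoints mid-read (off
by default), 16S copy-number variation, and reference databases with
misannotated or partial lineages beyond empty ranks.  Recovery results on
simulated communities bound the pipeline's bookkeeping correctness, not
its accuracy on biological samples.

## Numerical and scale choices

* Thresholds are compared with ≥ throughout; all orderings have
  deterministic lexicographic tie-breaks; profile mass is validated to
  1 within 1e-9.
* Identity levels must be strictly descending in (0, 1]; hit nesting
  across levels then holds by construction and is asserted.
* Test and acceptance runs use the preset community sizes (10,000–50,000
  read pairs, 17–55 templates); these sizes keep every property
  exercised — multinomial noise visible, thresholds binding — while the
  whole suite runs in well under a minute.
* Reads shorter than the retained length are discarded and counted
  (their handling in the field is unstated; discarding is the
  conservative choice and keeps the partition property exact).
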