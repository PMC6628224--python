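# Methods

This note documents the models, conventions and numerical choices behind
`passalus`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and missing-data policy

The substrate is a pre-aligned set of equal-length DNA sequences over the
IUPAC alphabet plus the gap character. Loci sequenced for overlapping sets of
individuals are concatenated per individual; an individual missing a locus
receives `N` across that locus' full span (`-` is reserved for true alignment
gaps). This is how partially-overlapping mitochondrial datasets are normally
merged, and it dictates the missing-data policy everywhere downstream:

* **Per-site statistics** (*S*, *S*<sub>pi</sub>): undetermined characters
  (`N`, ambiguity codes, gaps) are ignored per column. A column segregates
  iff ≥ 2 distinct determined states occur; it is parsimony-informative iff
  ≥ 2 distinct determined states each occur in ≥ 2 sequences. A state carried
  by a single sequence is a singleton and never contributes to
  *S*<sub>pi</sub>.
* **Distances**: pairwise deletion — each pair is compared over the sites
  where both members are determined. Complete deletion would annihilate
  datasets in which one subset of individuals is padded over a long span
  (exactly the situation concatenation produces), which is why it is not
  offered for the clade summaries. A pair with zero comparable sites raises
  an error rather than returning 0 — "identical" and "incomparable" must not
  be conflated.
* Ambiguity codes other than `N` are treated as undetermined for distances
  and site counts (the conservative, DnaSP-like convention).
  `p_distance(..., ambiguity="expand")` offers the alternative reading
  (IUPAC sets; mismatch only when the sets are disjoint).

## Haplotype collapsing

Two policies. `strict`: sequences share a haplotype iff character-identical.
`compatibility` (default): iff no site has both members determined and
different; merging is the transitive closure of this relation, processed in
input order, and each group is represented by its member with fewest
undetermined positions. The compatibility policy is the one that treats an
`N`-padded record as the same haplotype as its complete twin, which is the
desired behaviour for concatenated multi-locus mtDNA.

## Divergence summaries and the 10× rule

For two labelled clades, *P*<sub>within</sub> per clade is the mean pairwise
distance over within-clade pairs of *individuals* (haplotype multiplicity
counts; a haplotype-weighted mode is available), *P*<sub>between</sub> the
mean over all cross-clade pairs, and the headline ratio is
*P*<sub>between</sub> divided by the **unweighted mean** of the two
*P*<sub>within</sub> values — the convention used in clade-based summary
tables, which the reporting layer reproduces with half-up rounding at 4
decimals (binary-float `round()` would mis-round values such as 0.00255).
The ratio is computed at full precision; rounded table entries therefore
need not reproduce a ratio recomputed from the rounded rows.

The 10× rule flags candidate cryptic species when the ratio is **at least**
10 (inclusive threshold). When mean *P*<sub>within</sub> is exactly zero the
ratio is reported as `inf` (explicit sentinel) rather than an error, since
the flag is then trivially true. Distances may be *p* or K2P
(*d* = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)); K2P raises a saturation error when
a logarithm argument is non-positive instead of silently truncating.

## Two-clade partition

The purpose of the tree stage is a *reproducible bipartition*, not a
publication tree; a full ML analysis (model selection, SPR search) is out of
scope and user-supplied clade labels always override inference. Saitou–Nei
neighbor joining is implemented directly because the partition contract
needs a fixed tie-break: among pairs minimising the Q-criterion (within
1e-12), the pair whose cluster ids (smallest contained leaf id) sort
lexicographically smallest is joined. Negative branch-length estimates are
clamped to zero (standard practice, logged at debug level). Tests cross-check
against scikit-bio's independent NJ on random additive matrices, and verify
exact recovery of additive input (path-length additivity on every leaf
pair).

Midpoint rooting delegates to scikit-bio. Two degenerate cases are handled
explicitly: an all-zero-length tree has no midpoint, so the root is placed on
the first child edge with a warning; and when the midpoint coincides with an
internal node the adjacent edge towards the lexicographically smallest tip
is split, keeping the result binary and deterministic. The two subtrees of
the root define the clades; the larger one is labelled `A` (ties: the clade
containing the lexicographically smallest id). Support for the basal split
is the fraction of column-resampling bootstrap replicates whose basal
bipartition equals the full-data one; replicates with undefined distances
count as non-matching, and an invariant alignment yields `NaN` (no split to
support). The bootstrap default is B = 1000 with a mandatory seed; tests and
the acceptance script use B = 30–100, which is ample for a split whose
support is near 0 or 1.

## Geography

Site tallies count individuals per clade per site; percentages are reported
as whole numbers. Syntopy is computed over logs with ≥ 2 sampled individuals
(a single-beetle log cannot show co-occurrence); a log is mixed iff both
clades occur in it. The packaged per-site fixture transcribes a published
count table; per-log assignments are not recoverable from per-site counts,
so its `log_id` column is empty and syntopy on it deliberately raises —
fabricating log assignments would manufacture a co-occurrence statistic.

## PCR-RFLP design

Coordinates are 0-based half-open internally and 1-based in reports. A "cut
coordinate" is the number of top-strand bases left of the scissile position;
fragment lengths are successive differences of `{0, cuts…, length}`.
Sticky-end overhangs are ignored — gel band positions track top-strand
lengths, and the published expected-fragment convention is consistent with
this choice. Specific conventions:

* **Fixed differences** require disjoint singleton determined-state sets in
  the two clades, verified per member; members undetermined at the column
  are excluded rather than vetoing it (padded records would otherwise veto
  every site). This is stricter than comparing consensus strings.
* **Amplicon extraction**: degenerate primer letters bind any base in their
  IUPAC set; a position is a mismatch only when the primer and template sets
  are disjoint, and at most `max_mismatch` (default 0) mismatches are
  allowed. The amplicon includes both primer footprints (needed to reproduce
  a product length measured from primer start to primer end); among valid
  site pairs the smallest product wins.
* **Site scanning** is conservative in the opposite direction: an ambiguous
  template base matches a recognition letter only if *every* expansion does
  (an enzyme should not be predicted to cut sequence we are not sure of).
  Non-palindromic recognitions are scanned on both strands, mapping a bottom
  match at start *s* with offset *o* to top coordinate *L* − (*s* + *o*);
  Type IIS offsets may exceed the recognition length, and cuts landing on or
  outside the boundaries are discarded. Only the top-strand cut of a Type
  IIS enzyme is modelled (the bottom-strand nick position is irrelevant to
  band lengths under the convention above).
* **Assay search** enumerates every enzyme and (optionally) every unordered
  enzyme pair, digesting every amplifiable haplotype. A design is
  diagnostic iff each clade yields one uniform pattern and the clades'
  gel-visible band sets differ (bands below `min_visible_bp` = 20 are
  dropped; two bands within `min_separation_pct` = 5 % of each other are
  considered co-migrating). The ranking — larger smallest visible band,
  then larger band-count difference, then fewer enzymes — is this package's
  own proxy for gel interpretability; no published objective exists.

The packaged enzyme table carries TaqI (`T/CGA`), BsaI (`GGTCTCN/`, Type
IIS) and DdeI (`C/TNAG`) and accepts user extensions in the same TSV format.

## Synthetic generator

`simulate()` draws a uniform ancestral sequence, applies `k_fixed`
substitutions to the clade-B root (transition with probability
ts/(ts + 1), default ts:tv weight 2.0 — a conventional default for
protein-coding mtDNA in the absence of a fitted value), then gives each
individual Poisson(`within_mutations`) private substitutions at free
positions. Within-clade variation is therefore star-like; no coalescent,
recombination, indels or sequencing error are modelled. Consequences: every
private mutation is near-unique, so the generator produces many more
low-frequency haplotypes and segregating sites at a given divergence level
than a real genealogy would — tests that pass on it certify the *estimators*
and the planted divergence structure, not genealogical realism.

Under this model E[*P*<sub>within</sub>] ≈ 2m/L, E[*P*<sub>between</sub>] ≈
(k + 2m)/L, hence an expected ratio of (k + 2m)/2m; `expected_divergence()`
exposes these as the oracle for parameter-recovery tests (Monte-Carlo mean
within 3 standard errors over 50 seeds).

Defaults are the emulated study's conditions: L = 1069 bp, 123 + 45
individuals, k = 21 and m = 2.1 — chosen so the expected
*P*<sub>between</sub> ≈ 0.0233 and *P*<sub>within</sub> ≈ 0.0040 match the
combined-dataset summary row and the expected ratio ≈ 6 sits inside the
reported 5.9–7.5 range, below the 10× flag — across 46 sites and 82 logs
with a target mixed-log fraction of 10/27. Mixed-log status is drawn
per multi-individual log with that probability, reserving one member of each
clade for designated mixed logs up front (otherwise the smaller clade's pool
drains first and the realised rate biases low); the target is hit in
expectation, not exactly.

Primer footprints and enzyme sites can be planted at exact amplicon cut
coordinates; sites are written into one clade's root and broken by a single
substitution in the other, the amplicon is scrubbed of accidental
recognition matches of the planted enzymes (editing all roots identically so
no spurious fixed difference arises), and overlapping feature requests fail
before any mutation is applied. Planted diagnostic positions are included in
the fixed-site ground truth.

Two bundled reference layouts are *synthetic stand-ins* for haplotype sets
that live in GenBank and are not redistributed here (`rflp_reference_standin`,
`polymorphism_reference_standin`): they plant the published printed facts —
the 244-bp diagnostic primer pair, the enzyme-site layout implied by the
published fragment sizes (TaqI cuts at 103 in both clades and additionally at
80 in clade B; BsaI at 68 in clade A; DdeI at 108 in clade B), and the
published polymorphism level (41 segregating / 28 informative sites among 25
haplotypes of 1097 bp) — so the pipeline must recompute those numbers from
sequence data. What this certifies is the machinery at the published study
conditions, not agreement with the actual archived sequences.

## Problem sizes and determinism

Tests and the acceptance script run study-scale simulations (≤ 168 × 1069)
and moderate bootstrap/replicate counts (B = 30–100, 20–50 seeds), which keep
the whole suite in the tens of seconds while leaving the statistical checks
comfortably powered (the properties asserted are near-deterministic at these
sizes). Every stochastic step takes an explicit seed; the pipeline writes no
timestamps, so identical config + seed ⇒ byte-identical reports.

## Known limitations

* The clade partition machinery is two-clade by construction; finer
  structure is invisible to it.
* NJ + midpoint rooting can mis-root when the two clades' terminal branches
  are grossly asymmetric; user labels override inference for such data.
* Primer thermodynamics (Tm, dimers, 3′-end sensitivity), partial digestion
  and buffer compatibility are not modelled; a design that passes in silico
  still needs one wet-lab validation round.
* The divergence-ratio expectations ignore multiple hits at the same site
  (adequate at the ~2 % divergence scale the defaults emulate).
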