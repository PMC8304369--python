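# Methods

## Domain-hit filtering

A domain match (one `--domtblout` record) counts as domain presence
when its **per-domain bit score** is at or above the profile's
gathering (GA) threshold and, where the profile carries one, its
model coverage is at or above the coverage threshold. Conventions:

- **Coverage** is the fraction of the *profile* covered,
  `(hmm_to − hmm_from + 1) / model_length`. Coverage cutoffs are
  attached to profiles (they exist to stop short partial matches of
  long or promiscuous models from counting as presence), so the
  profile side, not the alignment side, is the relevant span.
- **Inclusive comparisons.** GA is a suggested *minimum* score, so a
  score or coverage exactly at the cutoff passes; one ulp below fails.
  The boundary is pinned by tests at the calibrated values 9.45
  (zf-C2H2), 14.00 (HLH), 0.75 (bZIP_AUREO) and 0.50 (bZIP_CDD).
- **Per-domain score, not full-sequence score.** GA filtering uses the
  per-domain bit score; the independent per-domain E-value (i-Evalue)
  is carried through unfiltered and used only to rank competing family
  candidates. Whether the full-sequence or per-domain score should
  gate presence is genuinely open; the per-domain convention is the
  more conservative one for multi-domain proteins and is what the rule
  engine's veto semantics require (a domain is "present" exactly when
  its own evidence clears its own bar).
- Multiple above-threshold hits of the same domain on one protein are
  all retained; classification consumes the best (smallest) i-Evalue.

## Rule engine

A family rule is a non-empty *should* set and a possibly empty
*should-not* set of domain names (`family; domain; should` /
`should not` triplets, `#` comments, optional `family; class; TF|TR|PT`
annotations; any other rule kind is rejected loudly rather than
guessed at). Evaluation per protein, over **filtered** hits only:

- candidate iff every should-domain has ≥ 1 surviving hit and no
  should-not-domain has any. A sub-threshold occurrence of a forbidden
  domain does not veto — the thresholds define presence, and vetoes
  are statements about present domains.
- each candidate's representative E-value is the minimum i-Evalue over
  its should-domain hits; the smallest representative wins, exact ties
  broken lexicographically by family name for determinism.
- each protein is assigned to at most one family (exclusive
  assignment). This is what makes the should-not mechanism meaningful:
  without vetoes a multi-domain protein simply goes to its
  strongest-scoring candidate.

The bundled demonstration catalogue (11 families, 13 profiles) covers
every rule shape — singleton should-sets, satellite families with
HLH/Homeobox vetoes, the HMG_box veto on PHD/CCAAT_HAP5/SWI-SNF, and
coverage-gated profiles — in both its current form and a previous
generation without the vetoes, so before/after behaviour of
multi-domain proteins is testable. Production catalogues are larger;
they load through the same parsers.

## Group comparisons

Family sizes (or per-species totals) are compared between two disjoint
species groups with a normality-gated protocol:

1. Shapiro–Wilk per group at `alpha_normality` (default 0.05). The
   gate is applied **per group**; if either group fails, the
   comparison routes to the rank-sum test. Constant data in a group
   make Shapiro–Wilk undefined; such comparisons are flagged
   `degenerate` and routed to the rank-sum test directly (identical
   constant groups report p = 1.0: perfect symmetry, no evidence of a
   shift).
2. Normal route: two-sided **Welch** t-test (unequal variances). The
   equal-variance flavour is not assumed because group sizes of 3–6
   genomes give no power to check it; Welch is also the default of the
   common statistical tooling for this test.
3. Rank-sum route: for tie-free groups of ≤ 10 each, the two-sided
   p-value is computed by **full enumeration** of all C(n+m, n) rank
   assignments (`P(|W − E[W]| ≥ |w_obs − E[W]|)`), which makes small-n
   p-values exactly reproducible — e.g. the most extreme 3-vs-3 split
   gives exactly 2/20 = 0.1. Ties or larger groups fall back to the
   tie-corrected normal approximation. The enumeration is
   cross-checked against an independent library implementation in the
   test suite.

## PCA

Species are observations, families variables. Columns are
mean-centered; unit-variance scaling is off by default (count data on
a common scale; scaling would up-weight rare, noisy families) but
available as a flag. Variance fractions are `σ_k² / Σ σ²` over all
returned components and sum to 1. Component signs are fixed by making
each component's largest-magnitude loading positive, so scores are
reproducible across runs and library versions. Tests verify the
fractions against an eigendecomposition of the covariance matrix and
the reconstruction of the centered data from all components.

## Asymmetric Wagner parsimony

Family sizes are integer characters on a rooted tree. Branch cost from
parent *s* to child *t*: `g·max(t−s, 0) + max(s−t, 0)` with gain
penalty `g > 0` (default 1, the conventional default for asymmetric
Wagner reconstruction of gene counts; exposed as `--gain-penalty`).
Branch lengths are parsed and preserved but ignored — this is pure
parsimony.

- **Exact optimisation** by Sankoff dynamic programming over bounded
  integer states `0..max_state`, default `max observed count + 2`. An
  optimal labeling never needs a state above the largest leaf count
  (lowering any node above that bound can only reduce incoming gain
  cost and outgoing loss cost), so the bound is slack; equivalence to
  exhaustive enumeration is asserted over 200 random instances
  (3–8 leaves, counts ≤ 5, g ∈ {0.5, 1, 2}) on both total cost and the
  full labeling.
- **Deterministic tie-break:** among minimum-cost labelings the root
  takes the smallest optimal state, then each child the smallest state
  optimal given its parent (top-down). This equals the
  lexicographically smallest optimal labeling in preorder, which the
  brute-force oracle reproduces independently. Smallest-state is the
  content-conservative choice: ancestral genomes are not credited with
  copies the data do not force.
- With g = 1 the cost function is symmetric, so reconstruction cost is
  invariant under complementing all counts against `max_state` — a
  property test.
- Costs are sums of multiples of g; for the tested g values these are
  exactly representable floats, so cost comparisons in the DP and the
  oracle are exact.

**Event taxonomy.** Per branch (parent *s* → child *t*): gain iff
s = 0 and t ≥ 1; loss iff s ≥ 1 and t = 0; expansion iff t > s ≥ 1;
contraction iff s > t ≥ 1; none iff s = t. The labels are mutually
exclusive — a 0 → n branch counts once, as a gain. Totals can be
restricted to labeled node groups (a branch is attributed to its child
node), giving per-clade event subtotals over all families.

## Synthetic fixtures

`generate_hits` plants one family signature per non-decoy protein:
every should-domain at full model coverage, 5–25 bits above GA,
i-Evalue 10⁻³⁰–10⁻¹⁰ (rounded to the hit-table writer's printed
precision so fixtures round-trip exactly). Decoys cycle through three
flavours — sub-GA score, above-GA but sub-cutoff coverage, and
forbidden-domain co-occurrence (using a forbidden domain no family
requires, so the veto resolves to *no* family) — exercising the score
filter, the coverage filter and the veto path. The generator assumes
each family requires at least one domain unique to it (true of the
bundled catalogue), which makes planted signatures unambiguous and the
expected recovery exactly 100%.

`generate_history` simulates family counts down a random bifurcating
tree: root counts uniform on 0..3, tip counts capped at 10 (the scale
of real TAP families), events changing a count by 1–2 units. In the
default rare-event regime at most one branch per family — drawn
**uniformly over branches** — may host an event; uniform placement
matters because a sequential capped walk would concentrate events near
the root. With `max_events_per_family=None` every branch samples an
event independently at the configured rates.

**What the simulator does not emulate:** correlated evolution among
families, rate variation across branches, multi-event histories along
a single lineage, and real sequence/HMM noise (only hit tables are
synthesized, never alignments). Passing recovery tests therefore shows
the *reconstruction machinery* is correct in the regime where
parsimony is identifiable, not that parsimony recovers any real
history.

**Known limitation — root polarization.** At g = 1, a loss or
contraction on a branch adjacent to the root has the same cost as the
mirrored gain or expansion on its sibling branch; the smallest-state
tie-break then reports the sibling interpretation. Such events are
fundamentally unpolarizable by parsimony without an outgroup. On the
30-species panels used for the recovery experiments the two
root-adjacent branches are ~3% of all branches, giving planted-event
recovery of 96–99%; the measured rate is reported by the acceptance
script.

## Seed-alignment augmentation

The selection procedure for rebalancing taxonomically biased seed
alignments: incomplete candidates are dropped first (completeness is
recorded as an input flag — it comes from manual assessment and is not
decided by the tool); the cap is `floor(0.25 × original seed size)`
("no more than 25% new sequences", read against the pre-augmentation
seed; floor because the cap must not be exceeded). Candidates are
ordered into priority tiers — tier k holds each taxon group's k-th
pick, groups interleaving their species — so early tiers maximise
group and species breadth. Whole tiers are taken while they fit; the
tier that would overflow is thinned by uniform random elimination from
an explicit RNG seed. Same seed, same plan; different seeds differ
only inside the boundary tier.

## Problem sizes and runtime

The test suite and acceptance script run at desk scale by design:
200 random parsimony instances against exhaustive enumeration
(vectorised; ~8 s), a 500-protein classification fixture with 30%
decoys, a 500-family / 30-species recovery experiment (~1 s; the DP is
O(nodes × states²) per family), and exact Wilcoxon enumeration at
n ≤ 10 per group. Full-genome panels (tens of thousands of proteins,
>100 families) run through the same code paths; only the fixture sizes
are small.
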