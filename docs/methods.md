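# Methods

## Duplex representation

A duplex is two antiparallel strands plus one registration integer.
The top strand is drawn 5′→3′ left→right; the bottom strand's 5′ end is
at the right edge. `left_ext` counts bottom-strand 3′ nucleotides
protruding past the top 5′ terminus (negative: the top 5′ protrudes);
`right_ext` is derived from the identity
`len(top) − right_ext = len(bottom) − left_ext`. Strand coordinates are
1-based from each strand's own 5′ terminus; BED outputs use 0-based
half-open template coordinates. Watson–Crick complementarity is enforced
over the paired region at construction; G·U wobble pairs are rejected by
default (the characterised substrates are perfect duplexes) with an
`allow_gu` switch. Untemplated 3′-tail nucleotides are exempt from the
complementarity check because they are added without a template.
Internal mismatches and bulges are not supported: no characterised
substrate contains them, and tolerating them would require a secondary-
structure model that is out of scope.

Each strand records its source polymerase, 5′ chemistry, a provenance
interval within its original transcript and the transcript's total
length, so any product or fragment can be asked whether it retains the
transcript's 5′ or 3′ terminus. New 5′ ends created by cleavage are
assigned a monophosphate, as RNase III chemistry leaves.

## Cut-site arithmetic

With measured strand M, complement C, overhang `o ≥ 0` and register
`L = measure_len + δ`:

* domain-B cut after M position `L` iff `0 < L < len(M)` and the domain
  is active;
* complementary product length `p = L − cut_offset + o`; domain-A cut
  iff `0 < p < len(C)` and the domain is active;
* a plan is valid if at least one cut is internal. Ends with 5′
  overhangs (`o < 0`) are refused outright — they are uncharacterised,
  and refusal is the conservative choice.

Defaults `measure_len = 24` and `cut_offset = 2` reproduce every
characterised substrate→product outcome (37/38 → 24+23, 37/39 → 24+24,
24/25 → 24+23, 23/24 → 23+23, blunt 24/24 → 24+22, 26/27 → 24+23 and
its domain-mutant decompositions). One published gel calls the distal
piece of the labeled 38-nt bottom strand a "16 nt product" where this
arithmetic yields 15 (38 − 23); the arithmetic is retained because it is
the one validated by all measured *product* lengths, and the offset is
not adjusted to force the distal-fragment value.

The blunt-end register jitter δ ∈ {−1, 0, +1}, applied only when
`o = 0`, reproduces the diverse 21–25-nt product sizes of fully blunt
substrates; an overhang fixes the register (δ = 0). The deterministic
path returns the δ = 0 outcome and `enumerate_dicing_outcomes` exposes
the full enumeration; the stochastic path draws δ uniformly.

## Decision cascade

`dice` proceeds: (1) refractory check — no valid plan at either end at
δ = 0 while at least one strand reaches `measure_len`; such duplexes are
geometrically indistinguishable from products and are returned intact.
With both RNase III domains inactivated every plan is trivially invalid,
so that case is reported as NO_CUT (enzyme-caused) rather than
REFRACTORY (geometry-caused). (2) degradation — both strands below
`measure_len`: each strand that can be cut receives one cut with
retained 5′-piece length uniform on `[degradation_min_len, len − 1]`
(default minimum 17, matching the observed 17–22-nt ladder); strands of
`degradation_min_len` or shorter are left whole, and a duplex where
neither strand can be cut is returned unchanged and flagged degenerate.
(3) end choice — deterministic argmax of the end scores with ties to
LEFT (arbitrary but reproducible, and matching the canonical left-side
drawings), or sampling proportional to scores in stochastic mode.
(4) register choice, (5) cleavage and assembly with provenance
propagated. Substrates are diced at most once; re-dicing of released
fragments is off by default because precursors are ≤ ~40 bp, and
degradation is never applied to products generated within the same call
(kinetics are out of scope — the 23/23-type products persist in the
assays on the timescale measured).

Scoring weights default to `w_nt = {A: 1.0, U: 1.0, C: 0.45, G: 0.45}`,
`w_chem = {MONO_P: 1.0, TRI_P: 0.9, OH: 0.05}` and
`w_overhang = {1–2 nt: 1.0, blunt: 0.3, other: 0.0}`. The data
constrain only the orderings (A = U > C = G; monophosphate slightly
preferred over triphosphate, hydroxyl strongly disfavoured; overhangs
over blunt; overhang-nucleotide identity neutral); the magnitudes are
package choices and all tests assert orderings, not absolute values.

## Precursor generator

The generator emulates the documented end features of Pol IV–RDR2
transcription: transcript length uniform on 25–40 nt (precursors are
~25–40 bp in vivo; the distribution shape is configurable), start
nucleotide drawn from A 0.50 / G 0.30 / C 0.15 / U 0.05 (the data give
orderings — purines preferred, A over G, C over U — not exact values;
these defaults encode that ordering), RDR2 initiation offset Δ uniform
on {1, 2} (the split is not quantified), one untemplated 3′ nucleotide
appended with probability 0.75 (frequent but not universal — "often
present"), uniform tail identity, and 5′ chemistries monophosphate
(Pol IV, matching its ligation-cloning behaviour) and triphosphate
(RDR2, a nascent transcript). Templated mode draws a start site whose
template base is complementary to the drawn start nucleotide and
transcribes the reverse complement of the window.

What the generator does **not** emulate: Pol IV arrest/backtracking
mechanics, sequence-dependent start-site usage, non-uniform length
distributions, RDR2 stem-loop side products, and any coupling between
length, start nucleotide and Δ. Passing pool-level tests therefore shows
the dicing code's combinatorics, not agreement with any particular
genomic locus.

A Pol IV transcript must be at least 25 nt to template RDR2 here — the
structural minimum for the shortest in-vivo-like precursor — keeping the
default length range self-consistent.

## Pool analysis and routes

Products are tallied by (length × source strand × origin end). Origin
follows the provenance interval: FIVE_PRIME if it starts at transcript
position 1 (taking precedence when a whole short strand spans both
termini, a case that is flagged by the precedence rule itself),
THREE_PRIME if it ends at the transcript's 3′ terminus, INTERNAL
otherwise. The 24:23 ratio is reported as undefined (None), not
infinity, when a pool has no 23-mers.

Scenario labels attach to Pol IV/RDR2 substrates only: S1 — dicing at
the Pol IV-5′ end guided by the RDR2 tail overhang (24-nt Pol IV +
23-nt RDR2 products); S2 — dicing at the RDR2-5′ end with Δ = 1 (23-nt
Pol IV + 24-nt RDR2); S3 — same end with Δ = 2 (24 + 24). Synthetic
substrates and blunt-end dicing report OTHER.

`enumerate_routes` evaluates the cut plan on a generic ≥27-nt
tail-bearing precursor over the {LEFT, RIGHT} × {Δ = 1, 2} grid. The two
LEFT cells give identical outcomes because the left end does not see Δ,
so `route_counts` deduplicates identical (end, product-size) outcomes
before counting: two routes to a 24-mer from each strand, one route to a
23-mer from each strand — the combinatorial reason 24-mers outnumber
23-mers in both simulated and observed pools.

## Numerical and testing choices

All randomness flows through one explicit numpy `Generator`; no global
state. Fixture sequences are seeded and arbitrary — the characterised
oligo substrates carry information only in lengths, end geometry, 5′
features and overhang identity, which the panel reproduces exactly.
Monte-Carlo checks in the test suite use 10,000-duplex ensembles
(50,000 for parameter recovery at three standard errors) and 10,000
degradation draws per substrate; these sizes give binomial standard
errors well below the asserted tolerances. The acceptance script's
deterministic quantities are single-substrate computations; its only
stochastic quantity is the degradation-ladder minimum over 10,000 draws
per substrate.

## Known limitations

No kinetics: cleavage efficiencies enter only as relative end scores,
so time courses, partial digestion and enzyme:substrate ratios are not
modelled, and ATP plays no role (none is required by the enzyme). No
secondary structure, mismatches or G·U-containing substrates by
default. Scenario frequencies downstream of the default weight
magnitudes (e.g. the simulated 24:23 ratio of ~1.5) are qualitative
outputs — the orderings are data-backed, the magnitudes are not.
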