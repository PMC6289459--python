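# Methods

## The assay model

The package models a two-round, single-species eDNA assay on the
mitochondrial 12S "MiFish" segment. Round one amplifies all vertebrates in a
water-sample extract with broad-range primers whose binding sites are highly
conserved; the ~220 bp product (primer to primer) contains hypervariable
stretches near both ends. Round two primes inside that product with a
species-specific pair carrying universal sequencing tails (forward
TGTAAAACGACGGCCAGT, 18 nt; reverse CAGGAAACAGCTATGAC, 17 nt), so every
positive can be Sanger-sequenced with one primer set. A detection requires a
gel-positive nested reaction *and* a read that matches a reference 100% over
the read's full length; reads matching a different taxon are recorded as
non-target amplification, not detections.

The design problem is therefore: find primer windows inside the target's
first-round amplicon whose 3' ends discriminate the target from every
co-occurring species, whose melting temperatures fall in a narrow window, and
whose amplified interior still contains diagnostic positions so the read
confirms the species.

## Melting temperature

Tm is computed with the unified nearest-neighbor parameters (SantaLucia 1998)
plus duplex-initiation terms per terminal base pair, and converted from 1 M
Na⁺ to assay conditions with the Owczarzy 2004 reciprocal-temperature sodium
correction. Divalent cations, when supplied, enter as sodium equivalents via
120·√([Mg²⁺]−[dNTP]).

The published assays report Tm "per the vendor calculator" without stating
the algorithm, so the defaults here are a reconstruction: 0.25 µM oligo,
50 mM Na⁺, no divalents, and — the one genuinely free choice — the duplex
concentration term. With oligo and complement assumed equimolar (effective
CT = oligo/2 = 125 nM) the package reproduces the published universal-pair
and bluefish/toadfish core values to within 0.8 °C, which is why that
convention is the default; the "oligo in excess" convention (CT = oligo) is
selectable via `ThermoConditions(duplex="excess")` and runs ~0.9 °C hotter.

Limitations, measured by the acceptance sweep over all 42 species-specific
cores: 26/42 printed values are matched within ±1.0 °C under the defaults.
The remainder are mostly 1.0–1.8 °C low (AT-rich ray/skate cores), and three
printed values are not reproducible under any nearest-neighbor setting we
tried (SantaLucia 1998/2004, Sugimoto, Breslauer tables; CT from 60–1000 nM):
the sand tiger shark pair (both ~5–6 °C high in print relative to any model,
suggesting a table transcription issue) and the Atlantic menhaden reverse
primer (printed equal to its mate, ~7 °C below any model value). The sweep
test reports every deviation rather than hiding them.

Degenerate cores expand over their IUPAC sets (bounded at 512 expansions) and
report the minimum Tm over expansions by default — the conservative annealing
estimate — with the mean selectable.

## Mismatch semantics

All classification happens in duplex orientation: the template base stored
with a primer base is the base it physically pairs against. Watson–Crick
pairs are matches; G·T and T·G are "permissive wobbles" — they destabilise
only mildly, so they count as mismatches in totals but never toward the
penalized tally that confers specificity; the other ten ordered pairs are
penalized. "At or near the 3' end" is implemented as a window over the
3'-terminal 5 bases (configurable): published primer-specificity practice
weights that region, and the packaged assay table remains self-consistent
under it. Degenerate positions (either side) match at zero cost if any
expansion matches.

## Virtual PCR

Binding sites are found by sliding the primer core over both strands of every
reference, classifying each position as above; thresholds on total and
3'-window penalized mismatches are configurable and may be disabled (the
specificity audit wants all counts, not a cutoff). An amplicon spans the
forward primer's 5' start to the sense-strand complement of the reverse
primer's 5' start — inclusive of both primer footprints, exclusive of tails,
which never anneal. Nested PCR reports an inner product only where it lies
entirely within an outer product on the same reference, mirroring nested
amplification of a diluted first-round template. No polymerase kinetics,
amplification efficiency, or chimera formation is modelled.

## Alignment summaries and row ordering

The difference matrix automates the spreadsheet a designer reads: row 0 is
the column-majority consensus (ties become the covering IUPAC code; gaps are
ignored in counts; all-gap columns stay gaps), data rows show `.` where they
agree with the consensus. Rows are ordered by a Saitou–Nei neighbor-joining
tree built on p-distances (columns with a gap or ambiguity in either row are
skipped). Because the tree exists only to order rows, no distance correction,
bootstrap, or likelihood machinery is included. Determinism: among equal
Q-criterion values the lexicographically smallest label pair is joined;
negative branch-length estimates are clamped to zero and flagged; leaf order
is depth-first from the final join with children visited by smallest
contained original index.

## Design criteria and ranking

Defaults: Tm window 50.0–52.0 °C (the stated design window; the packaged
published assays actually span 47.7–57.5 °C, so a widened `observed` preset
exists and both are explicit presets); primer length 17–27 nt (the published
cores span 17–26); at least 2 penalized mismatches within the 3' window
against **every** non-target, for **both** primers; at least one diagnostic
position between the primer footprints against every non-target the read
could otherwise not distinguish; amplicon size 120–200 bp.

Amplicon sizes are measured on the published-table convention, which includes
the 35 nt of M13 tails: the largest published assay size (192 bp) exceeds the
172 bp available between the first-round primer footprints, so the printed
sizes can only be tail-inclusive. `AssayDesign` reports both the tail-free
footprint span and the tail-inclusive size, and the criteria bounds apply to
the latter by default (`sizes_include_tails=False` switches to the bare
span).

Candidate primers never overlap the broad-range footprints — nested primers
must prime on first-round product interior. Non-targets identical to the
target over the whole segment make the assay impossible (no primer site or
read can separate them); they abort the design with the indistinguishable set
named, mirroring the real congener pairs (e.g. *Alosa* herrings) for which no
such assay exists. Non-targets lacking a homologous site (alignment gap at
the locus) auto-pass the primer audit with a flag. Taxa the primers exclude
but the read cannot (no diagnostic position) are reported per design as a
shared-detection set.

Ranking among valid pairs is necessarily an invention (human designers chose
"by eye"): worst-case penalized 3' count over both primers and all
non-targets, descending; then combined distance of both Tms from the window
midpoint; then amplicon size nearest mid-range; position as the final
deterministic tie-break. Every emitted design re-passes all criteria when
re-audited from scratch (`audit_design`), and tightening any criterion never
enlarges the design set.

## Detection statistics

The detection unit everywhere is one (sample, taxon) cell. The OTU read
filter zeroes a per-sample count when it is strictly below 0.1% of that OTU's
total reads across samples (equality retained); totals are taken on the
input, which makes the filter idempotent. Fisher's exact test is two-sided by
the probability-mass rule (sum of hypergeometric probabilities of tables no
more probable than the observed one), computed via `scipy.stats.fisher_exact`
and verified in the tests against exhaustive enumeration; the all-zero table
returns p = 1 by convention. Seasons default to meteorological boundaries
(Mar–May spring, Jun–Aug summer, Sep–Nov fall, Dec–Feb winter) and the
mapping is an argument, since field studies may mark seasons differently.
Concordance between two methods reports shared/only-A/only-B counts,
apparent sensitivity (method detections / union of detections), and an
optional stratification of method-B positives into read bins labelled
0.1K/1K/10K ([100, 1000), [1000, 10000), [10000, ∞); boundaries
configurable).

The exact contingency construction behind the original seasonal p-values is
not published; `compare_seasons` exposes its construction (detected vs
not-detected cells × season pair, excluded taxa removed) and makes no claim
to reproduce those specific numbers.

## Synthetic data: what it emulates and what it does not

`generate_panel` draws a uniform ancestor interior, mutates each species
independently at a per-site substitution rate (substitutions only by
default — the segment's variation is substitution-dominated; an indel mode
would be a separate concern), keeps the broad-range primer sites exact, and
appends twin species as verbatim copies. Defaults: 12 species + 1 twin pair,
172 bp interior flanked by the literal universal primer sites (220 bp total),
substitution rate 0.5. The rate emulates a taxonomically broad regional panel
whose hypervariable interiors are effectively independent; at rates ≤0.35
(panels of close relatives) some species become undesignable and the package
reports that honestly — the behaviour real congener panels show. All
randomness flows from the single spec seed; outputs are byte-identical across
runs.

`generate_time_series` draws per-(sample, taxon) Bernoulli occupancy by
season, emits error-free queries equal to the taxon's amplicon interior plus
log-normal read counts, and can drop detections at a false-negative rate
while keeping the truth matrix intact.

What passing tests on this generator do **not** show about real data:
sequencing error, PCR bias and chimeras, alignment gaps from indel-rich
taxa, contamination, and non-independent site evolution are all absent. The
end-to-end recovery result (zero-noise round trip is exact; planted 9:1
summer/spring occupancy is detected at p < 0.05 in ≥95% of 200 seeded
replicates of 60 samples) therefore validates the bookkeeping and the
statistical machinery, not field performance.

## Problem sizes

The test suite and the acceptance script run on desk-scale inputs chosen as
representative rather than exhaustive: panels of 12–14 references × 220 bp,
design enumeration over ~1,600 windows per orientation, Fisher enumeration
over all 2,401 tables with cells ≤6, NJ recovery over seeded 4- and 5-taxon
additive matrices, and 200-replicate seasonal power runs.

## Known limitations

- No secondary-structure, hairpin, or primer-dimer screening, and no
  multiplex compatibility scoring; annealing temperatures and cycle numbers
  in the packaged assay table are published metadata passed through, not
  optimised.
- The Tm reconstruction is calibrated to a vendor calculator whose algorithm
  is unstated; see the deviations above.
- Species assignment is exact substring matching; it does not handle
  sequencing errors or partial reads (by design — that is the assay's rule).
- The neighbor joining here is a row-ordering device, not a phylogenetics
  tool.
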