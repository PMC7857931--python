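# Methods

## Scope and model

`flavonet` implements a two-stage analysis of high-resolution negative-mode
LC-MS/MS peak lists of plant flavonoids.

**Stage 1 — identification.** The search space is an *expected-compound*
library: each aglycone skeleton is combined with every multiset of metabolic
transformations (phase I: reduction +H2, oxidation +O; phase II: glucoside
+C6H10O5, glucuronide +C6H8O6, pentoside +C5H8O4, methylation +CH2) within
configurable limits, and kept if its elemental composition fits the element
cap (default C30H60O20). Observed precursors are matched against the library
at 5 ppm above a 1e4 intensity floor; MS2 evidence is then collected at
10 ppm and the best candidate selected.

**Stage 2 — network pharmacology.** Compound–target tables become a bipartite
graph for compound ranking; PPI edge lists filtered at confidence > 0.4
become the interaction network whose high-centrality nodes (degree ≥ 50,
normalised betweenness ≥ 0.01, closeness ≥ 0.6, all inclusive) are the core
targets; a hypergeometric over-representation test scores those targets
against GO/pathway annotation tables. External target/interaction/annotation
services are deliberately not queried: all inputs are offline tables, and the
synthetic-data module generates inputs with planted ground truth.

## Mass arithmetic

Monoisotopic masses use CODATA/AME atomic values (C = 12 exactly,
H = 1.00782503207, O = 15.9949146196, N = 14.0030740048, S = 31.97207100 Da)
and the electron mass 0.00054857990907 Da. The deprotonated-ion convention is

    m/z([M−H]⁻) = M − m(H) + m(e⁻),

i.e. the anion's extra electron is included. This is the discriminating
choice: a small fragment such as the pyrogallol-type ion of taxifolin
(C6H5O3⁻, m/z 125.0244) shifts by 4.4 ppm if the electron term is dropped,
flipping its error from −8.1 ppm to about −3.8 ppm against the same observed
value. ppm error is (observed − theoretical)/theoretical × 1e6.

Rounding (half-even, 4 d.p. for m/z, 2 d.p. for ppm) happens only at
reporting boundaries; all internal arithmetic is full precision. A separate
helper recomputes error columns *between printed (4 d.p.) operands*, because
published tables are internally consistent at that precision, not against
full-precision theoreticals.

Three printed theoretical cells in the packaged reference table (C27H30O17,
C21H18O13, C15H12O5) are not reproducible from any standard atomic-mass
table under any single rounding rule; the corresponding exact values are
625.1410, 477.0675 and 271.0612. The fixture transcribes the printed values
verbatim; tests that assert computed masses use the exact values and the
discrepancy is surfaced, not hidden.

## Annotation engine

For each precursor match the engine gathers two evidence families, always
anchoring expected fragment positions on the candidate's *theoretical*
precursor m/z (a precursor measured a few ppm off would otherwise displace
every expected fragment by the same relative error):

* **Neutral losses.** For every non-empty sub-multiset of the candidate's
  sugar conjugates, each sugar departs either intact (162.0528 hexose,
  176.0321 glucuronide, 132.0423 pentose) or — hexoses only — via a
  cross-ring cleavage (120.0423 C4H8O4 or 90.0317 C3H6O3). Every distinct
  combination defines one expected fragment slot.
* **Diagnostic fragments.** Each skeleton carries its empirically
  established negative-mode aglycone ions (aglycone [M−H]⁻, radical
  [Y0−H]⁻• where typical, retro-Diels-Alder A/B-ring fragments). These are
  matched regardless of which conjugates are attached.

Candidates are ranked by: reference-standard support, evidence count
(losses + diagnostics), |precursor ppm|, number of transformations
(parsimony), label. Parsimony matters because phase I deltas can make a
transformed skeleton isobaric with a simpler conjugate of another skeleton;
when the spectrum cannot discriminate, the engine prefers the explanation
with fewer steps, which is what an analyst would report. All surviving
candidates are retained in the result's evidence trail for audit.

One hard-coded disambiguation exists: apigenin and baicalein share C15H10O5,
so their glycosides are exact isobars. When the two skeletons tie on all
other criteria, a base peak at the radical aglycone ion 268.0373 assigns
apigenin (homolytic O-glycoside cleavage characteristic of apigenin
glycosides); a base peak at the even-electron 269.0455 ion assigns
baicalein. Results decided this way are flagged `rule_derived`.

Glycosidic linkage is classified from the matched loss family: any intact
sugar loss ⇒ O-glycoside; at least two cross-ring losses and no intact loss
⇒ C-glycoside; otherwise undetermined (e.g. glucuronides whose aglycone ion
is absent). Confidence tiers: `standard_confirmed` (neutral formula and
retention time within `rt_tol`, default 0.1 min, of an authentic standard —
the RT tolerance is a package default, chosen as a typical UHPLC
reproducibility bound, not a published value), `characterized` (≥ 1 MS2
evidence hit), `tentative` (mass-only), `unannotated`. An aglycone-level
standard vouches only for its own skeleton; conjugate-level standards
(e.g. phlorizin) accept any candidate with the matching formula and let the
evidence ranking pick the skeleton.

Positional isomers are never distinguished: four distinct peaks may all be
reported as the same hexoside, separated only by retention time, which is
carried but never interpreted.

## Network analysis

Graphs are simple and undirected (duplicate edges merge keeping the maximum
confidence; self-loops are dropped and counted). Centralities follow common
network-tool conventions: integer degree; betweenness normalised by
(n−1)(n−2)/2; closeness computed within a node's connected component and
scaled by (|C|−1)/(n−1) so it stays in [0, 1] on disconnected graphs
(singletons get 0). Edge confidences filter (strictly greater than the
cutoff) but never weight shortest paths. Gene symbols are uppercased on
ingestion; symbol harmonisation beyond case is left to a user-supplied
synonym table. Computation is delegated to `networkx`; tests verify it
against an exhaustive shortest-path enumeration oracle on all small graphs.

## Enrichment

The statistic is the one-sided upper-tail hypergeometric probability
P(X ≥ k) for k study hits in a term of size K, study size n, background N.
The EASE variant (tail at k−1, floored at 0) is available to mimic the
conservative behaviour of popular enrichment services. The significance flag
defaults to raw p < 0.05 — the criterion used in the kind of study this
package supports — with Benjamini–Hochberg adjusted p-values always computed
per category and reported alongside, never silently substituted. The
background universe must come from the database file; there is no hidden
genome-size default.

## Synthetic data

The generator's defaults are the study conditions used throughout the tests:
30 true peaks + 10 decoys, precursor and fragment errors independent
Normal(0, 2 ppm) in ppm space (matching the |error| ≤ ~4 ppm seen in real
Orbitrap tables), 10 % fragment dropout, fragment relative intensities
uniform(5, 100) with the base peak forced to 100, decoy precursors redrawn
until ≥ 25 ppm from every library mass. All randomness flows through one
explicit seed.

True compounds are drawn as *pure phase II conjugates* of the skeleton panel
(generator `max_phase1 = 0`), while the annotator searches the full
phase-I-inclusive library. A reduced or oxidised aglycone is an exact
mass-and-diagnostic degenerate of an isomeric unmodified skeleton
(e.g. reduced kaempferol vs eriodictyol, both C15H12O6), so such ground
truths would be unattributable by construction; excluding them from the
generator — not from the search space — keeps the round-trip benchmark
meaningful. Simulated conjugates fragment as O-glycosides (intact losses +
skeleton diagnostics). The generator does not model chromatographic peak
shape, isotope envelopes, co-elution, in-source fragmentation or realistic
retention times, so round-trip recovery rates measure the rule engine under
its own noise model, not performance on raw instrument data.

## Problem sizes and determinism

The packaged fixture has 43 peaks; the default extended library holds 777
candidates (ten skeletons, ≤ 1 phase I + ≤ 3 phase II, C30H60O20 cap — the
deepest real annotations carry two sugars, so three phase II slots leave
head-room without bloating the library). Round-trip benchmarks use 30 true
peaks per seed across 20 seeds; oracle comparisons use all-pairs path
enumeration on graphs of ≤ 8 nodes and exact binomial-coefficient sums for
N ≤ 30. Every pipeline stage is deterministic given its inputs and seed;
annotation exports are byte-identical across reruns.

## Known limitations

* Identification is formula-level: positional isomers and stereochemistry
  are out of scope, as are positive-ion adducts, multiple charging and
  isotope-pattern scoring.
* Diagnostic-fragment lists are curated per skeleton; a skeleton without
  diagnostics falls back to mass-plus-loss evidence only.
* The centrality thresholds are meaningful for PPI networks of a few hundred
  nodes; on much larger or much sparser graphs they should be re-derived.
* Published network/enrichment node counts depend on the era-specific
  snapshots of external services and are not desk-reproducible; the package
  therefore validates those stages against planted synthetic ground truth
  instead.
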