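# flavonet

Rule-based identification of flavonoids from high-resolution negative-mode
LC-MS/MS peak lists, plus the network-pharmacology post-processing that turns
the identified compounds into ranked targets and enriched pathways.

The package is aimed at natural-products and metabolomics researchers who
profile plant extracts on Orbitrap-class instruments and want a transparent,
scriptable alternative to vendor "expected compounds" workflows and to
web-service-bound network analysis: every rule is explicit, every input is an
offline table, and every stage is testable against synthetic data with known
ground truth.

## What it computes

**Identification.** A candidate library is enumerated as
*aglycone skeleton × phase I/II transformation multiset* (reduction +H2,
oxidation +O, glucoside +C6H10O5, glucuronide +C6H8O6, pentoside +C5H8O4,
methylation +CH2) under an element cap (default C30H60O20). For a neutral
molecule M the deprotonated ion is

    m/z([M−H]⁻) = M − m(H) + m(e⁻)

and matching uses ppm error, (m/z_obs − m/z_theo)/m/z_theo × 10⁶, at 5 ppm
(MS1) and 10 ppm (MS2). MS2 evidence combines neutral losses of the
candidate's own sugars — intact (162.0528 / 176.0321 / 132.0423 Da) for
O-glycosides, cross-ring (120.0423 / 90.0317 Da) for C-glycosides — with
diagnostic aglycone fragments, and annotations are confirmed against
reference standards by retention time + formula.

**Network pharmacology.** Compound–target edge tables are ranked by degree
and betweenness; PPI edge lists (confidence > 0.4) yield centralities whose
thresholds (degree ≥ 50, betweenness ≥ 0.01, closeness ≥ 0.6) select core
targets; a one-sided hypergeometric test (optionally EASE-penalised, with
Benjamini–Hochberg values reported alongside) scores term enrichment.

See `docs/methods.md` for conventions, tie-breaking and limitations.

## Worked example

A packaged fixture transcribes a published 43-peak flavonoid profile of
*Potentilla freyniana* root extract. Annotate it end to end:

```bash
flavonet fixture --out peaks.tsv
flavonet annotate --spectra peaks.tsv --out annotations.tsv
# annotated 43/43 peaks -> annotations.tsv
```

The output table mirrors a publication-style identification table
(abridged):

```
peak  rt     theoretical_mz  experimental_mz  formula     identification        linkage  confidence
1     3.59   465.1038        465.1039         C21H22O12   taxifolin-glucoside   O        characterized
6     4.41   593.1512        593.1535         C27H30O15   apigenin-glucoside-
                                                          glucoside             C        characterized
27    12.16  435.1297        435.1300         C21H24O10   phlorizin             O        standard_confirmed
43    16.71  283.0612        283.0613         C16H12O5    wogonin               -        standard_confirmed
```

Peak 6 is read as a di-C-glycoside because its fragments match cross-ring
losses (−120.0423/−90.0317 combinations) with no intact hexose loss; peak 27
is confirmed as phlorizin because an authentic standard with the same
neutral formula elutes at the same retention time. 13 of the 43 peaks are
standard-confirmed; the rest are characterized from MS2 evidence.

The same stages are available as a library:

```python
from flavonet import (annotate, generate_candidates, load_preset,
                      reference_standards, table1_fixture)

library = generate_candidates(load_preset("extended"))
records, expected = table1_fixture()
results = annotate(records, library, reference_standards())
print(sum(r.candidate is not None for r in results))  # 43
```

For the network half, `flavonet network --edges ppi.tsv --out centrality.tsv`
writes per-node centralities with a core-target flag, and
`flavonet enrich --genes core.txt --database annotations.gmt.tsv --out enrich.tsv`
writes the enrichment table. `flavonet simulate` generates synthetic spectra
with ground truth for benchmarking.

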