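"""Rule-based MS1/MS2 flavonoid identification.

The engine mirrors how an analyst annotates glycosylated flavonoids in
negative mode:

1. the observed precursor is matched against the expected-compound library at
   a tight MS1 tolerance (default 5 ppm) above an intensity floor;
2. for every surviving candidate, MS2 evidence is collected: neutral losses of
   the candidate's own conjugates (intact sugars for O-glycosides, cross-ring
   cleavages 120.0423 / 90.0317 Da for C-glycosides, singly and in
   combination) and the diagnostic fragment ions of the aglycone skeleton;
3. the best candidate is selected by evidence count, then precursor accuracy,
   then parsimony (fewest transformations), then label;
4. the glycosidic linkage is classified from which loss family matched;
5. confidence is upgraded to ``standard_confirmed`` when an authentic
   reference standard with the same neutral formula elutes at the same
   retention time.

Expected fragment positions are always anchored on the candidate's
*theoretical* precursor m/z, never the observed one: precursor mass errors of
a few ppm would otherwise displace every expected fragment by the same
relative error, while real fragment measurements are independent of the
precursor's error.

One empirical disambiguation rule is encoded for the apigenin/baicalein pair,
which share C15H10O5 and therefore produce isobaric glycosides: when the two
tie on all other evidence, a base peak at the radical aglycone ion m/z
268.0373 ([Y0-H]-., homolytic O-glycoside cleavage typical of apigenin
glycosides) assigns the apigenin skeleton, while a base peak at the even-
electron aglycone ion 269.0455 assigns baicalein.  Annotations decided by
this rule are flagged ``rule_derived`` in their evidence trail.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .chem_core import (
    ElementalFormula,
    deprotonated_mz,
    monoisotopic_mass,
    ppm_error,
    round_mz,
    round_ppm,
    within_tolerance,
)
from .candidate_library import CandidateCompound, Skeleton

__all__ = [
    "SpectrumRecord",
    "NeutralLossRule",
    "MatchedLoss",
    "MatchedDiagnostic",
    "AnnotationResult",
    "ReferenceStandard",
    "AnnotationConfig",
    "standard_loss_rules",
    "match_ms1",
    "detect_neutral_losses",
    "match_diagnostic_fragments",
    "classify_glycoside_linkage",
    "confirm_with_standards",
    "annotate",
    "read_spectra_tsv",
    "write_spectra_tsv",
    "read_spectra_mgf",
    "write_spectra_mgf",
    "results_to_tsv",
]

# Radical / even-electron aglycone ions used by the apigenin-vs-baicalein rule.
APIGENIN_RADICAL_MZ = 268.0373
APIGENIN_ANION_MZ = 269.0455


@dataclass(frozen=True)
class SpectrumRecord:
    """One chromatographic peak: precursor plus its MS2 fragment list.

    Fragments are (m/z, relative intensity in 0-100) pairs and are stored
    sorted by descending intensity, so ``fragments[0]`` is the base peak.
    """

    peak_id: int
    rt: float
    precursor_mz: float
    precursor_intensity: float
    fragments: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError("retention time must be >= 0")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        frags = tuple(sorted(self.fragments, key=lambda f: (-f[1], f[0])))
        for mz, _ in frags:
            if mz >= self.precursor_mz + 0.5:
                raise ValueError(
                    f"fragment {mz} above precursor {self.precursor_mz} in peak "
                    f"{self.peak_id}"
                )
        object.__setattr__(self, "fragments", frags)

    @property
    def base_peak_mz(self) -> float | None:
        return self.fragments[0][0] if self.fragments else None


@dataclass(frozen=True)
class NeutralLossRule:
    """A departed neutral with its interpretation (intact sugar or cross-ring)."""

    name: str
    loss_formula: ElementalFormula
    interpretation: str  # "intact" or "cross_ring"

    @property
    def loss_mass(self) -> float:
        return monoisotopic_mass(self.loss_formula)


_INTACT_LOSS = {
    "glucoside": NeutralLossRule("glucose", ElementalFormula.parse("C6H10O5"), "intact"),
    "glucuronide": NeutralLossRule(
        "glucuronic acid", ElementalFormula.parse("C6H8O6"), "intact"
    ),
    "pentoside": NeutralLossRule("pentose", ElementalFormula.parse("C5H8O4"), "intact"),
}

# Cross-ring (0,2X / 0,3X) cleavages of a C-linked hexose.
_CROSS_RING = (
    NeutralLossRule("cross-ring C4H8O4", ElementalFormula.parse("C4H8O4"), "cross_ring"),
    NeutralLossRule("cross-ring C3H6O3", ElementalFormula.parse("C3H6O3"), "cross_ring"),
)


def standard_loss_rules() -> list[NeutralLossRule]:
    """The stock loss vocabulary: intact sugars plus hexose cross-ring losses."""
    return list(_INTACT_LOSS.values()) + list(_CROSS_RING)


@dataclass(frozen=True)
class MatchedLoss:
    rule_names: tuple[str, ...]
    interpretation: str  # "intact" or "cross_ring"
    expected_mz: float
    observed_mz: float
    ppm: float
    #: observed precursor minus observed fragment: the loss an analyst reads
    #: off the spectrum (e.g. printed at 3 d.p. in identification tables).
    observed_loss: float = 0.0

    def label(self) -> str:
        return "+".join(self.rule_names)


@dataclass(frozen=True)
class MatchedDiagnostic:
    diagnostic_mz: float
    diagnostic_label: str
    observed_mz: float
    ppm: float


@dataclass(frozen=True)
class ReferenceStandard:
    """An authentic standard: identity, neutral formula, expected RT (min)."""

    name: str
    neutral_formula: ElementalFormula
    expected_rt: float

    def __post_init__(self) -> None:
        if self.expected_rt <= 0:
            raise ValueError("standard retention time must be positive")


@dataclass(frozen=True)
class CandidateEvidence:
    """Evidence trail for one surviving candidate of one record."""

    candidate: CandidateCompound
    precursor_ppm: float
    losses: tuple[MatchedLoss, ...]
    diagnostics: tuple[MatchedDiagnostic, ...]
    standard_match: str | None = None
    rule_derived: bool = False

    @property
    def n_evidence(self) -> int:
        return len(self.losses) + len(self.diagnostics)


@dataclass(frozen=True)
class AnnotationResult:
    peak_id: int
    rt: float
    experimental_mz: float
    candidate: CandidateCompound | None
    precursor_ppm: float | None
    evidence: tuple[CandidateEvidence, ...] = ()  # winner first, then audit trail
    confidence: str = "unannotated"
    glycoside_linkage: str | None = None  # "O", "C", "undetermined" or None
    standard_name: str | None = None

    def __post_init__(self) -> None:
        if (self.candidate is None) != (self.confidence == "unannotated"):
            raise ValueError("candidate is None iff confidence is 'unannotated'")


@dataclass(frozen=True)
class AnnotationConfig:
    ms1_tol_ppm: float = 5.0
    ms2_tol_ppm: float = 10.0
    min_intensity: float = 10000.0
    rt_tol_min: float = 0.1


def match_ms1(
    record: SpectrumRecord,
    library: Sequence[CandidateCompound],
    tol_ppm: float = 5.0,
    min_intensity: float = 10000.0,
) -> list[tuple[CandidateCompound, float]]:
    """Library candidates within ``tol_ppm`` of the precursor, |ppm| ascending.

    Records below the intensity floor return no matches at all.
    """
    if record.precursor_intensity < min_intensity:
        return []
    hits = [
        (c, ppm_error(record.precursor_mz, c.theoretical_mz))
        for c in library
        if within_tolerance(record.precursor_mz, c.theoretical_mz, tol_ppm)
    ]
    hits.sort(key=lambda pair: (abs(pair[1]), pair[0].label))
    return hits


def _loss_combinations(candidate: CandidateCompound) -> list[tuple[tuple[str, ...], float, str]]:
    """All loss multisets consistent with the candidate's sugar complement.

    For every non-empty sub-multiset of the candidate's sugars, each chosen
    sugar either departs intact or (hexoses only) via one of the two
    cross-ring cleavages.  A combination is 'cross_ring' as soon as any of
    its components is.
    """
    sugars = candidate.sugar_multiset
    combos: dict[tuple[str, ...], tuple[float, str]] = {}
    for r in range(1, len(sugars) + 1):
        for subset in set(itertools.combinations(sugars, r)):
            options_per_sugar = []
            for sugar in subset:
                options = [_INTACT_LOSS[sugar]]
                if sugar == "glucoside":
                    options.extend(_CROSS_RING)
                options_per_sugar.append(options)
            for assignment in itertools.product(*options_per_sugar):
                names = tuple(sorted(rule.name for rule in assignment))
                mass = sum(rule.loss_mass for rule in assignment)
                kind = (
                    "cross_ring"
                    if any(r.interpretation == "cross_ring" for r in assignment)
                    else "intact"
                )
                combos[names] = (mass, kind)
    return [(names, mass, kind) for names, (mass, kind) in combos.items()]


def detect_neutral_losses(
    record: SpectrumRecord,
    candidate: CandidateCompound,
    tol_ppm: float = 10.0,
) -> list[MatchedLoss]:
    """Match expected neutral-loss fragments of ``candidate`` in the spectrum.

    Expected fragment m/z = theoretical precursor m/z - loss mass, anchored on
    the THEORETICAL precursor; every observed fragment within ``tol_ppm`` of
    an expected position is reported with its ppm deviation.
    """
    matches: list[MatchedLoss] = []
    for names, loss_mass, kind in _loss_combinations(candidate):
        expected = candidate.theoretical_mz - loss_mass
        if expected <= 0:
            continue
        best: MatchedLoss | None = None
        for frag_mz, _ in record.fragments:
            if within_tolerance(frag_mz, expected, tol_ppm):
                dev = ppm_error(frag_mz, expected)
                if best is None or abs(dev) < abs(best.ppm):
                    best = MatchedLoss(
                        names, kind, expected, frag_mz, dev,
                        record.precursor_mz - frag_mz,
                    )
        if best is not None:
            matches.append(best)
    matches.sort(key=lambda m: m.expected_mz, reverse=True)
    return matches


def match_diagnostic_fragments(
    record: SpectrumRecord,
    skeleton: Skeleton,
    tol_ppm: float = 10.0,
) -> list[MatchedDiagnostic]:
    """Diagnostic aglycone ions of ``skeleton`` found among the fragments."""
    matches: list[MatchedDiagnostic] = []
    for diag_mz, label in skeleton.diagnostic_fragments:
        best: MatchedDiagnostic | None = None
        for frag_mz, _ in record.fragments:
            if within_tolerance(frag_mz, diag_mz, tol_ppm):
                dev = ppm_error(frag_mz, diag_mz)
                if best is None or abs(dev) < abs(best.ppm):
                    best = MatchedDiagnostic(diag_mz, label, frag_mz, dev)
        if best is not None:
            matches.append(best)
    return matches


def classify_glycoside_linkage(
    record: SpectrumRecord,
    candidate: CandidateCompound,
    tol_ppm: float = 10.0,
    losses: Sequence[MatchedLoss] | None = None,
) -> str:
    """O / C / undetermined from which loss family the spectrum supports.

    An intact-sugar loss (162.0528 hexose, 176.0321 glucuronide, 132.0423
    pentose, alone or combined) is the signature of an O-glycoside; two or
    more cross-ring cleavages without any intact loss indicate a C-glycoside.
    """
    if not candidate.sugar_multiset:
        raise ValueError("linkage classification requires a sugar-bearing candidate")
    if losses is None:
        losses = detect_neutral_losses(record, candidate, tol_ppm)
    intact = [m for m in losses if m.interpretation == "intact"]
    cross = [m for m in losses if m.interpretation == "cross_ring"]
    if intact:
        return "O"
    if len(cross) >= 2:
        return "C"
    return "undetermined"


def _standards_matching(
    record: SpectrumRecord,
    standards: Sequence[ReferenceStandard],
    rt_tol: float,
    tol_ppm: float,
) -> list[ReferenceStandard]:
    out = []
    for std in standards:
        if abs(record.rt - std.expected_rt) > rt_tol:
            continue
        if within_tolerance(record.precursor_mz, deprotonated_mz(std.neutral_formula), tol_ppm):
            out.append(std)
    return out


def confirm_with_standards(
    result: AnnotationResult,
    record: SpectrumRecord,
    standards: Sequence[ReferenceStandard],
    rt_tol: float = 0.1,
    tol_ppm: float = 5.0,
) -> AnnotationResult:
    """Upgrade confidence to ``standard_confirmed`` on an RT + formula match."""
    if result.candidate is None:
        raise ValueError("cannot confirm a result without a candidate")
    for std in _standards_matching(record, standards, rt_tol, tol_ppm):
        if std.neutral_formula == result.candidate.neutral_formula:
            return replace(result, confidence="standard_confirmed", standard_name=std.name)
    return result


def _rank_candidates(
    record: SpectrumRecord,
    evidences: list[CandidateEvidence],
    ms2_tol_ppm: float,
) -> list[CandidateEvidence]:
    """Order candidate evidence: standards, evidence count, accuracy, parsimony.

    The apigenin/baicalein base-peak rule is applied only to break an
    otherwise exact tie between those two skeletons.
    """
    evidences = sorted(
        evidences,
        key=lambda e: (
            e.standard_match is None,
            -e.n_evidence,
            abs(e.precursor_ppm),
            e.candidate.n_transformations,
            e.candidate.label,
        ),
    )
    if len(evidences) >= 2:
        a, b = evidences[0], evidences[1]
        tied = (
            (a.standard_match is None) == (b.standard_match is None)
            and a.n_evidence == b.n_evidence
            and abs(a.precursor_ppm - b.precursor_ppm) < 1e-12
            and a.candidate.n_transformations == b.candidate.n_transformations
        )
        skeletons = {a.candidate.skeleton.name, b.candidate.skeleton.name}
        if tied and skeletons == {"apigenin", "baicalein"}:
            base = record.base_peak_mz
            chosen: str | None = None
            if base is not None:
                if within_tolerance(base, APIGENIN_RADICAL_MZ, ms2_tol_ppm):
                    chosen = "apigenin"
                elif within_tolerance(base, APIGENIN_ANION_MZ, ms2_tol_ppm):
                    chosen = "baicalein"
            if chosen is not None and a.candidate.skeleton.name != chosen:
                evidences[0], evidences[1] = b, a
            if chosen is not None:
                evidences[0] = replace(evidences[0], rule_derived=True)
    return evidences


def annotate(
    records: Sequence[SpectrumRecord],
    library: Sequence[CandidateCompound],
    standards: Sequence[ReferenceStandard] = (),
    config: AnnotationConfig | None = None,
) -> list[AnnotationResult]:
    """Full identification pass: MS1 match, MS2 evidence, linkage, standards.

    Deterministic: identical inputs give identical results.  Records with no
    library match (or below the intensity floor) come back ``unannotated``.
    """
    cfg = config or AnnotationConfig()
    skeleton_names = {c.skeleton.name for c in library}
    results: list[AnnotationResult] = []
    for record in records:
        ms1 = match_ms1(record, library, cfg.ms1_tol_ppm, cfg.min_intensity)
        if not ms1:
            results.append(
                AnnotationResult(
                    record.peak_id, record.rt, record.precursor_mz, None, None
                )
            )
            continue
        matched_standards = _standards_matching(
            record, standards, cfg.rt_tol_min, cfg.ms1_tol_ppm
        )
        evidences: list[CandidateEvidence] = []
        for candidate, prec_ppm in ms1:
            losses = detect_neutral_losses(record, candidate, cfg.ms2_tol_ppm)
            diagnostics = match_diagnostic_fragments(
                record, candidate.skeleton, cfg.ms2_tol_ppm
            )
            std_name = None
            for std in matched_standards:
                if std.neutral_formula != candidate.neutral_formula:
                    continue
                # an aglycone-level standard only vouches for its own skeleton
                if std.name in skeleton_names and (
                    std.name != candidate.skeleton.name or candidate.transformations
                ):
                    continue
                std_name = std.name
                break
            evidences.append(
                CandidateEvidence(candidate, prec_ppm, tuple(losses), tuple(diagnostics), std_name)
            )
        evidences = _rank_candidates(record, evidences, cfg.ms2_tol_ppm)
        winner = evidences[0]
        linkage = None
        if winner.candidate.sugar_multiset:
            linkage = classify_glycoside_linkage(
                record, winner.candidate, cfg.ms2_tol_ppm, winner.losses
            )
        if winner.standard_match is not None:
            confidence = "standard_confirmed"
        elif winner.n_evidence > 0:
            confidence = "characterized"
        else:
            confidence = "tentative"
        results.append(
            AnnotationResult(
                record.peak_id,
                record.rt,
                record.precursor_mz,
                winner.candidate,
                winner.precursor_ppm,
                tuple(evidences),
                confidence,
                linkage,
                winner.standard_match,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Peak-list I/O: a plain TSV dialect and MGF.
# ---------------------------------------------------------------------------

def _format_fragments(fragments: Iterable[tuple[float, float]]) -> str:
    return ";".join(f"{mz:.4f}:{inten:g}" for mz, inten in fragments) or "-"


def _parse_fragments(text: str) -> tuple[tuple[float, float], ...]:
    if not text or text == "-":
        return ()
    out = []
    for chunk in text.split(";"):
        mz, _, inten = chunk.partition(":")
        out.append((float(mz), float(inten or 100.0)))
    return tuple(out)


def write_spectra_tsv(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    lines = ["peak_id\trt_min\tprecursor_mz\tintensity\tfragments"]
    for r in records:
        lines.append(
            f"{r.peak_id}\t{r.rt:.2f}\t{r.precursor_mz:.4f}\t{r.precursor_intensity:g}"
            f"\t{_format_fragments(r.fragments)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectra_tsv(path: str | Path) -> list[SpectrumRecord]:
    records = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith(("#", "peak_id\t")):
            continue
        try:
            peak_id, rt, mz, intensity, fragments = line.split("\t")
            records.append(
                SpectrumRecord(
                    int(peak_id),
                    float(rt),
                    float(mz),
                    float(intensity),
                    _parse_fragments(fragments),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed spectrum row: {exc}") from exc
    return records


def write_spectra_mgf(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Write peaks as MGF via pyteomics (TITLE carries the peak id, RT in s)."""
    from pyteomics import mgf

    spectra = [
        {
            "m/z array": [mz for mz, _ in r.fragments],
            "intensity array": [inten for _, inten in r.fragments],
            "params": {
                "title": f"peak_{r.peak_id}",
                "pepmass": (r.precursor_mz, r.precursor_intensity),
                "rtinseconds": round(r.rt * 60.0, 2),
                "charge": "1-",
            },
        }
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as handle:
        mgf.write(spectra, handle)


def read_spectra_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF peak list via pyteomics into SpectrumRecords."""
    from pyteomics import mgf
    from pyteomics.auxiliary import PyteomicsError

    records: list[SpectrumRecord] = []
    try:
        with mgf.MGF(str(path)) as reader:
            for spectrum in reader:
                params = spectrum["params"]
                title = str(params.get("title", ""))
                digits = "".join(ch for ch in title if ch.isdigit())
                peak_id = int(digits) if digits else len(records) + 1
                pepmass = params.get("pepmass", (0.0, None))
                intensity = pepmass[1] if len(pepmass) > 1 and pepmass[1] else 0.0
                fragments = tuple(
                    zip(
                        (float(x) for x in spectrum["m/z array"]),
                        (float(x) for x in spectrum["intensity array"]),
                    )
                )
                records.append(
                    SpectrumRecord(
                        peak_id,
                        float(params.get("rtinseconds", 0.0)) / 60.0,
                        float(pepmass[0]),
                        float(intensity),
                        fragments,
                    )
                )
    except PyteomicsError as exc:
        raise ValueError(f"{path}: malformed MGF: {exc}") from exc
    return records


def results_to_tsv(
    results: Sequence[AnnotationResult],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Export annotations as a table mirroring a published identification table."""
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append(
        "peak\trt\ttheoretical_mz\texperimental_mz\terror_ppm\tformula\t"
        "identification\taglycone\tconjugates\tlinkage\tconfidence\tstandard\tevidence"
    )
    for r in results:
        if r.candidate is None:
            lines.append(
                f"{r.peak_id}\t{r.rt:.2f}\t-\t{round_mz(r.experimental_mz)}\t-\t-\t"
                "-\t-\t-\t-\tunannotated\t-\t-"
            )
            continue
        winner = r.evidence[0]
        evidence_text = (
            ";".join(
                [f"loss:{m.label()}@{round_mz(m.observed_mz)}" for m in winner.losses]
                + [
                    f"diag:{round_mz(d.diagnostic_mz)}@{round_mz(d.observed_mz)}"
                    for d in winner.diagnostics
                ]
            )
            or "-"
        )
        if winner.rule_derived:
            evidence_text += ";rule_derived"
        lines.append(
            "\t".join(
                [
                    str(r.peak_id),
                    f"{r.rt:.2f}",
                    f"{round_mz(r.candidate.theoretical_mz):.4f}",
                    f"{round_mz(r.experimental_mz):.4f}",
                    f"{round_ppm(r.precursor_ppm):.2f}",
                    r.candidate.neutral_formula.hill(),
                    r.standard_name or r.candidate.label,
                    r.candidate.skeleton.name,
                    "+".join(r.candidate.sugar_multiset) or "-",
                    r.glycoside_linkage or "-",
                    r.confidence,
                    r.standard_name or "-",
                    evidence_text,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
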