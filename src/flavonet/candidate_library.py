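"""Expected-compound library: aglycone skeletons x phase I/II transformations.

Untargeted identification of plant flavonoids works from a *predicted* search
space rather than a spectral library: each aglycone skeleton is combined with
a small set of metabolic transformations (reduction, oxidation, glucoside /
glucuronide / pentoside conjugation, methylation), and every combination whose
elemental composition stays within a configured cap becomes a candidate with
an exact theoretical [M-H]- m/z.  MS1 matching then only has to look up
observed precursor masses in this finite library.

Two skeleton presets ship with the package (see ``data/skeletons.tsv``):

``core``
    baicalein + phloretin, the minimal two-skeleton setting of the vendor
    metabolism workflow this module emulates.
``extended``
    the ten flavonoid aglycones (taxifolin, eriodictyol, naringenin, apigenin,
    quercetin, luteolin, kaempferol, baicalein, wogonin, phloretin) needed to
    cover every conjugate in the packaged reference fixture.

Positional isomers are deliberately *not* distinguished: candidates are
defined by (skeleton, transformation multiset) alone, and retention time is
carried through as an observation, never interpreted structurally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .chem_core import (
    ElementalFormula,
    deprotonated_mz,
    monoisotopic_mass,
)

__all__ = [
    "DEFAULT_ELEMENT_CAP",
    "Skeleton",
    "Transformation",
    "CandidateCompound",
    "transformation_set",
    "load_preset",
    "generate_candidates",
    "filter_by_cap",
    "library_to_tsv",
    "library_from_tsv",
]

#: Default maximum element counts for generated candidates.
DEFAULT_ELEMENT_CAP = ElementalFormula.parse("C30H60O20")

#: Sugar-type transformation names (used for neutral-loss logic downstream).
SUGAR_TRANSFORMATIONS = ("glucuronide", "glucoside", "pentoside")


@dataclass(frozen=True)
class Skeleton:
    """An aglycone carbon skeleton with its diagnostic negative-mode fragments.

    ``diagnostic_fragments`` are (anion m/z, label) pairs; every diagnostic
    must sit below the skeleton's own [M-H]- (they are fragments of it).
    """

    name: str
    neutral_formula: ElementalFormula
    diagnostic_fragments: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        mz = deprotonated_mz(self.neutral_formula)
        # diagnostics are stored at reporting precision (4 d.p.), so allow the
        # aglycone anion itself to sit a rounding step above the exact [M-H]-
        for frag_mz, _ in self.diagnostic_fragments:
            if frag_mz > mz + 0.001:
                raise ValueError(
                    f"diagnostic {frag_mz} exceeds [M-H]- of skeleton {self.name}"
                )

    @property
    def theoretical_mz(self) -> float:
        return deprotonated_mz(self.neutral_formula)


@dataclass(frozen=True)
class Transformation:
    """A phase I or phase II metabolic transformation as a formula delta."""

    name: str
    phase: str  # "I" or "II"
    delta_formula: ElementalFormula
    max_applications: int = 3

    def __post_init__(self) -> None:
        if self.phase not in ("I", "II"):
            raise ValueError(f"phase must be 'I' or 'II', got {self.phase!r}")

    @property
    def delta_mass(self) -> float:
        return monoisotopic_mass(self.delta_formula)


def transformation_set() -> list[Transformation]:
    """The standard six transformations.

    Phase I: reduction (+H2), oxidation (+O).
    Phase II: glucoside (+C6H10O5), glucuronide (+C6H8O6),
    pentoside (+C5H8O4), methylation (+CH2).
    """
    return [
        Transformation("reduction", "I", ElementalFormula.parse("H2"), 1),
        Transformation("oxidation", "I", ElementalFormula.parse("O"), 1),
        Transformation("glucoside", "II", ElementalFormula.parse("C6H10O5"), 3),
        Transformation("glucuronide", "II", ElementalFormula.parse("C6H8O6"), 3),
        Transformation("pentoside", "II", ElementalFormula.parse("C5H8O4"), 3),
        Transformation("methylation", "II", ElementalFormula.parse("CH2"), 3),
    ]


def _canonical_order(transforms: Iterable[Transformation]) -> tuple[Transformation, ...]:
    # Phase I before phase II, then heavier deltas first, then name: the label
    # of a multiset is unique no matter the order transformations were applied.
    return tuple(
        sorted(
            transforms,
            key=lambda t: (t.phase != "I", -t.delta_mass, t.name),
        )
    )


@dataclass(frozen=True)
class CandidateCompound:
    """An expected compound: skeleton plus a multiset of transformations."""

    skeleton: Skeleton
    transformations: tuple[Transformation, ...]
    neutral_formula: ElementalFormula
    theoretical_mz: float

    @classmethod
    def build(
        cls, skeleton: Skeleton, transforms: Iterable[Transformation]
    ) -> "CandidateCompound":
        ordered = _canonical_order(transforms)
        formula = skeleton.neutral_formula
        for t in ordered:
            formula = formula + t.delta_formula
        return cls(skeleton, ordered, formula, deprotonated_mz(formula))

    @property
    def label(self) -> str:
        parts = [self.skeleton.name] + [t.name for t in self.transformations]
        return "-".join(parts)

    @property
    def n_transformations(self) -> int:
        return len(self.transformations)

    @property
    def transformation_multiset(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.transformations)

    @property
    def sugar_multiset(self) -> tuple[str, ...]:
        """Names of sugar-type conjugates present (glycosides + glucuronide)."""
        return tuple(
            t.name for t in self.transformations if t.name in SUGAR_TRANSFORMATIONS
        )


def _parse_diagnostics(text: str) -> tuple[tuple[float, str], ...]:
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        mz, _, label = chunk.partition(":")
        out.append((float(mz), label.strip()))
    return tuple(out)


def load_preset(name: str, path: str | Path | None = None) -> list[Skeleton]:
    """Load a named skeleton preset from the packaged (or a user) TSV file."""
    if path is None:
        source = resources.files("flavonet.data").joinpath("skeletons.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    skeletons: list[Skeleton] = []
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        preset, skel, formula, diagnostics = line.split("\t")
        if preset != name:
            continue
        skeletons.append(
            Skeleton(
                skel,
                ElementalFormula.parse(formula),
                _parse_diagnostics(diagnostics),
            )
        )
    if not skeletons:
        raise KeyError(f"unknown skeleton preset {name!r}")
    return skeletons


def filter_by_cap(candidate: CandidateCompound, cap: ElementalFormula) -> bool:
    """True iff every element count of the candidate is within the cap."""
    return candidate.neutral_formula.fits_within(cap)


def generate_candidates(
    skeletons: Sequence[Skeleton],
    transformations: Sequence[Transformation] | None = None,
    cap: ElementalFormula = DEFAULT_ELEMENT_CAP,
    max_phase1: int = 1,
    max_phase2: int = 3,
) -> list[CandidateCompound]:
    """Enumerate all expected compounds within the application and element caps.

    Every multiset of transformations with at most ``max_phase1`` phase I and
    ``max_phase2`` phase II applications (and at most ``max_applications`` of
    any single transformation) is applied to every skeleton; candidates whose
    formula exceeds ``cap`` are dropped.  The result is deduplicated by
    (skeleton, multiset) and sorted by (theoretical m/z, label), so the
    library order is deterministic.
    """
    if transformations is None:
        transformations = transformation_set()
    phase1 = [t for t in transformations if t.phase == "I"]
    phase2 = [t for t in transformations if t.phase == "II"]

    def multisets(
        pool: Sequence[Transformation], limit: int
    ) -> list[tuple[Transformation, ...]]:
        found: list[tuple[Transformation, ...]] = [()]
        for size in range(1, limit + 1):
            for combo in itertools.combinations_with_replacement(pool, size):
                counts: dict[str, int] = {}
                for t in combo:
                    counts[t.name] = counts.get(t.name, 0) + 1
                if all(
                    n <= t.max_applications
                    for t in combo
                    for name, n in counts.items()
                    if name == t.name
                ):
                    found.append(combo)
        return found

    seen: set[tuple[str, tuple[str, ...]]] = set()
    library: list[CandidateCompound] = []
    for skeleton in skeletons:
        for combo1 in multisets(phase1, max_phase1):
            for combo2 in multisets(phase2, max_phase2):
                candidate = CandidateCompound.build(skeleton, combo1 + combo2)
                key = (skeleton.name, candidate.transformation_multiset)
                if key in seen:
                    continue
                seen.add(key)
                if filter_by_cap(candidate, cap):
                    library.append(candidate)
    library.sort(key=lambda c: (c.theoretical_mz, c.label))
    return library


def library_to_tsv(library: Sequence[CandidateCompound], path: str | Path) -> None:
    """Write a candidate library as TSV (label, skeleton, transformations,
    neutral_formula, theoretical_mz)."""
    lines = ["label\tskeleton\ttransformations\tneutral_formula\ttheoretical_mz"]
    for c in library:
        lines.append(
            "\t".join(
                [
                    c.label,
                    c.skeleton.name,
                    "+".join(c.transformation_multiset) or "-",
                    c.neutral_formula.hill(),
                    f"{c.theoretical_mz:.6f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def library_from_tsv(
    path: str | Path, skeletons: Sequence[Skeleton]
) -> list[CandidateCompound]:
    """Re-hydrate a library from TSV, resolving skeletons by name."""
    by_name = {s.name: s for s in skeletons}
    by_transform = {t.name: t for t in transformation_set()}
    library: list[CandidateCompound] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        _, skel, transforms, _, _ = line.split("\t")
        names = [] if transforms == "-" else transforms.split("+")
        library.append(
            CandidateCompound.build(by_name[skel], [by_transform[n] for n in names])
        )
    return library
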