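"""Synthetic inputs with known ground truth, plus the packaged reference fixture.

Every stage of the pipeline can be exercised offline:

* :func:`table1_fixture` returns the 43 transcribed reference peaks (retention
  time, printed theoretical/experimental m/z, fragment lists) together with
  their published identifications;
* :func:`simulate_spectra` emits glycosylated-flavonoid spectra drawn from an
  expected-compound library with controllable ppm noise, fragment dropout and
  off-grid decoys;
* :func:`simulate_ppi` builds hub-and-spoke interaction graphs whose planted
  hubs are exactly the nodes a centrality filter should select;
* :func:`simulate_annotation_db` builds a term database with one term whose
  overlap with the study set is planted, the rest drawn from the null.

All randomness flows through one explicit ``numpy`` seed; no global state.

The spectral noise model is multiplicative-in-ppm: observed m/z =
theoretical * (1 + e/1e6) with e ~ Normal(0, sd^2), independently for the
precursor and every fragment, matching the error structure of Orbitrap data
(|error| of a few ppm, uncorrelated between ions).  Simulated conjugates
fragment by intact sugar losses (O-glycoside behaviour) plus the skeleton's
diagnostic ions; chromatographic peak shape, isotope envelopes and realistic
retention-time modelling are out of scope, so retention times are assigned
arbitrarily except where the fixture pins them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_core import ElementalFormula, ppm_error
from .candidate_library import (
    CandidateCompound,
    generate_candidates,
    load_preset,
)
from .enrichment import AnnotationDatabase
from .spectral_annotation import ReferenceStandard, SpectrumRecord

__all__ = [
    "SpectraSimConfig",
    "GroundTruth",
    "Table1Row",
    "table1_fixture",
    "reference_standards",
    "simulate_spectra",
    "simulate_ppi",
    "simulate_annotation_db",
]

#: Precursor intensity assigned to fixture peaks (not published; any value
#: above the 1e4 workflow floor behaves identically).
FIXTURE_INTENSITY = 1.0e6


@dataclass(frozen=True)
class Table1Row:
    """One transcribed fixture row: the printed values plus the expected call."""

    peak: int
    rt: float
    mz_theor_printed: float
    mz_exp_printed: float
    error_ppm_printed: float
    formula: ElementalFormula
    fragments: tuple[tuple[float, float], ...]
    identification: str
    standard_confirmed: bool
    aglycone: str
    conjugates: tuple[str, ...]  # expected transformation multiset (sugars)
    linkage: str | None  # "O", "C", "undetermined" or None for aglycones


def _load_fixture_rows() -> list[Table1Row]:
    text = resources.files("flavonet.data").joinpath("table1.tsv").read_text("utf-8")
    rows: list[Table1Row] = []
    header_seen = False
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        (peak, rt, theor, exp, err, formula, fragments, ident, std,
         aglycone, conjugates, linkage) = line.split("\t")
        frags = tuple(
            (float(mz), float(inten))
            for mz, inten in (chunk.split(":") for chunk in fragments.split(";"))
        )
        rows.append(
            Table1Row(
                int(peak),
                float(rt),
                float(theor),
                float(exp),
                float(err),
                ElementalFormula.parse(formula),
                frags,
                ident,
                std == "1",
                aglycone,
                () if conjugates == "-" else tuple(conjugates.split("+")),
                None if linkage == "-" else linkage,
            )
        )
    return rows


def table1_fixture() -> tuple[list[SpectrumRecord], list[Table1Row]]:
    """The packaged 43-peak reference fixture as records + expected annotations."""
    rows = _load_fixture_rows()
    records = [
        SpectrumRecord(r.peak, r.rt, r.mz_exp_printed, FIXTURE_INTENSITY, r.fragments)
        for r in rows
    ]
    return records, rows


def reference_standards() -> list[ReferenceStandard]:
    """The 13 authentic standards with their fixture retention times."""
    rows = _load_fixture_rows()
    return [
        ReferenceStandard(r.identification.lower(), r.formula, r.rt)
        for r in rows
        if r.standard_confirmed
    ]


@dataclass(frozen=True)
class SpectraSimConfig:
    """Study conditions for the spectra simulator.

    True compounds are drawn as pure phase II conjugates of the preset's
    aglycones (``max_phase1 = 0``): phase-I-modified skeletons are excluded
    from the *generator* because a reduced or oxidised aglycone is an exact
    mass-and-diagnostic degenerate of an isomeric unmodified skeleton, so no
    annotator could attribute such a peak uniquely -- the annotation engine
    itself still searches the full phase-I-inclusive library.
    """

    skeleton_preset: str = "extended"
    max_phase1: int = 0
    max_phase2: int = 2
    n_true: int = 30
    n_decoys: int = 10
    ppm_noise_sd: float = 2.0
    fragment_dropout: float = 0.1
    min_decoy_ppm: float = 25.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragment_dropout <= 1.0:
            raise ValueError("fragment_dropout must be in [0, 1]")
        if self.ppm_noise_sd < 0:
            raise ValueError("ppm_noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """peak_id -> (candidate label, linkage, standard-confirmed flag)."""

    entries: dict[int, tuple[str, str, bool]] = field(default_factory=dict)

    def label_of(self, peak_id: int) -> str | None:
        entry = self.entries.get(peak_id)
        return entry[0] if entry else None


def _jitter(rng: np.random.Generator, mz: float, sd_ppm: float) -> float:
    return mz * (1.0 + rng.normal(0.0, sd_ppm) / 1e6) if sd_ppm > 0 else mz


def simulate_spectra(
    config: SpectraSimConfig,
    library: Sequence[CandidateCompound] | None = None,
) -> tuple[list[SpectrumRecord], GroundTruth]:
    """Generate true peaks from the library plus off-grid decoys.

    True peaks: precursor jittered in ppm space around the theoretical m/z;
    fragments are the candidate's intact sugar losses (all sub-multisets) and
    the skeleton diagnostics, each surviving with probability 1 - dropout and
    jittered by the same noise model.  Decoy precursors are redrawn until they
    sit at least ``min_decoy_ppm`` from every library mass.
    """
    rng = np.random.default_rng(config.rng_seed)
    if library is None:
        skeletons = load_preset(config.skeleton_preset)
        library = generate_candidates(
            skeletons, max_phase1=config.max_phase1, max_phase2=config.max_phase2
        )
    records: list[SpectrumRecord] = []
    truth: dict[int, tuple[str, str, bool]] = {}
    if config.n_true and not library:
        raise ValueError("cannot draw true peaks from an empty library")

    from .spectral_annotation import detect_neutral_losses  # fragment positions

    choices = rng.choice(
        len(library), size=config.n_true, replace=config.n_true > len(library)
    ) if config.n_true else []
    peak_id = 0
    for idx in choices:
        candidate = library[int(idx)]
        peak_id += 1
        precursor = _jitter(rng, candidate.theoretical_mz, config.ppm_noise_sd)
        expected: list[float] = []
        # intact sugar losses of the candidate's own conjugate multiset
        sugars = candidate.sugar_multiset
        from .spectral_annotation import _INTACT_LOSS  # stable loss masses
        import itertools as _it

        for r in range(1, len(sugars) + 1):
            for subset in set(_it.combinations(sugars, r)):
                loss = sum(_INTACT_LOSS[s].loss_mass for s in subset)
                expected.append(candidate.theoretical_mz - loss)
        for diag_mz, _ in candidate.skeleton.diagnostic_fragments:
            if diag_mz < precursor + 0.4:
                expected.append(diag_mz)
        fragments = []
        for mz in sorted(set(expected)):
            if mz <= 0:
                continue
            if rng.uniform() < config.fragment_dropout:
                continue
            fragments.append((_jitter(rng, mz, config.ppm_noise_sd), rng.uniform(5, 100)))
        if fragments:
            top = max(range(len(fragments)), key=lambda i: fragments[i][1])
            fragments[top] = (fragments[top][0], 100.0)
        records.append(
            SpectrumRecord(
                peak_id,
                float(rng.uniform(1.0, 18.0)),
                precursor,
                float(rng.uniform(1e5, 1e7)),
                tuple(fragments),
            )
        )
        truth[peak_id] = (candidate.label, "O" if sugars else "-", False)

    lib_masses = np.array([c.theoretical_mz for c in library]) if library else np.array([300.0])
    lo, hi = float(lib_masses.min()) * 0.9, float(lib_masses.max()) * 1.1
    for _ in range(config.n_decoys):
        peak_id += 1
        while True:
            mz = float(rng.uniform(lo, hi))
            if np.min(np.abs(mz - lib_masses) / lib_masses) * 1e6 >= config.min_decoy_ppm:
                break
        n_frag = int(rng.integers(0, 4))
        fragments = tuple(
            (float(rng.uniform(80.0, mz - 10.0)), float(rng.uniform(5, 100)))
            for _ in range(n_frag)
        )
        records.append(
            SpectrumRecord(
                peak_id,
                float(rng.uniform(1.0, 18.0)),
                mz,
                float(rng.uniform(1e5, 1e7)),
                fragments,
            )
        )
    return records, GroundTruth(truth)


def simulate_ppi(
    n_hubs: int = 3,
    n_leaves: int = 60,
    inter_hub_edges: int | None = None,
    rng_seed: int = 0,
) -> tuple[list[tuple[str, str, float]], list[str]]:
    """Hub-and-spoke PPI edge table with planted hubs as ground truth.

    Each hub is wired to its own ``n_leaves`` private leaves and to the other
    hubs (all pairs by default, or ``inter_hub_edges`` of them), so hubs are
    the only nodes with high degree, betweenness and closeness.  Confidences
    are drawn above the conventional 0.4 STRING-style cutoff so the filter
    keeps every edge.
    """
    rng = np.random.default_rng(rng_seed)
    hubs = [f"HUB{i + 1}" for i in range(n_hubs)]
    rows: list[tuple[str, str, float]] = []
    pairs = [(a, b) for i, a in enumerate(hubs) for b in hubs[i + 1:]]
    if inter_hub_edges is not None:
        pairs = pairs[:inter_hub_edges]
    for a, b in pairs:
        rows.append((a, b, round(float(rng.uniform(0.5, 0.99)), 3)))
    for i, hub in enumerate(hubs):
        for j in range(n_leaves):
            rows.append((hub, f"L{i + 1}_{j + 1}", round(float(rng.uniform(0.5, 0.99)), 3)))
    return rows, hubs


def simulate_annotation_db(
    n_terms: int = 50,
    planted_term_overlap: int = 15,
    background_size: int = 500,
    rng_seed: int = 0,
    study_size: int = 20,
    term_size: int = 30,
) -> tuple[AnnotationDatabase, list[str], str]:
    """Annotation database with one planted enriched term.

    Returns (database, study genes, planted term id).  The planted term
    contains ``planted_term_overlap`` of the study genes; all other terms are
    uniform draws from the background (the hypergeometric null).
    """
    if planted_term_overlap > study_size:
        raise ValueError("planted overlap cannot exceed the study size")
    rng = np.random.default_rng(rng_seed)
    background = [f"G{i:04d}" for i in range(1, background_size + 1)]
    study = list(rng.choice(background, size=study_size, replace=False))
    non_study = [g for g in background if g not in set(study)]
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    planted_id = "T0001"
    planted = list(rng.choice(study, size=planted_term_overlap, replace=False))
    planted += list(
        rng.choice(non_study, size=max(term_size - planted_term_overlap, 0), replace=False)
    )
    terms[planted_id] = ("PATHWAY", "planted pathway", frozenset(planted))
    for i in range(2, n_terms + 1):
        genes = frozenset(rng.choice(background, size=term_size, replace=False))
        terms[f"T{i:04d}"] = ("PATHWAY", f"null pathway {i}", genes)
    return AnnotationDatabase(terms, frozenset(background)), study, planted_id
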