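"""Rule engine for the MDS clinical diagnostic criteria for progressive
supranuclear palsy (PSP).

PSP is a 4R-tauopathy whose clinical diagnosis rests on four core functional
domains — ocular motor dysfunction (O), postural instability (P), akinesia (A)
and cognitive dysfunction (C) — each contributing three features stratified by
diagnostic certainty (1 highest .. 3 lowest), plus four supportive clinical
clues (CC1-CC4). Combinations of present features attribute one of eight
clinical phenotypes (PSP-RS and seven variants) at a certainty level of
probable, possible or suggestive-of. Because a patient commonly satisfies
several phenotype rows at the same visit, the Multiple Allocations eXtinction
(MAX) rules collapse the simultaneous allocations to a single diagnosis:
(1) highest diagnostic certainty wins; (2) among ties, the phenotype whose
qualifying symptoms began earliest wins; (3) among remaining ties PSP-RS
prevails over any variant. A final configuration step maps the resulting
(phenotype, certainty) pair to the "probable 4R-tauopathy" YES/NO category
used for trial recruitment.

The module is laid out in the order the method runs:

1.  Feature vocabulary — codes, domains, certainty strata, the set of
    time-constrained features.
2.  Feature profiles and composite-feature derivation — the 3-of-5 frontal
    presentation rule (C2), the corticobasal-syndrome rule (C3), levodopa
    resistance (A2 vs A3), the pull test (P2/P3), and the three-year
    temporal gate on P1-P3 and A1.
3.  Rule table and allocation engine — the combination table shipped as data
    (``data/rules.yaml``), evaluated per phenotype at the highest satisfied
    certainty.
4.  MAX resolution — extinction of multiple allocations with a full
    explanation trace, and the probable-4R-tauopathy flag.
5.  Patient records, batch classification and reports — CSV/JSON readers,
    the classification pipeline, JSON/CSV/text report writers.
6.  Synthetic fixtures — exhaustive profile enumeration over the 2^16
    boolean cube, minimal satisfying profiles per rule row, and seeded
    Bernoulli cohort simulation.

All rule formulas are positive (no negation), so every phenotype's allocated
certainty is monotone under feature addition; the test suite verifies this
exhaustively over all 65,536 profiles.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
import math
from collections import Counter
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

logger = logging.getLogger("pspmax")

#: Default width of the temporal gate, in months from disease onset. The
#: criteria require the time-constrained features (P1-P3, A1) to occur within
#: the first three years of disease; the boundary is inclusive.
DEFAULT_GATE_WINDOW_MONTHS = 36.0

#: Minimum levodopa challenge dose (mg) for the resistance assessment.
LEVODOPA_CHALLENGE_MIN_MG = 200.0
#: Minimum sustained daily levodopa dose (mg) and duration (days; "one month").
LEVODOPA_SUSTAINED_MIN_MG = 1000.0
LEVODOPA_SUSTAINED_MIN_DAYS = 30.0
#: Maximum fractional MDS-UPDRS motor improvement still counting as resistant.
LEVODOPA_RESISTANCE_MAX_IMPROVEMENT = 0.30


class RuleLoadError(ValueError):
    """A rule-table or resolution-config document failed validation."""


class RecordParseError(ValueError):
    """A patient-record file failed validation (carries row/column context)."""


# ---------------------------------------------------------------------------
# 1. Feature vocabulary
# ---------------------------------------------------------------------------

class Domain(str, enum.Enum):
    """Core functional domain of a clinical feature."""

    OCULAR_MOTOR = "O"
    POSTURAL_INSTABILITY = "P"
    AKINESIA = "A"
    COGNITIVE = "C"
    CLINICAL_CLUE = "CC"


class FeatureCode(str, enum.Enum):
    """The 16 core clinical features and clinical clues.

    O/P/A/C codes carry a certainty stratum (1 highest .. 3 lowest) within
    their domain; clinical clues (CC1-CC4) carry no stratum. The starred set
    {P1, P2, P3, A1} is time-constrained: the criteria require these features
    within the first three years of disease.
    """

    O1 = "O1"   # vertical supranuclear gaze palsy
    O2 = "O2"   # slow velocity of vertical saccades
    O3 = "O3"   # macro square wave jerks or eyelid opening apraxia
    P1 = "P1"   # repeated unprovoked falls *
    P2 = "P2"   # tendency to fall on the pull test *
    P3 = "P3"   # >2 steps backward on the pull test, unaided recovery *
    A1 = "A1"   # progressive gait freezing *
    A2 = "A2"   # parkinsonism, akinetic-rigid, axial, levodopa-resistant
    A3 = "A3"   # parkinsonism with tremor/asymmetry and/or levodopa response
    C1 = "C1"   # nfaPPA or progressive apraxia of speech
    C2 = "C2"   # frontal cognitive/behavioral presentation
    C3 = "C3"   # corticobasal syndrome
    CC1 = "CC1"
    CC2 = "CC2"
    CC3 = "CC3"
    CC4 = "CC4"

    @property
    def domain(self) -> Domain:
        if self.value.startswith("CC"):
            return Domain.CLINICAL_CLUE
        return Domain(self.value[0])

    @property
    def stratum(self) -> Optional[int]:
        """Certainty stratum 1-3 for core features; None for clinical clues."""
        if self.domain is Domain.CLINICAL_CLUE:
            return None
        return int(self.value[1])

    @property
    def time_constrained(self) -> bool:
        return self in TIME_CONSTRAINED_FEATURES


#: Canonical code order; also the bit order used for profile masks.
CODE_ORDER: tuple[FeatureCode, ...] = tuple(FeatureCode)
_CODE_BIT: dict[FeatureCode, int] = {c: i for i, c in enumerate(CODE_ORDER)}

#: Features gated to the first three years of disease (starred in the criteria).
TIME_CONSTRAINED_FEATURES = frozenset(
    {FeatureCode.P1, FeatureCode.P2, FeatureCode.P3, FeatureCode.A1}
)


class Certainty(enum.IntEnum):
    """Diagnostic certainty, totally ordered: suggestive-of < possible < probable."""

    SUGGESTIVE_OF = 1
    POSSIBLE = 2
    PROBABLE = 3

    @property
    def label(self) -> str:
        return {1: "suggestive of", 2: "possible", 3: "probable"}[self.value]

    @property
    def token(self) -> str:
        """Machine-readable token used in files ('suggestive-of', ...)."""
        return {1: "suggestive-of", 2: "possible", 3: "probable"}[self.value]

    @classmethod
    def parse(cls, text: str) -> "Certainty":
        key = str(text).strip().lower().replace("_", " ").replace("-", " ")
        try:
            return {
                "suggestive of": cls.SUGGESTIVE_OF,
                "suggestive": cls.SUGGESTIVE_OF,
                "possible": cls.POSSIBLE,
                "probable": cls.PROBABLE,
            }[key]
        except KeyError:
            raise ValueError(f"unknown certainty level: {text!r}") from None


class Phenotype(str, enum.Enum):
    """The eight clinical phenotypes; PSP-RS is the hierarchy apex."""

    RS = "PSP-RS"    # Richardson's syndrome
    P = "PSP-P"      # predominant parkinsonism
    PGF = "PSP-PGF"  # progressive gait freezing
    F = "PSP-F"      # predominant frontal presentation
    OM = "PSP-OM"    # predominant ocular motor dysfunction
    SL = "PSP-SL"    # predominant speech/language disorder
    CBS = "PSP-CBS"  # predominant corticobasal syndrome
    PI = "PSP-PI"    # predominant postural instability

    @property
    def is_hierarchy_apex(self) -> bool:
        return self is Phenotype.RS


#: Default residual tie-break order among variant phenotypes (PSP-RS wins
#: earlier, at the hierarchy step). Overridable via the resolution config.
DEFAULT_TIEBREAK_ORDER: tuple[Phenotype, ...] = (
    Phenotype.PGF,
    Phenotype.P,
    Phenotype.F,
    Phenotype.SL,
    Phenotype.CBS,
    Phenotype.OM,
    Phenotype.PI,
)


def _parse_code(text: str) -> FeatureCode:
    try:
        return FeatureCode(str(text).strip().upper())
    except ValueError:
        raise ValueError(f"unknown feature code: {text!r}") from None


def _parse_phenotype(text: str) -> Phenotype:
    try:
        return Phenotype(str(text).strip().upper())
    except ValueError:
        raise ValueError(f"unknown phenotype: {text!r}") from None


def _codes_from_mask(mask: int) -> frozenset[FeatureCode]:
    return frozenset(c for c in CODE_ORDER if mask >> _CODE_BIT[c] & 1)


# ---------------------------------------------------------------------------
# 2. Feature profiles and composite-feature derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=True)
class FeatureProfile:
    """Presence/absence of the 16 features, with optional onset times.

    ``onset_month`` maps a *present* feature to its onset in months from
    disease onset; features entered as bare 1/0 (the smartsheet-style entry)
    simply have no onset recorded and are trusted as temporally valid.
    """

    present: frozenset[FeatureCode] = frozenset()
    onset_month: Mapping[FeatureCode, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "present", frozenset(self.present))
        onsets = {k: float(v) for k, v in dict(self.onset_month).items()}
        for code, month in onsets.items():
            if code not in self.present:
                raise ValueError(f"onset recorded for absent feature {code.value}")
            if not math.isfinite(month) or month < 0:
                raise ValueError(f"onset for {code.value} must be >= 0, got {month}")
        object.__setattr__(self, "onset_month", onsets)

    @classmethod
    def from_codes(
        cls,
        codes: Iterable[Union[FeatureCode, str]],
        onsets: Optional[Mapping[Union[FeatureCode, str], float]] = None,
    ) -> "FeatureProfile":
        present = frozenset(_parse_code(c) for c in codes)
        onset = {_parse_code(k): float(v) for k, v in (onsets or {}).items()}
        return cls(present, onset)

    @classmethod
    def from_mask(cls, mask: int) -> "FeatureProfile":
        if not 0 <= mask < 1 << len(CODE_ORDER):
            raise ValueError(f"mask out of range: {mask}")
        return cls(_codes_from_mask(mask))

    @property
    def mask(self) -> int:
        m = 0
        for code in self.present:
            m |= 1 << _CODE_BIT[code]
        return m

    def __contains__(self, code: Union[FeatureCode, str]) -> bool:
        return _parse_code(code) in self.present

    def __hash__(self) -> int:
        return hash((self.present, tuple(sorted(self.onset_month.items()))))


@dataclass(frozen=True)
class FrontalSubitems:
    """The five items of the frontal cognitive/behavioral presentation (C2)."""

    apathy: bool
    bradyphrenia: bool
    dysexecutive: bool
    reduced_phonemic_fluency: bool
    impulsivity_disinhibition_perseveration: bool

    def count(self) -> int:
        return sum(
            (
                self.apathy,
                self.bradyphrenia,
                self.dysexecutive,
                self.reduced_phonemic_fluency,
                self.impulsivity_disinhibition_perseveration,
            )
        )


@dataclass(frozen=True)
class CbsSubitems:
    """Cortical and movement-disorder signs of corticobasal syndrome (C3)."""

    orobuccal_or_limb_apraxia: bool
    cortical_sensory_deficit: bool
    alien_limb: bool
    rigidity: bool
    akinesia: bool
    myoclonus: bool

    @property
    def any_cortical(self) -> bool:
        return self.orobuccal_or_limb_apraxia or self.cortical_sensory_deficit or self.alien_limb

    @property
    def any_movement(self) -> bool:
        return self.rigidity or self.akinesia or self.myoclonus


@dataclass(frozen=True)
class LevodopaChallenge:
    """Pre/post MDS-UPDRS motor scores under a levodopa regimen.

    A regimen qualifies with a challenge dose of at least 200 mg, or a
    sustained daily dose of at least 1000 mg for at least one month (30 days).
    """

    pre_score: float
    post_score: float
    challenge_dose_mg: Optional[float] = None
    sustained_dose_mg: Optional[float] = None
    sustained_duration_days: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pre_score < 0 or self.post_score < 0:
            raise ValueError("MDS-UPDRS motor scores must be >= 0")
        for dose in (self.challenge_dose_mg, self.sustained_dose_mg):
            if dose is not None and dose < 0:
                raise ValueError("levodopa doses must be >= 0")


@dataclass(frozen=True)
class PullTestObservation:
    """Outcome of the MDS-UPDRS item 3.12 retropulsion (pull) test."""

    would_fall_if_not_caught: bool
    steps_backward: int = 0
    unaided_recovery: bool = True
    months_from_onset: Optional[float] = None

    def __post_init__(self) -> None:
        if self.steps_backward < 0:
            raise ValueError("steps_backward must be >= 0")
        if self.months_from_onset is not None and self.months_from_onset < 0:
            raise ValueError("months_from_onset must be >= 0")


def derive_frontal_presentation(items: FrontalSubitems) -> bool:
    """C2 rule: a frontal presentation requires at least 3 of the 5 items."""
    return items.count() >= 3


def derive_cbs(items: CbsSubitems) -> bool:
    """C3 rule: at least one cortical sign AND at least one movement sign."""
    return items.any_cortical and items.any_movement


def assess_levodopa_resistance(challenge: LevodopaChallenge) -> Optional[bool]:
    """Classify levodopa resistance (A2-type) vs response from a challenge.

    Returns True (resistant: MDS-UPDRS motor improvement <= 30% under a
    qualifying regimen), False (responsive), or None when the assessment is
    not assessable — no qualifying dose regimen, or a zero pre-treatment
    score leaving the improvement ratio undefined. Improvement is
    ``(pre - post) / pre``; worsening (negative improvement) counts as
    resistant.
    """
    valid_challenge = (
        challenge.challenge_dose_mg is not None
        and challenge.challenge_dose_mg >= LEVODOPA_CHALLENGE_MIN_MG
    )
    valid_sustained = (
        challenge.sustained_dose_mg is not None
        and challenge.sustained_dose_mg >= LEVODOPA_SUSTAINED_MIN_MG
        and challenge.sustained_duration_days is not None
        and challenge.sustained_duration_days >= LEVODOPA_SUSTAINED_MIN_DAYS
    )
    if not (valid_challenge or valid_sustained) or challenge.pre_score <= 0:
        return None
    improvement = (challenge.pre_score - challenge.post_score) / challenge.pre_score
    return improvement <= LEVODOPA_RESISTANCE_MAX_IMPROVEMENT


def derive_pull_test_feature(obs: PullTestObservation) -> Optional[FeatureCode]:
    """Map a pull-test outcome to P2, P3 or None.

    P2: the patient would fall if not caught by the examiner. P3: more than
    two steps backward but unaided recovery. At-threshold results (exactly two
    steps) and assisted recovery yield neither.
    """
    if obs.would_fall_if_not_caught:
        return FeatureCode.P2
    if obs.steps_backward > 2 and obs.unaided_recovery:
        return FeatureCode.P3
    return None


def apply_temporal_gate(
    profile: FeatureProfile,
    window_months: float = DEFAULT_GATE_WINDOW_MONTHS,
) -> FeatureProfile:
    """Remove time-constrained features whose recorded onset exceeds the gate.

    P1-P3 and A1 must occur within the first three years of disease
    (``window_months`` = 36 by default, boundary inclusive). Features without
    a recorded onset are trusted as temporally valid and left unchanged, as
    are all non-time-constrained features. Idempotent; never adds a feature.
    """
    if window_months <= 0:
        raise ValueError("window_months must be > 0")
    gated_out = {
        code
        for code in profile.present & TIME_CONSTRAINED_FEATURES
        if profile.onset_month.get(code) is not None
        and profile.onset_month[code] > window_months
    }
    if not gated_out:
        return profile
    present = profile.present - gated_out
    onsets = {c: m for c, m in profile.onset_month.items() if c in present}
    return FeatureProfile(present, onsets)


# ---------------------------------------------------------------------------
# 3. Rule table and allocation engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleRow:
    """One row of the combination table: a phenotype at a certainty level,
    attributed by a positive boolean formula in disjunctive normal form.

    ``conjuncts`` is the DNF: the row is satisfied when every feature of at
    least one conjunct is present. Formulas contain no negation.
    """

    phenotype: Phenotype
    certainty: Certainty
    conjuncts: tuple[frozenset[FeatureCode], ...]

    def __post_init__(self) -> None:
        if not self.conjuncts or any(not c for c in self.conjuncts):
            raise ValueError("rule formula must have at least one non-empty conjunct")
        object.__setattr__(
            self, "conjuncts", tuple(frozenset(c) for c in self.conjuncts)
        )

    @cached_property
    def _conjunct_masks(self) -> tuple[int, ...]:
        masks = []
        for conj in self.conjuncts:
            m = 0
            for code in conj:
                m |= 1 << _CODE_BIT[code]
            masks.append(m)
        return tuple(masks)

    def satisfied_by_mask(self, mask: int) -> bool:
        return any(mask & m == m for m in self._conjunct_masks)


@dataclass(frozen=True)
class Allocation:
    """A (phenotype, certainty) pair a profile satisfies.

    ``satisfied_by`` records the present features that made the formula true
    (the union of the literals of every satisfied conjunct).
    """

    phenotype: Phenotype
    certainty: Certainty
    satisfied_by: frozenset[FeatureCode] = frozenset()

    def describe(self) -> str:
        codes = ", ".join(c.value for c in sorted(self.satisfied_by, key=_CODE_BIT.get))
        return f"{self.certainty.label} {self.phenotype.value} [{codes}]"


def _rows_from_document(doc: object, origin: str) -> list[RuleRow]:
    if doc is None:
        return []
    if not isinstance(doc, Mapping) or "rules" not in doc:
        raise RuleLoadError(f"{origin}: expected a mapping with a 'rules' key")
    raw_rows = doc["rules"] or []
    if not isinstance(raw_rows, Sequence) or isinstance(raw_rows, (str, bytes)):
        raise RuleLoadError(f"{origin}: 'rules' must be a list")
    rows: list[RuleRow] = []
    for i, raw in enumerate(raw_rows, start=1):
        where = f"{origin}: rule row {i}"
        if not isinstance(raw, Mapping):
            raise RuleLoadError(f"{where}: each row must be a mapping")
        try:
            phenotype = _parse_phenotype(raw["phenotype"])
            certainty = Certainty.parse(raw["certainty"])
            any_of = raw["any_of"]
            if not isinstance(any_of, Sequence) or isinstance(any_of, (str, bytes)):
                raise ValueError("'any_of' must be a list of conjunctions")
            conjuncts = tuple(
                frozenset(_parse_code(code) for code in conj) for conj in any_of
            )
            rows.append(RuleRow(phenotype, certainty, conjuncts))
        except KeyError as exc:
            raise RuleLoadError(f"{where}: missing key {exc}") from None
        except ValueError as exc:
            raise RuleLoadError(f"{where}: {exc}") from None
    return rows


def load_rule_table(
    source: Union[str, Path, Mapping, None] = None,
) -> list[RuleRow]:
    """Load and validate a rule-table document (YAML path or parsed mapping).

    With ``source=None`` returns the shipped default, which reproduces the
    criteria's combination table exactly: 16 rows over 8 phenotypes. An empty
    document yields an empty rule list (the engine then allocates nothing).
    """
    if source is None:
        text = resources.files("pspmax").joinpath("data/rules.yaml").read_text()
        return _rows_from_document(yaml.safe_load(text), "shipped rules.yaml")
    if isinstance(source, Mapping):
        return _rows_from_document(source, "rule document")
    path = Path(source)
    return _rows_from_document(yaml.safe_load(path.read_text()), str(path))


_DEFAULT_RULES: Optional[list[RuleRow]] = None


def default_rules() -> list[RuleRow]:
    """The shipped combination table (cached)."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rule_table()
    return _DEFAULT_RULES


#: Codes a given literal may be satisfied by under stratum subsumption:
#: a higher-certainty feature of the same domain (lower stratum number)
#: stands in for a lower one. Clinical clues only ever match themselves.
_SUBSTITUTES: dict[FeatureCode, frozenset[FeatureCode]] = {
    lit: frozenset(
        c
        for c in CODE_ORDER
        if c is lit
        or (
            lit.stratum is not None
            and c.domain is lit.domain
            and c.stratum is not None
            and c.stratum <= lit.stratum
        )
    )
    for lit in CODE_ORDER
}


def _effective_mask(mask: int) -> int:
    """Expand a present-feature mask so each literal's substitutes light it up."""
    eff = mask
    for lit in CODE_ORDER:
        if lit.stratum is None:
            continue
        for c in _SUBSTITUTES[lit]:
            if mask >> _CODE_BIT[c] & 1:
                eff |= 1 << _CODE_BIT[lit]
                break
    return eff


def evaluate_allocations(
    profile: FeatureProfile,
    rules: Optional[Sequence[RuleRow]] = None,
    *,
    stratum_subsumption: bool = False,
) -> set[Allocation]:
    """Evaluate every rule row against a profile.

    For each phenotype, returns at most one Allocation, at the highest
    certainty whose formula the present-feature set satisfies. Matching is
    literal by default: a higher-stratum feature (e.g. O1) does not stand in
    for a named lower one (e.g. O2). ``stratum_subsumption=True`` enables the
    optional relaxed mode in which it does; it is off by default and off in
    every shipped check.
    """
    if rules is None:
        rules = default_rules()
    mask = profile.mask
    eff = _effective_mask(mask) if stratum_subsumption else mask

    by_phenotype: dict[Phenotype, list[RuleRow]] = {}
    for row in rules:
        by_phenotype.setdefault(row.phenotype, []).append(row)

    out: set[Allocation] = set()
    for phenotype, rows in by_phenotype.items():
        for row in sorted(rows, key=lambda r: r.certainty, reverse=True):
            satisfied = [
                conj
                for conj, cmask in zip(row.conjuncts, row._conjunct_masks)
                if eff & cmask == cmask
            ]
            if not satisfied:
                continue
            literals = frozenset().union(*satisfied)
            if stratum_subsumption:
                contributors = frozenset(
                    c
                    for lit in literals
                    for c in _SUBSTITUTES[lit]
                    if mask >> _CODE_BIT[c] & 1
                )
            else:
                contributors = literals
            out.add(Allocation(phenotype, row.certainty, contributors))
            break
    return out


def highest_certainty(allocations: Iterable[Allocation]) -> Optional[Certainty]:
    """Maximum certainty over a set of allocations; None for an empty set."""
    certainties = [a.certainty for a in allocations]
    return max(certainties) if certainties else None


# ---------------------------------------------------------------------------
# 4. MAX resolution and the probable-4R-tauopathy flag
# ---------------------------------------------------------------------------

MAX_RULE_1 = "MAX rule 1 (diagnostic certainty)"
MAX_RULE_2 = "MAX rule 2 (temporal order of symptom onset)"
MAX_RULE_3 = "MAX rule 3 (PSP-RS prevails over variant phenotypes)"
TIEBREAK_RULE = "configured tie-break order"


@dataclass(frozen=True)
class TauopathyMap:
    """Which (phenotype, certainty) pairs qualify as probable 4R-tauopathy.

    Total over all 8 x 3 pairs: membership in ``qualifying`` means YES,
    absence means NO. The shipped default (``data/resolution.yaml``) follows
    the MDS criteria: any probable diagnosis, or possible PSP-CBS.
    """

    qualifying: frozenset[tuple[Phenotype, Certainty]]

    def is_4r(self, phenotype: Phenotype, certainty: Certainty) -> bool:
        return (phenotype, certainty) in self.qualifying


@dataclass(frozen=True)
class ResolutionConfig:
    """Tauopathy map plus the residual tie-break order among variants."""

    tau_map: TauopathyMap
    tiebreak_order: tuple[Phenotype, ...] = DEFAULT_TIEBREAK_ORDER

    def __post_init__(self) -> None:
        order = tuple(self.tiebreak_order)
        variants = [p for p in Phenotype if not p.is_hierarchy_apex]
        if sorted(order, key=lambda p: p.value) != sorted(variants, key=lambda p: p.value):
            raise RuleLoadError(
                "tiebreak_order must be a permutation of the seven variant phenotypes"
            )
        object.__setattr__(self, "tiebreak_order", order)

    def phenotype_rank(self, phenotype: Phenotype) -> int:
        if phenotype.is_hierarchy_apex:
            return 0
        return 1 + self.tiebreak_order.index(phenotype)


def load_resolution_config(
    source: Union[str, Path, Mapping, None] = None,
) -> ResolutionConfig:
    """Load the tauopathy map and tie-break order (YAML path or mapping)."""
    if source is None:
        text = resources.files("pspmax").joinpath("data/resolution.yaml").read_text()
        doc = yaml.safe_load(text)
        origin = "shipped resolution.yaml"
    elif isinstance(source, Mapping):
        doc, origin = source, "resolution document"
    else:
        path = Path(source)
        doc, origin = yaml.safe_load(path.read_text()), str(path)
    if not isinstance(doc, Mapping):
        raise RuleLoadError(f"{origin}: expected a mapping")
    try:
        tau_raw = doc.get("probable_4r_tauopathy", {}) or {}
        qualifying = frozenset(
            (_parse_phenotype(p), Certainty.parse(level))
            for level, phenotypes in tau_raw.items()
            for p in (phenotypes or [])
        )
        order_raw = doc.get("tiebreak_order")
        order = (
            tuple(_parse_phenotype(p) for p in order_raw)
            if order_raw
            else DEFAULT_TIEBREAK_ORDER
        )
        return ResolutionConfig(TauopathyMap(qualifying), order)
    except ValueError as exc:
        raise RuleLoadError(f"{origin}: {exc}") from None


_DEFAULT_RESOLUTION: Optional[ResolutionConfig] = None


def default_resolution() -> ResolutionConfig:
    global _DEFAULT_RESOLUTION
    if _DEFAULT_RESOLUTION is None:
        _DEFAULT_RESOLUTION = load_resolution_config()
    return _DEFAULT_RESOLUTION


@dataclass(frozen=True)
class Diagnosis:
    """Final diagnosis after MAX resolution.

    ``final`` is None iff no rule row was satisfied. ``extinguished`` pairs
    every removed allocation with the rule that removed it; together with
    ``final`` it partitions the input allocation set. ``trace`` is the ordered
    human-readable account of each resolution step.
    """

    final: Optional[Allocation]
    tauopathy_4r: bool
    extinguished: tuple[tuple[Allocation, str], ...] = ()
    trace: tuple[str, ...] = ()

    @property
    def phenotype(self) -> Optional[Phenotype]:
        return self.final.phenotype if self.final else None

    @property
    def certainty(self) -> Optional[Certainty]:
        return self.final.certainty if self.final else None


def phenotype_onset(
    allocation: Allocation, profile: FeatureProfile
) -> Optional[float]:
    """Onset of a phenotype: earliest onset among its satisfying features.

    Unknown (None) when any contributing feature lacks a recorded onset —
    absence of evidence must not promote a phenotype.
    """
    onsets = []
    for code in allocation.satisfied_by:
        month = profile.onset_month.get(code)
        if month is None:
            return None
        onsets.append(month)
    return min(onsets) if onsets else None


def flag_4r_tauopathy(
    final: Optional[Allocation], tau_map: Optional[TauopathyMap] = None
) -> bool:
    """Probable-4R-tauopathy YES/NO for a final allocation (NO when none)."""
    if final is None:
        return False
    if tau_map is None:
        tau_map = default_resolution().tau_map
    return tau_map.is_4r(final.phenotype, final.certainty)


def _describe_group(allocations: Sequence[Allocation]) -> str:
    return "; ".join(a.describe() for a in allocations)


def resolve_max(
    allocations: Iterable[Allocation],
    profile: FeatureProfile,
    *,
    config: Optional[ResolutionConfig] = None,
) -> Diagnosis:
    """Collapse simultaneous allocations to one diagnosis via the MAX rules.

    Applied lexicographically: (1) keep only the allocations at the highest
    diagnostic certainty; (2) among ties, keep those with the earliest known
    phenotype onset (unknown onsets tie with each other and never beat a known
    onset); (3) PSP-RS prevails over any variant; any residual variant tie is
    broken by the configured fixed order. Exactly one allocation survives for
    non-empty input; empty input yields ``final=None`` with an empty trace.
    """
    if config is None:
        config = default_resolution()
    # Stable deterministic working order: configured rank, then certainty.
    survivors = sorted(
        allocations,
        key=lambda a: (config.phenotype_rank(a.phenotype), -a.certainty),
    )
    if not survivors:
        return Diagnosis(final=None, tauopathy_4r=False)

    trace: list[str] = [f"allocations: {_describe_group(survivors)}"]
    extinguished: list[tuple[Allocation, str]] = []

    def extinguish(losers: Sequence[Allocation], rule: str, detail: str) -> None:
        extinguished.extend((a, rule) for a in losers)
        trace.append(f"{rule}: {detail}; extinguished {_describe_group(losers)}")

    if len(survivors) > 1:
        top = max(a.certainty for a in survivors)
        losers = [a for a in survivors if a.certainty < top]
        if losers:
            survivors = [a for a in survivors if a.certainty == top]
            extinguish(losers, MAX_RULE_1, f"kept certainty '{top.label}'")
        else:
            trace.append(f"{MAX_RULE_1}: all allocations tied at '{top.label}'")

    if len(survivors) > 1:
        onsets = {a: phenotype_onset(a, profile) for a in survivors}
        key = {a: (m if m is not None else math.inf) for a, m in onsets.items()}
        best = min(key.values())
        losers = [a for a in survivors if key[a] > best]
        if losers:
            survivors = [a for a in survivors if key[a] == best]
            extinguish(losers, MAX_RULE_2, f"kept earliest phenotype onset ({best:g} months)")
        else:
            tied = "unknown" if math.isinf(best) else f"{best:g} months"
            trace.append(f"{MAX_RULE_2}: all phenotype onsets tied ({tied})")

    if len(survivors) > 1:
        rs = [a for a in survivors if a.phenotype.is_hierarchy_apex]
        if rs:
            losers = [a for a in survivors if not a.phenotype.is_hierarchy_apex]
            survivors = rs
            extinguish(losers, MAX_RULE_3, "PSP-RS prevails")
        else:
            trace.append(f"{MAX_RULE_3}: PSP-RS not among the tied allocations")

    if len(survivors) > 1:
        survivors = sorted(survivors, key=lambda a: config.phenotype_rank(a.phenotype))
        winner, losers = survivors[0], survivors[1:]
        survivors = [winner]
        extinguish(losers, TIEBREAK_RULE, f"kept {winner.phenotype.value}")

    final = survivors[0]
    tau = flag_4r_tauopathy(final, config.tau_map)
    trace.append(f"final diagnosis: {final.describe()}")
    trace.append(f"probable 4R-tauopathy: {'YES' if tau else 'NO'}")
    return Diagnosis(
        final=final,
        tauopathy_4r=tau,
        extinguished=tuple(extinguished),
        trace=tuple(trace),
    )


def classify_profile(
    profile: FeatureProfile,
    rules: Optional[Sequence[RuleRow]] = None,
    *,
    config: Optional[ResolutionConfig] = None,
    gate_window: float = DEFAULT_GATE_WINDOW_MONTHS,
    stratum_subsumption: bool = False,
) -> tuple[FeatureProfile, set[Allocation], Diagnosis]:
    """Gate, allocate and resolve a single profile.

    Returns the gated profile, all allocations, and the resolved diagnosis.
    """
    gated = apply_temporal_gate(profile, gate_window)
    allocations = evaluate_allocations(
        gated, rules, stratum_subsumption=stratum_subsumption
    )
    diagnosis = resolve_max(allocations, gated, config=config)
    return gated, allocations, diagnosis


# ---------------------------------------------------------------------------
# 5. Patient records, batch classification and reports
# ---------------------------------------------------------------------------

#: Lower-case feature columns in file schemas, in canonical order.
FEATURE_COLUMNS: tuple[str, ...] = tuple(c.value.lower() for c in CODE_ORDER)
ONSET_COLUMNS: tuple[str, ...] = tuple(f"onset_{c}" for c in FEATURE_COLUMNS)
NO_ALLOCATION = "no PSP allocation"


@dataclass(frozen=True)
class RawObservations:
    """Optional raw clinical sub-observations attached to a record."""

    frontal: Optional[FrontalSubitems] = None
    cbs: Optional[CbsSubitems] = None
    levodopa: Optional[LevodopaChallenge] = None
    pull_test: Optional[PullTestObservation] = None


@dataclass(frozen=True)
class PatientRecord:
    """One patient visit: identifier, entered feature flags, optional raws.

    ``explicit`` lists the codes whose presence/absence was explicitly entered
    (as opposed to defaulted); when raw sub-observations disagree with an
    explicit flag, the explicit flag wins and a warning is logged.
    """

    patient_id: str
    profile: FeatureProfile
    visit_month: Optional[float] = None
    raw: Optional[RawObservations] = None
    explicit: frozenset[FeatureCode] = frozenset()

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.visit_month is not None and self.visit_month < 0:
            raise ValueError("visit_month must be >= 0")
        object.__setattr__(self, "explicit", frozenset(self.explicit))


def derive_raw_features(
    raw: RawObservations,
) -> tuple[dict[FeatureCode, bool], dict[FeatureCode, float]]:
    """Derive core feature values (and pull-test onsets) from raw observations.

    Frontal items decide C2; CBS signs decide C3; the levodopa challenge
    separates A2 (resistant) from A3 (responsive) when assessable; the pull
    test decides P2 and, when the patient does not require catching, P3.
    """
    values: dict[FeatureCode, bool] = {}
    onsets: dict[FeatureCode, float] = {}
    if raw.frontal is not None:
        values[FeatureCode.C2] = derive_frontal_presentation(raw.frontal)
    if raw.cbs is not None:
        values[FeatureCode.C3] = derive_cbs(raw.cbs)
    if raw.levodopa is not None:
        resistant = assess_levodopa_resistance(raw.levodopa)
        if resistant is True:
            values[FeatureCode.A2] = True
        elif resistant is False:
            values[FeatureCode.A2] = False
            values[FeatureCode.A3] = True
    if raw.pull_test is not None:
        feature = derive_pull_test_feature(raw.pull_test)
        if raw.pull_test.would_fall_if_not_caught:
            values[FeatureCode.P2] = True
        else:
            values[FeatureCode.P2] = False
            values[FeatureCode.P3] = feature is FeatureCode.P3
        if feature is not None and raw.pull_test.months_from_onset is not None:
            onsets[feature] = raw.pull_test.months_from_onset
    return values, onsets


def merge_raw_observations(record: PatientRecord) -> FeatureProfile:
    """Fold raw-derived feature values into a record's profile.

    An explicitly entered flag always wins over a derived value; any
    disagreement is logged as a warning.
    """
    if record.raw is None:
        return record.profile
    derived, derived_onsets = derive_raw_features(record.raw)
    present = set(record.profile.present)
    onsets = dict(record.profile.onset_month)
    for code, value in derived.items():
        if code in record.explicit and (code in present) != value:
            logger.warning(
                "record %s: raw observations derive %s=%s but explicit flag says %s; "
                "explicit flag wins",
                record.patient_id,
                code.value,
                int(value),
                int(code in present),
            )
            continue
        if value:
            present.add(code)
            if code in derived_onsets and code not in onsets:
                onsets[code] = derived_onsets[code]
        else:
            present.discard(code)
            onsets.pop(code, None)
    return FeatureProfile(frozenset(present), onsets)


@dataclass(frozen=True)
class RecordResult:
    """Classification outcome for one record (profile shown post-gating)."""

    patient_id: str
    visit_month: Optional[float]
    profile: FeatureProfile
    allocations: tuple[Allocation, ...]
    diagnosis: Diagnosis


@dataclass(frozen=True)
class ClassificationReport:
    """Per-record results plus a cohort summary."""

    results: tuple[RecordResult, ...]

    @property
    def summary(self) -> dict:
        phenotypes = Counter(
            r.diagnosis.phenotype.value if r.diagnosis.phenotype else NO_ALLOCATION
            for r in self.results
        )
        certainties = Counter(
            r.diagnosis.certainty.token
            for r in self.results
            if r.diagnosis.certainty is not None
        )
        return {
            "n_records": len(self.results),
            "final_phenotype_counts": dict(sorted(phenotypes.items())),
            "certainty_counts": dict(sorted(certainties.items())),
            "probable_4r_tauopathy_yes": sum(
                r.diagnosis.tauopathy_4r for r in self.results
            ),
        }


def classify_batch(
    records: Sequence[PatientRecord],
    rules: Optional[Sequence[RuleRow]] = None,
    *,
    config: Optional[ResolutionConfig] = None,
    gate_window: float = DEFAULT_GATE_WINDOW_MONTHS,
    stratum_subsumption: bool = False,
) -> ClassificationReport:
    """Classify a batch of records: derive, gate, allocate, resolve, flag."""
    results = []
    for record in records:
        profile = merge_raw_observations(record)
        gated, allocations, diagnosis = classify_profile(
            profile,
            rules,
            config=config,
            gate_window=gate_window,
            stratum_subsumption=stratum_subsumption,
        )
        results.append(
            RecordResult(
                patient_id=record.patient_id,
                visit_month=record.visit_month,
                profile=gated,
                allocations=tuple(
                    sorted(
                        allocations,
                        key=lambda a: (-a.certainty, a.phenotype.value),
                    )
                ),
                diagnosis=diagnosis,
            )
        )
    return ClassificationReport(tuple(results))


# --- record file readers ---------------------------------------------------

def _parse_flag(value: object, where: str) -> Optional[bool]:
    """Parse a 0/1/empty feature cell; None means 'not entered'."""
    if value is None:
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip()
    if text == "":
        return None
    if text in ("0", "1"):
        return text == "1"
    raise RecordParseError(f"{where}: feature value must be 0, 1 or empty, got {value!r}")


def _parse_optional_number(value: object, where: str) -> Optional[float]:
    if value is None:
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise RecordParseError(f"{where}: expected a number, got {value!r}") from None


def _record_from_fields(
    fields: Mapping[str, object],
    where: str,
    raw: Optional[RawObservations] = None,
) -> PatientRecord:
    patient_id = str(fields.get("patient_id") or "").strip()
    if not patient_id:
        raise RecordParseError(f"{where}: patient_id is required")
    visit_month = _parse_optional_number(fields.get("visit_month"), f"{where}, visit_month")
    present: set[FeatureCode] = set()
    explicit: set[FeatureCode] = set()
    for column, code in zip(FEATURE_COLUMNS, CODE_ORDER):
        if column not in fields:
            continue
        flag = _parse_flag(fields[column], f"{where}, column '{column}'")
        if flag is None:
            continue
        explicit.add(code)
        if flag:
            present.add(code)
    onsets: dict[FeatureCode, float] = {}
    for column, code in zip(ONSET_COLUMNS, CODE_ORDER):
        if column not in fields:
            continue
        month = _parse_optional_number(fields[column], f"{where}, column '{column}'")
        if month is None:
            continue
        if code not in present:
            raise RecordParseError(
                f"{where}, column '{column}': onset given for a feature not present"
            )
        if month < 0:
            raise RecordParseError(f"{where}, column '{column}': onset must be >= 0")
        onsets[code] = month
    return PatientRecord(
        patient_id=patient_id,
        visit_month=visit_month,
        profile=FeatureProfile(frozenset(present), onsets),
        raw=raw,
        explicit=frozenset(explicit),
    )


def _check_duplicates(records: Sequence[PatientRecord], origin: str) -> None:
    seen: set[tuple[str, Optional[float]]] = set()
    for record in records:
        key = (record.patient_id, record.visit_month)
        if key in seen:
            raise RecordParseError(
                f"{origin}: duplicate (patient_id, visit_month) = {key}"
            )
        seen.add(key)


def _raw_from_json(obj: Mapping, where: str) -> Optional[RawObservations]:
    if not obj:
        return None
    try:
        frontal = FrontalSubitems(**{k: bool(v) for k, v in obj["frontal"].items()}) if "frontal" in obj else None
        cbs = CbsSubitems(**{k: bool(v) for k, v in obj["cbs"].items()}) if "cbs" in obj else None
        levodopa = LevodopaChallenge(**obj["levodopa"]) if "levodopa" in obj else None
        pull = PullTestObservation(**obj["pull_test"]) if "pull_test" in obj else None
    except (TypeError, ValueError) as exc:
        raise RecordParseError(f"{where}, raw observations: {exc}") from None
    return RawObservations(frontal=frontal, cbs=cbs, levodopa=levodopa, pull_test=pull)


def read_records(
    path: Union[str, Path], fmt: Optional[str] = None
) -> list[PatientRecord]:
    """Read patient records from CSV or JSON.

    CSV: one row per visit; columns ``patient_id``, optional ``visit_month``,
    feature columns ``o1`` .. ``cc4`` with values 0/1/empty, optional onset
    columns ``onset_o1`` .. ``onset_cc4`` in months. JSON: a list of objects
    with the same keys, plus an optional ``raw`` object carrying sub-
    observations (``frontal``, ``cbs``, ``levodopa``, ``pull_test``). Missing
    feature columns default to absent with a logged warning; malformed values
    and duplicate (patient_id, visit_month) pairs raise
    :class:`RecordParseError`.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported record format: {fmt}")

    records: list[PatientRecord] = []
    if fmt == "csv":
        with path.open(newline="") as handle:
            reader = csv.DictReader(handle)
            header = reader.fieldnames or []
            if "patient_id" not in header:
                raise RecordParseError(f"{path}: missing required column 'patient_id'")
            missing = [c for c in FEATURE_COLUMNS if c not in header]
            if missing:
                logger.warning(
                    "%s: feature columns %s missing; defaulting to absent",
                    path,
                    ", ".join(missing),
                )
            known = {"patient_id", "visit_month", *FEATURE_COLUMNS, *ONSET_COLUMNS}
            unknown = [c for c in header if c not in known]
            if unknown:
                logger.warning("%s: ignoring unknown columns %s", path, ", ".join(unknown))
            for i, row in enumerate(reader, start=2):
                records.append(_record_from_fields(row, f"{path}, line {i}"))
    else:
        doc = json.loads(path.read_text())
        if isinstance(doc, Mapping) and "records" in doc:
            doc = doc["records"]
        if not isinstance(doc, list):
            raise RecordParseError(f"{path}: expected a JSON list of records")
        for i, obj in enumerate(doc, start=1):
            where = f"{path}, record {i}"
            if not isinstance(obj, Mapping):
                raise RecordParseError(f"{where}: expected an object")
            raw = _raw_from_json(obj.get("raw") or {}, where)
            records.append(_record_from_fields(obj, where, raw=raw))
    _check_duplicates(records, str(path))
    return records


def write_records(
    records: Sequence[PatientRecord], path: Union[str, Path], fmt: Optional[str] = None
) -> None:
    """Write records in the standard CSV or JSON schema (flags + onsets)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        onset_cols = [
            col
            for col, code in zip(ONSET_COLUMNS, CODE_ORDER)
            if any(code in r.profile.onset_month for r in records)
        ]
        with path.open("w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["patient_id", "visit_month", *FEATURE_COLUMNS, *onset_cols])
            for r in records:
                row = [
                    r.patient_id,
                    "" if r.visit_month is None else f"{r.visit_month:g}",
                ]
                row += [int(code in r.profile.present) for code in CODE_ORDER]
                for col in onset_cols:
                    code = _parse_code(col.removeprefix("onset_"))
                    month = r.profile.onset_month.get(code)
                    row.append("" if month is None else f"{month:g}")
                writer.writerow(row)
    elif fmt == "json":
        out = []
        for r in records:
            obj: dict = {"patient_id": r.patient_id}
            if r.visit_month is not None:
                obj["visit_month"] = r.visit_month
            for col, code in zip(FEATURE_COLUMNS, CODE_ORDER):
                obj[col] = int(code in r.profile.present)
            for col, code in zip(ONSET_COLUMNS, CODE_ORDER):
                if code in r.profile.onset_month:
                    obj[col] = r.profile.onset_month[code]
            out.append(obj)
        path.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unsupported record format: {fmt}")


# --- report serialization ---------------------------------------------------

def _allocation_to_dict(a: Allocation) -> dict:
    return {
        "phenotype": a.phenotype.value,
        "certainty": a.certainty.token,
        "satisfied_by": sorted(c.value for c in a.satisfied_by),
    }


def _allocation_from_dict(d: Mapping) -> Allocation:
    return Allocation(
        phenotype=_parse_phenotype(d["phenotype"]),
        certainty=Certainty.parse(d["certainty"]),
        satisfied_by=frozenset(_parse_code(c) for c in d["satisfied_by"]),
    )


def _profile_to_dict(p: FeatureProfile) -> dict:
    return {
        "present": sorted(c.value for c in p.present),
        "onset_month": {c.value: m for c, m in sorted(p.onset_month.items())},
    }


def _profile_from_dict(d: Mapping) -> FeatureProfile:
    return FeatureProfile.from_codes(d["present"], d.get("onset_month") or {})


def report_to_dict(report: ClassificationReport) -> dict:
    """Loss-free JSON-compatible rendering of a report (full traces)."""
    return {
        "records": [
            {
                "patient_id": r.patient_id,
                "visit_month": r.visit_month,
                "profile": _profile_to_dict(r.profile),
                "allocations": [_allocation_to_dict(a) for a in r.allocations],
                "diagnosis": {
                    "final": _allocation_to_dict(r.diagnosis.final)
                    if r.diagnosis.final
                    else None,
                    "tauopathy_4r": r.diagnosis.tauopathy_4r,
                    "extinguished": [
                        {"allocation": _allocation_to_dict(a), "rule": rule}
                        for a, rule in r.diagnosis.extinguished
                    ],
                    "trace": list(r.diagnosis.trace),
                },
            }
            for r in report.results
        ],
        "summary": report.summary,
    }


def report_from_dict(doc: Mapping) -> ClassificationReport:
    results = []
    for rec in doc["records"]:
        diag = rec["diagnosis"]
        results.append(
            RecordResult(
                patient_id=rec["patient_id"],
                visit_month=rec["visit_month"],
                profile=_profile_from_dict(rec["profile"]),
                allocations=tuple(_allocation_from_dict(a) for a in rec["allocations"]),
                diagnosis=Diagnosis(
                    final=_allocation_from_dict(diag["final"]) if diag["final"] else None,
                    tauopathy_4r=bool(diag["tauopathy_4r"]),
                    extinguished=tuple(
                        (_allocation_from_dict(e["allocation"]), e["rule"])
                        for e in diag["extinguished"]
                    ),
                    trace=tuple(diag["trace"]),
                ),
            )
        )
    return ClassificationReport(tuple(results))


def render_text_report(report: ClassificationReport) -> str:
    """Human-readable rendering echoing the smartsheet-style panels."""
    lines: list[str] = []
    for r in report.results:
        visit = "" if r.visit_month is None else f" (visit month {r.visit_month:g})"
        lines.append(f"Patient {r.patient_id}{visit}")
        present = sorted(r.profile.present, key=_CODE_BIT.get)
        if present:
            shown = []
            for code in present:
                month = r.profile.onset_month.get(code)
                shown.append(
                    code.value if month is None else f"{code.value} (onset {month:g} mo)"
                )
            lines.append(f"  Features present: {', '.join(shown)}")
        else:
            lines.append("  Features present: none")
        if r.allocations:
            lines.append("  Allocations:")
            lines.extend(f"    - {a.describe()}" for a in r.allocations)
            lines.append("  MAX resolution:")
            lines.extend(f"    {step}" for step in r.diagnosis.trace)
        else:
            lines.append(f"  Diagnosis: {NO_ALLOCATION}")
            lines.append("  Probable 4R-tauopathy: NO")
        lines.append("")
    summary = report.summary
    lines.append("Cohort summary")
    lines.append(f"  records: {summary['n_records']}")
    for phenotype, count in summary["final_phenotype_counts"].items():
        lines.append(f"  {phenotype}: {count}")
    lines.append(
        f"  probable 4R-tauopathy YES: {summary['probable_4r_tauopathy_yes']}"
    )
    return "\n".join(lines) + "\n"


def write_report(
    report: ClassificationReport, path: Union[str, Path], fmt: str = "json"
) -> None:
    """Write a report as loss-free JSON, per-record CSV, or readable text."""
    path = Path(path)
    if fmt == "json":
        path.write_text(
            json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
        )
    elif fmt == "csv":
        with path.open("w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(
                ["patient_id", "visit_month", "final_phenotype", "certainty",
                 "probable_4r_tauopathy"]
            )
            for r in report.results:
                d = r.diagnosis
                writer.writerow(
                    [
                        r.patient_id,
                        "" if r.visit_month is None else f"{r.visit_month:g}",
                        d.phenotype.value if d.phenotype else NO_ALLOCATION,
                        d.certainty.token if d.certainty else "",
                        "YES" if d.tauopathy_4r else "NO",
                    ]
                )
    elif fmt == "text":
        path.write_text(render_text_report(report))
    else:
        raise ValueError(f"unsupported report format: {fmt}")


def read_report(path: Union[str, Path]) -> ClassificationReport:
    """Read back a JSON report written by :func:`write_report`."""
    return report_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# 6. Synthetic fixtures
# ---------------------------------------------------------------------------

N_PROFILES = 1 << len(CODE_ORDER)  # 65,536

#: Default Bernoulli prevalences for the simulated clinic cohort: plausible
#: cross-sectional frequencies in a moderately advanced PSP population
#: (ocular motor and postural features common; gait freezing, speech/language
#: presentations and corticobasal syndrome rare). See docs/methods.md.
DEFAULT_PREVALENCE: dict[FeatureCode, float] = {
    FeatureCode.O1: 0.55,
    FeatureCode.O2: 0.30,
    FeatureCode.O3: 0.15,
    FeatureCode.P1: 0.60,
    FeatureCode.P2: 0.35,
    FeatureCode.P3: 0.15,
    FeatureCode.A1: 0.08,
    FeatureCode.A2: 0.30,
    FeatureCode.A3: 0.20,
    FeatureCode.C1: 0.07,
    FeatureCode.C2: 0.40,
    FeatureCode.C3: 0.08,
    FeatureCode.CC1: 0.25,
    FeatureCode.CC2: 0.30,
    FeatureCode.CC3: 0.20,
    FeatureCode.CC4: 0.25,
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort.

    Feature presence is independent Bernoulli per code; onsets, when an
    ``onset_model`` range (lo, hi) in months is configured for a code, are
    uniform over that range for present features.
    """

    n: int
    seed: int
    feature_prevalence: Mapping[FeatureCode, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    onset_model: Optional[Mapping[FeatureCode, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for code, p in self.feature_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {code.value} must be in [0, 1]")
        if self.onset_model:
            for code, (lo, hi) in self.onset_model.items():
                if lo < 0 or hi < lo:
                    raise ValueError(f"onset range for {code.value} must satisfy 0 <= lo <= hi")


def enumerate_profiles() -> Iterator[FeatureProfile]:
    """Yield all 2^16 = 65,536 present/absent combinations exactly once.

    Deterministic order: the integer mask 0..65535 with O1 as the lowest bit;
    the first profile has every feature absent. Onsets are undefined.
    """
    for mask in range(N_PROFILES):
        yield FeatureProfile.from_mask(mask)


def minimal_profiles_for_row(row: RuleRow) -> list[FeatureProfile]:
    """One profile per minimal satisfying assignment of a rule row's formula.

    Each profile has exactly the literals of one (minimal) conjunct present
    and everything else absent; duplicate and non-minimal conjuncts are
    dropped. Deterministic order follows the row's conjunct order.
    """
    minimal: list[frozenset[FeatureCode]] = []
    seen: set[frozenset[FeatureCode]] = set()
    for conj in row.conjuncts:
        if conj in seen or any(other < conj for other in row.conjuncts):
            continue
        seen.add(conj)
        minimal.append(conj)
    return [FeatureProfile(conj) for conj in minimal]


def sample_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort of patient records.

    Each record's features are independent Bernoulli draws at the configured
    prevalences; onsets are drawn for present features with an onset model.
    Identical specs (including the seed) yield identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    prevalence = np.array(
        [float(spec.feature_prevalence.get(code, 0.0)) for code in CODE_ORDER]
    )
    draws = rng.random((spec.n, len(CODE_ORDER))) < prevalence
    width = max(4, len(str(spec.n)))
    records = []
    for i in range(spec.n):
        present = frozenset(
            code for j, code in enumerate(CODE_ORDER) if draws[i, j]
        )
        onsets: dict[FeatureCode, float] = {}
        if spec.onset_model:
            for code in sorted(present, key=_CODE_BIT.get):
                if code in spec.onset_model:
                    lo, hi = spec.onset_model[code]
                    onsets[code] = float(rng.uniform(lo, hi))
        records.append(
            PatientRecord(
                patient_id=f"sim-{i + 1:0{width}d}",
                profile=FeatureProfile(present, onsets),
                explicit=frozenset(CODE_ORDER),
            )
        )
    return records
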