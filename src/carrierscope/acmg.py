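"""Five-tier variant classification from assigned ACMG/AMP evidence criteria.

The engine combines *assigned* evidence codes (PVS1, PS1-PS4, PM1-PM6,
PP1-PP5, BA1, BS1-BS4, BP1-BP7) into one of the five standard categories
(Pathogenic, Likely pathogenic, VUS, Likely benign, Benign) using the fixed
combining rules of the 2015 ACMG/AMP framework.  It does not *derive*
criteria from data -- population frequencies, computational predictors and
segregation evidence are upstream of this module and enter only as codes.

Each criterion carries an applied strength, defaulting to the strength its
code natively encodes; the combining rules count applied strengths, so an
evidence item downgraded (e.g. PVS1 applied at Strong) or upgraded (e.g.
PP1 applied at Moderate) contributes at its applied level.

Besides the rule engine, the module maps label-based pathogenicity sources
onto the same five categories: ClinVar-style assertion strings and HGMD-style
"DM" flags, so a panel can be selected under any of the three sources.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .records import VariantRecord


class Strength(enum.Enum):
    """Evidence strength levels, ordered strongest first."""

    STAND_ALONE = "stand-alone"
    VERY_STRONG = "very-strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


# Native strength of each recognised code family.
_CODE_PATTERN = re.compile(
    r"^(PVS1|PS[1-4]|PM[1-6]|PP[1-5]|BA1|BS[1-4]|BP[1-7])$"
)


def native_strength(code: str) -> Strength:
    """The strength a criterion code encodes by name."""
    if not _CODE_PATTERN.match(code):
        raise ValueError(f"unknown ACMG/AMP criterion code: {code!r}")
    prefix = code[:2]
    return {
        "PV": Strength.VERY_STRONG,
        "PS": Strength.STRONG,
        "PM": Strength.MODERATE,
        "PP": Strength.SUPPORTING,
        "BA": Strength.STAND_ALONE,
        "BS": Strength.STRONG,
        "BP": Strength.SUPPORTING,
    }[prefix]


def is_benign_code(code: str) -> bool:
    return code.startswith("B")


_STRENGTH_ALIASES = {
    "standalone": Strength.STAND_ALONE,
    "stand-alone": Strength.STAND_ALONE,
    "verystrong": Strength.VERY_STRONG,
    "very-strong": Strength.VERY_STRONG,
    "strong": Strength.STRONG,
    "moderate": Strength.MODERATE,
    "supporting": Strength.SUPPORTING,
}


@dataclass(frozen=True)
class Criterion:
    """One assigned evidence item: a code plus its applied strength."""

    code: str
    strength: Strength = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        native = native_strength(self.code)  # validates the code
        if self.strength is None:
            object.__setattr__(self, "strength", native)

    @classmethod
    def parse(cls, token: str) -> "Criterion":
        """Parse ``"PM2"`` or ``"PVS1_Strong"`` style tokens."""
        token = token.strip()
        if "_" in token:
            code, _, suffix = token.partition("_")
            key = suffix.strip().lower().replace(" ", "")
            if key not in _STRENGTH_ALIASES:
                raise ValueError(f"unknown strength modifier in {token!r}")
            return cls(code, _STRENGTH_ALIASES[key])
        return cls(token)

    def __str__(self) -> str:
        if self.strength is native_strength(self.code):
            return self.code
        return f"{self.code}_{self.strength.value.replace('-', '').title()}"


@dataclass(frozen=True)
class EvidenceProfile:
    """A set of assigned criteria; each base code appears at most once."""

    criteria: frozenset[Criterion] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", frozenset(self.criteria))
        codes = [c.code for c in self.criteria]
        if len(codes) != len(set(codes)):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"criterion codes assigned more than once: {dupes}")

    @classmethod
    def from_codes(cls, *tokens: str) -> "EvidenceProfile":
        return cls(frozenset(Criterion.parse(t) for t in tokens))

    @classmethod
    def parse(cls, text: str, sep: str = ";") -> "EvidenceProfile":
        """Parse a delimiter-separated criteria string, e.g. ``"PVS1;PM2"``."""
        tokens = [t for t in (s.strip() for s in text.split(sep)) if t]
        return cls.from_codes(*tokens)

    def __str__(self) -> str:
        return ";".join(sorted(str(c) for c in self.criteria))


class Category(enum.Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "Likely pathogenic"
    VUS = "Uncertain significance"
    LIKELY_BENIGN = "Likely benign"
    BENIGN = "Benign"


#: The two categories that select a variant into the pathogenic set.
PATHOGENIC_CATEGORIES = frozenset(
    {Category.PATHOGENIC, Category.LIKELY_PATHOGENIC}
)


@dataclass(frozen=True)
class Classification:
    category: Category
    source: str  # "acmg2015" | "clinvar" | "hgmd"
    rule_fired: str

    @property
    def is_pathogenic(self) -> bool:
        return self.category in PATHOGENIC_CATEGORIES


def _tally(profile: EvidenceProfile) -> tuple[int, int, int, int, bool, int, int]:
    """Count applied strengths on each side of the evidence.

    Returns (very_strong, strong, moderate, supporting) on the pathogenic
    side, then (ba, benign_strong, benign_supporting).  A second or further
    very-strong item counts as strong (strengths stack downward); on the
    benign side anything below strong counts toward supporting, since the
    benign combining rules only distinguish stand-alone / strong / supporting.
    """
    nvs = ns = nm = np_ = 0
    ba = False
    bs = bp = 0
    for c in profile.criteria:
        if is_benign_code(c.code):
            if c.strength is Strength.STAND_ALONE:
                ba = True
            elif c.strength in (Strength.VERY_STRONG, Strength.STRONG):
                bs += 1
            else:
                bp += 1
        else:
            if c.strength in (Strength.STAND_ALONE, Strength.VERY_STRONG):
                nvs += 1
            elif c.strength is Strength.STRONG:
                ns += 1
            elif c.strength is Strength.MODERATE:
                nm += 1
            else:
                np_ += 1
    if nvs > 1:  # surplus very-strong evidence stacks as strong
        ns += nvs - 1
        nvs = 1
    return nvs, ns, nm, np_, ba, bs, bp


# Combining-rule table: (rule id, predicate over the pathogenic-side tally).
_PATHOGENIC_RULES: Sequence[tuple[str, callable]] = (
    ("P:VS+S", lambda vs, s, m, p: vs >= 1 and s >= 1),
    ("P:VS+2M", lambda vs, s, m, p: vs >= 1 and m >= 2),
    ("P:VS+M+P", lambda vs, s, m, p: vs >= 1 and m >= 1 and p >= 1),
    ("P:VS+2P", lambda vs, s, m, p: vs >= 1 and p >= 2),
    ("P:2S", lambda vs, s, m, p: s >= 2),
    ("P:S+3M", lambda vs, s, m, p: s == 1 and m >= 3),
    ("P:S+2M+2P", lambda vs, s, m, p: s == 1 and m == 2 and p >= 2),
    ("P:S+M+4P", lambda vs, s, m, p: s == 1 and m == 1 and p >= 4),
)

_LIKELY_PATHOGENIC_RULES: Sequence[tuple[str, callable]] = (
    ("LP:VS+M", lambda vs, s, m, p: vs >= 1 and m == 1),
    ("LP:S+1-2M", lambda vs, s, m, p: s == 1 and 1 <= m <= 2),
    ("LP:S+2P", lambda vs, s, m, p: s == 1 and p >= 2),
    ("LP:3M", lambda vs, s, m, p: m >= 3),
    ("LP:2M+2P", lambda vs, s, m, p: m == 2 and p >= 2),
    ("LP:M+4P", lambda vs, s, m, p: m == 1 and p >= 4),
)


def combine_criteria(profile: EvidenceProfile, source: str = "acmg2015") -> Classification:
    """Combine assigned criteria into a five-tier classification.

    The mapping is total and deterministic: every profile yields exactly
    one category.  When rules fire on both the pathogenic and the benign
    side -- or a stand-alone benign criterion (BA1) coexists with any
    pathogenic-side evidence -- the evidence is conflicting and the call
    is VUS.
    """
    nvs, ns, nm, np_, ba, bs, bp = _tally(profile)

    path_rule: Optional[str] = None
    for rule_id, pred in _PATHOGENIC_RULES:
        if pred(nvs, ns, nm, np_):
            path_rule = rule_id
            break
    path_category: Optional[Category] = Category.PATHOGENIC if path_rule else None
    if path_category is None:
        for rule_id, pred in _LIKELY_PATHOGENIC_RULES:
            if pred(nvs, ns, nm, np_):
                path_rule = rule_id
                path_category = Category.LIKELY_PATHOGENIC
                break

    benign_rule: Optional[str] = None
    benign_category: Optional[Category] = None
    if ba or bs >= 2:
        benign_rule = "B:BA1" if ba else "B:2S"
        benign_category = Category.BENIGN
    elif (bs == 1 and bp >= 1) or bp >= 2:
        benign_rule = "LB:S+P" if bs == 1 else "LB:2P"
        benign_category = Category.LIKELY_BENIGN

    has_path_evidence = (nvs + ns + nm + np_) > 0
    if path_category is not None and benign_category is not None:
        return Classification(Category.VUS, source, "conflicting-evidence")
    if benign_category is Category.BENIGN and ba and has_path_evidence:
        # BA1 is stand-alone only in the absence of pathogenic evidence.
        return Classification(Category.VUS, source, "conflicting-evidence")
    if path_category is not None:
        return Classification(path_category, source, path_rule)  # type: ignore[arg-type]
    if benign_category is not None:
        return Classification(benign_category, source, benign_rule)  # type: ignore[arg-type]
    return Classification(Category.VUS, source, "default-VUS")


# ---------------------------------------------------------------------------
# Label-based classification sources


_CLINVAR_PATHOGENIC = {"pathogenic", "likely pathogenic", "pathogenic/likely pathogenic"}
_CLINVAR_BENIGN = {"benign", "likely benign", "benign/likely benign"}


def _normalize_label(label: str) -> str:
    return re.sub(r"[\s_]+", " ", label.strip().lower())


def classify_clinvar_label(label: str) -> Classification:
    """Map a ClinVar-style assertion string to a five-tier category.

    Pathogenic / Likely pathogenic (case-insensitive; slash-combined labels
    accepted) select the variant; anything else is treated as
    not-pathogenic for selection purposes.
    """
    norm = _normalize_label(label)
    if norm in _CLINVAR_PATHOGENIC:
        if norm == "likely pathogenic":
            category = Category.LIKELY_PATHOGENIC
        else:
            category = Category.PATHOGENIC
        return Classification(category, "clinvar", f"clinvar-label:{norm}")
    if norm in _CLINVAR_BENIGN:
        category = (
            Category.LIKELY_BENIGN if norm == "likely benign" else Category.BENIGN
        )
        return Classification(category, "clinvar", f"clinvar-label:{norm}")
    return Classification(Category.VUS, "clinvar", f"clinvar-label:{norm}")


def classify_hgmd_label(label: str) -> Classification:
    """Map an HGMD-style label: exactly ``"DM"`` (disease-causing mutation)
    is pathogenic-equivalent; DM?, DP, DFP, FP, R and anything else is not."""
    if label.strip() == "DM":
        return Classification(Category.PATHOGENIC, "hgmd", "hgmd-label:DM")
    return Classification(Category.VUS, "hgmd", f"hgmd-label:{label.strip()}")


SOURCES = ("acmg2015", "clinvar", "hgmd")


def classify_panel(
    records: Iterable[VariantRecord], source: str = "acmg2015"
) -> dict[str, Classification]:
    """Classify every record under one source; keys are record ``key``s.

    For ``acmg2015`` every record must carry an evidence profile; for
    ``clinvar``/``hgmd`` every record must carry the matching annotation.
    A missing source on any record is an error naming the offending
    variants rather than a silent exclusion.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown classification source {source!r}; choose from {SOURCES}")
    records = list(records)
    if source == "acmg2015":
        missing = [r.key for r in records if r.evidence is None]
        if missing:
            raise ValueError(
                f"source 'acmg2015' requires evidence profiles; missing for: {missing}"
            )
        return {r.key: combine_criteria(r.evidence) for r in records}
    missing = [r.key for r in records if source not in r.annotations]
    if missing:
        raise ValueError(
            f"source {source!r} annotation missing for: {missing}"
        )
    mapper = classify_clinvar_label if source == "clinvar" else classify_hgmd_label
    return {r.key: mapper(r.annotations[source]) for r in records}


def select_pathogenic(
    records: Iterable[VariantRecord],
    classifications: Mapping[str, Classification],
) -> list[VariantRecord]:
    """Records classified Pathogenic or Likely pathogenic, in input order."""
    return [
        r
        for r in records
        if r.key in classifications and classifications[r.key].is_pathogenic
    ]
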