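"""Tiered SRE code lists and the named composite case definitions.

Each skeletal-related-event (SRE) subtype — pathologic fracture (PF), spinal
cord compression (SCC), bone palliative radiotherapy (RAD), surgery to bone
(BS) — is identified by a code list organised in two nested tiers:

* ``SPECIFICITY`` — codes highly likely to indicate the subtype (e.g. the
  733.1x "pathologic fracture" diagnosis family for PF);
* ``SENSITIVITY_EXT`` — the *extension* that, unioned with the specificity
  tier, forms the "high sensitivity" list (e.g. the "other fracture"
  chapter codes for PF, IMRT/SRS delivery codes for RAD).

Storing the sensitive list as a disjoint extension makes the tier-nesting
invariant (sensitive ⊇ specific) structural. BS has a single list: bone
surgery procedure codes are unambiguous, so both tiers select it.

Two composite definitions are registered by default:

* ``base_case`` — sensitive PF, specific SCC and RAD (the most common
  configuration in the claims literature);
* ``alternative`` — specific PF, sensitive SCC and RAD.

Codebook rows may also carry non-event roles: ``TRAUMA`` external-cause
E-codes (accidents and falls) that trigger the fracture trauma-exclusion
rule, ``SAME_LEVEL_FALL`` E-codes exempt from it (low-energy falls from
routine activity), and ``RAD_CONTEXT`` diagnoses (bone metastasis, bone
pain) used by the optional radiotherapy concurrency filter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .core import CodeSystem, ValidationError, normalize_code

__all__ = [
    "SREType",
    "Tier",
    "Role",
    "CodeEntry",
    "Codebook",
    "SREDefinition",
    "load_codebook",
    "default_codebook",
    "match_code",
    "make_definition",
    "register_definition",
]

WILDCARD = "*"


class SREType(enum.Enum):
    PF = "PF"
    SCC = "SCC"
    RAD = "RAD"
    BS = "BS"


class Tier(enum.Enum):
    SPECIFICITY = "SPECIFICITY"
    SENSITIVITY_EXT = "SENSITIVITY_EXT"


class Role(enum.Enum):
    EVENT = "EVENT"
    TRAUMA = "TRAUMA"
    SAME_LEVEL_FALL = "SAME_LEVEL_FALL"
    RAD_CONTEXT = "RAD_CONTEXT"


@dataclass(frozen=True)
class CodeEntry:
    """One codebook row: a code pattern and its classification.

    ``pattern`` is a normalized code, optionally ending in ``*`` for prefix
    matching. ``sre_type`` is None for non-event roles.
    """

    pattern: str
    system: CodeSystem
    sre_type: SREType | None
    tier: Tier
    role: Role

    def matches(self, code: str, system: CodeSystem) -> bool:
        if system is not self.system:
            return False
        if self.pattern.endswith(WILDCARD):
            return code.startswith(self.pattern[:-1])
        return code == self.pattern


def _normalize_pattern(raw: str) -> str:
    """Normalize a codebook pattern; a trailing X/x is a wildcard synonym.

    ICD-9-CM codes never legitimately end in "X", so the conventional
    "733.1X" notation can be converted to the prefix pattern "7331*".
    """
    p = normalize_code(raw)
    if p.endswith(("X", "x")) and len(p) > 1:
        p = p[:-1] + WILDCARD
    return p


@dataclass(frozen=True)
class Codebook:
    entries: tuple[CodeEntry, ...]

    def __post_init__(self) -> None:
        seen = set()
        errors = []
        for i, e in enumerate(self.entries):
            if e.role is Role.EVENT and e.sre_type is None:
                errors.append(f"entry {i} ({e.pattern}): role EVENT requires an SRE type")
            if e.role is not Role.EVENT and e.sre_type is not None:
                errors.append(
                    f"entry {i} ({e.pattern}): role {e.role.value} must not carry an SRE type"
                )
            key = (e.pattern, e.system, e.role, e.sre_type)
            if key in seen:
                errors.append(f"entry {i} ({e.pattern}): duplicate of earlier entry")
            seen.add(key)
        if errors:
            raise ValidationError("invalid codebook:\n" + "\n".join(errors))

    def event_entries(self) -> list[CodeEntry]:
        return [e for e in self.entries if e.role is Role.EVENT]

    def extend(self, extra: list[CodeEntry]) -> "Codebook":
        return Codebook(self.entries + tuple(extra))


def load_codebook(path) -> Codebook:
    """Load and validate a codebook CSV (columns: pattern, system, sre_type, tier, role)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["pattern", "system", "sre_type", "tier", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing codebook column(s): {', '.join(missing)}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        sre = row.sre_type.strip().upper()
        entries.append(
            CodeEntry(
                pattern=_normalize_pattern(row.pattern),
                system=CodeSystem(row.system.strip()),
                sre_type=None if sre in ("", "NONE") else SREType(sre),
                tier=Tier(row.tier.strip().upper()),
                role=Role(row.role.strip().upper()),
            )
        )
    return Codebook(tuple(entries))


def default_codebook() -> Codebook:
    """The codebook shipped with the package.

    It covers the canonical members of each list — the 733.1x pathologic
    fracture family, the 800–829 "other fracture" chapter, 336.9 and spinal
    decompression procedures, myelopathy diagnoses, 2D/3D external-beam and
    radioisotope delivery codes, IMRT/SRS codes, bone surgery procedures,
    and the accident/fall E-code families — and is user-extensible; site
    code lists can replace it wholesale via :func:`load_codebook`.
    """
    with resources.as_file(
        resources.files("skelevent.data").joinpath("default_codebook.csv")
    ) as p:
        return load_codebook(p)


def match_code(
    codebook: Codebook, code: str, system: CodeSystem
) -> list[tuple[SREType | None, Tier, Role]]:
    """Return every (sre_type, tier, role) whose pattern matches ``code``.

    Exact match, or prefix match for patterns ending in ``*``. Order is
    deterministic: events first by (subtype, tier), then other roles.
    """
    hits = [
        (e.sre_type, e.tier, e.role)
        for e in codebook.entries
        if e.matches(code, system)
    ]
    hits.sort(
        key=lambda t: (
            t[2] is not Role.EVENT,
            t[0].value if t[0] else "",
            t[1].value,
            t[2].value,
        )
    )
    # collapse duplicates from overlapping patterns (e.g. nested prefixes)
    out = []
    for h in hits:
        if h not in out:
            out.append(h)
    return out


@dataclass(frozen=True)
class SREDefinition:
    """A named composite SRE definition: per-subtype tier selection + flags."""

    name: str
    tier_selection: dict[SREType, frozenset[Tier]]
    same_day_hierarchy: bool = False
    rad_concurrency_filter: bool = False
    bs_trauma_lookback: bool = False

    def __post_init__(self) -> None:
        both = frozenset({Tier.SPECIFICITY, Tier.SENSITIVITY_EXT})
        if self.tier_selection.get(SREType.BS) != both:
            raise ValidationError(
                "BS uses a single code list: its tier selection must include both tiers"
            )

    def selects(self, sre_type: SREType, tier: Tier) -> bool:
        return tier in self.tier_selection.get(sre_type, frozenset())


_BOTH = frozenset({Tier.SPECIFICITY, Tier.SENSITIVITY_EXT})
_SPEC = frozenset({Tier.SPECIFICITY})

_REGISTRY: dict[str, SREDefinition] = {
    "base_case": SREDefinition(
        name="base_case",
        tier_selection={
            SREType.PF: _BOTH,
            SREType.SCC: _SPEC,
            SREType.RAD: _SPEC,
            SREType.BS: _BOTH,
        },
    ),
    "alternative": SREDefinition(
        name="alternative",
        tier_selection={
            SREType.PF: _SPEC,
            SREType.SCC: _BOTH,
            SREType.RAD: _BOTH,
            SREType.BS: _BOTH,
        },
    ),
}


def register_definition(definition: SREDefinition) -> None:
    _REGISTRY[definition.name] = definition


def make_definition(name: str, **options: bool) -> SREDefinition:
    """Return a registered definition by name, with option flags overridden.

    ``base_case`` and ``alternative`` are always registered; more can be
    added with :func:`register_definition`.
    """
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown SRE definition {name!r}; registered: {sorted(_REGISTRY)}"
        )
    base = _REGISTRY[name]
    if options:
        from dataclasses import replace

        base = replace(base, **options)
    return base
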