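"""Phase-I biotransformation rules and bounded candidate enumeration.

A rule is a signed element-count delta on the neutral composition plus
site constraints (which moiety of the scaffold it may hit) and
applicability predicates expressed on the *state* of a partially
transformed molecule (fluorine still present, side chain still intact).

Candidates are unordered rule multisets up to a configurable depth; the
four fluorine-consuming transformations are mutually exclusive because
the parents carry a single fluorine on the pentyl side chain, and the
N-dealkylation removes the chain altogether.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .formula import Composition, FormulaError, IonMode, ion_mz

__all__ = [
    "MOIETIES",
    "Rule",
    "RuleSet",
    "CandidateMetabolite",
    "CandidateGroup",
    "RuleError",
    "default_ruleset",
    "apply_rule",
    "enumerate_candidates",
    "dedup_candidates",
]

#: Coarse structural moieties used for site constraints and localization.
MOIETIES = ("core", "side_chain", "adb_residue")

#: Rule ids that consume the side-chain fluorine / remove the chain.
F_CONSUMING = frozenset(
    {"defluor_oh", "defluor_aldehyde", "defluor_cooh", "n_dealkylation"}
)


class RuleError(ValueError):
    """Raised when a rule cannot be applied or a ruleset is invalid."""


@dataclass(frozen=True)
class Rule:
    """One biotransformation as a composition delta with site constraints."""

    id: str
    name: str
    delta: Mapping[str, int]
    allowed_moieties: frozenset[str]
    max_applications: int = 1
    requires_fluorine: bool = False
    requires_side_chain: bool = False
    removes_side_chain: bool = False

    def __post_init__(self):
        bad = set(self.allowed_moieties) - set(MOIETIES)
        if bad:
            raise RuleError(f"rule {self.id}: unknown moieties {sorted(bad)}")
        if not self.allowed_moieties:
            raise RuleError(f"rule {self.id}: allowed_moieties must be non-empty")

    def applicable(self, c: Composition, side_chain_present: bool = True) -> bool:
        if self.requires_fluorine and c.get("F") == 0:
            return False
        if self.requires_side_chain and not side_chain_present:
            return False
        return c.can_add(self.delta)


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[Rule, ...]
    depth_limit: int = 3

    def __post_init__(self):
        ids = [r.id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise RuleError("duplicate rule ids in ruleset")

    def __iter__(self):
        return iter(self.rules)

    def get(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    def to_yaml(self) -> str:
        doc = {
            "depth_limit": self.depth_limit,
            "rules": [
                {
                    "id": r.id,
                    "name": r.name,
                    "delta": dict(r.delta),
                    "allowed_moieties": sorted(r.allowed_moieties),
                    "max_applications": r.max_applications,
                    "requires_fluorine": r.requires_fluorine,
                    "requires_side_chain": r.requires_side_chain,
                    "removes_side_chain": r.removes_side_chain,
                }
                for r in self.rules
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RuleSet":
        doc = yaml.safe_load(text)
        rules = tuple(
            Rule(
                id=r["id"],
                name=r.get("name", r["id"]),
                delta={k: int(v) for k, v in r["delta"].items()},
                allowed_moieties=frozenset(r["allowed_moieties"]),
                max_applications=int(r.get("max_applications", 1)),
                requires_fluorine=bool(r.get("requires_fluorine", False)),
                requires_side_chain=bool(r.get("requires_side_chain", False)),
                removes_side_chain=bool(r.get("removes_side_chain", False)),
            )
            for r in doc["rules"]
        )
        return cls(rules=rules, depth_limit=int(doc.get("depth_limit", 3)))


@dataclass(frozen=True)
class CandidateMetabolite:
    """A parent plus an applied rule multiset, with its [M+H]+ m/z."""

    parent_id: str
    applied: tuple[str, ...]  # sorted rule ids, with repetition
    composition: Composition
    theoretical_mz: float
    depth: int


@dataclass
class CandidateGroup:
    """Candidates collapsed by distinct neutral composition."""

    composition: Composition
    theoretical_mz: float
    provenance: list[tuple[str, ...]] = field(default_factory=list)


# ---------------------------------------------------------------------------

_COMMON_RULES = [
    Rule(
        "hydroxylation",
        "hydroxylation (+OH)",
        {"O": 1},
        frozenset(MOIETIES),
        max_applications=2,
    ),
    Rule(
        "dehydrogenation",
        "dehydrogenation (-2H)",
        {"H": -2},
        frozenset({"adb_residue"}),
    ),
    Rule(
        "amide_hydrolysis",
        "amide hydrolysis (NH2 -> OH)",
        {"H": -1, "N": -1, "O": 1},
        frozenset({"adb_residue"}),
    ),
    Rule(
        "oxidation_aldehyde",
        "oxidation to aldehyde (-2H +O)",
        {"H": -2, "O": 1},
        frozenset({"adb_residue"}),
    ),
    Rule(
        "defluor_oh",
        "hydrolytic defluorination (F -> OH)",
        {"F": -1, "H": 1, "O": 1},
        frozenset({"side_chain"}),
        requires_fluorine=True,
        requires_side_chain=True,
    ),
    Rule(
        "defluor_aldehyde",
        "oxidative defluorination to aldehyde (F -> CHO)",
        {"F": -1, "H": -1, "O": 1},
        frozenset({"side_chain"}),
        requires_fluorine=True,
        requires_side_chain=True,
    ),
    Rule(
        "defluor_cooh",
        "defluorination to carboxylic acid (F -> COOH)",
        {"F": -1, "H": -1, "O": 2},
        frozenset({"side_chain"}),
        requires_fluorine=True,
        requires_side_chain=True,
    ),
]

_DEAMINATION = Rule(
    "deamination",
    "deamination (NH2 -> OH)",
    {"H": -1, "N": -1, "O": 1},
    frozenset({"adb_residue"}),
)

_N_DEALKYLATION = Rule(
    "n_dealkylation",
    "N-dealkylation (-C5H9F)",
    {"C": -5, "H": -9, "F": -1},
    frozenset({"side_chain"}),
    requires_fluorine=True,
    requires_side_chain=True,
    removes_side_chain=True,
)

SCAFFOLDS = ("indazole-ADB", "indole-ADB")


def default_ruleset(
    parent_scaffold: str,
    depth_limit: int = 3,
    enable_deamination: bool | None = None,
    enable_n_dealkylation: bool | None = None,
) -> RuleSet:
    """Default phase-I ruleset for an ADB-type scaffold.

    Deamination is enabled for the indazole scaffold and N-dealkylation
    for the indole scaffold by default (the observed asymmetry); both can
    be toggled on for either scaffold.
    """
    if parent_scaffold not in SCAFFOLDS:
        raise RuleError(
            f"unknown scaffold {parent_scaffold!r}; expected one of {SCAFFOLDS}"
        )
    if enable_deamination is None:
        enable_deamination = parent_scaffold == "indazole-ADB"
    if enable_n_dealkylation is None:
        enable_n_dealkylation = parent_scaffold == "indole-ADB"
    rules = list(_COMMON_RULES)
    if enable_deamination:
        rules.append(_DEAMINATION)
    if enable_n_dealkylation:
        rules.append(_N_DEALKYLATION)
    return RuleSet(rules=tuple(rules), depth_limit=depth_limit)


def load_ruleset(path) -> RuleSet:
    with open(path, "r", encoding="utf-8") as fh:
        return RuleSet.from_yaml(fh.read())


def apply_rule(c: Composition, r: Rule, side_chain_present: bool = True) -> Composition:
    """Apply one rule delta; raises :class:`RuleError` if not applicable."""
    if not r.applicable(c, side_chain_present):
        raise RuleError(f"rule {r.id} not applicable to {c.format() or 'empty'}")
    try:
        return c.add(r.delta)
    except FormulaError as exc:  # pragma: no cover - guarded by applicable()
        raise RuleError(str(exc)) from exc


def _multiset_valid(rules: list[Rule]) -> bool:
    counts = Counter(r.id for r in rules)
    for r in rules:
        if counts[r.id] > r.max_applications:
            return False
    f_rules = sum(n for rid, n in counts.items() if rid in F_CONSUMING)
    if f_rules > 1:
        return False
    # once the side chain is removed, no other side-chain rule may apply;
    # covered by f-rule exclusion for the default set, but kept general:
    if any(r.removes_side_chain for r in rules):
        if any(r.requires_side_chain and not r.removes_side_chain for r in rules):
            return False
    return True


def enumerate_candidates(
    parent: Composition,
    rs: RuleSet,
    parent_id: str = "parent",
) -> list[CandidateMetabolite]:
    """All valid rule multisets of size 1..depth_limit applied to ``parent``.

    Order-independent: one candidate per multiset.  Candidates whose
    cumulative delta would drive any element count negative are dropped.
    """
    out: list[CandidateMetabolite] = []
    pool: list[Rule] = []
    for r in rs.rules:
        pool.extend([r] * min(r.max_applications, rs.depth_limit))
    # combinations over an id-sorted pool yield each multiset exactly once
    pool.sort(key=lambda r: r.id)
    seen: set[tuple[str, ...]] = set()
    for depth in range(1, rs.depth_limit + 1):
        for combo in itertools.combinations(pool, depth):
            applied = tuple(r.id for r in combo)
            if applied in seen:
                continue
            seen.add(applied)
            combo_rules = list(combo)
            if not _multiset_valid(combo_rules):
                continue
            total: dict[str, int] = {}
            for r in combo_rules:
                for e, d in r.delta.items():
                    total[e] = total.get(e, 0) + d
            if not parent.can_add(total):
                continue
            comp = parent.add(total)
            out.append(
                CandidateMetabolite(
                    parent_id=parent_id,
                    applied=applied,
                    composition=comp,
                    theoretical_mz=ion_mz(comp, IonMode.PROTONATED),
                    depth=depth,
                )
            )
    out.sort(key=lambda c: (c.depth, c.applied))
    return out


def dedup_candidates(cands: list[CandidateMetabolite]) -> list[CandidateGroup]:
    """Group candidates by distinct neutral composition.

    Formula-degenerate multisets (e.g. amide hydrolysis vs deamination)
    collapse into one group with both provenances preserved.
    """
    groups: dict[tuple, CandidateGroup] = {}
    for c in cands:
        key = c.composition.counts
        g = groups.get(key)
        if g is None:
            g = CandidateGroup(
                composition=c.composition, theoretical_mz=c.theoretical_mz
            )
            groups[key] = g
        g.provenance.append(c.applied)
    out = list(groups.values())
    for g in out:
        g.provenance.sort()
    out.sort(key=lambda g: g.theoretical_mz)
    return out
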