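"""Family assignment by should / should-not domain rules.

A TAP family is defined by the domains a protein must carry ("should")
and domains that must be absent ("should not"). A forbidden domain
vetoes the family: e.g. a protein with both a bZIP_AUREO and an HLH
hit is not a bZIPAUREO candidate. Vetoes operate on *filtered* hits
only — a sub-threshold occurrence of a forbidden domain does not veto,
because the thresholds define domain presence.

Each protein is assigned to at most one family. When several families
remain candidates, the one whose required domains were matched with
the lowest (strongest) independent per-domain E-value wins; exact ties
fall back to lexicographic family order for determinism. This is how
multi-domain proteins (e.g. HMG_box plus a stronger-scoring PHD) end
up in the family the rule set intends: the competitor family carries
an explicit "HMG_box; should not" veto.

Rule files use semicolon-separated triplets::

    bZIPAUREO; bZIP_AUREO; should
    bZIPAUREO; HLH; should not
    bZIPAUREO; Homeobox; should not
    bZIPAUREO; class; TF        # optional TF/TR/PT class annotation

with '#' comments; whitespace around fields is ignored.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from tapkit.hmmio import DomainHit, ProfileLibrary, filter_hits

__all__ = [
    "FamilyRule",
    "RuleSet",
    "Assignment",
    "load_rules",
    "candidate_families",
    "resolve_assignment",
    "classify_proteome",
    "genome_tap_profile",
    "write_assignments",
]

PathLike = Union[str, Path]

VALID_CLASSES = ("TF", "TR", "PT")


class RuleError(ValueError):
    """Malformed or inconsistent rule definitions."""


@dataclass
class FamilyRule:
    family: str
    should: set[str] = field(default_factory=set)
    should_not: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if not self.should:
            raise RuleError(f"family {self.family!r} has no 'should' domain")
        overlap = self.should & self.should_not
        if overlap:
            raise RuleError(
                f"family {self.family!r} lists {sorted(overlap)} as both should and should not"
            )


@dataclass
class RuleSet:
    """Per-family rules plus optional TF/TR/PT class annotations."""

    rules: dict[str, FamilyRule] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)

    def families(self) -> list[str]:
        return list(self.rules)

    def domains_referenced(self) -> set[str]:
        out: set[str] = set()
        for rule in self.rules.values():
            out |= rule.should | rule.should_not
        return out

    def __len__(self) -> int:
        return len(self.rules)


@dataclass
class Assignment:
    """Outcome of classifying one protein.

    ``family`` is None iff no candidate family survived filtering and
    vetoes. ``vetoed_candidates`` records families whose should-domains
    were all present but that were knocked out by a forbidden domain,
    as (family, forbidden domain) pairs.
    """

    protein_id: str
    family: str | None
    supporting_hits: list[DomainHit] = field(default_factory=list)
    vetoed_candidates: list[tuple[str, str]] = field(default_factory=list)


def load_rules(path: PathLike) -> RuleSet:
    """Load a rule table of semicolon triplets (see module docstring)."""
    ruleset = RuleSet()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(";")]
            if len(parts) != 3:
                raise RuleError(f"{path}:{lineno}: expected 'family; domain; kind'")
            family, middle, kind = parts
            if middle == "class":
                if kind not in VALID_CLASSES:
                    raise RuleError(
                        f"{path}:{lineno}: class must be one of {VALID_CLASSES}, got {kind!r}"
                    )
                ruleset.classification[family] = kind
                continue
            rule = ruleset.rules.setdefault(family, FamilyRule(family))
            if kind == "should":
                rule.should.add(middle)
            elif kind == "should not":
                rule.should_not.add(middle)
            else:
                raise RuleError(
                    f"{path}:{lineno}: unknown rule kind {kind!r} "
                    "(only 'should' and 'should not' are supported)"
                )
    for rule in ruleset.rules.values():
        rule.validate()
    return ruleset


def candidate_families(
    hits_of_protein: Sequence[DomainHit], rules: RuleSet
) -> tuple[list[tuple[str, float]], list[tuple[str, str]]]:
    """Evaluate rules over one protein's filtered hits.

    Returns ``(candidates, vetoed)`` where each candidate is
    ``(family, representative_evalue)`` — the representative E-value
    being the minimum i-Evalue over the family's should-domain hits —
    and ``vetoed`` lists families excluded by a forbidden domain, with
    the offending domain.
    """
    by_domain: dict[str, list[DomainHit]] = defaultdict(list)
    for hit in hits_of_protein:
        by_domain[hit.domain].append(hit)

    candidates: list[tuple[str, float]] = []
    vetoed: list[tuple[str, str]] = []
    for family, rule in rules.rules.items():
        if not all(d in by_domain for d in rule.should):
            continue
        forbidden_present = sorted(d for d in rule.should_not if d in by_domain)
        if forbidden_present:
            vetoed.append((family, forbidden_present[0]))
            continue
        rep = min(h.domain_ievalue for d in rule.should for h in by_domain[d])
        candidates.append((family, rep))
    return candidates, vetoed


def resolve_assignment(candidates: Iterable[tuple[str, float]]) -> str | None:
    """Pick the family with the smallest representative E-value.

    Ties break lexicographically by family name; empty input yields None.
    """
    best: tuple[float, str] | None = None
    for family, evalue in candidates:
        key = (evalue, family)
        if best is None or key < best:
            best = key
    return best[1] if best else None


def classify_proteome(
    hits: Sequence[DomainHit], library: ProfileLibrary, rules: RuleSet
) -> list[Assignment]:
    """Assign every protein occurring in ``hits`` to at most one family.

    Hits are grouped per protein, GA/coverage-filtered, evaluated
    against the rules, and resolved by E-value. Proteins whose hits
    all fall below threshold, or whose every candidate is vetoed, get
    ``family=None``. Deterministic given (hits, library, rules);
    proteins are reported in order of first appearance.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        by_protein.setdefault(hit.protein_id, []).append(hit)

    assignments: list[Assignment] = []
    for protein_id, protein_hits in by_protein.items():
        surviving = filter_hits(protein_hits, library)
        candidates, vetoed = candidate_families(surviving, rules)
        family = resolve_assignment(candidates)
        supporting: list[DomainHit] = []
        if family is not None:
            should = rules.rules[family].should
            supporting = [h for h in surviving if h.domain in should]
        assignments.append(Assignment(protein_id, family, supporting, vetoed))
    return assignments


def genome_tap_profile(assignments: Iterable[Assignment]) -> dict[str, int]:
    """Count assigned proteins per family; unassigned proteins are excluded."""
    counts: dict[str, int] = {}
    for a in assignments:
        if a.family is not None:
            counts[a.family] = counts.get(a.family, 0) + 1
    return counts


def write_assignments(assignments: Iterable[Assignment], rules: RuleSet, path: PathLike) -> None:
    """Write a classification report TSV: protein, family, class, domains, E-values."""
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily\tclass\tsupporting_domains\tievalues\n")
        for a in assignments:
            fam = a.family or "-"
            cls = rules.classification.get(a.family, "-") if a.family else "-"
            doms = ",".join(h.domain for h in a.supporting_hits) or "-"
            evs = ",".join(f"{h.domain_ievalue:.3g}" for h in a.supporting_hits) or "-"
            fh.write(f"{a.protein_id}\t{fam}\t{cls}\t{doms}\t{evs}\n")
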