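"""Synthetic ground-truth fixtures for every pipeline stage.

Two generators, both fully deterministic under an explicit RNG seed:

* :func:`generate_hits` plants TAP family signatures into a synthetic
  domain-hit table. A planted protein carries every required domain of
  its family, above the GA threshold and at full model coverage, with
  strong i-Evalues. Decoy proteins exercise the failure paths and must
  classify to nothing: sub-GA scores, sub-cutoff model coverage, and
  forbidden-domain co-occurrence (veto). The emitted table is a valid
  ``--domtblout`` file; the planted labels are retained as ground truth.

* :func:`generate_history` simulates TAP family-size evolution on a
  random bifurcating species tree in the regime typical of real
  comparative panels: small counts (<= 10 per family) and rare,
  single-unit-to-two-unit change events (gain, loss, expansion,
  contraction), sampled per branch at configurable rates. Tip counts,
  the true per-node labeling and the true event list are all retained,
  so ancestral reconstructions can be scored against the planted
  history.

No sequences are emulated — only hit tables and count matrices, which
is what the downstream code consumes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from tapkit.ancestral import (
    EventSummary,
    SpeciesTree,
    TreeNode,
    WagnerParams,
    classify_branch_events,
    wagner_reconstruct,
)
from tapkit.comparative import CountMatrix, build_count_matrix
from tapkit.hmmio import DomainHit, ProfileLibrary, write_domain_table
from tapkit.rules import RuleSet

__all__ = [
    "PlantedProteome",
    "HistoryRates",
    "PlantedHistory",
    "generate_hits",
    "generate_history",
    "event_recovery_rate",
]

PathLike = Union[str, Path]


@dataclass
class PlantedProteome:
    """Synthetic hit table with per-protein ground-truth labels."""

    truth: dict[str, str | None]  # protein_id -> planted family (None = decoy)
    hits: list[DomainHit]
    decoy_kinds: dict[str, str] = field(default_factory=dict)

    def write_domtblout(self, path: PathLike) -> None:
        write_domain_table(self.hits, path)

    def write_truth(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump({"truth": self.truth, "decoy_kinds": self.decoy_kinds}, fh, indent=1)


def _signal_hit(
    protein: str, domain: str, library: ProfileLibrary, rng: random.Random
) -> DomainHit:
    meta = library[domain]
    assert meta.ga_threshold is not None
    score = meta.ga_threshold + rng.uniform(5.0, 25.0)
    # 3 significant digits: the domtblout writer's printed precision,
    # so fixture hits round-trip exactly through write/parse
    ievalue = float(f"{10 ** rng.uniform(-30.0, -10.0):.3g}")
    return DomainHit(
        protein_id=protein,
        domain=domain,
        full_seq_evalue=ievalue,
        domain_ievalue=ievalue,
        domain_score=round(score, 2),
        hmm_from=1,
        hmm_to=meta.model_length,
        ali_from=1,
        ali_to=meta.model_length,
    )


def _subga_hit(protein: str, domain: str, library: ProfileLibrary, rng: random.Random) -> DomainHit:
    hit = _signal_hit(protein, domain, library, rng)
    meta = library[domain]
    assert meta.ga_threshold is not None
    return DomainHit(
        protein_id=protein,
        domain=domain,
        full_seq_evalue=1.0,
        domain_ievalue=1.0,
        domain_score=round(meta.ga_threshold - rng.uniform(0.5, 5.0), 2),
        hmm_from=hit.hmm_from,
        hmm_to=hit.hmm_to,
        ali_from=hit.ali_from,
        ali_to=hit.ali_to,
    )


def _lowcov_hit(
    protein: str, domain: str, library: ProfileLibrary, rng: random.Random
) -> DomainHit | None:
    """A hit above GA whose model span falls below the coverage cutoff."""
    meta = library[domain]
    if meta.coverage_threshold is None or meta.ga_threshold is None:
        return None
    span = int(meta.model_length * meta.coverage_threshold) - 1
    if span < 1:
        return None
    return DomainHit(
        protein_id=protein,
        domain=domain,
        full_seq_evalue=1e-8,
        domain_ievalue=1e-8,
        domain_score=round(meta.ga_threshold + rng.uniform(5.0, 25.0), 2),
        hmm_from=1,
        hmm_to=span,
        ali_from=1,
        ali_to=span,
    )


def _veto_pairs(rules: RuleSet) -> list[tuple[str, str]]:
    """(family, forbidden domain) pairs usable as veto decoys.

    The forbidden domain must not itself be required by any family,
    so that its presence classifies the protein to nothing rather
    than to a competitor.
    """
    required = set()
    for rule in rules.rules.values():
        required |= rule.should
    pairs = []
    for family, rule in rules.rules.items():
        for dom in sorted(rule.should_not):
            if dom not in required:
                pairs.append((family, dom))
    return pairs


def generate_hits(
    n_proteins: int,
    rules: RuleSet,
    library: ProfileLibrary,
    decoy_rate: float,
    rng_seed: int,
) -> PlantedProteome:
    """Plant family signatures (and decoys) into a synthetic hit table.

    Each protein is either planted with a family drawn uniformly from
    the rule set, or (with probability ``decoy_rate``) a decoy cycling
    through three flavours: sub-GA score, sub-cutoff coverage, and
    forbidden-domain veto. Assumes each family requires at least one
    domain unique to it (true of the bundled catalogue), which makes
    every planted signature unambiguous.
    """
    if not rules.rules:
        raise ValueError("rule set is empty")
    rng = random.Random(rng_seed)
    families = sorted(rules.rules)
    veto_pairs = _veto_pairs(rules)
    covdomains = [
        d
        for d, m in library.profiles.items()
        if m.coverage_threshold is not None and int(m.model_length * m.coverage_threshold) > 1
    ]

    truth: dict[str, str | None] = {}
    decoy_kinds: dict[str, str] = {}
    hits: list[DomainHit] = []
    decoy_cycle = 0
    for i in range(n_proteins):
        protein = f"p{i:05d}"
        if rng.random() < decoy_rate:
            truth[protein] = None
            flavours = ["subga"]
            if covdomains:
                flavours.append("lowcov")
            if veto_pairs:
                flavours.append("veto")
            kind = flavours[decoy_cycle % len(flavours)]
            decoy_cycle += 1
            decoy_kinds[protein] = kind
            if kind == "subga":
                family = rng.choice(families)
                for dom in sorted(rules.rules[family].should):
                    hits.append(_subga_hit(protein, dom, library, rng))
            elif kind == "lowcov":
                dom = rng.choice(covdomains)
                hit = _lowcov_hit(protein, dom, library, rng)
                assert hit is not None
                hits.append(hit)
            else:  # veto
                family, forbidden = veto_pairs[rng.randrange(len(veto_pairs))]
                for dom in sorted(rules.rules[family].should):
                    hits.append(_signal_hit(protein, dom, library, rng))
                hits.append(_signal_hit(protein, forbidden, library, rng))
        else:
            family = rng.choice(families)
            truth[protein] = family
            for dom in sorted(rules.rules[family].should):
                hits.append(_signal_hit(protein, dom, library, rng))
    return PlantedProteome(truth=truth, hits=hits, decoy_kinds=decoy_kinds)


@dataclass
class HistoryRates:
    """Per-branch event probabilities for the history simulator."""

    p_gain: float = 0.05
    p_loss: float = 0.05
    p_shift: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_gain", "p_loss", "p_shift"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class PlantedHistory:
    """Simulated family-size history with full ground truth."""

    tree: SpeciesTree
    newick: str
    root_counts: dict[str, int]
    node_counts: dict[str, dict[str, int]]  # family -> node id -> count
    events: list[tuple[str, str, str]]  # (family, child node id, event type)
    matrix: CountMatrix


def _random_bifurcating_tree(n_leaves: int, rng: random.Random) -> SpeciesTree:
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    nodes = [TreeNode(id=f"SP{i:03d}", label=f"SP{i:03d}", length=1.0) for i in range(n_leaves)]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(TreeNode(id=f"N{counter}", length=1.0, children=[left, right]))
        counter += 1
    root = nodes[0]
    root.length = None
    return SpeciesTree(root=root)


def _to_newick(node: TreeNode) -> str:
    if node.is_leaf:
        core = node.label or node.id
    else:
        core = "(" + ",".join(_to_newick(c) for c in node.children) + ")"
    if node.length is not None:
        core += f":{node.length:g}"
    return core


MAX_TIP_COUNT = 10  # mirrors the small family sizes of real TAP panels


def generate_history(
    n_leaves: int,
    n_families: int,
    rates: HistoryRates,
    rng_seed: int,
    max_events_per_family: int | None = 1,
) -> PlantedHistory:
    """Simulate family counts down a random bifurcating tree.

    Root counts are drawn uniformly from 0..3. An event changes the
    count along a branch: gain to 1-2 from zero (``p_gain``), loss to
    zero (``p_loss``), or a +/-1..2 shift between nonzero counts
    (``p_shift``). With ``max_events_per_family`` set (default 1, the
    rare-event regime in which parsimony reconstruction is expected to
    recover the planted history), that many candidate branches are
    drawn uniformly over the tree per family and only they may host an
    event; with ``None``, every branch samples an event independently.
    Uniform candidate placement avoids biasing events toward
    root-adjacent branches, which a sequential capped walk would.
    """
    rng = random.Random(rng_seed)
    tree = _random_bifurcating_tree(n_leaves, rng)
    families = [f"FAM{i:04d}" for i in range(n_families)]
    root_counts: dict[str, int] = {}
    node_counts: dict[str, dict[str, int]] = {}
    events: list[tuple[str, str, str]] = []

    parent_of = tree.parent_map()
    order = tree.preorder()
    branch_ids = [n.id for n in order if n.id != tree.root.id]
    for fam in families:
        root_count = rng.randint(0, 3)
        root_counts[fam] = root_count
        counts: dict[str, int] = {tree.root.id: root_count}
        if max_events_per_family is None:
            candidates = None
        else:
            k = min(max_events_per_family, len(branch_ids))
            candidates = set(rng.sample(branch_ids, k))
        for node in order:
            if node.id == tree.root.id:
                continue
            s = counts[parent_of[node.id]]
            t = s
            if candidates is None or node.id in candidates:
                u = rng.random()
                if s == 0:
                    if u < rates.p_gain:
                        t = rng.randint(1, 2)
                        events.append((fam, node.id, "gain"))
                else:
                    if u < rates.p_loss:
                        t = 0
                        events.append((fam, node.id, "loss"))
                    elif u < rates.p_loss + rates.p_shift:
                        if s == 1 or rng.random() < 0.5:
                            t = min(s + rng.randint(1, 2), MAX_TIP_COUNT)
                            label = "expansion"
                        else:
                            t = max(s - rng.randint(1, 2), 1)
                            label = "contraction"
                        if t != s:
                            events.append((fam, node.id, label))
            counts[node.id] = t
        node_counts[fam] = counts

    profiles = {
        leaf.label: {fam: node_counts[fam][leaf.id] for fam in families}
        for leaf in tree.leaves()
    }
    matrix = build_count_matrix(profiles, family_universe=families)
    return PlantedHistory(
        tree=tree,
        newick=_to_newick(tree.root) + ";",
        root_counts=root_counts,
        node_counts=node_counts,
        events=events,
        matrix=matrix,
    )


def event_recovery_rate(history: PlantedHistory, params: WagnerParams | None = None) -> float:
    """Fraction of planted events recovered by parsimony reconstruction.

    An event counts as recovered when the reconstruction labels the
    same branch of the same family with the same event type. Histories
    with no planted events score 1.0.
    """
    if params is None:
        params = WagnerParams()
    if not history.events:
        return 1.0
    recovered = 0
    summaries: dict[str, EventSummary] = {}
    for fam in history.matrix.families:
        leaf_counts = {
            sp: int(history.matrix.data.loc[fam, sp]) for sp in history.matrix.species
        }
        profile = wagner_reconstruct(history.tree, leaf_counts, params, family=fam)
        summaries[fam] = classify_branch_events(history.tree, profile)
    for fam, child_id, etype in history.events:
        if summaries[fam].events.get(child_id) == etype:
            recovered += 1
    return recovered / len(history.events)
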