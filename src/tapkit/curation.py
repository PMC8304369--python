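"""Taxonomic rebalancing of profile seed alignments.

Most public seed alignments are biased towards animal and seed-plant
model organisms, which depresses profile sensitivity for algae. The
remedy is to add algal sequences — from red algae, brown algae, the
SAR group, and streptophyte algae — to a profile's seed alignment
before rebuilding the HMM. This module implements the *selection*
step: given a pool of candidate sequences annotated with taxon group,
species and a completeness flag, it picks an augmentation set that

* never exceeds 25% of the original seed-alignment size (floor),
* drops incomplete sequences first,
* spreads picks across all taxon groups and across as many species
  as possible (round-robin over groups, then species within group),
* and breaks the final equal-priority overflow uniformly at random,
  reproducibly from an explicit RNG seed.

Running the aligner (``mafft --add``) and ``hmmbuild`` on the result
is left to those external tools; this module emits the FASTA hand-off
and a plan manifest.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

__all__ = [
    "SeedAlignment",
    "Candidate",
    "CandidatePool",
    "AugmentationPlan",
    "compute_cap",
    "select_augmentation",
    "read_seed_alignment",
    "read_candidate_pool",
    "write_plan_manifest",
]

PathLike = Union[str, Path]

TAXON_GROUPS = ("red algae", "brown algae", "SAR", "streptophyte algae")


@dataclass
class SeedAlignment:
    """An aligned set of seed sequences for one domain profile."""

    domain: str
    sequences: list[tuple[str, str]]  # (id, aligned residues)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"seed alignment {self.domain!r} rows differ in length")

    @property
    def seed_size(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class Candidate:
    seq_id: str
    species: str
    group: str
    complete: bool


@dataclass
class CandidatePool:
    candidates: list[Candidate] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.candidates:
            if not c.group:
                raise ValueError(f"candidate {c.seq_id!r} has no taxon group")


@dataclass
class AugmentationPlan:
    """Selected sequence ids plus the provenance needed to reproduce them."""

    selected: list[str]
    cap: int
    rng_seed: int
    tiers: dict[str, int] = field(default_factory=dict)  # seq_id -> priority tier

    def __post_init__(self) -> None:
        if len(self.selected) > self.cap:
            raise ValueError("selection exceeds cap")


def compute_cap(seed_size: int) -> int:
    """Maximum number of new sequences: floor of 25% of the seed size."""
    if seed_size < 1:
        raise ValueError("seed_size must be >= 1")
    return math.floor(0.25 * seed_size)


def _tiered(pool: CandidatePool) -> list[list[Candidate]]:
    """Order complete candidates into priority tiers.

    Within each group, candidates are interleaved across species
    (first candidate of each species, then second of each, ...), in
    order of first appearance. Tier k then holds the k-th entry of
    every group's interleaved list, so early tiers maximise group and
    species breadth.
    """
    complete = [c for c in pool.candidates if c.complete]
    group_order: list[str] = []
    by_group_species: dict[str, dict[str, list[Candidate]]] = {}
    for c in complete:
        if c.group not in by_group_species:
            by_group_species[c.group] = {}
            group_order.append(c.group)
        by_group_species[c.group].setdefault(c.species, []).append(c)

    group_lists: dict[str, list[Candidate]] = {}
    for group in group_order:
        species_lists = list(by_group_species[group].values())
        interleaved: list[Candidate] = []
        depth = 0
        while True:
            layer = [lst[depth] for lst in species_lists if depth < len(lst)]
            if not layer:
                break
            interleaved.extend(layer)
            depth += 1
        group_lists[group] = interleaved

    tiers: list[list[Candidate]] = []
    depth = 0
    while True:
        tier = [group_lists[g][depth] for g in group_order if depth < len(group_lists[g])]
        if not tier:
            break
        tiers.append(tier)
        depth += 1
    return tiers


def select_augmentation(pool: CandidatePool, cap: int, rng_seed: int) -> AugmentationPlan:
    """Pick up to ``cap`` complete candidates, breadth-first over groups and species.

    Whole priority tiers are taken while they fit; the tier that would
    overflow the cap is thinned by uniform random elimination driven by
    ``rng_seed``. Deterministic given (pool order, cap, seed).
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    selected: list[Candidate] = []
    tier_of: dict[str, int] = {}
    rng = random.Random(rng_seed)
    for k, tier in enumerate(_tiered(pool)):
        room = cap - len(selected)
        if room <= 0:
            break
        if len(tier) <= room:
            take = tier
        else:
            # uniform elimination within the boundary tier; keep tier order
            idx = sorted(rng.sample(range(len(tier)), room))
            take = [tier[i] for i in idx]
        for c in take:
            tier_of[c.seq_id] = k
        selected.extend(take)
    return AugmentationPlan(
        selected=[c.seq_id for c in selected], cap=cap, rng_seed=rng_seed, tiers=tier_of
    )


def read_seed_alignment(path: PathLike, domain: str, fmt: str = "fasta") -> SeedAlignment:
    """Read a seed alignment (FASTA or Stockholm) via Biopython."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), fmt)]
    return SeedAlignment(domain=domain, sequences=records)


def read_candidate_pool(manifest: PathLike) -> CandidatePool:
    """Read a candidate manifest TSV: seq_id, species, group, complete(0/1)."""
    candidates: list[Candidate] = []
    with open(manifest) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{manifest}:{lineno}: expected 4 tab-separated fields")
            candidates.append(
                Candidate(fields[0], fields[1], fields[2], fields[3].strip() in ("1", "true", "yes"))
            )
    return CandidatePool(candidates)


def write_plan_manifest(
    plan: AugmentationPlan, pool: CandidatePool, path: PathLike
) -> None:
    by_id = {c.seq_id: c for c in pool.candidates}
    with open(path, "w") as fh:
        fh.write("seq_id\tspecies\tgroup\ttier\n")
        for sid in plan.selected:
            c = by_id[sid]
            fh.write(f"{sid}\t{c.species}\t{c.group}\t{plan.tiers[sid]}\n")


def write_handoff_fasta(
    plan: AugmentationPlan, sequences: dict[str, str], path: PathLike
) -> None:
    """Write the selected (unaligned) sequences for an external ``mafft --add`` run."""
    with open(path, "w") as fh:
        for sid in plan.selected:
            fh.write(f">{sid}\n{sequences[sid]}\n")
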