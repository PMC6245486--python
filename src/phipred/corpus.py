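"""Build the labelled pair corpus.

Positives are balanced across bacterial families by replication
(oversampling): each family's interactions are replicated
``round(target / n)`` times so every family is represented around the
target count, except families containing an exempt (dominant) species,
which are kept as-is.

Putative negatives are phage-bacterium pairs that (1) do not appear in the
positive set and (2) mismatch the phage's known host species. They are
drawn per bacterial species so each species has as many negatives as it
has (oversampled) positives.

The stratified train/test split keeps all replicates of a distinct
(phage, bacterium) pair in the same split, so the held-out set is free of
replicate leakage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import NEGATIVE, POSITIVE, InteractionRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FamilyGroup:
    """Positive interactions of one bacterial family."""

    family: str
    records: list[InteractionRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"family group {self.family!r} is empty")
        for r in self.records:
            if r.family != self.family:
                raise ValueError(
                    f"record {r.pair} has family {r.family!r}, expected "
                    f"{self.family!r}"
                )

    @property
    def n(self) -> int:
        return len(self.records)


@dataclass
class CorpusConfig:
    target_per_family: int = 300
    exempt_species: frozenset[str] = frozenset()
    test_fraction: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_per_family < 1:
            raise ValueError("target_per_family must be >= 1")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in [0, 1)")
        self.exempt_species = frozenset(self.exempt_species)


@dataclass
class BacteriumInfo:
    """Identity and taxonomy of one bacterium, for negative generation."""

    bacterium_id: str
    species: str
    family: str


@dataclass
class Corpus:
    train: list[InteractionRecord]
    test: list[InteractionRecord]

    def validate(self) -> None:
        """Assert the split-level invariants (no pair leakage, balance)."""
        train_pairs = {r.pair for r in self.train}
        test_pairs = {r.pair for r in self.test}
        overlap = train_pairs & test_pairs
        if overlap:
            raise AssertionError(f"pairs present in both splits: {overlap}")
        for name, split in (("train", self.train), ("test", self.test)):
            pos = sum(1 for r in split if r.label == POSITIVE)
            neg = len(split) - pos
            if pos != neg:
                logger.warning(
                    "%s split unbalanced: %d positives vs %d negatives",
                    name, pos, neg,
                )


# ---------------------------------------------------------------------------
# oversampling
# ---------------------------------------------------------------------------

def group_by_family(positives: Sequence[InteractionRecord]) -> list[FamilyGroup]:
    """One group per distinct family, in order of first appearance."""
    by_family: dict[str, list[InteractionRecord]] = {}
    for r in positives:
        if not r.family:
            raise ValueError(f"positive pair {r.pair} lacks a family")
        by_family.setdefault(r.family, []).append(r)
    return [FamilyGroup(fam, recs) for fam, recs in by_family.items()]


def replication_factor(n: int, target: int) -> int:
    """How many times each record of an n-interaction family is replicated.

    ``max(1, round(target / n))`` with half-away-from-zero rounding, so a
    4-interaction family at target 300 replicates 75 times and families
    already above target are never down-sampled.
    """
    if n < 1:
        raise ValueError("family size must be >= 1")
    if target < 1:
        raise ValueError("target must be >= 1")
    return max(1, math.floor(target / n + 0.5))


def oversample_positives(
    groups: Sequence[FamilyGroup], config: CorpusConfig
) -> list[InteractionRecord]:
    """Replicate each family's records to reach ~target_per_family.

    Families containing an exempt species appear once. Output order is
    deterministic: by family, then record, then replicate index.
    """
    if not groups:
        raise ValueError("no family groups to oversample")
    out: list[InteractionRecord] = []
    for g in groups:
        exempt = any(r.species in config.exempt_species for r in g.records)
        r = 1 if exempt else replication_factor(g.n, config.target_per_family)
        for rec in g.records:
            out.extend([rec] * r)
    return out


# ---------------------------------------------------------------------------
# negative generation
# ---------------------------------------------------------------------------

def generate_negatives(
    positives: Sequence[InteractionRecord],
    phage_hosts: Mapping[str, str],
    bacteria: Sequence[BacteriumInfo],
    config: CorpusConfig,
) -> list[InteractionRecord]:
    """Draw putative negatives matching per-species positive counts.

    The candidate pool holds every (phage, bacterium) pair that is absent
    from the positives and whose bacterium species differs from the phage's
    known host species. Per bacterial species, as many negatives are drawn
    as that species has (oversampled) positives -- without replacement
    while the pool lasts, then with replacement.
    """
    positive_pairs = {r.pair for r in positives}
    missing_hosts = {r.phage_id for r in positives} - set(phage_hosts)
    if missing_hosts:
        raise ValueError(f"phages without a known host species: {sorted(missing_hosts)}")

    counts: dict[str, int] = {}
    for r in positives:
        counts[r.species] = counts.get(r.species, 0) + 1

    phage_ids = list(dict.fromkeys(phage_hosts))
    by_species: dict[str, list[BacteriumInfo]] = {}
    for b in bacteria:
        by_species.setdefault(b.species, []).append(b)

    rng = np.random.default_rng(config.rng_seed)
    negatives: list[InteractionRecord] = []
    for species, need in counts.items():
        pool = [
            (p, b)
            for p in phage_ids
            for b in by_species.get(species, [])
            if (p, b.bacterium_id) not in positive_pairs
            and phage_hosts[p] != species
        ]
        if not pool:
            raise ValueError(
                f"no negative candidates available for species {species!r}"
            )
        order = rng.permutation(len(pool))
        chosen = [pool[i] for i in order[: min(need, len(pool))]]
        if need > len(pool):
            extra = rng.integers(0, len(pool), size=need - len(pool))
            chosen.extend(pool[i] for i in extra)
        for phage_id, bact in chosen:
            negatives.append(
                InteractionRecord(
                    phage_id=phage_id,
                    bacterium_id=bact.bacterium_id,
                    species=bact.species,
                    family=bact.family,
                    label=NEGATIVE,
                )
            )
    return negatives


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def _select_test_groups(
    records: Sequence[InteractionRecord],
    target: int,
    rng: np.random.Generator,
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Greedily move whole pair-groups to test until ~target records.

    All replicates of a (phage, bacterium) pair travel together, so a group
    is only taken if it fits under the target.
    """
    groups: dict[tuple[str, str], list[InteractionRecord]] = {}
    for r in records:
        groups.setdefault(r.pair, []).append(r)
    keys = list(groups)
    order = rng.permutation(len(keys))
    test: list[InteractionRecord] = []
    test_keys: set[tuple[str, str]] = set()
    taken = 0
    for i in order:
        g = groups[keys[i]]
        if taken + len(g) <= target:
            test.extend(g)
            test_keys.add(keys[i])
            taken += len(g)
        if taken == target:
            break
    train = [r for r in records if r.pair not in test_keys]
    return train, test


def stratified_split(
    pairs: Sequence[InteractionRecord], config: CorpusConfig
) -> Corpus:
    """Split per (family, label) stratum, keeping replicates together.

    Within each family the negative stratum's test count targets the count
    achieved by the positive stratum, so the splits stay label-balanced
    whenever the pool granularity allows.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 1)))
    families = list(dict.fromkeys(r.family for r in pairs))
    train: list[InteractionRecord] = []
    test: list[InteractionRecord] = []
    for fam in families:
        pos = [r for r in pairs if r.family == fam and r.label == POSITIVE]
        neg = [r for r in pairs if r.family == fam and r.label == NEGATIVE]
        t_pos = 0
        for stratum, is_pos in ((pos, True), (neg, False)):
            if not stratum:
                continue
            if len(stratum) < 2:
                logger.warning(
                    "stratum (%s, %s) has %d record(s); kept in train",
                    fam, POSITIVE if is_pos else NEGATIVE, len(stratum),
                )
                train.extend(stratum)
                continue
            if is_pos or not pos:
                target = _round_half_up(config.test_fraction * len(stratum))
            else:
                target = t_pos
            tr, te = _select_test_groups(stratum, target, rng)
            if is_pos:
                t_pos = len(te)
            train.extend(tr)
            test.extend(te)
    corpus = Corpus(train=train, test=test)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def build_corpus(
    positives: Sequence[InteractionRecord],
    phage_hosts: Mapping[str, str],
    bacteria: Sequence[BacteriumInfo],
    config: CorpusConfig,
) -> Corpus:
    """Oversample positives, draw negatives, and split into train/test."""
    groups = group_by_family(positives)
    oversampled = oversample_positives(groups, config)
    negatives = generate_negatives(oversampled, phage_hosts, bacteria, config)
    return stratified_split(list(oversampled) + negatives, config)


def dominant_species(positives: Sequence[InteractionRecord]) -> str:
    """The species carrying the most positive interactions."""
    counts: dict[str, int] = {}
    for r in positives:
        counts[r.species] = counts.get(r.species, 0) + 1
    if not counts:
        raise ValueError("no positives given")
    return max(counts, key=lambda s: counts[s])
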