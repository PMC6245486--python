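"""Fully synthetic corpora with a tunable planted interaction signal.

The generator emulates every input the pipeline consumes: random
proteomes, a domain vocabulary with per-protein annotations, a DDI score
table, and a positive pair list with a skewed family structure (one
dominant host species absorbing most positives, ~19 families of ~2
bacteria each).

The planted signal mimics receptor-binding: every bacterial species
carries a species-specific receptor domain on one of its proteins, and
with probability ``signal_strength`` a phage carries the matching
receptor-binding-protein (RBP) domain for its host's receptor. Matching
(RBP, receptor) pairs score high in the DDI table (above every background
score), so true pairs — and only true pairs — contain one high-scoring PPI.
A ground-truth log records which positives carry the planted domains.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from . import features_chem, features_ddi
from .corpus import BacteriumInfo, Corpus, CorpusConfig, build_corpus
from .features_chem import AA_ORDER, build_chem_dataset
from .features_ddi import CHEMICAL, DatasetConfig, build_ddi_dataset
from .io_formats import (
    BACTERIUM,
    PHAGE,
    DDITable,
    DomainAnnotation,
    InteractionRecord,
    ProteinRecord,
    Proteome,
    annotations_by_protein,
    matrix_to_xy,
    read_ddi_table,
    read_domain_hits,
    read_interaction_table,
    read_protein_fasta,
    write_ddi_table,
    write_domain_hits,
    write_interaction_table,
    write_protein_fasta,
)
from .modeling import EvalReport, cross_validate

#: background DDI scores are drawn from (BACKGROUND_SCORE_MIN, BACKGROUND_SCORE_MAX)
BACKGROUND_SCORE_MIN = 0.01
BACKGROUND_SCORE_MAX = 0.30
#: planted receptor/RBP scores are drawn from (PLANTED_SCORE_MIN, PLANTED_SCORE_MAX)
PLANTED_SCORE_MIN = 0.70
PLANTED_SCORE_MAX = 1.00


@dataclass
class SynthConfig:
    """Knobs for the synthetic corpus generator.

    Defaults mirror the skew of the real corpus (19 families, ~2 bacteria
    per family, one species absorbing 86% of positives) at scaled-down
    proteome sizes (10 x 50 protein grid instead of the real-data average
    of 74 x 3417).
    """

    n_families: int = 19
    bacteria_per_family: int = 2
    n_phages: int = 100
    dominant_species_fraction: float = 0.86
    proteins_per_bacterium: int = 50
    proteins_per_phage: int = 10
    protein_length_range: tuple[int, int] = (60, 150)
    domain_vocab_size: int = 100
    domains_per_protein_range: tuple[int, int] = (1, 3)
    n_receptor_pairs: int | None = None  # default: one per bacterium
    signal_strength: float = 1.0
    background_ddi_density: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "bacteria_per_family", "n_phages",
                     "proteins_per_bacterium", "proteins_per_phage",
                     "domain_vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("dominant_species_fraction", "signal_strength",
                     "background_ddi_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_receptor_pairs is None:
            self.n_receptor_pairs = self.n_bacteria
        if self.n_receptor_pairs < 1:
            raise ValueError("n_receptor_pairs must be >= 1")
        if self.n_bacteria < 2 and self.dominant_species_fraction < 1.0:
            raise ValueError(
                "dominant_species_fraction < 1 needs at least two bacteria "
                "to host the remaining positives"
            )
        for rng_field in ("protein_length_range", "domains_per_protein_range"):
            lo, hi = getattr(self, rng_field)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid {rng_field} ({lo}, {hi})")

    @property
    def n_bacteria(self) -> int:
        return self.n_families * self.bacteria_per_family


@dataclass
class SynthCorpusBundle:
    """Everything the pipeline needs, plus the ground-truth signal log."""

    config: SynthConfig
    proteomes: dict[str, Proteome]
    annotations: dict[str, list[str]]  # protein_id -> accessions
    ddi_table: DDITable
    positives: list[InteractionRecord]
    signal_log: list[dict]  # one entry per positive: planted flag + domains

    def phage_hosts(self) -> dict[str, str]:
        """Host species per phage, derived from the positive pairs."""
        hosts: dict[str, str] = {}
        for r in self.positives:
            hosts.setdefault(r.phage_id, r.species)
        return hosts

    def bacteria_info(self) -> list[BacteriumInfo]:
        return [
            BacteriumInfo(p.organism_id, self._species[p.organism_id],
                          self._families[p.organism_id])
            for p in self.proteomes.values() if p.kind == BACTERIUM
        ]

    def __post_init__(self) -> None:
        self._species = {}
        self._families = {}
        for r in self.positives:
            if (r.phage_id not in self.proteomes
                    or r.bacterium_id not in self.proteomes):
                raise ValueError(f"positive pair {r.pair} references a missing proteome")
            self._species[r.bacterium_id] = r.species
            self._families[r.bacterium_id] = r.family
        # bacteria never appearing in a positive still need taxonomy labels
        for org, prot in self.proteomes.items():
            if prot.kind == BACTERIUM and org not in self._species:
                idx = int(org.lstrip("B"))
                self._species[org] = _species_name(idx)
                self._families[org] = _family_name(idx // self.config.bacteria_per_family)
        if len(self.signal_log) != len(self.positives):
            raise ValueError("signal log must cover every positive pair")

    def dominant_species(self) -> str:
        from .corpus import dominant_species

        return dominant_species(self.positives)


def _species_name(i: int) -> str:
    return f"species{i:03d}"


def _family_name(i: int) -> str:
    return f"family{i:02d}"


def _random_sequence(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AA_ORDER[i] for i in rng.integers(0, len(AA_ORDER), size=length))


def generate(config: SynthConfig) -> SynthCorpusBundle:
    """Generate a full synthetic bundle; all randomness from rng_seed."""
    rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.protein_length_range
    d_lo, d_hi = config.domains_per_protein_range
    vocab = [f"BG{i:04d}" for i in range(config.domain_vocab_size)]

    proteomes: dict[str, Proteome] = {}
    annotations: dict[str, list[str]] = {}

    def make_proteome(org_id: str, kind: str, n_proteins: int) -> Proteome:
        proteins = []
        for j in range(n_proteins):
            pid = f"{org_id}_p{j:03d}"
            proteins.append(ProteinRecord(pid, org_id, _random_sequence(rng, lo, hi)))
            k = int(rng.integers(d_lo, d_hi + 1))
            annotations[pid] = [vocab[i] for i in rng.integers(0, len(vocab), size=k)]
        return Proteome(org_id, kind, proteins)

    # bacteria: one species each, families of bacteria_per_family
    bacteria_ids = [f"B{i:04d}" for i in range(config.n_bacteria)]
    for i, bid in enumerate(bacteria_ids):
        proteomes[bid] = make_proteome(bid, BACTERIUM, config.proteins_per_bacterium)
    phage_ids = [f"P{i:04d}" for i in range(config.n_phages)]
    for pid in phage_ids:
        proteomes[pid] = make_proteome(pid, PHAGE, config.proteins_per_phage)

    # species-specific receptor domain, planted on one protein per bacterium
    receptor_of = {
        bid: i % config.n_receptor_pairs for i, bid in enumerate(bacteria_ids)
    }
    for bid in bacteria_ids:
        target = f"{bid}_p{int(rng.integers(0, config.proteins_per_bacterium)):03d}"
        annotations[target].append(f"REC{receptor_of[bid]:04d}")

    # host assignment: the dominant bacterium absorbs its share of phages
    n_dominant = round(config.dominant_species_fraction * config.n_phages)
    n_dominant = min(n_dominant, config.n_phages)
    host_idx = np.concatenate([
        np.zeros(n_dominant, dtype=int),
        rng.integers(1, config.n_bacteria, size=config.n_phages - n_dominant)
        if config.n_phages > n_dominant else np.array([], dtype=int),
    ])

    positives: list[InteractionRecord] = []
    signal_log: list[dict] = []
    for pid, bi in zip(phage_ids, host_idx):
        bid = bacteria_ids[bi]
        rec = InteractionRecord(
            phage_id=pid,
            bacterium_id=bid,
            species=_species_name(bi),
            family=_family_name(bi // config.bacteria_per_family),
        )
        positives.append(rec)
        planted = bool(rng.random() < config.signal_strength)
        k = receptor_of[bid]
        if planted:
            target = f"{pid}_p{int(rng.integers(0, config.proteins_per_phage)):03d}"
            annotations[target].append(f"RBP{k:04d}")
        signal_log.append({
            "phage_id": pid,
            "bacterium_id": bid,
            "planted": planted,
            "rbp_domain": f"RBP{k:04d}" if planted else None,
            "receptor_domain": f"REC{k:04d}",
        })

    # DDI table: low-scoring background pairs + high-scoring receptor pairs
    table = DDITable()
    all_pairs = [
        (vocab[i], vocab[j])
        for i in range(len(vocab))
        for j in range(i + 1, len(vocab))
    ]
    n_background = round(config.background_ddi_density * len(all_pairs))
    chosen = rng.choice(len(all_pairs), size=n_background, replace=False)
    bg_scores = rng.uniform(BACKGROUND_SCORE_MIN, BACKGROUND_SCORE_MAX,
                            size=n_background)
    for idx, score in zip(chosen, bg_scores):
        a, b = all_pairs[idx]
        table.add(a, b, float(score))
    planted_scores = rng.uniform(PLANTED_SCORE_MIN, PLANTED_SCORE_MAX,
                                 size=config.n_receptor_pairs)
    for k in range(config.n_receptor_pairs):
        table.add(f"RBP{k:04d}", f"REC{k:04d}", float(planted_scores[k]))

    return SynthCorpusBundle(
        config=config,
        proteomes=proteomes,
        annotations=annotations,
        ddi_table=table,
        positives=positives,
        signal_log=signal_log,
    )


# ---------------------------------------------------------------------------
# file emission (the exact io_formats file set)
# ---------------------------------------------------------------------------

def write_bundle(bundle: SynthCorpusBundle, out_dir: str | Path,
                 force: bool = False) -> None:
    """Emit the bundle as production input files.

    Layout: ``proteomes/<organism_id>.fasta``, ``domain_hits.tsv``,
    ``ddi.tsv``, ``pairs.tsv`` and the ground-truth ``signal_log.json``.
    Deterministic ordering, so equal bundles write byte-identical trees.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"{out_dir} exists and is not empty")
        shutil.rmtree(out_dir)
    (out_dir / "proteomes").mkdir(parents=True, exist_ok=True)

    for org_id in sorted(bundle.proteomes):
        write_protein_fasta(
            bundle.proteomes[org_id], out_dir / "proteomes" / f"{org_id}.fasta"
        )
    hits = [
        DomainAnnotation(p.protein_id, acc)
        for org_id in sorted(bundle.proteomes)
        for p in bundle.proteomes[org_id].proteins
        for acc in bundle.annotations.get(p.protein_id, ())
    ]
    write_domain_hits(hits, out_dir / "domain_hits.tsv")
    write_ddi_table(bundle.ddi_table, out_dir / "ddi.tsv")
    write_interaction_table(bundle.positives, out_dir / "pairs.tsv")
    with (out_dir / "signal_log.json").open("w") as fh:
        json.dump(bundle.signal_log, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_bundle(bundle_dir: str | Path) -> tuple[
    dict[str, Proteome], dict[str, list[str]], DDITable, list[InteractionRecord]
]:
    """Read back the files written by :func:`write_bundle`."""
    bundle_dir = Path(bundle_dir)
    positives = read_interaction_table(bundle_dir / "pairs.tsv")
    phage_ids = {r.phage_id for r in positives}
    proteomes = {}
    for fasta in sorted((bundle_dir / "proteomes").glob("*.fasta")):
        org_id = fasta.stem
        kind = PHAGE if org_id in phage_ids else BACTERIUM
        proteomes[org_id] = read_protein_fasta(fasta, org_id, kind)
    hits = read_domain_hits(bundle_dir / "domain_hits.tsv", dialect="tsv")
    table = read_ddi_table(bundle_dir / "ddi.tsv")
    return proteomes, annotations_by_protein(hits), table, positives


# ---------------------------------------------------------------------------
# end-to-end signal recovery
# ---------------------------------------------------------------------------

def signal_recovery_experiment(
    config: SynthConfig,
    dataset_config: DatasetConfig,
    method: str = "rf",
    params: Mapping | None = None,
    folds: int = 10,
    seed: int = 0,
    corpus_config: CorpusConfig | None = None,
) -> EvalReport:
    """Generate -> corpus build -> featurize -> cross-validate, end to end.

    Folding is group-aware (all replicates of a distinct pair share a
    fold), so under the null (signal_strength 0) accuracy sits at chance
    instead of being inflated by replicate memorization.
    """
    bundle = generate(replace(config, rng_seed=seed))
    ccfg = corpus_config or CorpusConfig(
        target_per_family=10, test_fraction=0.0, rng_seed=seed
    )
    corpus = build_corpus(
        bundle.positives, bundle.phage_hosts(), bundle.bacteria_info(), ccfg
    )
    if dataset_config.featurizer == CHEMICAL:
        train_rows, _, _ = build_chem_dataset(corpus, bundle.proteomes)
    else:
        train_rows, _, _ = build_ddi_dataset(
            corpus, bundle.proteomes, bundle.annotations,
            bundle.ddi_table, dataset_config,
        )
    X, y, pair_ids = matrix_to_xy(train_rows)
    return cross_validate(
        X, y, method, params or {"n_trees": 100, "leaf_size": 2},
        folds=folds, seed=seed, groups=pair_ids,
        dataset_name=dataset_config.name,
    )
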