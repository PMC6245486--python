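"""PPI score vectors from domain-domain interaction tables, and their
histogram featurizations.

A protein-protein interaction (PPI) is any pairing of one phage protein
with one bacterium protein; its score is the sum of the DDI-table scores
over all ordered (phage domain, bacterium domain) pairs, counting domain
multiplicity. A phage-bacterium pair therefore yields one score per cell
of the n_phage x n_bact protein grid. Because that grid size varies across
pairs, score vectors are reduced to fixed-length histograms:

* ``fixed_number``: N equal-width bins spanning the pair's own
  [0, max score] range ([0, 1] when all scores are zero);
* ``fixed_size``: bins of width w spanning [0, upper_bound) plus one
  overflow bin. The upper bound is global; when not set explicitly it is
  taken as the maximum PPI score over the training split and recorded in
  the dataset manifest so test rows use the same bound.

Counts are optionally normalized to frequencies.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus
from .io_formats import DDITable, FeatureRow, InteractionRecord, Proteome

FIXED_NUMBER = "fixed_number"
FIXED_SIZE = "fixed_size"


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class HistogramConfig:
    """How a PPI score vector is binned into a fixed-length histogram."""

    mode: str  # FIXED_NUMBER or FIXED_SIZE
    value: float  # bin count N (fixed_number) or bin width w (fixed_size)
    normalized: bool = False
    upper_bound: float | None = None  # fixed_size only: global score cap
    include_zero_scores: bool = True

    def __post_init__(self) -> None:
        if self.mode not in (FIXED_NUMBER, FIXED_SIZE):
            raise ValueError(f"unknown histogram mode {self.mode!r}")
        if self.value <= 0:
            raise ValueError("histogram value must be > 0")
        if self.mode == FIXED_NUMBER and self.value != int(self.value):
            raise ValueError("fixed_number mode requires an integer bin count")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "value": self.value,
            "normalized": self.normalized,
            "upper_bound": self.upper_bound,
            "include_zero_scores": self.include_zero_scores,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HistogramConfig":
        return cls(**dict(d))


DDI_HISTOGRAM = "ddi_histogram"
CHEMICAL = "chemical"


@dataclass
class DatasetConfig:
    """One named featurization recipe (histogram variant or chemical)."""

    name: str
    featurizer: str  # DDI_HISTOGRAM or CHEMICAL
    histogram: HistogramConfig | None = None

    def __post_init__(self) -> None:
        if self.featurizer not in (DDI_HISTOGRAM, CHEMICAL):
            raise ValueError(f"unknown featurizer {self.featurizer!r}")
        if self.featurizer == DDI_HISTOGRAM and self.histogram is None:
            raise ValueError(f"dataset {self.name!r} needs a HistogramConfig")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "featurizer": self.featurizer,
            "histogram": self.histogram.to_dict() if self.histogram else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DatasetConfig":
        hist = d.get("histogram")
        return cls(
            name=d["name"],
            featurizer=d["featurizer"],
            histogram=HistogramConfig.from_dict(hist) if hist else None,
        )


@dataclass
class PairScoreVector:
    """All PPI scores of one phage-bacterium pair, phage-protein-major."""

    phage_id: str
    bacterium_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def ppi_score(
    phage_domains: Sequence[str],
    bact_domains: Sequence[str],
    table: DDITable,
    unique_domains: bool = False,
) -> float:
    """Cumulated interaction score of one PPI.

    Sum of table scores over all ordered (phage domain, bacterium domain)
    pairs; a domain annotated twice contributes twice unless
    ``unique_domains`` is set.
    """
    cp = Counter(set(phage_domains) if unique_domains else phage_domains)
    cb = Counter(set(bact_domains) if unique_domains else bact_domains)
    total = 0.0
    for a, na in cp.items():
        for b, nb in cb.items():
            total += na * nb * table.lookup(a, b)
    return total


def pair_score_vector(
    phage: Proteome,
    bact: Proteome,
    annotations: Mapping[str, Sequence[str]],
    table: DDITable,
    unique_domains: bool = False,
) -> PairScoreVector:
    """Score every protein pair of the phage x bacterium grid.

    Scores are enumerated phage-protein-major, bacterium-protein-minor;
    unannotated proteins contribute zero rows/columns. Runs in
    O(|table| + grid) by accumulating one rank-1 update per DDI entry whose
    accessions occur in both proteomes.
    """
    def count_matrix(proteome: Proteome) -> dict[str, np.ndarray]:
        cols: dict[str, np.ndarray] = {}
        for i, p in enumerate(proteome.proteins):
            doms = annotations.get(p.protein_id, ())
            if unique_domains:
                doms = set(doms)
            for d in doms:
                if d not in cols:
                    cols[d] = np.zeros(len(proteome.proteins))
                cols[d][i] += 1.0
        return cols

    pcols = count_matrix(phage)
    bcols = count_matrix(bact)
    grid = np.zeros((len(phage.proteins), len(bact.proteins)))
    for (a, b), score in table.items():
        directed = {(a, b), (b, a)}
        for x, y in directed:
            if x in pcols and y in bcols:
                grid += score * np.outer(pcols[x], bcols[y])
    return PairScoreVector(phage.organism_id, bact.organism_id, grid.ravel())


# ---------------------------------------------------------------------------
# histogram featurization
# ---------------------------------------------------------------------------

def _right_closed_counts(scores: np.ndarray, edges: np.ndarray,
                         n_bins: int) -> np.ndarray:
    """Count scores into bins (e_i, e_{i+1}]; zero lands in the first bin.

    Anything beyond the last edge is clipped into the last bin, which
    serves as the overflow bin in fixed_size mode.
    """
    idx = np.clip(np.searchsorted(edges, scores, side="left") - 1, 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(float)


def histogram_featurize(v: PairScoreVector, h: HistogramConfig) -> np.ndarray:
    """Bin a PPI score vector into a fixed-length frequency vector."""
    scores = v.scores
    if not h.include_zero_scores:
        scores = scores[scores > 0]

    if h.mode == FIXED_NUMBER:
        n_bins = int(h.value)
        hi = float(scores.max()) if scores.size and scores.max() > 0 else 1.0
        counts = _right_closed_counts(scores, np.linspace(0.0, hi, n_bins + 1), n_bins)
    else:
        if h.upper_bound is None:
            raise ValueError("fixed_size histograms require an upper_bound")
        w = float(h.value)
        n_regular = math.ceil(h.upper_bound / w)
        # n_regular width-w bins covering [0, upper_bound) plus one overflow
        counts = _right_closed_counts(
            scores, np.arange(n_regular + 1) * w, n_regular + 1
        )

    if h.normalized:
        total = scores.size
        if total:
            counts /= total
    return counts


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _pair_vectors(
    records: Sequence[InteractionRecord],
    proteomes: Mapping[str, Proteome],
    annotations: Mapping[str, Sequence[str]],
    table: DDITable,
    cache: dict[tuple[str, str], PairScoreVector],
    unique_domains: bool,
) -> None:
    for r in records:
        if r.pair in cache:
            continue
        for org in r.pair:
            if org not in proteomes:
                raise KeyError(f"no proteome available for organism {org!r}")
        cache[r.pair] = pair_score_vector(
            proteomes[r.phage_id], proteomes[r.bacterium_id],
            annotations, table, unique_domains,
        )


def build_ddi_dataset(
    corpus: Corpus,
    proteomes: Mapping[str, Proteome],
    annotations: Mapping[str, Sequence[str]],
    table: DDITable,
    config: DatasetConfig,
    unique_domains: bool = False,
) -> tuple[list[FeatureRow], list[FeatureRow], dict]:
    """Featurize a corpus under one histogram config.

    Returns ``(train_rows, test_rows, manifest)``. The manifest records the
    resolved config, including the training-split upper bound chosen for
    fixed_size histograms without an explicit one.
    """
    if config.featurizer != DDI_HISTOGRAM:
        raise ValueError(f"dataset {config.name!r} is not a DDI histogram config")
    hist = config.histogram
    assert hist is not None
    cache: dict[tuple[str, str], PairScoreVector] = {}
    _pair_vectors(corpus.train, proteomes, annotations, table, cache, unique_domains)
    _pair_vectors(corpus.test, proteomes, annotations, table, cache, unique_domains)

    if hist.mode == FIXED_SIZE and hist.upper_bound is None:
        train_max = max(
            (float(cache[r.pair].scores.max()) for r in corpus.train),
            default=0.0,
        )
        hist = replace(hist, upper_bound=train_max if train_max > 0 else 1.0)

    def rows(records: Sequence[InteractionRecord]) -> list[FeatureRow]:
        return [
            FeatureRow(
                pair_id=f"{r.phage_id}|{r.bacterium_id}",
                label=r.label,
                values=histogram_featurize(cache[r.pair], hist),
            )
            for r in records
        ]

    manifest = {
        "config": replace(config, histogram=hist).to_dict(),
        "n_train": len(corpus.train),
        "n_test": len(corpus.test),
    }
    return rows(corpus.train), rows(corpus.test), manifest


# ---------------------------------------------------------------------------
# the standard 19-config grid
# ---------------------------------------------------------------------------

#: fixed-number bin counts (normalized -> NBN sets, absolute -> NB sets)
NBIN_VALUES = (5, 10, 15, 30, 50)
#: fixed-size bin widths for normalized (SBN) sets
SBN_WIDTHS = (1.0, 5.0, 10.0, 15.0, 20.0)
#: fixed-size bin widths for absolute-frequency (SB) sets
SB_WIDTHS = (1e-6, 2.5e-6, 5e-6)

#: alternate spellings seen for the selected fixed-size dataset
CONFIG_ALIASES = {
    "SBN1e-6": "SB1e-06",
    "SBN1E-6": "SB1e-06",
    "SB1E-6": "SB1e-06",
    "SB1e-6": "SB1e-06",
}


def _width_tag(w: float) -> str:
    if w == int(w) and w >= 1:
        return str(int(w))
    return f"{w:g}"


def standard_config_grid() -> list[DatasetConfig]:
    """The 19 canonical dataset configs: 18 DDI histograms plus chemical."""
    configs: list[DatasetConfig] = []
    for n in NBIN_VALUES:
        configs.append(DatasetConfig(
            name=f"NBN{n}",
            featurizer=DDI_HISTOGRAM,
            histogram=HistogramConfig(FIXED_NUMBER, n, normalized=True),
        ))
    for n in NBIN_VALUES:
        configs.append(DatasetConfig(
            name=f"NB{n}",
            featurizer=DDI_HISTOGRAM,
            histogram=HistogramConfig(FIXED_NUMBER, n, normalized=False),
        ))
    for w in SBN_WIDTHS:
        configs.append(DatasetConfig(
            name=f"SBN{_width_tag(w)}",
            featurizer=DDI_HISTOGRAM,
            histogram=HistogramConfig(FIXED_SIZE, w, normalized=True),
        ))
    for w in SB_WIDTHS:
        configs.append(DatasetConfig(
            name=f"SB{_width_tag(w)}",
            featurizer=DDI_HISTOGRAM,
            histogram=HistogramConfig(FIXED_SIZE, w, normalized=False),
        ))
    configs.append(DatasetConfig(name="CH", featurizer=CHEMICAL))
    return configs


def resolve_config(name: str) -> DatasetConfig:
    """Look up a standard config by canonical name or known alias."""
    canonical = CONFIG_ALIASES.get(name, name)
    for cfg in standard_config_grid():
        if cfg.name == canonical:
            return cfg
    raise KeyError(f"unknown dataset config {name!r}")
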