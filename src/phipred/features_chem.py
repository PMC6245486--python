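"""Chemical-composition (CH) features from protein primary structure.

Per protein: 27 features — the frequencies of the 20 standard amino acids
(alphabetical by one-letter code) plus one "unknown" bucket, the atom-count
fractions of C, H, N, O and S, and the average molecular weight in Daltons.
Per PPI: the 54-float concatenation [phage protein 27 | bacterium protein
27]. Per phage-bacterium pair: the per-coordinate mean and population
standard deviation of that 54-vector over the full protein grid — 108
features, means before standard deviations.

Residue elemental formulas are the water-subtracted residue formulas (e.g.
Gly = C2H3NO); one water molecule is added back per chain. Masses derive
from IUPAC 2021 standard atomic weights. Non-standard letters (X, B, Z, J,
U, O, ...) count toward the unknown frequency bucket and contribute the
mean composition/mass of the 20 standard residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus
from .io_formats import FeatureRow, InteractionRecord, ProteinRecord, Proteome

#: the 20 standard amino acids, alphabetical by one-letter code
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
ELEMENTS = ("C", "H", "N", "O", "S")

#: water-subtracted residue formulas as (C, H, N, O, S) atom counts
RESIDUE_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 5, 1, 1, 0),
    "C": (3, 5, 1, 1, 1),
    "D": (4, 5, 1, 3, 0),
    "E": (5, 7, 1, 3, 0),
    "F": (9, 9, 1, 1, 0),
    "G": (2, 3, 1, 1, 0),
    "H": (6, 7, 3, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "K": (6, 12, 2, 1, 0),
    "L": (6, 11, 1, 1, 0),
    "M": (5, 9, 1, 1, 1),
    "N": (4, 6, 2, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "Q": (5, 8, 2, 2, 0),
    "R": (6, 12, 4, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "T": (4, 7, 1, 2, 0),
    "V": (5, 9, 1, 1, 0),
    "W": (11, 10, 2, 1, 0),
    "Y": (9, 9, 1, 2, 0),
}

#: standard (average) atomic weights, IUPAC 2021
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

WATER_FORMULA = np.array([0, 2, 0, 1, 0], dtype=float)
WATER_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]

_FORMULA_MATRIX = np.array([RESIDUE_FORMULA[a] for a in AA_ORDER], dtype=float)
_MASS_VECTOR = _FORMULA_MATRIX @ np.array([ATOMIC_MASS[e] for e in ELEMENTS])

#: imputation used for unknown residues: mean over the 20 standard residues
MEAN_RESIDUE_FORMULA = _FORMULA_MATRIX.mean(axis=0)
MEAN_RESIDUE_MASS = float(_MASS_VECTOR.mean())

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

N_PROTEIN_FEATURES = 27
N_PPI_FEATURES = 54
N_PAIR_FEATURES = 108


@dataclass
class ProteinFeatures:
    """The 27 per-protein features: 21 aa frequencies, 5 element fractions,
    molecular weight."""

    aa_freq: np.ndarray  # 21 floats, AA_ORDER then unknown bucket
    elem_frac: np.ndarray  # 5 floats, C H N O S
    mol_weight: float

    def vector(self) -> np.ndarray:
        return np.concatenate([self.aa_freq, self.elem_frac, [self.mol_weight]])


@dataclass
class PairChemFeatures:
    """Mean and population std of the 54 PPI features over a pair's grid."""

    mean: np.ndarray  # 54 floats
    std: np.ndarray  # 54 floats

    def vector(self) -> np.ndarray:
        return np.concatenate([self.mean, self.std])


def protein_features(
    protein: ProteinRecord | str, absolute_elements: bool = False
) -> ProteinFeatures:
    """Compute the 27-feature chemical profile of one protein.

    ``absolute_elements`` switches the C/H/N/O/S block from atom-count
    fractions to absolute atom counts.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not seq:
        raise ValueError("empty protein sequence")
    seq = seq.upper()

    counts = np.zeros(21)
    atoms = WATER_FORMULA.copy()
    mass = WATER_MASS
    for aa in seq:
        idx = _AA_INDEX.get(aa)
        if idx is None:
            counts[20] += 1
            atoms += MEAN_RESIDUE_FORMULA
            mass += MEAN_RESIDUE_MASS
        else:
            counts[idx] += 1
            atoms += _FORMULA_MATRIX[idx]
            mass += _MASS_VECTOR[idx]

    aa_freq = counts / len(seq)
    elem = atoms if absolute_elements else atoms / atoms.sum()
    return ProteinFeatures(aa_freq=aa_freq, elem_frac=elem, mol_weight=mass)


def ppi_chem_features(
    phage_p: ProteinFeatures, bact_p: ProteinFeatures
) -> np.ndarray:
    """The 54-feature PPI vector: [phage protein 27 | bacterium protein 27]."""
    return np.concatenate([phage_p.vector(), bact_p.vector()])


def _proteome_feature_matrix(proteome: Proteome) -> np.ndarray:
    return np.vstack([protein_features(p).vector() for p in proteome.proteins])


def pair_chem_features(phage: Proteome, bact: Proteome) -> PairChemFeatures:
    """Mean/std of the 54 PPI features over the full protein grid.

    Exploits that on the n_phage x n_bact grid the phage coordinates are
    constant across bacterium proteins and vice versa, so the grid-wide
    mean and population std of each coordinate equal the per-proteome mean
    and std of its 27 columns. Matches the explicit grid enumeration.
    """
    fp = _proteome_feature_matrix(phage)
    fb = _proteome_feature_matrix(bact)
    mean = np.concatenate([fp.mean(axis=0), fb.mean(axis=0)])
    std = np.concatenate([fp.std(axis=0), fb.std(axis=0)])
    return PairChemFeatures(mean=mean, std=std)


def build_chem_dataset(
    corpus: Corpus, proteomes: Mapping[str, Proteome]
) -> tuple[list[FeatureRow], list[FeatureRow], dict]:
    """Featurize a corpus with the 108-feature chemical profile.

    Returns ``(train_rows, test_rows, manifest)``.
    """
    cache: dict[tuple[str, str], np.ndarray] = {}

    def rows(records: Sequence[InteractionRecord]) -> list[FeatureRow]:
        out = []
        for r in records:
            if r.pair not in cache:
                for org in r.pair:
                    if org not in proteomes:
                        raise KeyError(f"no proteome available for organism {org!r}")
                cache[r.pair] = pair_chem_features(
                    proteomes[r.phage_id], proteomes[r.bacterium_id]
                ).vector()
            out.append(
                FeatureRow(f"{r.phage_id}|{r.bacterium_id}", r.label, cache[r.pair])
            )
        return out

    train_rows, test_rows = rows(corpus.train), rows(corpus.test)
    manifest = {
        "config": {"name": "CH", "featurizer": "chemical", "histogram": None},
        "n_train": len(train_rows),
        "n_test": len(test_rows),
    }
    return train_rows, test_rows, manifest
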