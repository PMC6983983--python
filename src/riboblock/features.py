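"""Block location-based feature extraction (BLBFE).

Each sequence becomes one *observation*: an integer vector whose i-th entry
is the 1-based start of the first occurrence of block i's motif on the
sequence, or 0 when the block is absent.  Stacking the observations of all
family members over a fixed combined block vocabulary yields the feature
matrix used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sbf import Block, locate_block
from .sequence_io import FamilyDataset, SequenceRecord


@dataclass
class FeatureMatrix:
    """Observations-by-blocks matrix of first-occurrence locations.

    Rows follow dataset-then-file order; columns follow ``block_order``.
    Entries are non-negative; 0 means the block's motif does not occur.
    """

    observation_ids: list[str]
    families: list[str]
    block_order: list[Block]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        n, m = self.values.shape
        if n != len(self.observation_ids) or n != len(self.families):
            raise ValueError("FeatureMatrix: row count does not match ids/labels")
        if m != len(self.block_order):
            raise ValueError("FeatureMatrix: column count does not match block order")
        if np.any(self.values < 0):
            raise ValueError("FeatureMatrix: negative location entry")

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.values.shape[1]

    @property
    def class_labels(self) -> list[str]:
        """Distinct family labels in first-appearance (dataset) order."""
        seen: list[str] = []
        for fam in self.families:
            if fam not in seen:
                seen.append(fam)
        return seen


def extract_features(record: SequenceRecord, blocks: list[Block]) -> np.ndarray:
    """Observation vector for one sequence over a fixed block order."""
    if not blocks:
        raise ValueError("extract_features: empty block list")
    return np.array([locate_block(record.residues, b.motif) for b in blocks], dtype=int)


def build_feature_matrix(datasets: list[FamilyDataset], blocks: list[Block]) -> FeatureMatrix:
    """Stack observations for all members of all families.

    One row per member, in dataset-then-file order; duplicate observation
    ids across families are an error.
    """
    if not datasets:
        raise ValueError("build_feature_matrix: no datasets")
    ids: list[str] = []
    families: list[str] = []
    rows: list[np.ndarray] = []
    for ds in datasets:
        for rec in ds:
            ids.append(rec.id)
            families.append(rec.family)
            rows.append(extract_features(rec, blocks))
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"build_feature_matrix: duplicate observation id {dup!r}")
    return FeatureMatrix(
        observation_ids=ids,
        families=families,
        block_order=list(blocks),
        values=np.vstack(rows),
    )
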