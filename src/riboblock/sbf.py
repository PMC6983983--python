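"""Sequential block finding (SBF): alignment-free discovery of family blocks.

A *sequential block* is a short contiguous motif that occurs in a very high
fraction of a family's members with its first occurrence at (approximately)
the same sequence position.  The finder enumerates every substring of the
configured length range as a candidate, records each candidate's first
occurrence on every member (0 when absent), keeps candidates whose first
occurrences concentrate inside a window around the modal location in at
least a threshold fraction of members, and finally drops candidates that are
substrings of a longer surviving block at an overlapping placement.

Locations are 1-based throughout; 0 is the reserved "absent" value.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import RNA_ALPHABET, FamilyDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Block:
    """A family-specific motif with its canonical (modal) start location.

    ``prevalence`` is the fraction of family members whose first occurrence
    of the motif falls within the location window used at discovery time.
    """

    family: str
    motif: str
    canonical_location: int
    prevalence: float

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("Block: empty motif")
        bad = set(self.motif) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"Block {self.motif!r}: invalid character {sorted(bad)[0]!r}"
            )
        if self.canonical_location < 1:
            raise ValueError(
                f"Block {self.motif!r}: canonical_location must be >= 1 "
                f"(got {self.canonical_location})"
            )
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"Block {self.motif!r}: prevalence {self.prevalence} not in [0, 1]")

    def __len__(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class SBFConfig:
    """Tunable knobs of the block finder.

    min_len/max_len bound candidate motif lengths in nucleotides;
    prevalence_threshold is the minimum fraction of members that must carry
    the motif inside the window; location_window is the allowed deviation
    (nt) of a member's first occurrence from the modal first occurrence.
    """

    min_len: int = 3
    max_len: int = 8
    prevalence_threshold: float = 0.7
    location_window: int = 5

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.min_len > self.max_len:
            raise ValueError(f"SBFConfig: need 1 <= min_len <= max_len, got {self}")
        if not 0.0 < self.prevalence_threshold <= 1.0:
            raise ValueError(f"SBFConfig: prevalence_threshold {self.prevalence_threshold} not in (0, 1]")
        if self.location_window < 0:
            raise ValueError(f"SBFConfig: negative location_window {self.location_window}")


@dataclass
class CandidateSet:
    """All candidate motifs of a family with per-member first occurrences.

    ``locations[motif]`` is an int array aligned with the dataset's member
    order; entry i is the 1-based first occurrence of the motif on member i,
    or 0 when the member does not contain the motif.
    """

    family: str
    n_members: int
    locations: dict[str, np.ndarray] = field(default_factory=dict)


def locate_block(residues: str, motif: str) -> int:
    """1-based first-occurrence position of ``motif`` in ``residues`` (0 = absent)."""
    if not motif:
        raise ValueError("locate_block: empty motif")
    for s, name in ((residues, "sequence"), (motif, "motif")):
        bad = set(s) - RNA_ALPHABET
        if bad:
            raise ValueError(f"locate_block: invalid {name} character {sorted(bad)[0]!r}")
    return residues.find(motif) + 1


def candidate_motifs(dataset: FamilyDataset, config: SBFConfig = SBFConfig()) -> CandidateSet:
    """Enumerate every substring of length min_len..max_len across the family.

    Each distinct motif occurring in at least one member appears exactly
    once, with its first-occurrence location (or 0) recorded per member.
    """
    if len(dataset) == 0:
        raise ValueError("candidate_motifs: empty dataset")
    n = len(dataset)
    per_member: list[dict[str, int]] = []
    for rec in dataset:
        seen: dict[str, int] = {}
        seq = rec.residues
        L = len(seq)
        for start in range(L):
            upper = min(config.max_len, L - start)
            for m_len in range(config.min_len, upper + 1):
                motif = seq[start:start + m_len]
                if motif not in seen:
                    seen[motif] = start + 1
        per_member.append(seen)

    all_motifs = set()
    for seen in per_member:
        all_motifs.update(seen)
    locations = {}
    for motif in all_motifs:
        locations[motif] = np.array([seen.get(motif, 0) for seen in per_member], dtype=int)
    return CandidateSet(family=dataset.family, n_members=n, locations=locations)


def _modal_location(locs: np.ndarray) -> int:
    """Most common non-zero location; ties broken toward the smallest."""
    nonzero = locs[locs > 0]
    counts = Counter(nonzero.tolist())
    return min(counts, key=lambda loc: (-counts[loc], loc))


def filter_blocks(candidates: CandidateSet, config: SBFConfig = SBFConfig()) -> list[Block]:
    """Keep candidates concentrated around their modal first occurrence.

    A motif survives iff the fraction of members whose (non-zero) first
    occurrence lies within ``canonical_location ± location_window`` is at
    least ``prevalence_threshold``; the canonical location is the modal
    first occurrence with ties broken toward the smallest location.
    """
    blocks: list[Block] = []
    w = config.location_window
    for motif, locs in candidates.locations.items():
        if not config.min_len <= len(motif) <= config.max_len:
            continue
        if not np.any(locs > 0):
            continue
        mode = _modal_location(locs)
        in_window = (locs > 0) & (np.abs(locs - mode) <= w)
        prevalence = float(np.count_nonzero(in_window)) / candidates.n_members
        if prevalence >= config.prevalence_threshold:
            blocks.append(
                Block(family=candidates.family, motif=motif,
                      canonical_location=mode, prevalence=prevalence)
            )
    blocks.sort(key=lambda b: (b.canonical_location, b.motif))
    return blocks


def eliminate_redundant(blocks: list[Block]) -> list[Block]:
    """Drop blocks that a longer surviving block already explains.

    A block A is removed when its motif is a proper substring of a longer
    kept block B and their canonical locations imply overlapping placements
    (|loc(A) − loc(B)| ≤ len(B)).  Longer motifs are preferred; the result
    is sorted by canonical location then motif.
    """
    ordered = sorted(blocks, key=lambda b: (-len(b.motif), b.canonical_location, b.motif))
    kept: list[Block] = []
    for cand in ordered:
        redundant = any(
            len(cand.motif) < len(other.motif)
            and cand.motif in other.motif
            and abs(cand.canonical_location - other.canonical_location) <= len(other.motif)
            for other in kept
        )
        if not redundant:
            kept.append(cand)
    kept.sort(key=lambda b: (b.canonical_location, b.motif))
    return kept


def find_blocks(dataset: FamilyDataset, config: SBFConfig = SBFConfig()) -> list[Block]:
    """Full block-finding pipeline: enumerate, filter, de-duplicate.

    Deterministic for a fixed dataset and config, and invariant to member
    order (modal ties break toward the smallest location).
    """
    if len(dataset) < 2:
        raise ValueError(
            f"find_blocks: family {dataset.family!r} has {len(dataset)} member(s); "
            "prevalence is undefined for fewer than 2"
        )
    blocks = eliminate_redundant(filter_blocks(candidate_motifs(dataset, config), config))
    if not blocks:
        logger.warning("find_blocks: no blocks survived filtering for family %r", dataset.family)
    return blocks
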