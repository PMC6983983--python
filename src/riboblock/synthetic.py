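"""Synthetic RNA families with planted, location-constrained blocks.

The generator emulates the structure the block finder assumes: each family
is a set of i.i.d. uniform-background RNA sequences whose lengths follow a
rounded normal, with family-specific motifs written at an approximately
fixed 1-based location (configurable prevalence and positional jitter).

By default chance background occurrences of a family's *own* planted
motifs are rewritten (``clean_background=True``), so that the first
occurrence of a planted motif on a member is exactly its planted position
when present and 0 when absent.  Without this, short motifs (3-mers) at
late canonical locations would almost surely first occur much earlier by
chance, making the planted ground truth ill-defined.  Real riboswitches
have composition bias and internal repeats that this generator does not
emulate; see the methods note.

``RIBOSWITCH_PRESETS`` mirrors the seven published Rfam riboswitch seed
families (member counts, mean/variance of lengths, and each family's
reference blocks planted at their canonical locations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sbf import Block
from .sequence_io import RNA_ALPHABET, FamilyDataset, SequenceRecord

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class PlantedBlock:
    """One motif to plant: canonical 1-based location, prevalence, jitter (nt)."""

    motif: str
    location: int
    prevalence: float = 1.0
    jitter: int = 0

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - RNA_ALPHABET:
            raise ValueError(f"PlantedBlock: invalid motif {self.motif!r}")
        if self.location < 1:
            raise ValueError(f"PlantedBlock {self.motif!r}: location must be >= 1")
        if not 0.0 < self.prevalence <= 1.0:
            raise ValueError(f"PlantedBlock {self.motif!r}: prevalence not in (0, 1]")
        if self.jitter < 0:
            raise ValueError(f"PlantedBlock {self.motif!r}: negative jitter")
        if self.location - self.jitter < 1:
            raise ValueError(f"PlantedBlock {self.motif!r}: jitter reaches past position 1")

    @property
    def max_end(self) -> int:
        """Largest 0-based end index (exclusive) a jittered placement can reach."""
        return self.location - 1 + self.jitter + len(self.motif)


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic family."""

    name: str
    n_members: int
    mean_length: float
    length_sd: float
    planted: tuple[PlantedBlock, ...] = ()

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError(f"FamilySpec {self.name!r}: n_members must be >= 1")
        if self.mean_length <= 0 or self.length_sd < 0:
            raise ValueError(f"FamilySpec {self.name!r}: bad length parameters")
        object.__setattr__(self, "planted", tuple(self.planted))
        min_needed = max((p.max_end for p in self.planted), default=1)
        if min_needed > self.mean_length:
            raise ValueError(
                f"FamilySpec {self.name!r}: planted blocks need length >= {min_needed}, "
                f"mean_length is only {self.mean_length}"
            )
        motifs = [p.motif for p in self.planted]
        if len(set(motifs)) != len(motifs):
            raise ValueError(f"FamilySpec {self.name!r}: duplicate planted motif")
        for a in self.planted:
            for b in self.planted:
                if a is not b and a.motif in b.motif:
                    # a copy of the shorter motif sits inside every planted
                    # copy of the longer one, so its own first occurrence
                    # cannot be pinned to an independent location
                    raise ValueError(
                        f"FamilySpec {self.name!r}: planted motif {a.motif!r} is a "
                        f"substring of planted motif {b.motif!r}"
                    )

    @property
    def min_length(self) -> int:
        """Shortest sequence able to carry every jittered planted block."""
        return max((p.max_end for p in self.planted), default=1)


def _scrub_early_hits(seq: np.ndarray, spec: FamilySpec,
                      placements: dict[str, tuple[int, int]], rng) -> np.ndarray:
    """Rewrite chance occurrences of planted motifs that would precede
    (or replace) the planted copy, leaving planted placements untouched."""
    protected = list(placements.values())

    def in_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected)

    text = "".join(seq)
    for _ in range(200):
        dirty = False
        for p in spec.planted:
            start, end = placements.get(p.motif, (len(text) + 1, len(text) + 1))
            # any occurrence starting before the planted copy (or anywhere,
            # when the motif was not planted on this member) is spurious
            limit = start
            pos = text.find(p.motif)
            while 0 <= pos < limit:
                free = [i for i in range(pos, pos + len(p.motif)) if not in_protected(i)]
                if not free:
                    raise ValueError(
                        f"cannot scrub {p.motif!r}: occurrence lies inside planted blocks"
                    )
                i = int(rng.choice(free))
                old = text[i]
                new = str(rng.choice([b for b in "ACGU" if b != old]))
                text = text[:i] + new + text[i + 1:]
                dirty = True
                pos = text.find(p.motif, pos)
            if dirty:
                break
        if not dirty:
            return np.array(list(text))
    raise RuntimeError("scrubbing did not converge")


def generate_family(spec: FamilySpec, seed: int, *,
                    clean_background: bool = True) -> FamilyDataset:
    """Generate one family; deterministic given (spec, seed).

    Lengths are rounded normal draws clamped so every jittered planted
    block fits.  Each planted motif is written at location + U[-j, +j]
    with probability ``prevalence``, overwriting background only: a member
    whose jittered placements would overlap each other is redrawn, so every
    planted copy stays intact.
    """
    rng = np.random.default_rng(seed)
    records = []
    order = sorted(spec.planted, key=lambda p: p.location)
    for i in range(spec.n_members):
        # a draw is rejected and the member redrawn when (a) two jittered
        # placements overlap (a later motif would destroy an earlier one)
        # or (b) adjacent placements spell a third planted motif across
        # protected positions, which cannot be scrubbed
        for _attempt in range(50):
            length = int(round(rng.normal(spec.mean_length, spec.length_sd)))
            length = max(length, spec.min_length)
            seq = rng.choice(_BASES, size=length)
            placements: dict[str, tuple[int, int]] = {}
            for p in order:
                if rng.random() <= p.prevalence:
                    offset = int(rng.integers(-p.jitter, p.jitter + 1))
                    start = p.location - 1 + offset
                    placements[p.motif] = (start, start + len(p.motif))
            spans = sorted(placements.values())
            if any(b_start < a_end for (_, a_end), (b_start, _) in zip(spans, spans[1:])):
                continue
            for p in order:
                if p.motif in placements:
                    start, end = placements[p.motif]
                    seq[start:end] = list(p.motif)
            if clean_background and spec.planted:
                try:
                    seq = _scrub_early_hits(seq, spec, placements, rng)
                except ValueError:
                    continue
            break
        else:
            raise RuntimeError(
                f"generate_family: could not place blocks for {spec.name!r} "
                f"member {i + 1} in 50 attempts"
            )
        records.append(SequenceRecord(
            id=f"{spec.name}_{i + 1:04d}", family=spec.name, residues="".join(seq)
        ))
    return FamilyDataset(family=spec.name, records=records)


def generate_benchmark(specs: list[FamilySpec], seed: int, *,
                       clean_background: bool = True
                       ) -> tuple[list[FamilyDataset], list[Block]]:
    """Generate several families plus the planted-truth block table.

    Each family gets an independent child seed derived from ``seed``, so
    the benchmark is deterministic and families are uncorrelated.
    """
    if not specs:
        raise ValueError("generate_benchmark: empty spec list")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"generate_benchmark: duplicate family names in {names}")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(specs))
    datasets = [
        generate_family(s, int(cs) % (2 ** 31), clean_background=clean_background)
        for s, cs in zip(specs, child_seeds)
    ]
    truth = [
        Block(family=s.name, motif=p.motif, canonical_location=p.location,
              prevalence=p.prevalence)
        for s in specs for p in s.planted
    ]
    return datasets, truth


def _preset(name: str, n: int, mean: float, var: float,
            blocks: list[tuple[str, int]], prevalence: float, jitter: int) -> FamilySpec:
    return FamilySpec(
        name=name, n_members=n, mean_length=mean, length_sd=math.sqrt(var),
        planted=tuple(PlantedBlock(motif=m, location=loc, prevalence=prevalence,
                                   jitter=jitter) for m, loc in blocks),
    )


# Seven-family benchmark mirroring the published Rfam riboswitch seed sets:
# member counts and length mean/variance per family, with the family's
# reference blocks planted at their canonical locations.  Prevalence 0.95
# and jitter 2 nt encode "present in a very high fraction of members at
# nearly the same position".
_PRESET_PREVALENCE = 0.95
_PRESET_JITTER = 2

RIBOSWITCH_PRESETS: dict[str, FamilySpec] = {
    spec.name: spec for spec in [
        _preset("Lysine", 47, 183, 11.06,
                [("AGAGGUGC", 10), ("AGUAA", 28)], _PRESET_PREVALENCE, _PRESET_JITTER),
        _preset("Cobalamin", 430, 203, 15.54,
                [("CGGUG", 18), ("GCA", 77), ("AGC", 92), ("AGA", 175), ("GACC", 180)],
                _PRESET_PREVALENCE, _PRESET_JITTER),
        _preset("Glycine", 44, 101, 15.99,
                [("GGAGA", 13), ("CCGA", 35)], _PRESET_PREVALENCE, _PRESET_JITTER),
        _preset("SAM-alpha", 40, 79, 1.18,
                [("GUGGU", 11), ("AUUUG", 17), ("GCCACGU", 37)],
                _PRESET_PREVALENCE, _PRESET_JITTER),
        _preset("SAM-IV", 40, 116, 4.13,
                [("UCA", 3), ("GAG", 7), ("CAG", 13), ("GCUGG", 32), ("CGGCAACC", 38)],
                _PRESET_PREVALENCE, _PRESET_JITTER),
        _preset("Cyclic-di-GMP-I", 155, 87, 6.0,
                [("GAAA", 23), ("CGCAAAGC", 35)], _PRESET_PREVALENCE, _PRESET_JITTER),
        _preset("SAH", 52, 85, 15.4,
                [("GAGGAGCG", 7), ("UGC", 16), ("AGGCUCGG", 36)],
                _PRESET_PREVALENCE, _PRESET_JITTER),
    ]
}


def riboswitch_benchmark(seed: int) -> tuple[list[FamilyDataset], list[Block]]:
    """The seven-family preset benchmark (808 sequences in total)."""
    return generate_benchmark(list(RIBOSWITCH_PRESETS.values()), seed)
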