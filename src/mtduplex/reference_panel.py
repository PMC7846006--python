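"""Circular mitochondrial reference and the two-pool amplicon panel.

The human mitochondrial genome is a closed circle of 16,569 bp.  All public
coordinates are 1-based inclusive (rCRS convention, variants written
``m.<pos><ref>><alt>``).  An amplicon whose ``end`` is smaller than its
``start`` wraps across the replication origin — the control region spans
position 16569|1, and variants on both sides of the junction occur in real
panels, so the wrap is modelled explicitly.

Two complementary primer pools (A and B) interrogate the two strands of the
molecule independently; each pool must tile the whole circle on its own so
that every position can be called on both strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import ConfigurationError, FormatError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: Length of the rCRS mitochondrial reference frame.
MT_LENGTH = 16569

_PACKAGED_REFERENCE = "mt_reference.fasta"


@dataclass(frozen=True)
class MtReference:
    """A circular mitochondrial reference sequence."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError("reference sequence is empty")
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise FormatError(f"non-ACGT characters in reference: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= len(self):
            raise FormatError(f"position {position} outside reference 1..{len(self)}")
        return self.sequence[position - 1]

    @property
    def base_indices(self) -> np.ndarray:
        """Per-position index into ``BASES`` (array of length L)."""
        return np.array([BASE_INDEX[b] for b in self.sequence], dtype=np.int8)


@dataclass(frozen=True)
class Amplicon:
    """One amplicon of a primer pool. ``end < start`` means origin wrap."""

    id: str
    start: int
    end: int
    pool: str

    def positions(self, genome_length: int) -> np.ndarray:
        """1-based positions covered, honouring the circular wrap."""
        if self.end >= self.start:
            return np.arange(self.start, self.end + 1)
        return np.concatenate(
            [np.arange(self.start, genome_length + 1), np.arange(1, self.end + 1)]
        )

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return (genome_length - self.start + 1) + self.end


@dataclass
class PanelDesign:
    """A two-pool amplicon panel over a circular reference."""

    amplicons: list[Amplicon]
    reference: MtReference

    def pool(self, pool: str) -> list[Amplicon]:
        return [a for a in self.amplicons if a.pool == pool]


def load_reference(path: str | Path) -> MtReference:
    """Read a single-record FASTA into an :class:`MtReference`.

    The sequence is uppercased; ambiguity codes and multi-record files are
    rejected because every downstream stage assumes one unambiguous circular
    molecule.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"expected exactly one FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()
    return MtReference(name=records[0].id, sequence=seq)


def load_packaged_reference() -> MtReference:
    """The packaged rCRS-length (16,569 bp) synthetic reference stand-in.

    It carries the printed reference allele at every position the packaged
    table fixtures refer to; a real rCRS FASTA can be supplied by path via
    :func:`load_reference` instead.
    """
    with resources.as_file(
        resources.files("mtduplex.data").joinpath(_PACKAGED_REFERENCE)
    ) as p:
        return load_reference(p)


def design_panel(
    reference: MtReference, n_pairs: int = 171, min_overlap: int = 20
) -> PanelDesign:
    """Tile the circle with ``n_pairs`` overlapping amplicons per pool.

    Both pools use the same even tiling (they differ in which strand their
    primers anneal to, not in the territory they cover); pool B is phase
    shifted by half a tile so that pool boundaries do not coincide.
    Deterministic for fixed arguments.
    """
    L = len(reference)
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    if min_overlap < 0:
        raise ConfigurationError("min_overlap must be >= 0")
    if n_pairs > L:
        raise ConfigurationError(f"cannot tile {L} bp with {n_pairs} amplicons")
    step = L / n_pairs
    amp_len = min(L, math.ceil(step) + min_overlap)
    if n_pairs * (amp_len - min_overlap) < L:
        raise ConfigurationError(
            f"infeasible tiling: {n_pairs} x ({amp_len} - {min_overlap}) < {L}"
        )
    amplicons: list[Amplicon] = []
    for pool, phase in (("A", 0.0), ("B", step / 2.0)):
        for i in range(n_pairs):
            start = (math.floor(i * step + phase)) % L + 1
            end = (start - 1 + amp_len - 1) % L + 1
            amplicons.append(Amplicon(id=f"{pool}{i + 1:03d}", start=start, end=end, pool=pool))
    return PanelDesign(amplicons=amplicons, reference=reference)


def coverage_profile(panel: PanelDesign) -> dict[str, np.ndarray]:
    """Per-position amplicon coverage count for each pool (arrays of length L)."""
    L = len(panel.reference)
    out: dict[str, np.ndarray] = {}
    for pool in ("A", "B"):
        cov = np.zeros(L, dtype=np.int64)
        for amp in panel.pool(pool):
            cov[amp.positions(L) - 1] += 1
        out[pool] = cov
    return out


def write_panel_tsv(panel: PanelDesign, path: str | Path) -> None:
    """Serialize the panel as a BED-like TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("# amplicon panel; coordinates are 1-based inclusive; end < start wraps the origin\n")
        fh.write("amplicon_id\tstart\tend\tpool\n")
        for amp in panel.amplicons:
            fh.write(f"{amp.id}\t{amp.start}\t{amp.end}\t{amp.pool}\n")


def read_panel_tsv(path: str | Path, reference: MtReference) -> PanelDesign:
    amplicons = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("amplicon_id"):
                continue
            aid, start, end, pool = line.rstrip("\n").split("\t")
            amplicons.append(Amplicon(aid, int(start), int(end), pool))
    if not amplicons:
        raise FormatError("panel file contains no amplicons")
    return PanelDesign(amplicons=amplicons, reference=reference)
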