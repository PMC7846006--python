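"""Strand-resolved pileup simulator.

Generates subjects, tissues and per-pool pileups with the statistical
structure the dual-strand analysis assumes:

* germline homoplasmies follow a haplogroup path in a phylogenetic mini-tree
  and sit at ~99.5% allele frequency in every tissue of a subject;
* true heteroplasmies are present on both strands (both primer pools) at
  their minor allele frequency;
* single-strand artifacts (deamination-like C>T / G>A damage introduced
  after DNA extraction) appear in one pool only — the signature the duplex
  concordance rule exploits;
* per-position sequencing depth is log-uniform between ``depth_min`` and
  ``depth_max`` and rescaled so its mean is close to ``depth_mean``
  (defaults 1,000 / 100,000 / 30,000, the deep-amplicon regime this kind of
  panel produces), independently per pool;
* base errors substitute the reference read at ``base_error_rate``
  (default 0.1%), split across the three non-reference bases — uniformly by
  default, or with a configurable transition bias.

Every draw flows from one :func:`numpy.random.default_rng` generator seeded
from the single config seed, so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ValidationError
from .reference_panel import BASE_INDEX, BASES, MtReference, PanelDesign
from .variant_classification import MiniHaplotree

TISSUES = ("blood", "retina", "rpe_choroid")

#: Allele frequency used for planted germline homoplasmies.  The printed
#: homoplasmy frequencies cluster at 99.0-99.9%, never exactly 100%: a small
#: amount of reference signal (errors, trace contamination) always remains.
GERMLINE_MAF = 0.995


@dataclass(frozen=True)
class SubjectProfile:
    """A simulated subject: a haplogroup and its germline variants.

    The germline set is identical across all tissues of the subject — the
    defining property of inherited homoplasmies.
    """

    subject_id: str
    haplogroup: str
    germline_variants: tuple[tuple[int, str, str], ...]
    germline_maf: float = GERMLINE_MAF


@dataclass(frozen=True)
class PlantedEvent:
    """A somatic event planted into one tissue.

    ``true_heteroplasmy`` events are real biology and go onto both strands;
    ``single_strand_artifact`` events emulate post-extraction DNA
    modification and appear only in ``artifact_pool``.
    """

    position: int
    ref: str
    alt: str
    maf: float
    kind: str = "true_heteroplasmy"
    artifact_pool: str = "none"

    def __post_init__(self) -> None:
        if self.ref == self.alt or self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(f"invalid substitution {self.ref}>{self.alt}")
        if not 0.0 < self.maf < 1.0:
            raise ValidationError(f"maf must be in (0,1), got {self.maf}")
        if self.kind == "true_heteroplasmy" and self.artifact_pool != "none":
            raise ValidationError("true heteroplasmy cannot carry an artifact pool")
        if self.kind == "single_strand_artifact" and self.artifact_pool not in ("A", "B"):
            raise ValidationError("artifact events need artifact_pool A or B")
        if self.kind not in ("true_heteroplasmy", "single_strand_artifact"):
            raise ValidationError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Depth and error model for one pileup simulation."""

    depth_mean: int = 30_000
    depth_min: int = 1_000
    depth_max: int = 100_000
    base_error_rate: float = 0.001
    seed: int = 0
    #: weight of the transition substitution among the three error targets;
    #: 1/3 = uniform spectrum.  Raising it emulates transition-biased noise.
    ts_error_weight: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not self.depth_min <= self.depth_mean <= self.depth_max:
            raise ConfigurationError("need depth_min <= depth_mean <= depth_max")
        if not 0.0 <= self.base_error_rate < 0.05:
            raise ConfigurationError("base_error_rate must be in [0, 0.05)")
        if not 0.0 < self.ts_error_weight < 1.0:
            raise ConfigurationError("ts_error_weight must be in (0,1)")


@dataclass
class TissueTruth:
    """Ground truth for one simulated tissue: subject + planted events."""

    profile: SubjectProfile
    tissue: str
    events: tuple[PlantedEvent, ...]


@dataclass
class StrandPileup:
    """Per-pool nucleotide counts; row ``i`` is position ``i+1`` (1-based)."""

    pool: str
    counts: np.ndarray  # shape (L, 4), columns in BASES order

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def at(self, position: int) -> tuple[int, int, int, int]:
        return tuple(int(x) for x in self.counts[position - 1])


def simulate_subject(tree: MiniHaplotree, haplogroup: str, seed: int = 0) -> SubjectProfile:
    """Build a subject whose germline is the root-to-haplogroup SNP path."""
    variants = tuple(sorted(tree.path_snps(haplogroup)))
    return SubjectProfile(
        subject_id=f"sim-{haplogroup}-{seed}",
        haplogroup=haplogroup,
        germline_variants=variants,
    )


def plant_events(
    profile: SubjectProfile,
    tissue: str,
    events: list[PlantedEvent] | tuple[PlantedEvent, ...],
    genome_length: int = 16_569,
) -> TissueTruth:
    """Attach somatic events to one tissue, keeping the truth for scoring."""
    if tissue not in TISSUES:
        raise ValidationError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    seen: set[tuple[int, str]] = set()
    for ev in events:
        if not 1 <= ev.position <= genome_length:
            raise ValidationError(f"event position {ev.position} outside 1..{genome_length}")
        key = (ev.position, ev.alt)
        if key in seen:
            raise ValidationError(f"duplicate event at {ev.position}>{ev.alt}")
        seen.add(key)
    return TissueTruth(profile=profile, tissue=tissue, events=tuple(events))


def _sample_depths(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Log-uniform depths rescaled to hit the configured mean, then clipped."""
    lo, hi = float(config.depth_min), float(config.depth_max)
    if lo == hi:
        return np.full(n, int(lo), dtype=np.int64)
    raw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    analytic_mean = (hi - lo) / (np.log(hi) - np.log(lo))
    scaled = raw * (config.depth_mean / analytic_mean)
    return np.clip(np.rint(scaled), lo, hi).astype(np.int64)


def simulate_strand_pileups(
    truth: TissueTruth,
    panel: PanelDesign,
    config: SimulationConfig,
) -> tuple[StrandPileup, StrandPileup]:
    """Simulate the two per-pool pileups for one tissue.

    Depth is drawn independently per pool and position.  Alt reads for the
    germline variants and for true heteroplasmies are binomial at their
    allele frequency in both pools; artifact alt reads are binomial in the
    artifact pool only.  Base errors then convert reference reads to each
    non-reference base.
    """
    reference = panel.reference
    L = len(reference)
    ref_idx = reference.base_indices
    rng = np.random.default_rng(config.seed)

    events: list[tuple[int, int, int, float, str]] = []  # pos0, refi, alti, maf, pool
    for pos, ref, alt in truth.profile.germline_variants:
        events.append((pos - 1, BASE_INDEX[ref], BASE_INDEX[alt], truth.profile.germline_maf, "both"))
    for ev in truth.events:
        pool = "both" if ev.kind == "true_heteroplasmy" else ev.artifact_pool
        events.append((ev.position - 1, BASE_INDEX[ev.ref], BASE_INDEX[ev.alt], ev.maf, pool))
    for pos0, refi, _alti, _maf, _pool in events:
        if ref_idx[pos0] != refi:
            raise ValidationError(
                f"event ref allele at position {pos0 + 1} disagrees with the reference "
                f"({BASES[refi]} vs {BASES[ref_idx[pos0]]})"
            )

    w_ts = config.ts_error_weight
    w_tv = (1.0 - w_ts) / 2.0
    transition_of = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T in BASES order

    pileups = []
    for pool in ("A", "B"):
        depth = _sample_depths(rng, L, config)
        counts = np.zeros((L, 4), dtype=np.int64)
        counts[np.arange(L), ref_idx] = depth

        for pos0, refi, alti, maf, ev_pool in events:
            if ev_pool not in ("both", pool):
                continue
            n_alt = rng.binomial(counts[pos0, refi], maf)
            counts[pos0, alti] += n_alt
            counts[pos0, refi] -= n_alt

        if config.base_error_rate > 0.0:
            ref_reads = counts[np.arange(L), ref_idx]
            for k in (1, 2, 3):
                target = (ref_idx + k) % 4
                weight = np.where(target == np.array([transition_of[i] for i in range(4)])[ref_idx], w_ts, w_tv)
                errs = rng.binomial(ref_reads, config.base_error_rate * weight)
                counts[np.arange(L), target] += errs
                counts[np.arange(L), ref_idx] -= errs
        np.maximum(counts, 0, out=counts)
        pileups.append(StrandPileup(pool=pool, counts=counts))
    return pileups[0], pileups[1]


def simulate_cohort_presence(
    group_sizes: dict[str, int],
    carrier_prob: dict[tuple[str, tuple[int, str, str]], float],
    seed: int = 0,
) -> "dict[str, int | dict]":
    """Draw per-group carrier counts for a set of SNPs.

    Returns a plain mapping compatible with
    :class:`mtduplex.cohort_stats.CohortPresence` construction: carrier
    counts are independent binomial draws ``Binom(n_group, p)``.
    """
    rng = np.random.default_rng(seed)
    carriers: dict[tuple[str, tuple[int, str, str]], int] = {}
    for (group, snp), p in sorted(carrier_prob.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        if group not in group_sizes:
            raise ValidationError(f"unknown group {group!r}")
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"carrier probability out of [0,1]: {p}")
        carriers[(group, snp)] = int(rng.binomial(group_sizes[group], p))
    return {"groups": dict(group_sizes), "carriers": carriers}


def write_pileup_tsv(pileups: tuple[StrandPileup, StrandPileup], path: str | Path) -> None:
    """Serialize both pools as TSV (pool, position, nA, nC, nG, nT)."""
    with open(path, "w") as fh:
        fh.write("pool\tposition\tnA\tnC\tnG\tnT\n")
        for pu in pileups:
            for pos0 in range(pu.counts.shape[0]):
                a, c, g, t = pu.counts[pos0]
                fh.write(f"{pu.pool}\t{pos0 + 1}\t{a}\t{c}\t{g}\t{t}\n")


def read_pileup_tsv(path: str | Path, genome_length: int) -> tuple[StrandPileup, StrandPileup]:
    arrays = {"A": np.zeros((genome_length, 4), dtype=np.int64),
              "B": np.zeros((genome_length, 4), dtype=np.int64)}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pool\t"):
            raise ValidationError("pileup TSV missing header")
        for line in fh:
            pool, pos, a, c, g, t = line.rstrip("\n").split("\t")
            arrays[pool][int(pos) - 1] = [int(a), int(c), int(g), int(t)]
    return StrandPileup("A", arrays["A"]), StrandPileup("B", arrays["B"])


def write_truth_tsv(truths: list[TissueTruth], path: str | Path) -> None:
    """Serialize ground truth (subject, tissue, position, ref, alt, maf, kind, pool)."""
    with open(path, "w") as fh:
        fh.write("subject\ttissue\tposition\tref\talt\tmaf\tkind\tpool\n")
        for tr in truths:
            for pos, ref, alt in tr.profile.germline_variants:
                fh.write(f"{tr.profile.subject_id}\t{tr.tissue}\t{pos}\t{ref}\t{alt}\t"
                         f"{tr.profile.germline_maf}\tgermline\tboth\n")
            for ev in tr.events:
                pool = "both" if ev.kind == "true_heteroplasmy" else ev.artifact_pool
                fh.write(f"{tr.profile.subject_id}\t{tr.tissue}\t{ev.position}\t{ev.ref}\t"
                         f"{ev.alt}\t{ev.maf}\t{ev.kind}\t{pool}\n")
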