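"""Per-pool variant calling from strand pileups.

A deliberately minimal caller: for every non-reference base observed at a
position it tests the alt count against a uniform sequencing-error model
with a one-sided binomial tail, converts the tail probability to a
Phred-scaled quality capped at 100, and applies frequency / depth / quality
thresholds.  Candidates at half the frequency floor and above are emitted
with explanatory filter flags rather than dropped, so the downstream
concordance stage can account for every near-threshold observation.

Only substitutions are called; each alt allele at a position is an
independent record (multi-allelic sites produce one record per alt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .reference_panel import BASES, MtReference
from .synthetic_data import StrandPileup

MAX_QUAL = 100.0


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the per-pool caller.

    ``min_maf`` (default 1%) is the reporting floor of the assay;
    candidates down to ``min_maf / 2`` are kept with a ``low_maf`` flag.
    ``error_rate`` is the total substitution error rate per read base; a
    specific alt base receives ``error_rate / 3`` of it (uniform spectrum).
    """

    min_maf: float = 0.01
    min_depth: int = 1_000
    min_qual: float = 30.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.min_maf < 1.0:
            raise ConfigurationError("min_maf must be in (0,1)")
        if self.min_depth < 1:
            raise ConfigurationError("min_depth must be >= 1")
        if not 0.0 < self.error_rate < 1.0:
            raise ConfigurationError("error_rate must be in (0,1)")


@dataclass(frozen=True)
class StrandVariantCall:
    """One candidate substitution call in one pool."""

    pool: str
    position: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    frequency: float
    qual: float
    filter: str  # PASS | low_maf | low_depth | low_qual


def binomial_tail(alt_count: int, depth: int, error_rate: float) -> float:
    """P[X >= alt_count] for X ~ Binomial(depth, error_rate / 3).

    The upper tail of the per-base error model: the probability that random
    sequencing error alone produces at least the observed alt count.  For
    very large counts the tail underflows double precision; the smallest
    positive float is returned so the value stays in (0, 1].
    """
    if not 0 <= alt_count <= depth:
        raise ValidationError(f"alt_count {alt_count} outside 0..{depth}")
    if alt_count == 0:
        return 1.0
    p = stats.binom.sf(alt_count - 1, depth, error_rate / 3.0)
    return float(p) if p > 0.0 else math.ulp(0.0)


def _phred_from_logsf(log_sf: float) -> float:
    """Phred-scale a natural-log tail probability, capped at 100."""
    if not np.isfinite(log_sf):
        return MAX_QUAL
    return float(min(MAX_QUAL, -10.0 * log_sf / math.log(10.0)))


def call_pool_variants(
    pileup: StrandPileup,
    reference: MtReference,
    config: CallerConfig | None = None,
) -> list[StrandVariantCall]:
    """Call candidate substitutions in one pool.

    One record per (position, alt) with ``alt_count > 0`` and frequency at
    least ``min_maf / 2``.  PASS requires frequency >= min_maf, depth >=
    min_depth and qual >= min_qual; failing candidates carry the first
    failing filter (depth, then frequency, then quality).
    """
    config = config or CallerConfig()
    L = len(reference)
    if pileup.counts.shape != (L, 4):
        raise ValidationError(
            f"pileup shape {pileup.counts.shape} does not match reference length {L}"
        )
    counts = pileup.counts
    depth = counts.sum(axis=1)
    ref_idx = reference.base_indices

    alt_mask = np.ones_like(counts, dtype=bool)
    alt_mask[np.arange(L), ref_idx] = False
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth[:, None] > 0, counts / np.maximum(depth, 1)[:, None], 0.0)
    candidate = alt_mask & (counts > 0) & (freq >= config.min_maf / 2.0)

    calls: list[StrandVariantCall] = []
    pos0s, base_is = np.nonzero(candidate)
    if len(pos0s):
        log_sf = stats.binom.logsf(
            counts[pos0s, base_is] - 1, depth[pos0s], config.error_rate / 3.0
        )
    for i, (pos0, bi) in enumerate(zip(pos0s, base_is)):
        d = int(depth[pos0])
        k = int(counts[pos0, bi])
        f = k / d
        qual = _phred_from_logsf(float(log_sf[i]))
        if d < config.min_depth:
            flt = "low_depth"
        elif f < config.min_maf:
            flt = "low_maf"
        elif qual < config.min_qual:
            flt = "low_qual"
        else:
            flt = "PASS"
        calls.append(
            StrandVariantCall(
                pool=pileup.pool,
                position=int(pos0) + 1,
                ref=BASES[ref_idx[pos0]],
                alt=BASES[bi],
                alt_count=k,
                depth=d,
                frequency=f,
                qual=qual,
                filter=flt,
            )
        )
    calls.sort(key=lambda c: (c.position, c.alt))
    return calls
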