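"""Duplex concordance: the core filtering rule of the dual-strand design.

The two primer pools sequence opposite strands of the mitochondrial circle.
Real variants exist on both strands, so they are observed by both pools;
DNA-modification artifacts (e.g. post-extraction cytosine deamination) live
on one strand and appear in one pool only.  Intersecting the per-pool call
sets therefore separates true variants from artifacts without any error
model beyond the per-pool caller's.

Three stringency modes:

* strict (default): a true variant must PASS in both pools;
* lenient: PASS in one pool plus a sub-threshold candidate (frequency >=
  min_maf/2) in the other;
* presence (``require_pass=False``): any candidate record in both pools —
  the literal both-strand-presence rule, used for detection-limit studies
  where a hard PASS threshold at the target frequency would censor
  borderline events.

The combined frequency of a true variant is the depth-weighted mean of the
two pool frequencies (the minimum-variance combination of two binomial
estimates); ``combine="min"`` gives the conservative alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataConsistencyError, ValidationError
from .strand_caller import StrandVariantCall


@dataclass(frozen=True)
class TrueVariant:
    """A variant confirmed on both strands."""

    position: int
    ref: str
    alt: str
    freq_A: float
    freq_B: float
    depth_A: int
    depth_B: int
    combined_freq: float

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


@dataclass(frozen=True)
class RejectedArtifact:
    """A candidate rejected by the duplex rule, with the reason."""

    position: int
    ref: str
    alt: str
    pool_seen: str
    frequency: float
    reason: str


def _combined(freq_a: float, freq_b: float, depth_a: int, depth_b: int, how: str) -> float:
    if how == "weighted_mean":
        return (freq_a * depth_a + freq_b * depth_b) / (depth_a + depth_b)
    if how == "min":
        return min(freq_a, freq_b)
    raise ValidationError(f"unknown combine mode {how!r}")


def concord(
    calls_A: list[StrandVariantCall],
    calls_B: list[StrandVariantCall],
    require_pass: bool = True,
    lenient: bool = False,
    combine: str = "weighted_mean",
) -> tuple[list[TrueVariant], list[RejectedArtifact]]:
    """Intersect the two pools' calls into true variants and artifacts.

    Every distinct (position, ref, alt) key across both inputs lands in
    exactly one of the two output lists.  Conflicting reference alleles for
    the same position across pools indicate corrupt pileups and raise
    :class:`DataConsistencyError`.
    """
    by_key: dict[tuple[int, str, str], dict[str, StrandVariantCall]] = {}
    ref_at: dict[int, str] = {}
    for call in list(calls_A) + list(calls_B):
        if call.pool not in ("A", "B"):
            raise ValidationError(f"unknown pool {call.pool!r}")
        prev = ref_at.setdefault(call.position, call.ref)
        if prev != call.ref:
            raise DataConsistencyError(
                f"conflicting reference alleles at position {call.position}: "
                f"{prev} vs {call.ref}"
            )
        slot = by_key.setdefault((call.position, call.ref, call.alt), {})
        if call.pool in slot:
            raise ValidationError(
                f"duplicate call for {call.position}{call.ref}>{call.alt} in pool {call.pool}"
            )
        slot[call.pool] = call

    true_variants: list[TrueVariant] = []
    artifacts: list[RejectedArtifact] = []
    for key in sorted(by_key):
        slot = by_key[key]
        a, b = slot.get("A"), slot.get("B")
        if a is not None and b is not None:
            if require_pass:
                n_pass = (a.filter == "PASS") + (b.filter == "PASS")
                accept = n_pass == 2 or (lenient and n_pass == 1)
            else:
                accept = True
            if accept:
                true_variants.append(
                    TrueVariant(
                        position=key[0],
                        ref=key[1],
                        alt=key[2],
                        freq_A=a.frequency,
                        freq_B=b.frequency,
                        depth_A=a.depth,
                        depth_B=b.depth,
                        combined_freq=_combined(
                            a.frequency, b.frequency, a.depth, b.depth, combine
                        ),
                    )
                )
                continue
            # present in both pools but failing the stringency requirement:
            # report under the pool with the stronger evidence
            best = a if (a.filter == "PASS", a.frequency) >= (b.filter == "PASS", b.frequency) else b
            artifacts.append(
                RejectedArtifact(
                    position=key[0],
                    ref=key[1],
                    alt=key[2],
                    pool_seen=best.pool,
                    frequency=best.frequency,
                    reason="present in both pools but below PASS stringency "
                    f"(filters A={a.filter}, B={b.filter})",
                )
            )
        else:
            seen = a if a is not None else b
            assert seen is not None
            other = "B" if seen.pool == "A" else "A"
            artifacts.append(
                RejectedArtifact(
                    position=key[0],
                    ref=key[1],
                    alt=key[2],
                    pool_seen=seen.pool,
                    frequency=seen.frequency,
                    reason=f"absent from pool {other}: single-strand observation "
                    "(DNA-modification artifact signature)",
                )
            )
    return true_variants, artifacts
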