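"""Cross-sample aggregation of heteroplasmy variants.

Works on a long-format heteroplasmy table: one row per
(SNP, subject, tissue) with the observed allele frequency.  Provides the
per-tissue burden summary, recurrence-based hot-spot detection (a hot-spot
is a heteroplasmy SNP seen in at least ``min_subjects`` distinct subjects,
in any tissue), the blood-only filter, and allele-frequency band histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

TABLE_COLUMNS = ["position", "ref", "alt", "subject", "tissue", "frequency"]

#: Optional exclusion preset for the homopolymeric C tract of the control
#: region (rCRS 302-316), whose length-variation alignments make per-base
#: calls there unreliable.
POLY_C_TRACT = (302, 316)


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"heteroplasmy table missing columns {missing}")
    return table


@dataclass
class TissueCountSummary:
    """Heteroplasmy burden per subject and tissue."""

    counts: pd.DataFrame          # index subject, columns tissue, values row counts
    tissue_totals: pd.Series      # per-tissue totals across subjects
    tissue_shares: pd.Series      # per-tissue share of all rows, percent
    total: int


@dataclass(frozen=True)
class HotspotRecord:
    """A recurrent heteroplasmy SNP and where it was seen."""

    position: int
    ref: str
    alt: str
    n_subjects: int
    frequencies: tuple[tuple[str, str, float], ...]  # (subject, tissue, freq)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


def tissue_counts(table: pd.DataFrame) -> TissueCountSummary:
    """Count heteroplasmy rows per (subject, tissue) and per-tissue shares."""
    _check_table(table)
    if table.empty:
        empty = pd.DataFrame()
        return TissueCountSummary(
            counts=empty,
            tissue_totals=pd.Series(dtype=int),
            tissue_shares=pd.Series(dtype=float),
            total=0,
        )
    counts = (
        table.groupby(["subject", "tissue"]).size().unstack(fill_value=0).sort_index()
    )
    totals = counts.sum(axis=0)
    total = int(totals.sum())
    shares = 100.0 * totals / total
    return TissueCountSummary(
        counts=counts, tissue_totals=totals, tissue_shares=shares, total=total
    )


def detect_hotspots(
    table: pd.DataFrame,
    min_subjects: int = 2,
    excluded_regions: list[tuple[int, int]] | None = None,
) -> list[HotspotRecord]:
    """SNPs heteroplasmic in at least ``min_subjects`` distinct subjects.

    Subject counting is tissue-agnostic: a subject counts once no matter how
    many of its tissues carry the SNP.  ``excluded_regions`` is a list of
    1-based inclusive intervals (e.g. ``[POLY_C_TRACT]``) removed before
    counting.  Results are sorted by position.
    """
    _check_table(table)
    if min_subjects < 1:
        raise ValidationError("min_subjects must be >= 1")
    excluded_regions = excluded_regions or []
    if table.empty:
        return []
    df = table
    for lo, hi in excluded_regions:
        df = df[(df["position"] < lo) | (df["position"] > hi)]
    records = []
    for (pos, ref, alt), grp in df.groupby(["position", "ref", "alt"]):
        n = grp["subject"].nunique()
        if n >= min_subjects:
            freqs = tuple(
                (row.subject, row.tissue, float(row.frequency))
                for row in grp.sort_values(["subject", "tissue"]).itertuples()
            )
            records.append(
                HotspotRecord(position=int(pos), ref=ref, alt=alt, n_subjects=int(n), frequencies=freqs)
            )
    records.sort(key=lambda r: (r.position, r.alt))
    return records


def blood_only_snps(
    table: pd.DataFrame, require_all_subjects: bool = True
) -> list[tuple[int, str, str]]:
    """SNPs heteroplasmic in blood and never in retina or RPE+choroid.

    With ``require_all_subjects`` (default) the SNP must additionally be in
    the blood of *every* subject in the table — the reading under which the
    published blood-only list is reproducible.
    """
    _check_table(table)
    if table.empty:
        return []
    subjects = set(table["subject"].unique())
    out = []
    for (pos, ref, alt), grp in table.groupby(["position", "ref", "alt"]):
        tissues = set(grp["tissue"])
        if tissues - {"blood"}:
            continue
        blood_subjects = set(grp.loc[grp["tissue"] == "blood", "subject"])
        if require_all_subjects and blood_subjects != subjects:
            continue
        out.append((int(pos), ref, alt))
    return sorted(out)


def maf_band_histogram(
    table: pd.DataFrame, band_edges: list[float] | tuple[float, ...]
) -> pd.Series:
    """Row counts per half-open frequency band [lo, hi).

    ``band_edges`` are strictly increasing values in (0, 1]; consecutive
    pairs form the bands.
    """
    _check_table(table)
    edges = list(band_edges)
    if len(edges) < 2:
        raise ValidationError("need at least two band edges")
    if any(not 0.0 < e <= 1.0 for e in edges) or any(
        b <= a for a, b in zip(edges, edges[1:])
    ):
        raise ValidationError("band edges must be strictly increasing within (0,1]")
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges, edges[1:])]
    freqs = table["frequency"].to_numpy()
    counts = [
        int(np.sum((freqs >= lo) & (freqs < hi))) for lo, hi in zip(edges, edges[1:])
    ]
    return pd.Series(counts, index=labels, name="count")
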