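"""Variant classification: zygosity, category, substitution class, haplogroup.

A sample's homoplasmies (allele frequency at or near 100%) are inherited and
define its maternal haplogroup; low-frequency variants are somatic
heteroplasmies.  Substitutions partition into transitions (within purines,
A<->G, or within pyrimidines, C<->T; the replication-error signature) and
transversions (purine <-> pyrimidine; the oxidative-damage signature).

Haplogroup assignment here is a deliberately small scorer over a packaged
mini phylogeny, not a reimplementation of Haplogrep/Phylotree: each node is
scored with a Kulczynski-style symmetric match fraction between the sample's
homoplasmy set and the node's root-path defining SNPs, and the best-scoring
node wins.  The packaged tree contains the I1a1b, H7b and U2e2a1 paths; the
fixture tests pin those three labels so the simplification is audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .errors import ConfigurationError, HaplogroupLookupError, ValidationError

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

SnpKey = tuple[int, str, str]


def parse_snp(label: str) -> SnpKey:
    """Parse ``"73A>G"`` / ``"m.73A>G"`` into ``(73, "A", "G")``."""
    s = label.removeprefix("m.").replace(" ", "")
    i = 0
    while i < len(s) and s[i].isdigit():
        i += 1
    pos, rest = s[:i], s[i:]
    if not pos or len(rest) != 3 or rest[1] != ">":
        raise ValidationError(f"cannot parse SNP label {label!r}")
    return int(pos), rest[0], rest[2]


def format_snp(key: SnpKey) -> str:
    return f"m.{key[0]}{key[1]}>{key[2]}"


@dataclass(frozen=True)
class ZygosityThresholds:
    """Frequency cut-offs for zygosity and the low-frequency reporting flag.

    ``homoplasmy_min`` defaults to 0.85: observed homoplasmies sit at
    >= 89.5% and heteroplasmies at <= 60.4%, and 85-90% is the heteroplasmy
    load at which point mutations start to affect cellular function, so 0.85
    separates the two regimes cleanly.  ``low_frequency_max`` (0.40) is a
    reporting flag for the "<40% heteroplasmy" analyses, not part of the
    heteroplasmy definition.
    """

    homoplasmy_min: float = 0.85
    low_frequency_max: float = 0.40

    def __post_init__(self) -> None:
        if not 0.0 < self.low_frequency_max < self.homoplasmy_min <= 1.0:
            raise ConfigurationError("need 0 < low_frequency_max < homoplasmy_min <= 1")


@dataclass(frozen=True)
class AnnotationRecord:
    """One row of the packaged hot-spot annotation fixture."""

    position: int
    ref: str
    alt: str
    locus_type: str
    locus: str
    aa_change: str
    rs_id: str
    pathogenicity_note: str

    @property
    def key(self) -> SnpKey:
        return (self.position, self.ref, self.alt)


@dataclass(frozen=True)
class ClassifiedVariant:
    """A duplex-confirmed variant with its classification labels."""

    position: int
    ref: str
    alt: str
    freq_A: float
    freq_B: float
    depth_A: int
    depth_B: int
    combined_freq: float
    zygosity: str
    category: str
    mutation_class: str
    low_frequency_flag: bool

    @property
    def key(self) -> SnpKey:
        return (self.position, self.ref, self.alt)


class MiniHaplotree:
    """A small rooted haplogroup tree: label -> (parent, defining SNPs)."""

    def __init__(self, nodes: dict[str, tuple[str | None, list[SnpKey]]]):
        if not nodes:
            raise ConfigurationError("empty haplogroup tree")
        roots = [k for k, (parent, _) in nodes.items() if parent is None]
        if len(roots) != 1:
            raise ConfigurationError(f"tree must have exactly one root, found {roots}")
        self.nodes = nodes
        self.root = roots[0]
        self._paths: dict[str, frozenset[SnpKey]] = {}
        for label in nodes:
            chain: list[str] = []
            cur: str | None = label
            seen = set()
            while cur is not None:
                if cur in seen:
                    raise ConfigurationError(f"cycle in haplogroup tree at {cur}")
                seen.add(cur)
                chain.append(cur)
                cur = nodes[cur][0]
            snps: set[SnpKey] = set()
            for node in chain:
                snps.update(nodes[node][1])
            self._paths[label] = frozenset(snps)

    def labels(self) -> list[str]:
        return sorted(self.nodes)

    def depth(self, label: str) -> int:
        d, cur = 0, label
        while self.nodes[cur][0] is not None:
            cur = self.nodes[cur][0]
            d += 1
        return d

    def path_snps(self, label: str) -> frozenset[SnpKey]:
        """Union of defining SNPs on the root -> label path."""
        if label not in self._paths:
            raise HaplogroupLookupError(f"unknown haplogroup {label!r}")
        return self._paths[label]


def load_packaged_tree() -> MiniHaplotree:
    """The packaged mini haplogroup tree (paths for I1a1b, H7b, U2e2a1)."""
    raw = json.loads(
        resources.files("mtduplex.data").joinpath("mini_haplotree.json").read_text()
    )
    nodes = {
        label: (entry["parent"], [parse_snp(s) for s in entry["snps"]])
        for label, entry in raw.items()
    }
    return MiniHaplotree(nodes)


def classify_substitution(ref: str, alt: str) -> str:
    """``"transition"`` iff {ref, alt} is {A,G} or {C,T}, else ``"transversion"``."""
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValidationError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref and alt are identical: {ref}")
    pair = {ref, alt}
    return "transition" if pair in (set(PURINES), set(PYRIMIDINES)) else "transversion"


def classify_zygosity(
    combined_freq: float, thresholds: ZygosityThresholds | None = None
) -> str:
    """``"homoplasmy"`` iff frequency >= ``homoplasmy_min`` (inclusive)."""
    thresholds = thresholds or ZygosityThresholds()
    if not 0.0 < combined_freq <= 1.0:
        raise ValidationError(f"frequency out of (0,1]: {combined_freq}")
    return "homoplasmy" if combined_freq >= thresholds.homoplasmy_min else "heteroplasmy"


def assign_haplogroup(
    homoplasmies: set[SnpKey], tree: MiniHaplotree
) -> tuple[str, float]:
    """Best-matching haplogroup for a homoplasmy set, with its match score.

    Score per node = 1/2 * (matched/expected_on_path + matched/observed),
    a symmetric (Kulczynski) match fraction penalising both missing expected
    SNPs and unexplained observed ones.  Ties break toward the shallowest
    node, then lexicographically.  An empty homoplasmy set returns the root.
    """
    observed = set(homoplasmies)
    best: tuple[float, int, str] | None = None
    for label in tree.labels():
        path = tree.path_snps(label)
        matched = len(observed & path)
        if path:
            term_expected = matched / len(path)
        else:
            term_expected = 1.0 if not observed else 0.0
        if observed:
            term_observed = matched / len(observed)
        else:
            term_observed = 1.0 if not path else 0.0
        score = 0.5 * (term_expected + term_observed)
        cand = (-score, tree.depth(label), label)
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best[2], -best[0]


def categorize_variant(
    key: SnpKey,
    haplogroup_path_snps: frozenset[SnpKey] | set[SnpKey],
    annotation_db: set[SnpKey],
) -> str:
    """haplogroup_defining > private (known to the DB) > unique (novel).

    "Unique" is relative to the packaged annotation fixture — no live
    database lookup is performed.
    """
    if key in haplogroup_path_snps:
        return "haplogroup_defining"
    if key in annotation_db:
        return "private"
    return "unique"


def classify_variants(
    true_variants,
    tree: MiniHaplotree,
    annotation_db: set[SnpKey],
    thresholds: ZygosityThresholds | None = None,
) -> tuple[list[ClassifiedVariant], str, float]:
    """Classify a sample's duplex-confirmed variants end to end.

    Assigns the haplogroup from the sample's homoplasmies, then labels every
    variant.  Returns (classified variants, haplogroup label, score).
    """
    thresholds = thresholds or ZygosityThresholds()
    homoplasmies = {
        (v.position, v.ref, v.alt)
        for v in true_variants
        if classify_zygosity(v.combined_freq, thresholds) == "homoplasmy"
    }
    label, score = assign_haplogroup(homoplasmies, tree)
    path = tree.path_snps(label)
    out = []
    for v in sorted(true_variants, key=lambda v: (v.position, v.alt)):
        zyg = classify_zygosity(v.combined_freq, thresholds)
        out.append(
            ClassifiedVariant(
                position=v.position,
                ref=v.ref,
                alt=v.alt,
                freq_A=v.freq_A,
                freq_B=v.freq_B,
                depth_A=v.depth_A,
                depth_B=v.depth_B,
                combined_freq=v.combined_freq,
                zygosity=zyg,
                category=categorize_variant((v.position, v.ref, v.alt), path, annotation_db),
                mutation_class=classify_substitution(v.ref, v.alt),
                low_frequency_flag=v.combined_freq < thresholds.low_frequency_max,
            )
        )
    return out, label, score


def tstv_summary(variants) -> "pandas.DataFrame":
    """Transition/transversion counts per (subject, tissue) group.

    ``variants`` is an iterable of records with ``subject``, ``tissue``,
    ``ref``, ``alt`` attributes or a DataFrame with those columns; intended
    for heteroplasmy variants (filter upstream).
    """
    import pandas as pd

    if not isinstance(variants, pd.DataFrame):
        variants = pd.DataFrame(
            [
                {"subject": v.subject, "tissue": v.tissue, "ref": v.ref, "alt": v.alt}
                for v in variants
            ]
        )
    if variants.empty:
        return pd.DataFrame(columns=["subject", "tissue", "n_transition", "n_transversion"])
    df = variants.copy()
    df["mutation_class"] = [
        classify_substitution(r, a) for r, a in zip(df["ref"], df["alt"])
    ]
    counts = (
        df.groupby(["subject", "tissue"])["mutation_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["transition", "transversion"], fill_value=0)
        .reset_index()
        .rename(columns={"transition": "n_transition", "transversion": "n_transversion"})
    )
    counts.columns.name = None
    return counts
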