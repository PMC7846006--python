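"""Packaged transcriptions of the published summary tables.

The package ships five small TSV fixtures — the per-subject SNP totals, the
homoplasmy table, the full heteroplasmy table, the hot-spot annotation
table, and the 222-subject cohort carrier counts — so the whole reporting
pipeline can run without any download.  Values are preserved exactly as
printed, including the known internal inconsistencies of the source tables
(documented in ``docs/methods.md``); each file is checksummed and verified
on load.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .cohort_stats import CohortPresence
from .errors import IntegrityError
from .variant_classification import AnnotationRecord, SnpKey

FIXTURE_FILES = {
    "table2": "table2_total_snps.tsv",
    "table3": "table3_homoplasmy.tsv",
    "table5": "table5_heteroplasmy.tsv",
    "table7": "table7_annotations.tsv",
    "table8": "table8_cohort.tsv",
}

SUBJECTS = ("S1", "S2", "S3")
TISSUES = ("blood", "rpe_choroid", "retina")

#: Expected per-column heteroplasmy totals of the shipped table5 fixture
#: (S1 35/8/9, S2 135/5/8, S3 167/32/3).  Note the printed summary table
#: says 165 for S3 blood while the printed full table contains 167 entries;
#: the fixture preserves the full table as printed.
TABLE5_COLUMN_TOTALS = (35, 8, 9, 135, 5, 8, 167, 32, 3)

_EXPECTED_SHAPES = {
    "table2": (4, 5),
    "table3": (59, 12),
    "table5": (191, 12),
    "table7": (21, 9),
    "table8": (21, 7),
}


def _data_bytes(filename: str) -> bytes:
    return resources.files("mtduplex.data").joinpath(filename).read_bytes()


def _verify_checksum(filename: str) -> None:
    sums = json.loads(_data_bytes("checksums.json"))
    digest = hashlib.sha256(_data_bytes(filename)).hexdigest()
    if sums.get(filename) != digest:
        raise IntegrityError(f"checksum mismatch for packaged fixture {filename}")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged table by name (``table2``/``table3``/``table5``/``table7``/``table8``)."""
    if name not in FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURE_FILES)}")
    filename = FIXTURE_FILES[name]
    _verify_checksum(filename)
    with resources.as_file(resources.files("mtduplex.data").joinpath(filename)) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    if df.shape != _EXPECTED_SHAPES[name]:
        raise IntegrityError(
            f"fixture {name} has shape {df.shape}, expected {_EXPECTED_SHAPES[name]}"
        )
    return df


def _freq_columns(subject: str) -> dict[str, str]:
    prefix = subject.lower()
    return {
        f"{prefix}_blood": "blood",
        f"{prefix}_rpe_choroid": "rpe_choroid",
        f"{prefix}_retina": "retina",
    }


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for subject in SUBJECTS:
        for col, tissue in _freq_columns(subject).items():
            sel = df[df[col].notna()]
            for r in sel.itertuples():
                rows.append(
                    {
                        "position": int(r.position),
                        "ref": r.ref,
                        "alt": r.alt,
                        "subject": subject,
                        "tissue": tissue,
                        "frequency": float(getattr(r, col)) / 100.0,
                    }
                )
    return pd.DataFrame(rows, columns=["position", "ref", "alt", "subject", "tissue", "frequency"])


def heteroplasmy_table() -> pd.DataFrame:
    """The heteroplasmy fixture in long format (frequencies as fractions)."""
    return _wide_to_long(load_fixture("table5"))


def homoplasmy_table() -> pd.DataFrame:
    """The homoplasmy fixture in long format (frequencies as fractions)."""
    return _wide_to_long(load_fixture("table3"))


def homoplasmy_sets() -> dict[tuple[str, str], set[SnpKey]]:
    """Per (subject, tissue) homoplasmy SNP-key sets from the fixture."""
    long = homoplasmy_table()
    out: dict[tuple[str, str], set[SnpKey]] = {
        (s, t): set() for s in SUBJECTS for t in TISSUES
    }
    for r in long.itertuples():
        out[(r.subject, r.tissue)].add((r.position, r.ref, r.alt))
    return out


def annotation_records() -> list[AnnotationRecord]:
    """The hot-spot annotation fixture as records."""
    df = load_fixture("table7").fillna("")
    return [
        AnnotationRecord(
            position=int(r.position),
            ref=r.ref,
            alt=r.alt,
            locus_type=str(r.locus_type),
            locus=str(r.locus),
            aa_change=str(r.aa_change),
            rs_id=str(r.rs_id),
            pathogenicity_note=str(r.pathogenicity_note),
        )
        for r in df.itertuples()
    ]


def annotation_db() -> set[SnpKey]:
    """Known-SNP keys: annotation fixture plus every homoplasmy-table SNP.

    "Unique" classifications are relative to this packaged set.
    """
    keys = {rec.key for rec in annotation_records()}
    t3 = load_fixture("table3")
    keys |= {(int(r.position), r.ref, r.alt) for r in t3.itertuples()}
    return keys


def cohort_presence() -> CohortPresence:
    """The 222-subject cohort fixture (young_nl 83, old_nl 66, old_amd 73)."""
    df = load_fixture("table8")
    groups = {"young_nl": 83, "old_nl": 66, "old_amd": 73}
    carriers: dict[tuple[str, SnpKey], int] = {}
    for r in df.itertuples():
        snp = (int(r.position), r.ref, r.alt)
        carriers[("young_nl", snp)] = int(r.young_nl)
        carriers[("old_nl", snp)] = int(r.old_nl)
        carriers[("old_amd", snp)] = int(r.old_amd)
    return CohortPresence(groups=groups, carriers=carriers)


def total_snp_counts() -> pd.DataFrame:
    """Per-subject total SNP counts fixture (subjects + Total row)."""
    return load_fixture("table2")
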