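"""Pipeline configuration and stage composition.

``run_pipeline`` drives the full chain on simulated subjects:
simulate -> call -> concord -> classify -> aggregate -> stats, writing one
VCF per sample plus cohort-style summary TSVs.  ``reproduce_paper`` runs
the reporting stages on the packaged fixture tables instead of simulated
data, emitting the tissue-count, group-comparison and transition/
transversion summaries.

Every output is a pure function of (config, seed); the run log records the
seed and a config hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .cohort_stats import compare_groups, tissue_count_ttest
from .duplex_concordance import concord
from .errors import ConfigurationError, UndefinedStatisticError
from .hotspot_analysis import blood_only_snps, detect_hotspots, maf_band_histogram, tissue_counts
from .reference_panel import design_panel, load_packaged_reference, load_reference
from .strand_caller import CallerConfig, call_pool_variants
from .synthetic_data import (
    TISSUES,
    PlantedEvent,
    SimulationConfig,
    plant_events,
    simulate_strand_pileups,
    simulate_subject,
)
from .variant_classification import (
    ZygosityThresholds,
    assign_haplogroup,
    classify_variants,
    load_packaged_tree,
    tstv_summary,
)
from .vcfio import write_artifacts_tsv, write_variants_vcf

logger = logging.getLogger("mtduplex")

DEFAULT_GROUP_PAIRS = [("young_nl", "old_nl"), ("young_nl", "old_amd"), ("old_nl", "old_amd")]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; YAML round-trippable."""

    reference_path: str | None = None  # None -> packaged reference
    n_pairs: int = 171
    min_overlap: int = 20
    # caller
    min_maf: float = 0.01
    min_depth: int = 1_000
    min_qual: float = 30.0
    error_rate: float = 0.001
    # concordance
    require_pass: bool = True
    lenient: bool = False
    combine: str = "weighted_mean"
    # classification
    homoplasmy_min: float = 0.85
    low_frequency_max: float = 0.40
    # hotspots
    min_subjects: int = 2
    exclude_poly_c: bool = False
    # cohort
    group_pairs: list = field(default_factory=lambda: [list(p) for p in DEFAULT_GROUP_PAIRS])
    # simulation
    subjects: list = field(default_factory=lambda: ["I1a1b", "H7b", "U2e2a1"])
    events_per_tissue: dict = field(
        default_factory=lambda: {"blood": 30, "rpe_choroid": 8, "retina": 4}
    )
    artifacts_per_tissue: int = 5
    maf_range: list = field(default_factory=lambda: [0.01, 0.40])
    depth_mean: int = 30_000
    depth_min: int = 1_000
    depth_max: int = 100_000
    base_error_rate: float = 0.001
    seed: int = 0
    output_dir: str = "mtduplex_out"

    def caller_config(self) -> CallerConfig:
        return CallerConfig(
            min_maf=self.min_maf,
            min_depth=self.min_depth,
            min_qual=self.min_qual,
            error_rate=self.error_rate,
        )

    def zygosity_thresholds(self) -> ZygosityThresholds:
        return ZygosityThresholds(
            homoplasmy_min=self.homoplasmy_min, low_frequency_max=self.low_frequency_max
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _plant_random_tissue_events(
    rng: np.random.Generator, reference, config: PipelineConfig, used: set[int]
) -> dict[str, list[PlantedEvent]]:
    """Random somatic events per tissue at log-uniform MAFs within range."""
    from .reference_panel import BASES

    lo, hi = config.maf_range
    out: dict[str, list[PlantedEvent]] = {}
    for tissue in TISSUES:
        events = []
        n_true = int(config.events_per_tissue.get(tissue, 0))
        for i in range(n_true + config.artifacts_per_tissue):
            while True:
                pos = int(rng.integers(1, len(reference) + 1))
                if pos not in used:
                    used.add(pos)
                    break
            ref = reference.base(pos)
            if i < n_true:
                alt = str(rng.choice([b for b in BASES if b != ref]))
                maf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                events.append(PlantedEvent(pos, ref, alt, maf, "true_heteroplasmy"))
            else:
                alt = {"C": "T", "G": "A"}.get(ref) or str(
                    rng.choice([b for b in BASES if b != ref])
                )
                maf = float(np.exp(rng.uniform(np.log(0.01), np.log(0.10))))
                events.append(
                    PlantedEvent(pos, ref, alt, maf, "single_strand_artifact", str(rng.choice(["A", "B"])))
                )
        out[tissue] = events
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the simulation pipeline end to end; returns a result bundle.

    The bundle maps stage names to their in-memory results and the output
    directory contains per-sample VCFs and the aggregated TSVs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run seed=%d config=%s", config.seed, config.digest())

    reference = (
        load_reference(config.reference_path)
        if config.reference_path
        else load_packaged_reference()
    )
    panel = design_panel(reference, config.n_pairs, config.min_overlap)
    tree = load_packaged_tree()
    caller_cfg = config.caller_config()
    thresholds = config.zygosity_thresholds()
    ann_db = fixtures.annotation_db()
    master = np.random.default_rng(config.seed)

    het_rows = []
    sample_results = {}
    truths = []
    for s_idx, haplogroup in enumerate(config.subjects, start=1):
        subject_id = f"S{s_idx}"
        profile = simulate_subject(tree, haplogroup, seed=config.seed + s_idx)
        used: set[int] = {p for p, _, _ in profile.germline_variants}
        tissue_events = _plant_random_tissue_events(master, reference, config, used)
        for tissue in TISSUES:
            truth = plant_events(profile, tissue, tissue_events[tissue], len(reference))
            truths.append(truth)
            sim_cfg = SimulationConfig(
                depth_mean=config.depth_mean,
                depth_min=config.depth_min,
                depth_max=config.depth_max,
                base_error_rate=config.base_error_rate,
                seed=int(master.integers(0, 2**31 - 1)),
            )
            pu_a, pu_b = simulate_strand_pileups(truth, panel, sim_cfg)
            calls_a = call_pool_variants(pu_a, reference, caller_cfg)
            calls_b = call_pool_variants(pu_b, reference, caller_cfg)
            true_vars, artifacts = concord(
                calls_a,
                calls_b,
                require_pass=config.require_pass,
                lenient=config.lenient,
                combine=config.combine,
            )
            classified, hg_label, hg_score = classify_variants(
                true_vars, tree, ann_db, thresholds
            )
            write_variants_vcf(classified, reference, outdir / f"{subject_id}_{tissue}.vcf")
            write_artifacts_tsv(artifacts, outdir / f"{subject_id}_{tissue}_artifacts.tsv")
            sample_results[(subject_id, tissue)] = {
                "haplogroup": hg_label,
                "haplogroup_score": hg_score,
                "n_true_variants": len(true_vars),
                "n_artifacts": len(artifacts),
            }
            for v in classified:
                if v.zygosity == "heteroplasmy":
                    het_rows.append(
                        {
                            "position": v.position,
                            "ref": v.ref,
                            "alt": v.alt,
                            "subject": subject_id,
                            "tissue": tissue,
                            "frequency": v.combined_freq,
                        }
                    )

    het_table = pd.DataFrame(
        het_rows, columns=["position", "ref", "alt", "subject", "tissue", "frequency"]
    )
    summary = tissue_counts(het_table)
    excluded = [(302, 316)] if config.exclude_poly_c else []
    hotspots = detect_hotspots(het_table, config.min_subjects, excluded)
    tstv = tstv_summary(het_table) if not het_table.empty else None

    if not het_table.empty:
        counts = summary.counts.reindex(columns=list(TISSUES), fill_value=0)
        counts.to_csv(outdir / "tissue_counts.tsv", sep="\t")
        het_table.to_csv(outdir / "heteroplasmy_table.tsv", sep="\t", index=False)
        if tstv is not None:
            tstv.to_csv(outdir / "tstv_summary.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"position": h.position, "ref": h.ref, "alt": h.alt, "n_subjects": h.n_subjects}
                for h in hotspots
            ]
        ).to_csv(outdir / "hotspots.tsv", sep="\t", index=False)

    ttest_p = None
    if not het_table.empty:
        blood = summary.counts.get("blood")
        retina = summary.counts.get("retina")
        if blood is not None and retina is not None:
            try:
                ttest_p = tissue_count_ttest(blood.to_numpy(), retina.to_numpy())
            except UndefinedStatisticError:
                ttest_p = None

    return {
        "reference": reference,
        "samples": sample_results,
        "heteroplasmy_table": het_table,
        "tissue_summary": summary,
        "hotspots": hotspots,
        "tstv": tstv,
        "blood_vs_retina_ttest_p": ttest_p,
        "truths": truths,
        "output_dir": str(outdir),
    }


def reproduce_paper(output_dir: str | Path, group_pairs=None) -> dict:
    """Run the reporting stages on the packaged fixture tables.

    Emits tissue-count, blood-only, frequency-band, transition/transversion
    and cohort-comparison summaries computed from the shipped
    transcriptions, plus per-subject haplogroup assignments from the
    homoplasmy fixture.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    group_pairs = group_pairs or DEFAULT_GROUP_PAIRS

    het = fixtures.heteroplasmy_table()
    summary = tissue_counts(het)
    summary.counts.to_csv(outdir / "table4_style_counts.tsv", sep="\t")

    tstv = tstv_summary(het)
    tstv.to_csv(outdir / "table10_style_tstv.tsv", sep="\t", index=False)

    hotspots = detect_hotspots(het, min_subjects=2)
    pd.DataFrame(
        [
            {"position": h.position, "ref": h.ref, "alt": h.alt, "n_subjects": h.n_subjects}
            for h in hotspots
        ]
    ).to_csv(outdir / "table6_style_hotspots.tsv", sep="\t", index=False)

    blood_only = blood_only_snps(het)
    bands = maf_band_histogram(het, [0.01, 0.30, 0.50, 1.0])

    cohort = fixtures.cohort_presence()
    snps = sorted({snp for (_group, snp) in cohort.carriers})
    comparisons = compare_groups(cohort, snps, list(group_pairs))
    pd.DataFrame(
        [
            {
                "snp": f"m.{c.snp[0]}{c.snp[1]}>{c.snp[2]}",
                "pair": f"{c.group_pair[0]}_vs_{c.group_pair[1]}",
                "odds_ratio": c.odds_ratio,
                "p_two_sided": c.p_two_sided,
            }
            for c in comparisons
        ]
    ).to_csv(outdir / "table9_style_comparisons.tsv", sep="\t", index=False)

    tree = load_packaged_tree()
    haplogroups = {}
    for (subject, tissue), snp_set in fixtures.homoplasmy_sets().items():
        label, _score = assign_haplogroup(snp_set, tree)
        haplogroups[(subject, tissue)] = label

    return {
        "tissue_summary": summary,
        "tstv": tstv,
        "hotspots": hotspots,
        "blood_only": blood_only,
        "maf_bands": bands,
        "comparisons": comparisons,
        "haplogroups": haplogroups,
        "output_dir": str(outdir),
    }
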