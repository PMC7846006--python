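"""Packaged fixtures, VCF round-trips and pipeline configuration I/O."""

import numpy as np
import pytest

from mtduplex import fixtures as fx
from mtduplex.errors import IntegrityError, ValidationError
from mtduplex.pipeline import PipelineConfig
from mtduplex.variant_classification import ClassifiedVariant
from mtduplex.vcfio import read_variants_vcf, write_pool_calls_vcf, write_variants_vcf
from mtduplex.strand_caller import StrandVariantCall


class TestLoadFixture:
    def test_cohort_fixture_shape_and_key_row(self):
        t8 = fx.load_fixture("table8")
        assert len(t8) == 21
        row = t8[t8.position == 4104].iloc[0]
        assert (row.young_nl, row.old_nl, row.old_amd) == (82, 50, 55)

    def test_homoplasmy_counts_per_subject(self):
        sets = fx.homoplasmy_sets()
        assert len(sets[("S1", "blood")]) == 30
        assert len(sets[("S2", "blood")]) == 3
        assert len(sets[("S3", "blood")]) == 32

    def test_heteroplasmy_fixture_column_totals(self, het_table):
        """Per-tissue totals of the shipped table are pinned; the S3 blood
        column holds 167 entries (the printed summary row says 165 — the
        full printed table disagrees with its own summary by two rows)."""
        counts = het_table.groupby(["subject", "tissue"]).size()
        expected = {
            ("S1", "blood"): 35, ("S1", "rpe_choroid"): 8, ("S1", "retina"): 9,
            ("S2", "blood"): 135, ("S2", "rpe_choroid"): 5, ("S2", "retina"): 8,
            ("S3", "blood"): 167, ("S3", "rpe_choroid"): 32, ("S3", "retina"): 3,
        }
        assert counts.to_dict() == expected

    def test_annotation_fixture(self):
        recs = fx.annotation_records()
        assert len(recs) == 21
        by_key = {r.key: r for r in recs}
        assert by_key[(5320, "C", "T")].aa_change == "Thr284Ile"
        assert by_key[(13105, "A", "G")].aa_change == "Ile257Val"
        assert by_key[(1120, "C", "T")].rs_id == "rs727505171"

    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError):
            fx.load_fixture("table99")

    def test_checksum_tamper_detected(self, monkeypatch):
        real = fx._data_bytes

        def tampered(name):
            data = real(name)
            return data + b"x" if name == fx.FIXTURE_FILES["table8"] else data

        monkeypatch.setattr(fx, "_data_bytes", tampered)
        with pytest.raises(IntegrityError):
            fx.load_fixture("table8")

    def test_frequencies_are_fractions(self, het_table):
        assert het_table.frequency.between(0, 1).all()
        assert het_table.frequency.max() < 0.7  # heteroplasmies only


class TestVcfRoundTrip:
    def _simulated_variants(self, n, reference):
        rng = np.random.default_rng(21)
        positions = np.sort(rng.choice(len(reference), size=n, replace=False) + 1)
        out = []
        for pos in positions:
            ref = reference.base(int(pos))
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fa, fb = rng.uniform(0.01, 0.99, size=2)
            da, db = rng.integers(1000, 90000, size=2)
            cf = (fa * da + fb * db) / (da + db)
            out.append(
                ClassifiedVariant(
                    position=int(pos), ref=ref, alt=str(alt),
                    freq_A=round(float(fa), 6), freq_B=round(float(fb), 6),
                    depth_A=int(da), depth_B=int(db),
                    combined_freq=round(float(cf), 6),
                    zygosity="heteroplasmy" if cf < 0.85 else "homoplasmy",
                    category=str(rng.choice(["haplogroup_defining", "private", "unique"])),
                    mutation_class=str(rng.choice(["transition", "transversion"])),
                    low_frequency_flag=bool(cf < 0.40),
                )
            )
        return out

    def test_hundred_variant_round_trip_is_field_identical(self, tmp_path, reference):
        variants = self._simulated_variants(100, reference)
        path = tmp_path / "vars.vcf"
        write_variants_vcf(variants, reference, path)
        back = read_variants_vcf(path)
        assert back == variants

    def test_empty_list_gives_header_only(self, tmp_path, reference):
        path = tmp_path / "empty.vcf"
        write_variants_vcf([], reference, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        assert f"##contig=<ID={reference.name},length=16569>" in lines
        assert all(l.startswith("#") for l in lines)
        assert read_variants_vcf(path) == []

    def test_unsorted_input_rejected(self, tmp_path, reference):
        variants = self._simulated_variants(5, reference)[::-1]
        with pytest.raises(ValidationError):
            write_variants_vcf(variants, reference, tmp_path / "x.vcf")

    def test_data_line_count(self, tmp_path, reference):
        variants = self._simulated_variants(3, reference)
        path = tmp_path / "three.vcf"
        write_variants_vcf(variants, reference, path)
        data = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(data) == 3

    def test_written_vcf_parses_with_independent_reader(self, tmp_path, reference):
        """cyvcf2 (htslib) accepts the emitted VCF and sees the same records."""
        from cyvcf2 import VCF

        variants = self._simulated_variants(20, reference)
        path = tmp_path / "check.vcf"
        write_variants_vcf(variants, reference, path)
        seen = [
            (rec.POS, rec.REF, rec.ALT[0], rec.INFO["AF"], rec.INFO["ZYG"])
            for rec in VCF(str(path))
        ]
        assert seen == [
            (v.position, v.ref, v.alt, pytest.approx(v.combined_freq, rel=1e-5), v.zygosity)
            for v in variants
        ]

    def test_pool_calls_vcf_has_filters_and_info(self, tmp_path, reference):
        calls = [
            StrandVariantCall("A", 100, reference.base(100),
                              "T" if reference.base(100) != "T" else "C",
                              300, 30000, 0.01, 100.0, "PASS"),
            StrandVariantCall("A", 200, reference.base(200),
                              "G" if reference.base(200) != "G" else "A",
                              150, 30000, 0.005, 100.0, "low_maf"),
        ]
        path = tmp_path / "pool.vcf"
        write_pool_calls_vcf(calls, reference, path)
        text = path.read_text()
        assert "POOL=A" in text and "low_maf" in text and "##FILTER=<ID=low_maf" in text


class TestPipelineConfig:
    def test_yaml_round_trip_identity(self, tmp_path):
        cfg = PipelineConfig(seed=42, min_maf=0.02, subjects=["H7b"], exclude_poly_c=True)
        path = tmp_path / "cfg.yaml"
        cfg.save(path)
        assert PipelineConfig.load(path) == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("bogus_key: 1\n")
        from mtduplex.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            PipelineConfig.load(path)

    def test_digest_stable_and_sensitive(self):
        a, b = PipelineConfig(seed=1), PipelineConfig(seed=2)
        assert a.digest() == PipelineConfig(seed=1).digest()
        assert a.digest() != b.digest()
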