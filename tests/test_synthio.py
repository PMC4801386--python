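import dataclasses

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from sialoquant import synthio
from sialoquant.errors import ConfigurationError, InputError
from sialoquant.readmap import LIBRARIES
from sialoquant.synthio import SyntheticConfig, generate_cds_set, synthesize_reads


def _single_class_config(cls, **kwargs):
    proportions = {c: 0.0 for c in synthio.CLASSES}
    proportions[cls] = 1.0
    return SyntheticConfig(class_proportions=proportions, **kwargs)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value,message",
        [
            ("per_base_error_rate", 0.05, "per_base_error_rate"),
            ("read_length", 25, "read_length"),
            ("library_depths", {"FSG": 10, "MSG": 10, "FWB": 10, "MWB": 0}, "library_depths"),
            ("class_proportions", {c: 0.3 for c in synthio.CLASSES}, "class_proportions"),
            ("enriched_wb_tpm", 0.0, "enriched_wb_tpm"),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value, message):
        cfg = dataclasses.replace(SyntheticConfig(), **{field: value})
        with pytest.raises(ConfigurationError, match=message):
            cfg.validate()

    def test_wrong_library_labels_rejected(self):
        cfg = SyntheticConfig(library_depths={"FSG": 1, "MSG": 1, "FWB": 1, "XXX": 1})
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestGenerateCdsSet:
    def test_empty_request(self):
        records, truth = generate_cds_set(SyntheticConfig(n_cds=0))
        assert records == [] and truth.empty

    def test_fixed_seed_reproducibility(self):
        cfg = SyntheticConfig(n_cds=60, rng_seed=99)
        a_records, a_truth = generate_cds_set(cfg)
        b_records, b_truth = generate_cds_set(cfg)
        assert [(r.cds_id, r.sequence) for r in a_records] == [
            (r.cds_id, r.sequence) for r in b_records
        ]
        assert a_truth.equals(b_truth)

    def test_degenerate_proportions(self):
        cfg = _single_class_config("female_sg_enriched", n_cds=30)
        _, truth = generate_cds_set(cfg)
        assert (truth["class_label"] == "female_sg_enriched").all()

    def test_sequences_distinct_unless_duplicates_requested(self):
        cfg = SyntheticConfig(n_cds=50, rng_seed=3)
        records, _ = generate_cds_set(cfg)
        seqs = [r.sequence for r in records]
        assert len(set(seqs)) == len(seqs)
        cfg = SyntheticConfig(n_cds=50, rng_seed=3, n_duplicate_cds=2)
        records, _ = generate_cds_set(cfg)
        seqs = [r.sequence for r in records]
        assert seqs.count(seqs[0]) == 3  # the original plus two copies

    def test_planted_folds_hold_in_expected_tpm(self):
        cfg = SyntheticConfig(n_cds=100, rng_seed=5)
        _, truth = generate_cds_set(cfg)
        for lib in LIBRARIES:
            assert truth[f"true_tpm_{lib}"].sum() == pytest.approx(1e6)
        enriched = truth[truth["class_label"] != "background"]
        sg = enriched["true_tpm_FSG"] + enriched["true_tpm_MSG"]
        wb = enriched["true_tpm_FWB"] + enriched["true_tpm_MWB"]
        np.testing.assert_allclose(sg / wb, enriched["true_sg_fold"], rtol=1e-9)
        female = truth[truth["class_label"] == "female_sg_enriched"]
        np.testing.assert_allclose(
            female["true_tpm_FSG"] / female["true_tpm_MSG"],
            female["true_sex_fold"],
            rtol=1e-9,
        )
        background = truth[truth["class_label"] == "background"]
        assert (background["true_sg_fold"] < 10).all()


class TestSynthesizeReads:
    def test_zero_noise_reads_are_exact_substrings(self):
        cfg = _single_class_config(
            "background",
            n_cds=1,
            cds_length_range=(200, 200),
            library_depths={lib: 10 for lib in LIBRARIES},
            per_base_error_rate=0.0,
            low_quality_tail_prob=0.0,
            rng_seed=8,
        )
        records, truth = generate_cds_set(cfg)
        libraries, _ = synthesize_reads(records, truth, cfg)
        seq = records[0].sequence
        for lib in LIBRARIES:
            assert len(libraries[lib]) == 10
            for read in libraries[lib]:
                assert read.sequence in seq or reverse_complement(read.sequence) in seq

    def test_expected_counts_sum_to_depth(self, small_config):
        records, truth = generate_cds_set(small_config)
        expected = synthio.expected_counts(records, truth, small_config)
        for lib in LIBRARIES:
            assert expected[f"expected_{lib}"].sum() == pytest.approx(
                small_config.library_depths[lib]
            )

    def test_planted_sex_fold_recovered_in_raw_counts(self):
        # one female CDS at sex fold 25 among background: depth-adjusted
        # FSG:MSG count ratio matches 25x within 3 binomial SDs
        fold_ranges = dict(synthio._default_fold_ranges())
        fold_ranges["female_sg_enriched"] = ((25.0, 25.0), (25.0, 25.0))
        cfg = SyntheticConfig(
            n_cds=20,
            cds_length_range=(300, 300),
            class_proportions={
                "female_sg_enriched": 0.05,
                "male_sg_enriched": 0.0,
                "shared_sg": 0.0,
                "background": 0.95,
            },
            fold_ranges=fold_ranges,
            library_depths={"FSG": 10_000, "MSG": 10_000, "FWB": 1000, "MWB": 1000},
            per_base_error_rate=0.0,
            low_quality_tail_prob=0.0,
            rng_seed=77,
        )
        records, truth = generate_cds_set(cfg)
        libraries, expected = synthesize_reads(records, truth, cfg)
        target = truth.loc[truth["class_label"] == "female_sg_enriched", "cds_id"].iloc[0]
        exp = expected.set_index("cds_id").loc[target]
        n_fsg = sum(1 for r in libraries["FSG"] if _source(r, records) == target)
        n_msg = sum(1 for r in libraries["MSG"] if _source(r, records) == target)
        for lib, n in (("FSG", n_fsg), ("MSG", n_msg)):
            mu = exp[f"expected_{lib}"]
            depth = cfg.library_depths[lib]
            sd = np.sqrt(mu * (1 - mu / depth))
            assert abs(n - mu) <= 3 * sd
        # the expectations themselves embody the planted 25x sex ratio
        assert exp["expected_FSG"] / exp["expected_MSG"] == pytest.approx(25.0)

    def test_empirical_counts_match_multinomial_expectation(self, small_config):
        records, truth = generate_cds_set(small_config)
        libraries, expected = synthesize_reads(records, truth, small_config)
        exp = expected.set_index("cds_id")
        counts = {cid: 0 for cid in exp.index}
        for read in libraries["FSG"]:
            counts[_source(read, records)] += 1
        depth = small_config.library_depths["FSG"]
        for cid in exp.index:
            mu = exp.at[cid, "expected_FSG"]
            sd = np.sqrt(max(mu * (1 - mu / depth), 1e-12))
            assert abs(counts[cid] - mu) <= 4 * sd + 1e-9

    def test_fixed_seed_fastq_byte_identical(self, tmp_path, small_config):
        records, truth = generate_cds_set(small_config)
        synthesize_reads(records, truth, small_config, out_dir=tmp_path / "a")
        synthesize_reads(records, truth, small_config, out_dir=tmp_path / "b")
        for lib in LIBRARIES:
            a = (tmp_path / "a" / f"{lib}.fastq").read_bytes()
            b = (tmp_path / "b" / f"{lib}.fastq").read_bytes()
            assert a == b and len(a) > 0

    def test_truth_must_cover_all_cds(self, small_config):
        records, truth = generate_cds_set(small_config)
        with pytest.raises(InputError):
            synthesize_reads(records, truth.iloc[:-5], small_config)

    def test_short_cds_excluded_with_warning(self, caplog):
        cfg = _single_class_config(
            "background",
            n_cds=10,
            cds_length_range=(60, 140),
            library_depths={lib: 200 for lib in LIBRARIES},
            read_length=101,
            per_base_error_rate=0.0,
            rng_seed=21,
        )
        records, truth = generate_cds_set(cfg)
        assert any(r.length < 101 for r in records)
        with caplog.at_level("WARNING"):
            libraries, expected = synthesize_reads(records, truth, cfg)
        assert "excluded from sampling" in caplog.text
        short_ids = {r.cds_id for r in records if r.length < 101}
        exp = expected.set_index("cds_id")
        assert (exp.loc[sorted(short_ids)].sum(axis=1) == 0).all()


def _source(read, records):
    """Recover the source CDS of an error-free read by exact search."""
    from Bio.Seq import reverse_complement as rc

    for rec in records:
        if read.sequence in rec.sequence or rc(read.sequence) in rec.sequence:
            return rec.cds_id
    raise AssertionError("read is not a substring of any CDS")
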