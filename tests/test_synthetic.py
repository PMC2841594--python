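"""Synthetic-bundle generation: determinism, reader compatibility, forced
parameters and parameter recovery through the full pipeline."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from imprintmarks.annotations_io import ValidationError
from imprintmarks.signatures import scan_icr_signature
from imprintmarks.states import UNKNOWN
from imprintmarks.synthetic import (
    K4,
    K9,
    K20,
    K27,
    MarkStateProbs,
    SyntheticBundle,
    SyntheticConfig,
    generate_bundle,
    recover_parameters,
)

SMALL = dict(n_genes=400, n_imprinted=60, n_icr_intergenic=6)


def _dir_files(d: Path):
    return sorted(p.relative_to(d) for p in d.rglob("*") if p.is_file())


class TestDeterminism:
    def test_same_config_and_seed_byte_identical(self, tmp_path):
        config = SyntheticConfig(seed=9, **SMALL)
        for sub in ("a", "b"):
            bundle, _ = generate_bundle(config)
            bundle.write(tmp_path / sub)
        files_a = _dir_files(tmp_path / "a")
        assert files_a == _dir_files(tmp_path / "b")
        for rel in files_a:
            assert (tmp_path / "a" / rel).read_bytes() == (
                tmp_path / "b" / rel
            ).read_bytes(), rel

    def test_different_seeds_differ(self):
        b1, _ = generate_bundle(SyntheticConfig(seed=1, **SMALL))
        b2, _ = generate_bundle(SyntheticConfig(seed=2, **SMALL))
        assert b1.callset("ESC", K4) != b2.callset("ESC", K4)


class TestReaderCompatibility:
    def test_written_bundle_parses_cleanly(self, tmp_path):
        bundle, _ = generate_bundle(SyntheticConfig(seed=4, **SMALL))
        bundle.write(tmp_path)
        again = SyntheticBundle.read(tmp_path)
        assert len(again.gene_table) == len(bundle.gene_table)
        assert set(again.callsets) == set(bundle.callsets)
        for key in bundle.callsets:
            assert again.callsets[key] == bundle.callsets[key]
        assert again.imprinted_queries == bundle.imprinted_queries
        assert again.dmr.keys() == bundle.dmr.keys()

    def test_random_configs_respect_reader_invariants(self):
        """Fuzz over configs: emitted call sets are merged, sorted, valid."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            config = SyntheticConfig(
                n_genes=int(rng.integers(100, 400)),
                n_imprinted=int(rng.integers(20, 80)),
                p_signature_icr=float(rng.random()),
                p_k9k20_given_germline_dmr=float(rng.random()),
                noise_rate=float(rng.random() * 0.1),
                seed=int(rng.integers(0, 2**31)),
            )
            bundle, _ = generate_bundle(config)
            for cs in bundle.callsets.values():
                for chrom in cs.chromosomes:
                    starts, ends = cs.arrays(chrom)
                    assert (ends > starts).all()
                    assert (starts[1:] > ends[:-1]).all()


class TestForcedParameters:
    def test_zero_probability_parameters_give_zero_estimates(self):
        bundle, truth = generate_bundle(SyntheticConfig(seed=5, **SMALL))
        table = bundle.state_table()
        rec = recover_parameters(table, truth).set_index("parameter")
        # Repressive-pair exclusivity: never outside germline ICR promoters.
        assert rec.loc["p_k9k20_given_no_dmr", "estimate"] == 0.0
        assert rec.loc["p_k9k20_given_somatic_dmr", "estimate"] == 0.0
        assert rec.loc["p_k9k20_given_germline_dmr", "estimate"] == 1.0

    def test_signature_probability_one_forces_full_icr_fraction(self):
        bundle, _ = generate_bundle(SyntheticConfig(seed=6, **SMALL))
        _, summary = scan_icr_signature(
            bundle.scan_regions(),
            [bundle.callset("ESC", m) for m in (K4, K9, K20)],
        )
        assert summary.icr_fraction == 1.0
        assert summary.non_icr_with_signature == ()

    def test_mixed_signature_fraction_matches_truth_record(self):
        config = SyntheticConfig(
            seed=8, n_genes=400, n_imprinted=60, n_icr_intergenic=50,
            p_signature_icr=0.8,
        )
        bundle, truth = generate_bundle(config)
        _, summary = scan_icr_signature(
            bundle.scan_regions(),
            [bundle.callset("ESC", m) for m in (K4, K9, K20)],
        )
        inter = truth.regions[truth.regions.region_class == "intergenic_icr"]
        assert summary.fraction("intergenic_icr") == pytest.approx(
            inter.signature.mean()
        )

    def test_non_icr_germline_dmr_lacks_signature(self):
        bundle, truth = generate_bundle(SyntheticConfig(seed=2, **SMALL))
        _, summary = scan_icr_signature(
            bundle.scan_regions(),
            [bundle.callset("ESC", m) for m in (K4, K9, K20)],
        )
        assert summary.fraction("non_icr_germline_dmr") == 0.0


class TestMissingness:
    def test_expression_missing_genes_are_unknown_in_state_table(self):
        config = SyntheticConfig(seed=12, p_missing_expression=0.3, **SMALL)
        bundle, truth = generate_bundle(config)
        table = bundle.state_table()
        esc = table[table.cell_type == "ESC"].set_index("gene_id")
        missing = set(truth.missing_expression["ESC"]) & set(esc.index)
        assert missing, "fixture should include missing imprinted genes"
        assert (esc.loc[sorted(missing), "expression"] == UNKNOWN).all()
        present = set(esc.index) - missing
        assert (esc.loc[sorted(present), "expression"] != UNKNOWN).all()


class TestRecovery:
    def test_pipeline_estimates_within_three_binomial_se(self):
        """Full-pipeline identifiability at mid-range probabilities.

        Every conditioning group exceeds 200 genes; estimates flow through
        interval realization, overlap calling and state integration, never
        through the truth record.
        """
        config = SyntheticConfig(
            n_genes=5000,
            n_imprinted=1500,
            dmr_split=(0.3, 0.2, 0.5),
            p_k9k20_given_germline_dmr=0.7,
            p_expressed_dmr=0.6,
            p_expressed_no_dmr=0.4,
            esc_marks_repressed=MarkStateProbs(0.5, 0.3, 0.0),
            esc_marks_expressed=MarkStateProbs(0.25, 0.5, 0.0),
            seed=0,
        )
        bundle, truth = generate_bundle(config)
        rec = recover_parameters(bundle.state_table(), truth)
        assert (rec.group_size >= 200).all()
        assert rec.within_3se.all(), rec.to_string()

    def test_truth_bundle_mismatch_rejected(self):
        b1, _ = generate_bundle(SyntheticConfig(seed=1, **SMALL))
        _, t2 = generate_bundle(SyntheticConfig(seed=1, n_genes=200, n_imprinted=30))
        with pytest.raises(ValidationError, match="truth"):
            recover_parameters(b1.state_table(), t2)


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(p_signature_icr=1.5, **SMALL).validate()

    def test_imprinted_exceeding_genome_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(n_genes=10, n_imprinted=20).validate()

    def test_dmr_split_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(dmr_split=(0.5, 0.5, 0.5), **SMALL).validate()
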