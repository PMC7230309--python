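"""Run-info/abundance parsing and the TPM computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from coexstream.quantification import (
    AbundanceTable,
    FixtureDirEngine,
    KallistoEngine,
    ParseError,
    QuantParams,
    QuantificationError,
    RunStats,
    compute_tpm,
    parse_abundance,
    parse_run_info,
    run_quantifier,
    serialize_run_info,
)
from coexstream.synthetic import generate_run_fixture


class TestParseRunInfo:
    def test_basic_document(self):
        stats = parse_run_info(
            '{"n_processed": 100, "n_pseudoaligned": 60, '
            '"p_pseudoaligned": 60.0}')
        assert stats == RunStats(100, 60, 60.0)

    def test_zero_reads_percent_defined_as_zero(self):
        stats = parse_run_info(
            '{"n_processed": 0, "n_pseudoaligned": 0, "p_pseudoaligned": 0}')
        assert stats.p_pseudoaligned == 0.0

    def test_more_aligned_than_processed_rejected(self):
        with pytest.raises(ValueError):
            parse_run_info('{"n_processed": 10, "n_pseudoaligned": 20, '
                           '"p_pseudoaligned": 200.0}')

    @pytest.mark.parametrize("doc,fragment", [
        ('{"n_processed": 1}', "n_pseudoaligned"),
        ("not json", "JSON"),
    ])
    def test_parse_errors_name_the_problem(self, doc, fragment):
        with pytest.raises(ParseError, match=fragment):
            parse_run_info(doc)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            parse_run_info('{"n_processed": -5, "n_pseudoaligned": 0, '
                           '"p_pseudoaligned": 0}')

    def test_inconsistent_percentage_rejected(self):
        with pytest.raises(ValueError):
            parse_run_info('{"n_processed": 100, "n_pseudoaligned": 60, '
                           '"p_pseudoaligned": 90.0}')

    @settings(max_examples=50, derandomize=True)
    @given(n=st.integers(1, 10**9), frac=st.floats(0, 1))
    def test_parse_serialize_identity(self, n, frac):
        aligned = int(n * frac)
        stats = RunStats(n, aligned, 100.0 * aligned / n, n_targets=42)
        assert parse_run_info(serialize_run_info(stats)) == stats


class TestComputeTpm:
    def test_single_expressed_gene_takes_full_mass(self):
        assert compute_tpm(np.array([5.0]), np.array([123.0]))[0] == 1e6

    def test_hand_example(self):
        # rates (0.1, 0.05, 0.05) sum 0.2 -> (5e5, 2.5e5, 2.5e5)
        tpm = compute_tpm(np.array([10.0, 10.0, 20.0]),
                          np.array([100.0, 200.0, 400.0]))
        np.testing.assert_allclose(tpm, [500000.0, 250000.0, 250000.0])

    def test_all_zero_counts_stay_zero(self):
        assert compute_tpm(np.zeros(3), np.ones(3)).sum() == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_tpm(np.ones(3), np.ones(2))

    def test_positive_count_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_tpm(np.array([1.0]), np.array([0.0]))

    @settings(max_examples=200, derandomize=True)
    @given(
        counts=hnp.arrays(float, st.integers(1, 50),
                          elements=st.one_of(st.just(0.0),
                                             st.floats(1e-3, 1e6))),
        scale=st.floats(1e-3, 1e3),
        data=st.data(),
    )
    def test_sums_to_million_and_scale_invariant(self, counts, scale, data):
        lengths = data.draw(hnp.arrays(float, counts.shape,
                                       elements=st.floats(1.0, 1e4)))
        tpm = compute_tpm(counts, lengths)
        if counts.sum() > 0:
            assert tpm.sum() == pytest.approx(1e6, rel=1e-9)
            np.testing.assert_allclose(compute_tpm(scale * counts, lengths),
                                       tpm, rtol=1e-9)
        else:
            assert tpm.sum() == 0.0


class TestAbundanceTable:
    def _table_text(self):
        return ("target_id\tlength\teff_length\test_counts\ttpm\n"
                "g1\t100\t50\t10\t500000.0\n"
                "g2\t200\t100\t20\t500000.0\n")

    def test_parse_tsv_text(self):
        table = parse_abundance(self._table_text())
        assert table.ids == ["g1", "g2"]
        assert table.tpm.sum() == pytest.approx(1e6)

    def test_duplicate_ids_rejected(self):
        text = self._table_text().replace("g2", "g1")
        with pytest.raises(ValueError):
            parse_abundance(text)

    def test_tpm_not_summing_to_million_rejected(self):
        with pytest.raises(ValueError):
            AbundanceTable(ids=["g1"], lengths=[100], eff_lengths=[50],
                           est_counts=[10], tpm=[5.0])

    def test_missing_column_is_parse_error(self):
        with pytest.raises(ParseError, match="tpm"):
            parse_abundance("target_id\tlength\teff_length\test_counts\n"
                            "g1\t100\t50\t10\n")

    def test_tpm_rederivable_from_counts(self):
        table = parse_abundance(self._table_text())
        rederived = compute_tpm(table.est_counts, table.eff_lengths)
        np.testing.assert_allclose(rederived, table.tpm, rtol=1e-4)


class _EchoEngine:
    """Engine emitting a configured run-info and abundance document."""

    def __init__(self, n_processed, n_pseudoaligned, counts):
        self.stats = RunStats(
            n_processed, n_pseudoaligned,
            100.0 * n_pseudoaligned / n_processed if n_processed else 0.0)
        self.counts = np.asarray(counts, dtype=float)

    def quantify(self, accession, stream, params):
        for _ in stream:
            pass
        ids = [f"g{i}" for i in range(len(self.counts))]
        lengths = np.full(len(ids), 1000.0)
        tpm = compute_tpm(self.counts, lengths)
        lines = ["target_id\tlength\teff_length\test_counts\ttpm"]
        for i, gid in enumerate(ids):
            lines.append(f"{gid}\t1150\t1000\t{float(self.counts[i])!r}"
                         f"\t{float(tpm[i])!r}")
        return serialize_run_info(self.stats), "\n".join(lines) + "\n"


class TestRunQuantifier:
    def test_emulator_configuration_is_echoed(self):
        engine = _EchoEngine(100, 60, [1.0, 2.0, 3.0])
        stats, table = run_quantifier("SRR1", iter([b"reads"]),
                                      QuantParams(), engine)
        assert (stats.n_processed, stats.n_pseudoaligned) == (100, 60)
        assert table.tpm.sum() == pytest.approx(1e6, rel=1e-6)

    def test_all_zero_counts_give_zero_tpm(self):
        engine = _EchoEngine(100, 0, [0.0, 0.0])
        _, table = run_quantifier("SRR1", iter([]), QuantParams(), engine)
        assert np.all(table.tpm == 0)

    def test_malformed_run_info_is_parse_error(self):
        class BrokenEngine:
            def quantify(self, accession, stream, params):
                return "not json", "target_id\n"

        with pytest.raises(ParseError):
            run_quantifier("SRR1", iter([]), QuantParams(), BrokenEngine())

    def test_fixture_dir_engine_round_trip(self, tmp_path):
        stats = RunStats(1000, 600, 60.0, n_targets=3)
        generate_run_fixture("SRR5555555", ["a", "b", "c"],
                             np.array([1.0, 2.0, 3.0]), stats, tmp_path,
                             seed=3)
        engine = FixtureDirEngine(tmp_path)
        parsed_stats, table = run_quantifier("SRR5555555", iter([b"x"]),
                                             QuantParams(), engine)
        assert parsed_stats == stats
        assert table.ids == ["a", "b", "c"]

    def test_fixture_dir_engine_missing_run(self, tmp_path):
        with pytest.raises(QuantificationError):
            run_quantifier("SRR0000000", iter([]), QuantParams(),
                           FixtureDirEngine(tmp_path))


class TestKallistoEngine:
    def test_command_mirrors_single_end_parameters(self):
        cmd = KallistoEngine().build_command(
            QuantParams(index_path="cds.idx"), "out")
        assert cmd[:5] == ["kallisto", "quant", "-i", "cds.idx", "-o"]
        joined = " ".join(cmd)
        assert "--single -l 200.0 -s 20.0" in joined
        assert "-t 2" in joined
        assert cmd[-1] == "-"  # reads from the streamed stdin

    def test_index_required(self):
        with pytest.raises(ValueError):
            KallistoEngine().build_command(QuantParams(), "out")
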