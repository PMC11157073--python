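"""Instrument selection: F statistic, LD clumping, and the selection funnel."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from mrkit.exceptions import ConfigurationError, InputError, SelectionError
from mrkit.instruments import (
    LDMatrix,
    SelectionConfig,
    clump,
    f_statistic,
    select_instruments,
)


def clump_oracle(df, ld, r2_cut, window_kb):
    """Independent exhaustive greedy clumping used as the reference."""
    remaining = df.sort_values(
        ["pvalue", "chrom", "pos", "variant_id"], kind="mergesort"
    ).to_dict("records")
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index["variant_id"])
        remaining = [
            s
            for s in remaining
            if not (
                s["chrom"] == index["chrom"]
                and abs(s["pos"] - index["pos"]) <= window_kb * 1000
                and ld.r2(index["variant_id"], s["variant_id"]) > r2_cut
            )
        ]
    return kept


def random_instance(rng, n=20):
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(n)],
            "chrom": rng.choice(["1", "2"], n),
            "pos": rng.integers(1, 5_000_000, n),
            "pvalue": 10.0 ** rng.uniform(-12, -1, n),
        }
    )
    ld = LDMatrix()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                ld.set(f"rs{i}", f"rs{j}", rng.random())
    return df, ld


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.1, 0.02, 25.0), (0.0, 0.05, 0.0), (-0.3, 0.03, 100.0)],
    )
    def test_direct_arithmetic(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(InputError):
            f_statistic(0.1, 0.0)


class TestSelectionConfig:
    def test_trait_class_presets(self):
        assert SelectionConfig.for_trait_class("microbiome").p_threshold == 1e-5
        assert SelectionConfig.for_trait_class("cytokine").p_threshold == 5e-6
        assert SelectionConfig.for_trait_class("eqtl").clump_r2 == 0.1
        assert SelectionConfig.for_trait_class("disease").p_threshold == 5e-8

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            SelectionConfig(p_threshold=2.0)
        with pytest.raises(ConfigurationError):
            SelectionConfig(clump_r2=1.5)
        with pytest.raises(ConfigurationError):
            SelectionConfig.for_trait_class("unknown_class")


class TestLDMatrix:
    def test_defaults_and_symmetry(self):
        ld = LDMatrix()
        ld.set("a", "b", 0.5)
        assert ld.r2("b", "a") == 0.5
        assert ld.r2("a", "c") == 0.0
        assert ld.r2("a", "a") == 1.0

    def test_triplet_file_round_trip(self, tmp_path):
        ld = LDMatrix()
        ld.set("rs1", "rs2", 0.42)
        ld.set("rs2", "rs3", 0.9)
        path = tmp_path / "ld.tsv"
        ld.to_file(path)
        back = LDMatrix.from_file(path)
        assert back.r2("rs1", "rs2") == pytest.approx(0.42)
        assert back.r2("rs3", "rs2") == pytest.approx(0.9)

    def test_square_matrix_dialect(self, tmp_path):
        path = tmp_path / "ld.txt"
        path.write_text(
            "\trs1\trs2\trs3\n"
            "rs1\t1\t0.3\t0\n"
            "rs2\t0.3\t1\t0.8\n"
            "rs3\t0\t0.8\t1\n"
        )
        ld = LDMatrix.from_file(path)
        assert ld.r2("rs1", "rs2") == pytest.approx(0.3)
        assert ld.r2("rs3", "rs2") == pytest.approx(0.8)
        assert ld.r2("rs1", "rs3") == 0.0

    def test_out_of_range_r2_rejected(self):
        with pytest.raises(InputError):
            LDMatrix().set("a", "b", 1.2)


class TestClump:
    def test_single_snp_identity(self):
        df = pd.DataFrame(
            {"variant_id": ["rs1"], "chrom": ["1"], "pos": [100], "pvalue": [1e-6]}
        )
        assert clump(df, LDMatrix(), SelectionConfig(p_threshold=1e-5)) == ["rs1"]

    def test_linked_neighbour_is_claimed_by_stronger_index(self):
        df = pd.DataFrame(
            {
                "variant_id": ["A", "B"],
                "chrom": ["1", "1"],
                "pos": [100_000, 150_000],
                "pvalue": [1e-8, 1e-6],
            }
        )
        ld = LDMatrix()
        ld.set("A", "B", 0.5)
        cfg = SelectionConfig(p_threshold=1e-5, clump_r2=0.01, clump_window_kb=10_000)
        assert clump(df, ld, cfg) == ["A"]

    def test_cross_chromosome_pairs_never_claimed(self):
        df = pd.DataFrame(
            {
                "variant_id": ["A", "B"],
                "chrom": ["1", "2"],
                "pos": [100, 100],
                "pvalue": [1e-8, 1e-6],
            }
        )
        ld = LDMatrix()
        ld.set("A", "B", 0.99)
        assert clump(df, ld, SelectionConfig(p_threshold=1e-5)) == ["A", "B"]

    def test_matches_exhaustive_oracle_on_random_instances(self):
        cfg = SelectionConfig(p_threshold=0.5, clump_r2=0.2, clump_window_kb=1000)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df, ld = random_instance(rng)
            assert clump(df, ld, cfg) == clump_oracle(df, ld, 0.2, 1000)

    def test_retained_set_has_no_linked_pair_within_window(self):
        cfg = SelectionConfig(p_threshold=0.5, clump_r2=0.1, clump_window_kb=1000)
        rng = np.random.default_rng(7)
        df, ld = random_instance(rng, n=30)
        kept = clump(df, ld, cfg)
        assert set(kept) <= set(df["variant_id"])
        sub = df.set_index("variant_id").loc[kept]
        for a in kept:
            for b in kept:
                if a >= b or sub.loc[a, "chrom"] != sub.loc[b, "chrom"]:
                    continue
                if abs(int(sub.loc[a, "pos"]) - int(sub.loc[b, "pos"])) <= 1_000_000:
                    assert ld.r2(a, b) <= 0.1

    def test_permissive_cutoff_retains_everything(self):
        # at r2 cutoff 1.0 no pair can exceed the threshold, so clumping is
        # the identity up to ordering (retained count is NOT monotone in the
        # cutoff for intermediate values: freeing one claimed SNP can turn it
        # into an index that claims several others)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df, ld = random_instance(rng)
            kept = clump(df, ld, SelectionConfig(p_threshold=0.5, clump_r2=1.0))
            assert set(kept) == set(df["variant_id"])

    def test_empty_input_gives_empty_output(self):
        df = pd.DataFrame(columns=["variant_id", "chrom", "pos", "pvalue"])
        assert clump(df, LDMatrix(), SelectionConfig()) == []


class TestSelectInstruments:
    def _table(self):
        return make_table(
            [
                {"variant_id": "rs1", "pos": 1_000, "pvalue": 1e-9, "beta": 0.2, "se": 0.02},
                {"variant_id": "rs2", "pos": 20_000_000, "pvalue": 1e-7, "beta": 0.1, "se": 0.02},
                {"variant_id": "rs3", "chrom": "2", "pos": 1_000, "pvalue": 1e-6,
                 "beta": 0.06, "se": 0.02},  # F = 9
                {"variant_id": "rs4", "chrom": "3", "pos": 1_000, "pvalue": 0.2},
            ],
            name="exp",
        )

    def test_no_snp_below_threshold_is_an_error(self):
        table = self._table()
        with pytest.raises(SelectionError, match="exp"):
            select_instruments(table, LDMatrix(), SelectionConfig(p_threshold=1e-20))

    def test_weak_instrument_dropped_under_drop_action(self):
        chosen = select_instruments(
            self._table(), LDMatrix(), SelectionConfig(p_threshold=1e-5, f_action="drop")
        )
        assert "rs3" not in chosen.ids
        assert set(chosen.ids) == {"rs1", "rs2"}
        assert chosen.weak_ids == ["rs3"]

    def test_weak_instrument_kept_under_flag_action(self):
        chosen = select_instruments(
            self._table(), LDMatrix(), SelectionConfig(p_threshold=1e-5, f_action="flag")
        )
        assert "rs3" in chosen.ids
        assert chosen.weak_ids == ["rs3"]

    def test_fully_permissive_config_is_identity_on_ids(self):
        table = self._table()
        cfg = SelectionConfig(p_threshold=0.999999, clump_r2=1.0, f_min=0.0)
        chosen = select_instruments(table, LDMatrix(), cfg)
        assert set(chosen.ids) == set(table.variant_ids)

    def test_unlinked_strong_snps_all_retained(self):
        rows = [
            {"variant_id": f"rs{i}", "chrom": str(i + 1), "pos": 1000,
             "pvalue": 1e-8, "beta": 0.2, "se": 0.02}
            for i in range(5)
        ]
        chosen = select_instruments(
            make_table(rows, name="exp"), LDMatrix(), SelectionConfig(p_threshold=1e-5)
        )
        assert len(chosen.ids) == 5
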