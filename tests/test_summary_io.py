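"""IO, harmonization and clumping against hand examples and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from mrmediate.exceptions import (
    EmptyInstrumentError,
    FormatError,
    HarmonizationError,
    ValidationError,
)
from mrmediate.summary_io import (
    InstrumentCriteria,
    PairwiseLD,
    SummaryStats,
    clump,
    harmonize,
    read_gwas_table,
    read_ld_table,
    select_instruments,
)

from conftest import make_stats

TABLE = (
    "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
    "rs1\t1\t1000\tA\tG\t0.2\t0.10\t0.01\t1e-20\t10000\n"
    "rs2\t2\t2000\tC\tT\t0.3\t-0.05\t0.02\t1e-9\t10000\n"
    "rs3\t3\t3000\tG\tA\tNA\t0.02\t0.03\t0.5\t10000\n"
)


class TestReadGwasTable:
    def test_well_formed_table_round_trips(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(TABLE)
        ss = read_gwas_table(p)
        assert len(ss) == 3 and len(ss.rejected) == 0
        assert np.isnan(ss.df.loc[2, "eaf"])
        # writing and re-reading is the identity
        out = tmp_path / "rt.tsv"
        ss.write(out)
        again = read_gwas_table(out)
        pd.testing.assert_frame_equal(ss.df, again.df)

    def test_nonpositive_se_rejected_with_reason(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(TABLE + "rs4\t4\t4000\tA\tC\t0.1\t0.01\t0\t0.1\t5000\n")
        ss = read_gwas_table(p)
        assert len(ss) == 3
        assert list(ss.rejected["variant_id"]) == ["rs4"]
        assert ss.rejected["reason"].iloc[0] == "nonpositive se"

    def test_shuffled_columns_with_dialect_remap(self, tmp_path):
        shuffled = (
            "pvalue\tbeta_hat\tmarker\tchrom\tbp\tref\talt\tfreq\tstderr\tsamples\n"
            "1e-20\t0.10\trs1\t1\t1000\tG\tA\t0.2\t0.01\t10000\n"
            "1e-9\t-0.05\trs2\t2\t2000\tT\tC\t0.3\t0.02\t10000\n"
            "0.5\t0.02\trs3\t3\t3000\tA\tG\tNA\t0.03\t10000\n"
        )
        p = tmp_path / "s.tsv"
        p.write_text(shuffled)
        dialect = {
            "variant_id": "marker", "chrom": "chrom", "pos": "bp",
            "effect_allele": "alt", "other_allele": "ref", "eaf": "freq",
            "beta": "beta_hat", "se": "stderr", "pval": "pvalue", "n": "samples",
        }
        q = tmp_path / "t.tsv"
        q.write_text(TABLE)
        pd.testing.assert_frame_equal(read_gwas_table(p, dialect).df, read_gwas_table(q).df)

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tN\nrs1\t1\t1\tA\tG\t0.1\t0\t1\t10\n")
        with pytest.raises(FormatError, match="P"):
            read_gwas_table(p)

    def test_duplicate_ids_raise_listing_them(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(TABLE + "rs1\t1\t1000\tA\tG\t0.2\t0.10\t0.01\t1e-20\t10000\n")
        with pytest.raises(ValidationError, match="rs1"):
            read_gwas_table(p)


def _one(label, ea, oa, eaf, beta, vid="rs1", se=0.01):
    return make_stats([(vid, "1", 1000, ea, oa, eaf, beta, se, 1e-10, 10000)], label)


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        H = harmonize(_one("x", "A", "G", 0.2, 0.10), _one("y", "G", "A", 0.8, -0.05))
        assert H.gamma_out[0] == pytest.approx(0.05)
        assert H.gamma[0] == pytest.approx(0.10)

    def test_ambiguous_palindrome_dropped(self):
        H = harmonize(
            make_stats(
                [
                    ("rs1", "1", 1000, "A", "T", 0.50, 0.1, 0.01, 1e-10, 1000),
                    ("rs2", "1", 2000, "A", "G", 0.20, 0.1, 0.01, 1e-10, 1000),
                ]
            ),
            make_stats(
                [
                    ("rs1", "1", 1000, "A", "T", 0.50, 0.1, 0.01, 1e-10, 1000),
                    ("rs2", "1", 2000, "A", "G", 0.20, 0.1, 0.01, 1e-10, 1000),
                ]
            ),
            palindrome_policy="drop_ambiguous",
        )
        assert H.variant_ids == ["rs2"]
        dropped = dict(zip(H.dropped["variant_id"], H.dropped["reason"]))
        assert dropped["rs1"] == "palindromic_ambiguous"

    def test_palindrome_inferred_from_matching_minor_alleles(self):
        # both tables report the A allele as clearly minor: same orientation
        H = harmonize(
            _one("x", "A", "T", 0.10, 0.1),
            _one("y", "A", "T", 0.12, 0.07),
            palindrome_policy="infer_by_eaf",
            eaf_window=0.08,
        )
        assert len(H) == 1
        assert H.gamma_out[0] == pytest.approx(0.07)

    def test_palindrome_inferred_flip_on_opposite_minor_alleles(self):
        H = harmonize(
            _one("x", "A", "T", 0.10, 0.1),
            _one("y", "A", "T", 0.90, 0.07),
            palindrome_policy="infer_by_eaf",
        )
        assert H.gamma_out[0] == pytest.approx(-0.07)

    def test_irreconcilable_alleles_dropped_not_raised(self):
        H = harmonize(
            make_stats(
                [
                    ("rs1", "1", 1000, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
                    ("rs2", "1", 2000, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
                ]
            ),
            make_stats(
                [
                    ("rs1", "1", 1000, "A", "C", 0.2, 0.1, 0.01, 1e-10, 1000),
                    ("rs2", "1", 2000, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
                ]
            ),
        )
        assert H.variant_ids == ["rs2"]
        assert "allele_mismatch" in set(H.dropped["reason"])

    def test_zero_shared_snps_is_an_error(self):
        with pytest.raises(HarmonizationError):
            harmonize(_one("x", "A", "G", 0.2, 0.1, vid="rs1"), _one("y", "A", "G", 0.2, 0.1, vid="rs2"))

    def test_idempotent_on_aligned_tables(self, rng):
        n = 30
        rows_x, rows_y = [], []
        for i in range(n):
            eaf = rng.uniform(0.05, 0.95)
            rows_x.append((f"rs{i}", "1", 1000 + i, "A", "G", eaf, rng.normal(), 0.01, 1e-9, 1000))
            rows_y.append((f"rs{i}", "1", 1000 + i, "A", "G", eaf, rng.normal(), 0.02, 1e-9, 1000))
        H1 = harmonize(make_stats(rows_x), make_stats(rows_y))
        # re-harmonizing tables that already share the convention changes nothing
        assert np.allclose(H1.gamma_out, [r[6] for r in rows_y])

    def test_swapping_exposure_and_outcome_transposes_pairs(self, rng):
        n = 20
        flips = rng.random(n) < 0.5
        rows_x, rows_y = [], []
        for i in range(n):
            eaf = rng.uniform(0.05, 0.4)
            bx, by = rng.normal(), rng.normal()
            rows_x.append((f"rs{i}", "1", 1000 + i, "A", "G", eaf, bx, 0.01, 1e-9, 1000))
            if flips[i]:
                rows_y.append((f"rs{i}", "1", 1000 + i, "G", "A", 1 - eaf, -by, 0.02, 1e-9, 1000))
            else:
                rows_y.append((f"rs{i}", "1", 1000 + i, "A", "G", eaf, by, 0.02, 1e-9, 1000))
        x, y = make_stats(rows_x, "x"), make_stats(rows_y, "y")
        fwd = harmonize(x, y).df.set_index("variant_id")
        rev = harmonize(y, x).df.set_index("variant_id")
        for vid in fwd.index:
            assert abs(fwd.loc[vid, "gamma"]) == pytest.approx(abs(rev.loc[vid, "gamma_out"]))
            assert abs(fwd.loc[vid, "gamma_out"]) == pytest.approx(abs(rev.loc[vid, "gamma"]))
            # the (exposure, outcome) effect pair is transposed SNP for SNP
            assert fwd.loc[vid, "gamma"] * fwd.loc[vid, "gamma_out"] == pytest.approx(
                rev.loc[vid, "gamma"] * rev.loc[vid, "gamma_out"]
            )


def brute_force_clump(df, ld, r2_threshold, window_kb):
    """Independent greedy re-implementation: explicit pairwise scan."""
    remaining = df.sort_values(["pval", "variant_id"]).to_dict("records")
    accepted = []
    for row in remaining:
        conflict = False
        for acc in accepted:
            if (
                acc["chrom"] == row["chrom"]
                and abs(acc["pos"] - row["pos"]) <= window_kb * 1000
                and ld.r2(acc["variant_id"], row["variant_id"]) >= r2_threshold
            ):
                conflict = True
        if not conflict:
            accepted.append(row)
    return [a["variant_id"] for a in accepted]


class TestClump:
    def test_single_snp_kept(self):
        ss = make_stats([("rs1", "1", 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000)])
        assert clump(ss, None) == ["rs1"]

    def test_greedy_rule_keeps_smaller_p(self):
        ss = make_stats(
            [
                ("rs1", "1", 1000, "A", "G", 0.2, 0.1, 0.01, 1e-20, 1000),
                ("rs2", "1", 6000, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000),
            ]
        )
        ld = PairwiseLD({("rs1", "rs2"): 0.5})
        assert clump(ss, ld) == ["rs1"]

    def test_window_rule_keeps_distant_pair(self):
        ss = make_stats(
            [
                ("rs1", "1", 1000, "A", "G", 0.2, 0.1, 0.01, 1e-20, 1000),
                ("rs2", "1", 1000 + 20_000_000, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000),
            ]
        )
        ld = PairwiseLD({("rs1", "rs2"): 0.9})
        assert set(clump(ss, ld)) == {"rs1", "rs2"}

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle_on_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 21))
        rows = [
            (
                f"rs{i}", str(rng.integers(1, 4)), int(rng.integers(1, 30_000_000)),
                "A", "G", 0.2, 0.1, 0.01, float(rng.uniform(1e-20, 1e-4)), 1000,
            )
            for i in range(n)
        ]
        ld = PairwiseLD()
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    ld.set(f"rs{i}", f"rs{j}", float(rng.random()))
        ss = make_stats(rows)
        crit = InstrumentCriteria(r2_threshold=0.1, window_kb=10_000)
        result = clump(ss, ld, crit)
        assert result == brute_force_clump(ss.df, ld, 0.1, 10_000)
        # kept set invariant: no same-chromosome in-window pair at or above threshold
        kept = ss.df[ss.df["variant_id"].isin(result)].to_dict("records")
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if a["chrom"] == b["chrom"] and abs(a["pos"] - b["pos"]) <= 10_000_000:
                    assert ld.r2(a["variant_id"], b["variant_id"]) < 0.1
        assert set(result) <= set(ss.df["variant_id"])


class TestSelectInstruments:
    def test_no_significant_snp_is_an_error_naming_trait(self):
        ss = make_stats(
            [("rs1", "1", 1000, "A", "G", 0.2, 0.1, 0.01, 1e-4, 1000)], label="bmi"
        )
        with pytest.raises(EmptyInstrumentError, match="bmi"):
            select_instruments(ss)

    def test_independent_significant_snps_all_kept(self):
        rows = [
            (f"rs{i}", str(i + 1), 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000)
            for i in range(5)
        ]
        out = select_instruments(make_stats(rows))
        assert len(out) == 5

    def test_restrict_to_intersects_before_clumping(self):
        rows = [
            (f"rs{i}", str(i + 1), 1000, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000)
            for i in range(5)
        ]
        out = select_instruments(make_stats(rows), restrict_to=["rs0", "rs3"])
        assert set(out.variant_ids) == {"rs0", "rs3"}

    def test_equals_filter_then_clump_composition(self, rng):
        rows = []
        ld = PairwiseLD()
        for b in range(20):  # 20 blocks of 10 SNPs
            ids = [f"rs{b}_{i}" for i in range(10)]
            for i, vid in enumerate(ids):
                rows.append(
                    (
                        vid, str(b % 5 + 1), int(1_000_000 * (b // 5) + 2000 * i),
                        "A", "G", 0.2, 0.1, 0.01,
                        float(rng.choice([1e-12, 1e-9, 1e-5])), 1000,
                    )
                )
                for other in ids[:i]:
                    ld.set(vid, other, 0.8)
        ss = make_stats(rows)
        crit = InstrumentCriteria()
        got = select_instruments(ss, ld, crit).variant_ids
        sig = ss.df[ss.df["pval"] < crit.p_threshold]
        expected = brute_force_clump(sig, ld, crit.r2_threshold, crit.window_kb)
        assert sorted(got) == sorted(expected)


class TestLDIO:
    def test_pair_list_and_matrix_agree(self, tmp_path):
        pairs = tmp_path / "ld.tsv"
        pairs.write_text("SNP_A\tSNP_B\tR2\nrs1\trs2\t0.5\nrs2\trs3\t0.2\n")
        mat = tmp_path / "ldm.tsv"
        mat.write_text(
            "\trs1\trs2\trs3\nrs1\t1\t0.5\t0\nrs2\t0.5\t1\t0.2\nrs3\t0\t0.2\t1\n"
        )
        a, b = read_ld_table(pairs), read_ld_table(mat)
        for x, y in [("rs1", "rs2"), ("rs2", "rs3"), ("rs1", "rs3")]:
            assert a.r2(x, y) == b.r2(x, y)
        assert a.r2("rs1", "rs1") == 1.0
        assert a.r2("rs1", "rs99") == 0.0
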