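import numpy as np
import pandas as pd
import pytest

from cghcnv.errors import PlacementError, StructuralError
from cghcnv.genome import GenomeModel
from cghcnv.intervals import (
    IntervalSet,
    coverage_table,
    genes_overlapping,
    merge_intervals,
    overlap_length,
    random_interval_test,
)


def iset(rows, **kwargs):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), **kwargs)


def mask_union_length(df, chrom_len):
    """Oracle: per-bp boolean mask."""
    mask = np.zeros(chrom_len, dtype=bool)
    for row in df.itertuples():
        mask[row.start:row.end] = True
    return int(mask.sum())


class TestMergeIntervals:
    def test_textbook_merge(self):
        out = merge_intervals(iset([("chr1", 0, 100), ("chr1", 50, 150)]))
        assert out.intervals.values.tolist() == [["chr1", 0, 150]]

    def test_disjoint_unchanged(self):
        out = merge_intervals(iset([("chr1", 0, 100), ("chr1", 200, 300)]))
        assert out.total_length == 200
        assert len(out) == 2

    def test_bookended_intervals_merge(self):
        out = merge_intervals(iset([("chr1", 0, 100), ("chr1", 100, 200)]))
        assert len(out) == 1

    def test_invalid_interval_rejected(self):
        with pytest.raises(StructuralError):
            iset([("chr1", 100, 100)])

    def test_matches_mask_oracle_on_random_input(self):
        rng = np.random.default_rng(23)
        chrom_len = 100_000
        starts = rng.integers(0, chrom_len - 500, 1000)
        lengths = rng.integers(1, 500, 1000)
        df = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + lengths}
        )
        merged = merge_intervals(IntervalSet(df))
        assert merged.total_length == mask_union_length(df, chrom_len)
        iv = merged.intervals
        assert (iv["start"].values[1:] > iv["end"].values[:-1]).all()


class TestOverlapLength:
    def test_textbook(self):
        assert overlap_length(iset([("chr1", 0, 100)]), iset([("chr1", 50, 150)])) == 50

    def test_disjoint_zero(self):
        assert overlap_length(iset([("chr1", 0, 100)]), iset([("chr2", 0, 100)])) == 0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(29)
        chrom_len = 1_000_000

        def random_set(seed):
            r = np.random.default_rng(seed)
            starts = r.integers(0, chrom_len - 5000, 200)
            lens = r.integers(100, 5000, 200)
            return IntervalSet(
                pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + lens})
            )

        a, b = random_set(1), random_set(2)
        ab = overlap_length(a, b)
        assert ab == overlap_length(b, a)
        am, bm = merge_intervals(a), merge_intervals(b)
        assert ab <= min(am.total_length, bm.total_length)
        # per-bp mask oracle
        ma = np.zeros(chrom_len, dtype=bool)
        mb = np.zeros(chrom_len, dtype=bool)
        for row in a.intervals.itertuples():
            ma[row.start:row.end] = True
        for row in b.intervals.itertuples():
            mb[row.start:row.end] = True
        assert ab == int((ma & mb).sum())


class TestCoverageTable:
    def test_reproduces_printed_gene_intergenic_split(self):
        """A CNVR set of 22.75/13.56 Mb with 1.91/1.31 Mb gene overlap
        must yield the familiar 8.40/9.66/8.87% gene percentages."""
        genome = GenomeModel(chromosomes={"chr1": 2_830_000_000})
        cnvrs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 100_000_000],
                "end": [22_750_000, 113_560_000],
                "status": ["gain", "loss"],
            }
        )
        genes = iset(
            [
                ("chr1", 0, 1_910_000),                  # inside the gain CNVR
                ("chr1", 100_000_000, 101_310_000),      # inside the loss CNVR
                ("chr1", 2_000_000_000, 2_601_095_000),  # elsewhere
            ],
            merged=True,
        )
        table = coverage_table(cnvrs, genes, genome).set_index("region")
        assert table.loc["Gain", "gene_pct"] == pytest.approx(8.40, abs=0.005)
        assert table.loc["Gain", "intergenic_pct"] == pytest.approx(91.60, abs=0.005)
        assert table.loc["Gain", "intergenic_bp"] == 20_840_000
        assert table.loc["Loss", "gene_pct"] == pytest.approx(9.66, abs=0.005)
        assert table.loc["Loss", "intergenic_pct"] == pytest.approx(90.34, abs=0.005)
        assert table.loc["Total", "gene_pct"] == pytest.approx(8.87, abs=0.005)
        assert table.loc["Total", "intergenic_pct"] == pytest.approx(91.13, abs=0.005)
        assert table.loc["Genome", "gene_pct"] == pytest.approx(21.35, abs=0.01)

    def test_cnvrs_entirely_inside_genes(self):
        genome = GenomeModel(chromosomes={"chr1": 1_000_000})
        cnvrs = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100_000], "end": [200_000], "status": ["gain"]}
        )
        genes = iset([("chr1", 50_000, 250_000)], merged=True)
        table = coverage_table(cnvrs, genes, genome).set_index("region")
        assert table.loc["Gain", "intergenic_bp"] == 0
        assert table.loc["Gain", "gene_pct"] == pytest.approx(100.0)


class TestGenesOverlapping:
    @staticmethod
    def gene_frame(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "strand"])

    def test_single_bp_overlap_counts(self):
        genes = self.gene_frame([("chr1", 100, 200, "g1", "+")])
        cnvrs = pd.DataFrame(
            {"chrom": ["chr1"], "start": [199], "end": [300], "status": ["gain"]}
        )
        assert genes_overlapping(cnvrs, genes)["gain"] == ["g1"]

    def test_bookended_half_open_excluded(self):
        genes = self.gene_frame([("chr1", 100, 200, "g1", "+")])
        cnvrs = pd.DataFrame(
            {"chrom": ["chr1"], "start": [200], "end": [300], "status": ["gain"]}
        )
        assert genes_overlapping(cnvrs, genes)["gain"] == []

    def test_planted_genes_recovered_exactly(self):
        rng = np.random.default_rng(7)
        genes = self.gene_frame(
            [("chr1", i * 10_000, i * 10_000 + 2_000, f"g{i}", "+") for i in range(50)]
        )
        cnvrs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [95_000, 300_000],
                "end": [155_000, 342_000],
                "status": ["gain", "loss"],
            }
        )
        out = genes_overlapping(cnvrs, genes)
        assert out["gain"] == [f"g{i}" for i in range(10, 16)]
        assert out["loss"] == [f"g{i}" for i in range(30, 35)]


class TestRandomIntervalTest:
    def test_features_covering_genome_degenerate(self):
        genome = GenomeModel(chromosomes={"chr1": 10_000})
        features = iset([("chr1", 0, 10_000)], merged=True)
        query = iset([("chr1", 100, 600), ("chr1", 2_000, 2_300)])
        res = random_interval_test(query, features, genome, n_rounds=200, seed=1)
        assert res.observed == 800
        assert (res.null_overlaps == 800).all()
        assert res.p_value == 1.0

    def test_toy_case_matches_exhaustive_enumeration(self):
        """One query of length 2 on a 6 bp chromosome with features [0,3):
        the 5 equiprobable placements overlap {2, 2, 1, 0, 0}."""
        genome = GenomeModel(chromosomes={"chr1": 6})
        features = iset([("chr1", 0, 3)], merged=True)
        query = iset([("chr1", 4, 6)])
        res = random_interval_test(query, features, genome, n_rounds=10_000, seed=2)
        counts = pd.Series(res.null_overlaps).value_counts(normalize=True)
        assert counts[2] == pytest.approx(2 / 5, abs=0.02)
        assert counts[1] == pytest.approx(1 / 5, abs=0.02)
        assert counts[0] == pytest.approx(2 / 5, abs=0.02)
        assert res.observed == 0

    def test_null_calibration(self):
        """Independent random query and features: depletion p < 0.05 in
        roughly 5% of replicate datasets."""
        genome = GenomeModel(chromosomes={"chr1": 1_000_000})
        n_sig = 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(31_000 + r)
            fs = rng.integers(0, 990_000, 40)
            features = merge_intervals(
                IntervalSet(pd.DataFrame({"chrom": "chr1", "start": fs, "end": fs + 8_000}))
            )
            qs = rng.integers(0, 980_000, 15)
            query = IntervalSet(
                pd.DataFrame({"chrom": "chr1", "start": qs, "end": qs + 15_000})
            )
            res = random_interval_test(
                query, features, genome, n_rounds=500, seed=32_000 + r
            )
            n_sig += res.p_value < 0.05
        assert 0.0 <= n_sig / reps <= 0.12

    def test_null_mean_scales_with_feature_coverage(self):
        genome = GenomeModel(chromosomes={"chr1": 1_000_000})
        single = iset(
            [("chr1", i * 100_000, i * 100_000 + 10_000) for i in range(10)], merged=True
        )
        double = iset(
            [("chr1", i * 100_000, i * 100_000 + 20_000) for i in range(10)], merged=True
        )
        query = iset([("chr1", 0, 20_000), ("chr1", 500_000, 530_000)])
        r1 = random_interval_test(query, single, genome, n_rounds=2_000, seed=5)
        r2 = random_interval_test(query, double, genome, n_rounds=2_000, seed=6)
        assert r2.expected / r1.expected == pytest.approx(2.0, rel=0.05)

    def test_p_value_never_zero_and_deterministic(self):
        genome = GenomeModel(chromosomes={"chr1": 100_000})
        features = iset([("chr1", 0, 50_000)], merged=True)
        query = iset([("chr1", 60_000, 61_000)])
        a = random_interval_test(query, features, genome, n_rounds=300, seed=9)
        b = random_interval_test(query, features, genome, n_rounds=300, seed=9)
        assert a.p_value > 0
        assert np.array_equal(a.null_overlaps, b.null_overlaps)

    def test_oversized_interval_rejected(self):
        genome = GenomeModel(chromosomes={"chr1": 10_000})
        features = iset([("chr1", 0, 1_000)], merged=True)
        query = iset([("chr1", 0, 10_000)])
        # length 10000 fits exactly; length > chrom does not
        query_bad = IntervalSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [20_000]})
        )
        with pytest.raises(PlacementError):
            random_interval_test(query_bad, features, genome, n_rounds=10, seed=1)
        random_interval_test(query, features, genome, n_rounds=10, seed=1)
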