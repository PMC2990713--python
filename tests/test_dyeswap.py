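import numpy as np
import pandas as pd
import pytest

from cghcnv.dyeswap import (
    cluster_arrays,
    correct_dye_bias,
    fit_dye_model,
    merge_samples,
    significant_beta_fraction,
    validate_design,
)
from cghcnv.errors import StructuralError
from cghcnv.genome import plant_cnvs
from cghcnv.preprocess import preprocess_scan
from cghcnv.simulate import DyeBiasSpec, make_dye_bias, simulate_study


ARRAYS = ["s1_F", "s2_F", "s3_F", "s1_R", "s2_R", "s3_R"]


def design_3x2():
    return pd.DataFrame(
        {
            "array_id": ARRAYS,
            "sample_id": ["s1", "s2", "s3", "s1", "s2", "s3"],
            "orientation": ["forward"] * 3 + ["reverse"] * 3,
        }
    )


def m_table(rows):
    return pd.DataFrame(rows, columns=ARRAYS)


class TestFitDyeModel:
    def test_balanced_closed_form(self):
        """Forward (1,1,1) / reverse-oriented (0,0,0): alpha = grand mean,
        beta = half the forward-minus-reverse difference."""
        m = m_table([[1.0, 1.0, 1.0, 0.0, 0.0, 0.0]])
        fits = fit_dye_model(m, design_3x2())
        assert fits["alpha"].iloc[0] == pytest.approx(0.5)
        assert fits["beta"].iloc[0] == pytest.approx(0.5)

    def test_constant_spot_has_zero_beta(self):
        m = m_table([[0.7] * 6])
        fits = fit_dye_model(m, design_3x2())
        assert fits["alpha"].iloc[0] == pytest.approx(0.7)
        assert fits["beta"].iloc[0] == pytest.approx(0.0)

    def test_alpha_equals_mean_of_oriented_values(self):
        rng = np.random.default_rng(8)
        m = m_table(rng.normal(0, 0.3, (50, 6)))
        fits = fit_dye_model(m, design_3x2())
        assert np.allclose(fits["alpha"], m.mean(axis=1))

    def test_single_dye_level_skipped(self):
        m = m_table([[1.0, 1.2, 0.8, np.nan, np.nan, np.nan]])
        fits = fit_dye_model(m, design_3x2())
        assert not fits["fitted"].iloc[0]
        assert np.isnan(fits["beta"].iloc[0])

    def test_partial_missingness_still_fitted(self):
        m = m_table([[1.0, 1.2, np.nan, 0.1, np.nan, 0.3]])
        fits = fit_dye_model(m, design_3x2())
        assert fits["fitted"].iloc[0]
        assert fits["n_obs"].iloc[0] == 4

    def test_null_calibration(self):
        """Type-I error of the beta t-test at the 0.05 level on a null
        simulation (no dye bias, pure noise)."""
        rng = np.random.default_rng(11)
        m = m_table(rng.normal(0.0, 0.2, (10_000, 6)))
        fits = fit_dye_model(m, design_3x2())
        frac = significant_beta_fraction(fits, 0.05)
        assert 0.04 <= frac <= 0.06

    def test_planted_bias_recovered(self):
        rng = np.random.default_rng(12)
        n = 2000
        noise_sd = 0.15
        bias = rng.normal(0, 0.3, n)
        dye = np.array([1, 1, 1, -1, -1, -1])
        m = np.outer(bias, dye) + rng.normal(0, noise_sd, (n, 6))
        fits = fit_dye_model(m_table(m), design_3x2())
        mae = np.abs(fits["beta"].to_numpy() - bias).mean()
        assert mae < noise_sd / np.sqrt(3)


class TestCorrectDyeBias:
    def test_closed_form_correction(self):
        m = m_table([[1.0, 1.0, 1.0, 0.0, 0.0, 0.0]])
        design = design_3x2()
        fits = fit_dye_model(m, design)
        corr = correct_dye_bias(m, fits, design)
        assert np.allclose(corr.to_numpy(), 0.5)

    def test_zero_beta_unchanged(self):
        m = m_table([[0.3] * 6])
        design = design_3x2()
        corr = correct_dye_bias(m, fit_dye_model(m, design), design)
        assert np.allclose(corr.to_numpy(), 0.3)

    def test_refit_on_corrected_gives_zero_beta(self):
        rng = np.random.default_rng(13)
        m = m_table(rng.normal(0, 0.5, (100, 6)))
        design = design_3x2()
        corr = correct_dye_bias(m, fit_dye_model(m, design), design)
        refits = fit_dye_model(corr, design)
        assert np.abs(refits["beta"]).max() < 1e-12

    def test_invariant_to_global_dye_relabeling(self):
        """Swapping every forward/reverse label flips beta's sign but
        leaves the corrected M values unchanged."""
        rng = np.random.default_rng(14)
        m = m_table(rng.normal(0, 0.5, (80, 6)))
        design = design_3x2()
        flipped = design.copy()
        flipped["orientation"] = flipped["orientation"].map(
            {"forward": "reverse", "reverse": "forward"}
        )
        corr = correct_dye_bias(m, fit_dye_model(m, design), design)
        corr_flipped = correct_dye_bias(m, fit_dye_model(m, flipped), flipped)
        assert np.allclose(corr.to_numpy(), corr_flipped.to_numpy(), atol=1e-12)

    def test_missing_fit_passes_through(self):
        m = m_table([[1.0, 1.2, 0.8, np.nan, np.nan, np.nan]])
        design = design_3x2()
        corr = correct_dye_bias(m, fit_dye_model(m, design), design)
        assert np.allclose(
            corr.to_numpy()[0][:3], [1.0, 1.2, 0.8]
        )


class TestClusterDiagnostic:
    def test_identical_arrays_merge_first_at_zero_height(self):
        rng = np.random.default_rng(15)
        base = rng.normal(0, 0.3, (200, 6))
        base[:, 3] = base[:, 0]  # s1_R identical to s1_F
        cl = cluster_arrays(m_table(base))
        first = cl.first_merges()[0]
        assert first == frozenset({"s1_F", "s1_R"})
        assert cl.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_needs_two_arrays(self):
        with pytest.raises(StructuralError):
            cluster_arrays(pd.DataFrame({"a": [0.1, 0.2, 0.3]}))

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(16)
        cl = cluster_arrays(m_table(rng.normal(0, 1, (50, 6))))
        nwk = cl.newick()
        assert nwk.endswith(";")
        for a in ARRAYS:
            assert a in nwk


@pytest.fixture(scope="module")
def study_tables(small_genome, small_layout):
    truth = plant_cnvs(
        small_genome, 4, length_range=(80_000, 200_000), shared_fraction=0.5, seed=2
    )
    study = simulate_study(
        small_genome,
        truth,
        small_layout,
        bias_spec=DyeBiasSpec(sd=0.05, big_fraction=0.25, big_magnitude=0.4),
        noise_sd=0.15,
        seed=2,
    )
    tables = {s.array_id: preprocess_scan(s) for s in study.scans}
    m = pd.DataFrame({k: v.set_index("probe_id")["M"] for k, v in tables.items()})
    return study, m


class TestStudyDiagnostic:
    """Dye-bias separation before correction, dye-swap pairing after."""

    def test_before_correction_arrays_split_by_dye(self, study_tables):
        study, m = study_tables
        cl = cluster_arrays(m)
        fwd = frozenset(s.array_id for s in study.scans if s.orientation == "forward")
        rev = frozenset(s.array_id for s in study.scans if s.orientation == "reverse")
        assert cl.partition() == frozenset({fwd, rev})

    def test_after_correction_dye_swap_pairs_rejoin(self, study_tables):
        study, m = study_tables
        design = study.design()
        corr = correct_dye_bias(m, fit_dye_model(m, design), design)
        cl = cluster_arrays(corr)
        fwd = frozenset(s.array_id for s in study.scans if s.orientation == "forward")
        rev = frozenset(s.array_id for s in study.scans if s.orientation == "reverse")
        assert cl.partition() != frozenset({fwd, rev})
        pairs = {
            frozenset(sub["array_id"]) for _, sub in design.groupby("sample_id")
        }
        assert set(cl.first_merges()) <= pairs


class TestMergeSamples:
    def test_pair_mean_and_replicate_average(self, small_layout):
        design = pd.DataFrame(
            {
                "array_id": ["s1_F", "s1_R"],
                "sample_id": ["s1", "s1"],
                "orientation": ["forward", "reverse"],
            }
        )
        probe_ids = small_layout.probes["probe_id"]
        m = pd.DataFrame(
            {"s1_F": np.full(len(probe_ids), 0.4), "s1_R": np.full(len(probe_ids), 0.6)},
            index=probe_ids,
        )
        merged = merge_samples(m, design, small_layout)
        assert np.allclose(merged["s1"], 0.5)
        # replicate probes collapsed: one row per locus
        loci = small_layout.probes[["chrom", "start", "end"]].drop_duplicates()
        assert len(merged) == len(loci)

    def test_replicate_probes_averaged_to_single_locus(self):
        from cghcnv.simulate import ChipLayout

        probes = pd.DataFrame(
            {
                "probe_id": ["p0", "p1", "r0"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [100, 500, 100],
                "end": [160, 560, 160],
                "grid_row": [0, 0, 0],
                "grid_col": [0, 1, 2],
            }
        )
        layout = ChipLayout(probes, n_rows=1, n_cols=3)
        design = pd.DataFrame(
            {
                "array_id": ["a_F", "a_R"],
                "sample_id": ["s1", "s1"],
                "orientation": ["forward", "reverse"],
            }
        )
        m = pd.DataFrame(
            {"a_F": [0.1, 0.8, 0.3], "a_R": [0.1, 0.8, 0.3]},
            index=["p0", "p1", "r0"],
        )
        merged = merge_samples(m, design, layout)
        assert len(merged) == 2
        locus = merged[merged["start"] == 100]["s1"].iloc[0]
        assert locus == pytest.approx(0.2)  # mean of 0.1 and 0.3

    def test_unpaired_array_raises(self, small_layout):
        design = pd.DataFrame(
            {
                "array_id": ["s1_F", "s2_F", "s2_R"],
                "sample_id": ["s1", "s2", "s2"],
                "orientation": ["forward", "forward", "reverse"],
            }
        )
        m = pd.DataFrame(
            np.zeros((len(small_layout), 3)),
            index=small_layout.probes["probe_id"],
            columns=design["array_id"],
        )
        with pytest.raises(StructuralError, match="s1"):
            merge_samples(m, design, small_layout)

    def test_zero_noise_merged_m_matches_truth(self, small_genome, small_layout):
        truth = plant_cnvs(
            small_genome, 3, length_range=(100_000, 200_000), shared_fraction=0.0, seed=5
        )
        study = simulate_study(
            small_genome,
            truth,
            small_layout,
            bias_spec=DyeBiasSpec(sd=0.0, big_fraction=0.0),
            noise_sd=0.0,
            seed=6,
        )
        tables = {s.array_id: preprocess_scan(s, normalize=False) for s in study.scans}
        m = pd.DataFrame({k: v.set_index("probe_id")["M"] for k, v in tables.items()})
        design = study.design()
        corr = correct_dye_bias(m, fit_dye_model(m, design), design)
        merged = merge_samples(corr, design, small_layout)
        for sample in truth.sample_ids:
            expected = np.zeros(len(merged))
            for row in truth.for_sample(sample).itertuples():
                inside = (
                    (merged["chrom"] == row.chrom)
                    & (merged["start"] < row.end)
                    & (merged["end"] > row.start)
                ).to_numpy()
                expected[inside] = np.log2(row.copy_state / 2)
            assert np.allclose(merged[sample].to_numpy(), expected, atol=1e-9)


def test_design_validation_requires_both_orientations():
    bad = pd.DataFrame(
        {
            "array_id": ["a", "b"],
            "sample_id": ["s", "s"],
            "orientation": ["forward", "forward"],
        }
    )
    with pytest.raises(StructuralError):
        validate_design(bad)
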