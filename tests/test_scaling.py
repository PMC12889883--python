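import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scaledabund import (
    BiasModel,
    CommunityDesign,
    CountTable,
    InternalStandardSpec,
    RelativeAbundanceTable,
    SequencingModel,
    SpikeTruth,
    estimate_bias_ratio,
    fold_change,
    quantify_actual,
    relative_abundance,
    scaled_abundance,
    simulate_counts,
)
from scaledabund.errors import ConfigError, ValidationError


def _ra(rows: dict, samples) -> RelativeAbundanceTable:
    return RelativeAbundanceTable(pd.DataFrame(rows, index=samples))


class TestRelativeAbundance:
    def test_direct_division(self):
        table = CountTable(pd.DataFrame({"a": [30.0], "b": [70.0]}, index=["s"]))
        ra = relative_abundance(table)
        assert ra.data.loc["s"].tolist() == [0.30, 0.70]

    def test_only_taxon_present_gets_ra_one(self):
        table = CountTable(pd.DataFrame({"a": [50.0], "b": [0.0]}, index=["s"]))
        assert relative_abundance(table).data.loc["s", "a"] == 1.0

    def test_equal_counts_symmetry(self):
        table = CountTable(
            pd.DataFrame({t: [10.0] for t in "abcd"}, index=["s"])
        )
        assert (relative_abundance(table).data.loc["s"] == 0.25).all()

    def test_zero_total_names_sample(self):
        table = CountTable(
            pd.DataFrame({"a": [1.0, 0.0], "b": [1.0, 0.0]}, index=["s1", "s2"])
        )
        with pytest.raises(ValidationError, match="s2"):
            relative_abundance(table)

    def test_proportions_pass_through(self):
        table = CountTable(
            pd.DataFrame({"a": [0.2], "b": [0.8]}, index=["s"]), mode="proportions"
        )
        assert relative_abundance(table).data.loc["s", "b"] == 0.8

    def test_pseudocount_shifts_counts(self):
        table = CountTable(pd.DataFrame({"a": [0.0], "b": [98.0]}, index=["s"]))
        ra = relative_abundance(table, pseudocount=1.0)
        assert ra.data.loc["s", "a"] == pytest.approx(1 / 100)


class TestScaledAbundance:
    def test_equal_ra_gives_is_abundance(self):
        ra = _ra({"z": [0.3], "IS": [0.3], "other": [0.4]}, ["s"])
        sa = scaled_abundance(ra, InternalStandardSpec("IS", 2.16e5))
        assert sa.data.loc["s", "z"] == pytest.approx(2.16e5)

    def test_direct_substitution(self):
        ra = _ra({"z": [0.04], "IS": [0.01], "other": [0.95]}, ["s"])
        sa = scaled_abundance(ra, InternalStandardSpec("IS", 1000.0))
        assert sa.data.loc["s", "z"] == pytest.approx(4000.0)

    def test_zero_ra_gives_zero_sa(self):
        ra = _ra({"z": [0.0], "IS": [0.5], "other": [0.5]}, ["s"])
        sa = scaled_abundance(ra, InternalStandardSpec("IS", 1000.0))
        assert sa.data.loc["s", "z"] == 0.0

    def test_is_column_exact(self, toy_counts, is_spec):
        sa = scaled_abundance(relative_abundance(toy_counts), is_spec)
        assert (sa.data["IS"] == is_spec.actual_abundance).all()
        assert sa.is_taxon_id == "IS"
        assert sa.units == "copies/mcL"

    def test_missing_is_taxon(self, toy_counts):
        ra = relative_abundance(toy_counts)
        with pytest.raises(ConfigError, match="ghost"):
            scaled_abundance(ra, InternalStandardSpec("ghost", 1.0))

    def test_zero_is_errors_by_default_and_drops_on_flag(self):
        ra = _ra({"z": [0.5, 0.4], "IS": [0.0, 0.2], "w": [0.5, 0.4]}, ["s1", "s2"])
        spec = InternalStandardSpec("IS", 100.0)
        with pytest.raises(ValidationError, match="s1"):
            scaled_abundance(ra, spec)
        sa = scaled_abundance(ra, spec, on_zero_is="drop")
        assert sa.sample_ids == ["s2"]


class TestBiasRatio:
    def test_exact_replicates_zero_width_ci(self):
        df = pd.DataFrame({"z": [100.0] * 3, "IS": [1.0] * 3}, index=list("abc"))
        from scaledabund.scaling import ScaledAbundanceTable

        table = ScaledAbundanceTable(df, is_taxon_id="IS")
        truth = SpikeTruth.uniform({"z": 100.0})
        est = estimate_bias_ratio(table, truth, list("abc"))["z"]
        assert est.point == 1.0 and est.ci_low == 1.0 and est.ci_high == 1.0

    def test_hand_computed_t_interval(self):
        """SAs {200, 220, 180} over truth 100: mean 2.0, sd 0.2,
        t(0.975, df=2) = 4.3027 -> CI (1.5031, 2.4969)."""
        from scaledabund.scaling import ScaledAbundanceTable

        df = pd.DataFrame(
            {"z": [200.0, 220.0, 180.0], "IS": [1.0] * 3}, index=list("abc")
        )
        table = ScaledAbundanceTable(df, is_taxon_id="IS")
        est = estimate_bias_ratio(table, SpikeTruth.uniform({"z": 100.0}), list("abc"))[
            "z"
        ]
        assert est.point == pytest.approx(2.0)
        assert est.ci_low == pytest.approx(2.0 - 4.302652729911275 * 0.2 / 3**0.5)
        assert est.ci_high == pytest.approx(2.0 + 4.302652729911275 * 0.2 / 3**0.5)
        assert est.n_replicates == 3

    def test_geometric_aggregation_is_log_space_mean(self):
        from scaledabund.scaling import ScaledAbundanceTable

        df = pd.DataFrame({"z": [100.0, 400.0], "IS": [1.0] * 2}, index=["a", "b"])
        table = ScaledAbundanceTable(df, is_taxon_id="IS")
        est = estimate_bias_ratio(
            table, SpikeTruth.uniform({"z": 100.0}), ["a", "b"],
            aggregation="geometric",
        )["z"]
        assert est.point == pytest.approx(2.0)  # sqrt(1 * 4)

    def test_needs_two_replicates(self, toy_sa):
        with pytest.raises(ValidationError, match=">= 2"):
            estimate_bias_ratio(toy_sa, SpikeTruth.uniform({"taxon_a": 1.0}), ["s1"])

    def test_absent_taxon_errors(self, toy_sa):
        with pytest.raises(ValidationError, match="ghost"):
            estimate_bias_ratio(
                toy_sa, SpikeTruth.uniform({"ghost": 1.0}), ["s1", "s2"]
            )

    def test_ci_covers_generator_ratio(self, rng):
        """Nominal-95% t-interval covers the true bias ratio in most seeded
        multinomial runs (5 replicates, depth 1e5)."""
        taxa = ["spike", "filler", "IS"]
        design = CommunityDesign(
            pd.DataFrame(
                [[100.0, 1e4, 500.0]] * 5,
                index=[f"r{i}" for i in range(5)],
                columns=taxa,
            )
        )
        bias = BiasModel(pd.Series({"spike": 3.0, "filler": 1.0, "IS": 1.0}))
        seq = SequencingModel(depth=100_000)
        hits = 0
        n_runs = 60
        for _ in range(n_runs):
            table, bundle = simulate_counts(design, bias, seq, rng=rng)
            sa = scaled_abundance(
                relative_abundance(table), InternalStandardSpec("IS", 500.0)
            )
            est = estimate_bias_ratio(
                sa, SpikeTruth.uniform({"spike": 100.0}), design.sample_ids
            )["spike"]
            hits += est.ci_low <= 3.0 <= est.ci_high
        assert hits / n_runs >= 0.85


class TestQuantifyActual:
    def _sa(self, values):
        from scaledabund.scaling import ScaledAbundanceTable

        return ScaledAbundanceTable(values, is_taxon_id="IS")

    def test_unit_bias_is_identity(self, toy_sa):
        from scaledabund.scaling import BiasRatioEstimate

        bias = {
            "taxon_a": BiasRatioEstimate("taxon_a", 1.0, 1.0, 1.0, 3),
        }
        est = quantify_actual(toy_sa, bias)
        pd.testing.assert_series_equal(est.data["taxon_a"], toy_sa.data["taxon_a"])

    def test_direct_division_and_ci_propagation(self):
        from scaledabund.scaling import BiasRatioEstimate

        sa = self._sa(pd.DataFrame({"z": [4000.0], "IS": [1.0]}, index=["s"]))
        bias = {"z": BiasRatioEstimate("z", 2.0, 1.6, 2.5, 3)}
        est = quantify_actual(sa, bias)
        assert est.data.loc["s", "z"] == pytest.approx(2000.0)
        assert est.ci_low.loc["s", "z"] == pytest.approx(4000.0 / 2.5)
        assert est.ci_high.loc["s", "z"] == pytest.approx(4000.0 / 1.6)

    def test_missing_bias_lists_taxa(self, toy_sa):
        with pytest.raises(ValidationError, match="taxon_a"):
            quantify_actual(toy_sa, {}, ["taxon_a"])


class TestFoldChange:
    def test_self_pair_is_unity(self, toy_sa):
        fc = fold_change(toy_sa, [("s1", "s1")])
        assert (fc.data.loc[("s1", "s1")].dropna() == 1.0).all()

    def test_zero_sa_gives_nan_not_inf(self):
        from scaledabund.scaling import ScaledAbundanceTable

        sa = ScaledAbundanceTable(
            pd.DataFrame({"z": [5.0, 0.0], "IS": [1.0, 1.0]}, index=["a", "b"])
        )
        fc = fold_change(sa, [("a", "b")])
        assert np.isnan(fc.data.loc[("a", "b"), "z"])

    def test_unknown_sample(self, toy_sa):
        with pytest.raises(ValidationError, match="nope"):
            fold_change(toy_sa, [("s1", "nope")])

    def test_pair_order_recorded(self, toy_sa):
        fc = fold_change(toy_sa, [("s2", "s1"), ("s1", "s2")])
        a = fc.data.loc[("s2", "s1"), "taxon_a"]
        b = fc.data.loc[("s1", "s2"), "taxon_a"]
        assert a == pytest.approx(1.0 / b)


class TestModelIdentities:
    """Noise-free (expectation-mode) identities of the measurement model."""

    @settings(max_examples=50, deadline=None)
    @given(
        background=st.lists(
            st.floats(min_value=1.0, max_value=1e6), min_size=2, max_size=6
        ),
        data=st.data(),
    )
    def test_composition_invariance(self, background, data):
        """For fixed taxon and IS actual abundance, SA is invariant to
        arbitrary changes in all other taxa's abundances."""
        n = len(background)
        biases = data.draw(
            st.lists(
                st.floats(min_value=0.01, max_value=100.0),
                min_size=n + 2,
                max_size=n + 2,
            )
        )
        a_z, a_is = 250.0, 1000.0
        taxa = [f"bg{i}" for i in range(n)] + ["z", "IS"]
        design = CommunityDesign(
            pd.DataFrame(
                [list(background) + [a_z, a_is], [1.0] * n + [a_z, a_is]],
                index=["varied", "reference"],
                columns=taxa,
            )
        )
        bias = BiasModel(pd.Series(biases, index=taxa))
        table, _ = simulate_counts(
            design, bias, SequencingModel(depth=10**6, noise="expectation")
        )
        sa = scaled_abundance(
            relative_abundance(table), InternalStandardSpec("IS", a_is)
        )
        np.testing.assert_allclose(
            sa.data.loc["varied", "z"], sa.data.loc["reference", "z"], rtol=1e-9
        )

    def test_scale_free_in_counts(self, toy_counts, is_spec):
        sa1 = scaled_abundance(relative_abundance(toy_counts), is_spec)
        scaled = CountTable(toy_counts.data * 37.5)
        sa2 = scaled_abundance(relative_abundance(scaled), is_spec)
        np.testing.assert_allclose(sa1.values, sa2.values, rtol=1e-12)

    def test_sa_equals_abundance_times_bias_ratio(self, rng):
        """In expectation mode SA_z / A_z equals the generator's bias ratio
        for every taxon, sample and composition."""
        taxa = [f"t{i}" for i in range(8)] + ["IS"]
        design = CommunityDesign(
            pd.DataFrame(
                rng.uniform(10.0, 1e5, size=(4, 9)),
                index=[f"s{i}" for i in range(4)],
                columns=taxa,
            )
        )
        design.abundances["IS"] = 2.16e5
        bias = BiasModel.lognormal(taxa, sigma=1.0, rng=rng)
        table, bundle = simulate_counts(
            design, bias, SequencingModel(depth=10**6, noise="expectation")
        )
        bundle.is_spec = InternalStandardSpec("IS", 2.16e5)
        sa = scaled_abundance(relative_abundance(table), bundle.is_spec)
        for taxon in taxa[:-1]:
            expected = bundle.bias_ratio(taxon)
            ratios = sa.data[taxon] / design.abundances[taxon]
            np.testing.assert_allclose(ratios, expected, rtol=1e-9)

    def test_fold_change_equals_abundance_ratio_exactly(self):
        taxa = ["z", "w", "IS"]
        design = CommunityDesign(
            pd.DataFrame(
                [[100.0, 5000.0, 300.0], [200.0, 1234.0, 300.0]],
                index=["before", "after"],
                columns=taxa,
            )
        )
        bias = BiasModel(pd.Series([2.5, 0.3, 1.7], index=taxa))
        table, _ = simulate_counts(
            design, bias, SequencingModel(depth=10**6, noise="expectation")
        )
        sa = scaled_abundance(
            relative_abundance(table), InternalStandardSpec("IS", 300.0)
        )
        fc = fold_change(sa, [("after", "before")])
        assert fc.data.loc[("after", "before"), "z"] == pytest.approx(2.0, rel=1e-12)

    def test_quantify_recovers_truth_in_expectation(self, rng):
        """quantify(scale(...), estimate_bias(...)) returns the generator
        abundances to 1e-9 relative in expectation mode."""
        taxa = ["spike1", "spike2", "bulk", "IS"]
        design = CommunityDesign(
            pd.DataFrame(
                [[480.0, 96.0, 9e4, 2160.0]] * 3,
                index=["r1", "r2", "r3"],
                columns=taxa,
            )
        )
        bias = BiasModel.lognormal(taxa, sigma=1.0, rng=rng)
        table, _ = simulate_counts(
            design, bias, SequencingModel(depth=10**6, noise="expectation")
        )
        sa = scaled_abundance(
            relative_abundance(table), InternalStandardSpec("IS", 2160.0)
        )
        truth = SpikeTruth.uniform({"spike1": 480.0, "spike2": 96.0})
        est_bias = estimate_bias_ratio(sa, truth, ["r1", "r2", "r3"])
        est = quantify_actual(sa, est_bias)
        np.testing.assert_allclose(est.data["spike1"], 480.0, rtol=1e-9)
        np.testing.assert_allclose(est.data["spike2"], 96.0, rtol=1e-9)
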