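import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from ancinv import iim, simulate
from ancinv.io import GenomePartition

PARAM_POINTS = {
    "iso": iim.ModelParams.iso(1.0, 2.0, 1.5, 1.2),
    "im": iim.ModelParams.im(1.0, 2.0, 1.5, 2.0, 0.5, 0.3),
    "iim": iim.ModelParams.iim(2.0, 2.0, 2.0, 1.5, 0.6, 0.5, 0.0),
}


class TestModelParams:
    def test_constraints_enforced(self):
        with pytest.raises(ValueError):
            iim.ModelParams("iso", 1, 1, 1, 1.0, t1=1.0, m1=0.5)
        with pytest.raises(ValueError):
            iim.ModelParams("im", 1, 1, 1, 1.0, t1=0.5)
        with pytest.raises(ValueError):
            iim.ModelParams.iim(1, 1, 1, 1.0, 1.5, 0, 0)  # t1 > t0
        with pytest.raises(ValueError):
            iim.ModelParams.iso(-1, 1, 1, 1.0)

    def test_free_parameter_counts(self):
        assert [iim.n_free_params(m) for m in iim.MODELS] == [4, 6, 7]


class TestPairCoalDensity:
    @pytest.mark.parametrize("model", list(PARAM_POINTS))
    @pytest.mark.parametrize("cls", iim.CLASSES)
    def test_density_integrates_to_one(self, model, cls):
        p = PARAM_POINTS[model]
        f = iim.pair_coal_density(p, cls)
        m1, _ = quad(f, 0, p.t0, limit=200)
        m2, _ = quad(f, p.t0, p.t0 + 60 * p.theta_anc, limit=200)
        assert m1 + m2 == pytest.approx(1.0, abs=1e-8)

    def test_iso_within_reduces_to_exponential(self):
        """With a very old split the within-pop density is Exp(mean theta)."""
        p = iim.ModelParams.iso(1.5, 1.0, 1.0, 60.0)
        f = iim.pair_coal_density(p, "within_pop1")
        t = np.linspace(0.01, 8, 50)
        assert np.allclose(f(t), np.exp(-t / 1.5) / 1.5, atol=1e-10)
        mean, _ = quad(lambda x: x * f(x), 0, 60)
        assert mean == pytest.approx(1.5, abs=1e-6)

    def test_iso_between_zero_before_split(self):
        p = PARAM_POINTS["iso"]
        f = iim.pair_coal_density(p, "between")
        assert np.all(f(np.linspace(0, p.t0 * 0.999, 20)) == 0)

    def test_strong_migration_approaches_panmixia(self):
        """Huge symmetric migration homogenizes the two demes: the between
        density approaches the single-population coalescent of the pooled
        deme (size theta1 + theta2 for a lineage pair)."""
        theta = 1.0
        p = iim.ModelParams.im(theta, theta, theta, 8.0, 400.0, 400.0)
        f = iim.pair_coal_density(p, "between")
        t = np.linspace(0.05, 3.0, 30)
        pooled = np.exp(-t / (2 * theta)) / (2 * theta)
        assert np.allclose(f(t), pooled, rtol=0.02)


class TestPmf:
    def test_iso_between_geometric_at_zero_split(self):
        p = iim.ModelParams.iso(1, 1, 1.0, 0.0)
        assert iim.pmf(p, "between", [0, 1, 2]) == pytest.approx([0.5, 0.25, 0.125])

    def test_iso_between_closed_form_at_log2(self):
        p = iim.ModelParams.iso(1, 1, 1.0, np.log(2))
        assert iim.pmf(p, "between", [0])[0] == pytest.approx(0.25, abs=1e-10)

    @pytest.mark.parametrize("model", list(PARAM_POINTS))
    @pytest.mark.parametrize("cls", iim.CLASSES)
    def test_pmf_sums_to_one(self, model, cls):
        p = PARAM_POINTS[model]
        s = np.arange(250)
        assert iim.pmf(p, cls, s).sum() == pytest.approx(1.0, abs=1e-8)

    def test_iso_between_matches_closed_form(self):
        for t0, tha, r in [(1.2, 1.5, 1.0), (0.3, 0.7, 2.0), (2.5, 1.0, 0.5)]:
            p = iim.ModelParams.iso(1.0, 1.0, tha, t0)
            s = np.arange(51)
            numeric = iim.pmf(p, "between", s, r=np.full(51, r))
            closed = iim.iso_between_pmf_closed(s, r, t0, tha)
            assert np.abs(numeric - closed).max() < 1e-8

    def test_matches_direct_quadrature(self):
        """Spot-check the piecewise pmf against brute scipy.integrate.quad."""
        p = PARAM_POINTS["iim"]
        f = iim.pair_coal_density(p, "between")
        import math

        for s in (0, 3, 7):
            direct, _ = quad(
                lambda t: f(t) * np.exp(-t) * t**s / math.factorial(s),
                0,
                p.t0 + 60 * p.theta_anc,
                limit=400,
            )
            assert iim.pmf(p, "between", [s])[0] == pytest.approx(direct, abs=1e-8)

    def test_relative_rate_scales_expectation(self):
        p = PARAM_POINTS["iso"]
        s = np.arange(300)
        mean_r1 = (s * iim.pmf(p, "between", s)).sum()
        mean_r2 = (s * iim.pmf(p, "between", s, r=np.full(300, 2.0))).sum()
        assert mean_r2 == pytest.approx(2 * mean_r1, rel=1e-6)


class TestLocusHelpers:
    def test_relative_rates_normalized(self):
        r = iim.relative_rates([0.02, 0.04])
        assert r == pytest.approx([2 / 3, 4 / 3])
        assert r.mean() == pytest.approx(1.0)

    def test_relative_rates_floor_and_errors(self):
        r = iim.relative_rates([0.0, 0.02])
        assert r[0] == 1e-3
        with pytest.raises(ValueError):
            iim.relative_rates([0.0, 0.0])

    def test_sample_loci_constraints(self):
        part = GenomePartition(
            "intergenic",
            pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 50_000], "end": [30_500, 50_400]}),
        )
        loci = iim.sample_loci(part, locus_len=500, min_gap=10_000, seed=3)
        # the 400 bp interval fits no locus; the 30,500 bp interval at most 3
        assert 1 <= len(loci) <= 3
        assert (loci["end"] - loci["start"] == 500).all()
        for c, sub in loci.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts[1:] - ends[:-1] >= 10_000).all()
        inside = [
            ((part.df["chrom"] == r.chrom) & (part.df["start"] <= r.start) & (part.df["end"] >= r.end)).any()
            for r in loci.itertuples()
        ]
        assert all(inside)

    def test_sample_loci_deterministic_and_sets(self):
        part = GenomePartition("ig", pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [500_000]}))
        a = iim.sample_loci(part, seed=11)
        b = iim.sample_loci(part, seed=11)
        assert a.equals(b)
        assert set(a["set"]) <= {0, 1, 2}
        counts = a["set"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_tiny_interval_places_nothing(self):
        part = GenomePartition("ig", pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [400]}))
        assert len(iim.sample_loci(part)) == 0


@pytest.fixture(scope="module")
def iso_loci():
    params = iim.ModelParams.iso(1.0, 1.5, 2.0, 1.0)
    loci, _ = simulate.make_locus_dataset(params, 800, seed=21)
    return loci


class TestFitting:
    def test_nesting_lnl_ordering(self, iso_loci):
        fits = {m: iim.fit_model(iso_loci, m, n_restarts=2, seed=0) for m in iim.MODELS}
        assert fits["iso"].lnl <= fits["im"].lnl + 1e-4
        assert fits["im"].lnl <= fits["iim"].lnl + 1e-4

    def test_fit_deterministic_given_seed(self, iso_loci):
        a = iim.fit_model(iso_loci, "iso", n_restarts=2, seed=5)
        b = iim.fit_model(iso_loci, "iso", n_restarts=2, seed=5)
        assert a.lnl == b.lnl and a.params == b.params

    def test_iso_recovery_within_ci(self, iso_loci):
        res = iim.fit_model(iso_loci, "iso", n_restarts=3, seed=1)
        truth = {"theta1": 1.0, "theta2": 1.5, "theta_anc": 2.0, "t0": 1.0}
        inside = 0
        for name, v in truth.items():
            ci = res.ci[name]
            assert ci is not None
            inside += ci[0] <= v <= ci[1]
        assert inside >= 3  # allow one marginal miss in a single replicate


class TestScaledLrt:
    def test_table_arithmetic_xl(self):
        stat, p = iim.scaled_lrt(-1390.10, -1372.71, x=7.75, df=3)
        assert stat == pytest.approx(4.49, abs=0.005)
        assert 0 < p < 1

    def test_table_arithmetic_xr(self):
        stat, _ = iim.scaled_lrt(-2241.11, -2225.54, x=7.75, df=1)
        assert stat == pytest.approx(4.02, abs=0.005)

    def test_equal_likelihoods(self):
        stat, p = iim.scaled_lrt(-10.0, -10.0, x=2.0, df=1)
        assert stat == 0.0 and p == 1.0

    def test_nesting_violation_raises(self):
        with pytest.raises(ValueError, match="nesting"):
            iim.scaled_lrt(-10.0, -20.0, x=1.0, df=1)


class TestHierarchicalFit:
    def test_identical_partitions_zero_lrt(self):
        params = iim.ModelParams.iso(1.0, 1.0, 1.0, 0.8)
        loci, _ = simulate.make_locus_dataset(params, 150, seed=2)
        free, lnl_free, shared, lnl_shared, df = iim.hierarchical_fit(
            {"a": loci, "b": loci.copy()}, model="iso", n_restarts=2, seed=0
        )
        assert df == 4
        assert lnl_free >= lnl_shared - 1e-3
        stat, _ = iim.scaled_lrt(lnl_shared, lnl_free, x=1.0, df=df)
        assert stat == pytest.approx(0.0, abs=0.05)

    def test_different_split_times_detected(self):
        a, _ = simulate.make_locus_dataset(iim.ModelParams.iso(1, 1, 1, 0.5), 400, seed=4)
        b, _ = simulate.make_locus_dataset(iim.ModelParams.iso(1, 1, 1, 2.5), 400, seed=5)
        _, lnl_free, _, lnl_shared, df = iim.hierarchical_fit(
            {"a": a, "b": b}, model="iso", n_restarts=2, seed=0
        )
        stat, p = iim.scaled_lrt(lnl_shared, lnl_free, x=1.0, df=df)
        assert p < 0.01

    def test_empty_partition_errors(self):
        loci, _ = simulate.make_locus_dataset(iim.ModelParams.iso(1, 1, 1, 1), 20, seed=1)
        with pytest.raises(ValueError, match="no loci"):
            iim.hierarchical_fit({"a": loci, "b": loci.iloc[:0]}, model="iso")


class TestMsprimeCrossCheck:
    def test_im_pair_time_mean_matches_msprime(self):
        """Independent oracle: mean between-pair coalescence time under IM
        from msprime agrees with our analytic density."""
        msprime = pytest.importorskip("msprime")
        theta1, theta2, tha, t0, m = 1.0, 1.0, 1.0, 2.0, 0.5
        params = iim.ModelParams.im(theta1, theta2, tha, t0, m, m)
        f = iim.pair_coal_density(params, "between")
        mean_analytic, _ = quad(lambda t: t * f(t), 0, 200, limit=400)
        # msprime with ploidy=1 coalesces a pair at rate 1/N per generation,
        # so initial_size = theta makes one generation one mutational unit.
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=theta1)
        dem.add_population(name="p2", initial_size=theta2)
        dem.add_population(name="anc", initial_size=tha)
        dem.set_migration_rate("p1", "p2", m / theta1)
        dem.set_migration_rate("p2", "p1", m / theta1)
        dem.add_population_split(time=t0, derived=["p1", "p2"], ancestral="anc")
        reps = msprime.sim_ancestry(
            samples={"p1": 1, "p2": 1},
            demography=dem,
            ploidy=1,
            num_replicates=4000,
            random_seed=17,
        )
        times = [ts.first().time(ts.first().root) for ts in reps]
        se = np.std(times) / np.sqrt(len(times))
        assert np.mean(times) == pytest.approx(mean_analytic, abs=4 * se)
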