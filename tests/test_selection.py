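"""EHH decay, additive-model association, and BH FDR control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from _oracles import brute_force_bh
from svdivkit.core import GenotypeMatrix, PhenotypeTable
from svdivkit.errors import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from svdivkit.selection import (
    HaplotypePanel,
    associate,
    association_scan,
    bh_fdr,
    ehh,
    ehh_curve,
    joint_association,
    joint_association as _joint,
    read_haplotypes,
    write_haplotypes,
)
from svdivkit.simulate import simulate_haplotypes, simulate_phenotypes, simulate_population_svs


def _panel(rows, positions=None, focal=None, allele=1):
    haps = np.array(rows, dtype=np.int8)
    m = haps.shape[1]
    positions = positions if positions is not None else np.arange(m) * 1000
    focal = m // 2 if focal is None else focal
    return HaplotypePanel(haplotypes=haps, positions=np.array(positions),
                          focal_index=focal, focal_allele=allele)


class TestEhh:
    def test_core_site_is_one(self):
        p = _panel([[0, 1, 0], [1, 1, 1], [0, 1, 1]], focal=1)
        assert ehh(p, p.focal_position) == 1.0

    def test_all_distinct_carriers(self):
        p = _panel([
            [0, 0, 1, 0, 0],
            [0, 1, 1, 1, 0],
            [1, 0, 1, 0, 1],
            [1, 1, 1, 1, 1],
        ], focal=2)
        assert ehh(p, p.positions[4]) == 0.0

    def test_two_identical_pairs(self):
        # 4 carriers forming two identical pairs: (1+1)/C(4,2) = 1/3
        p = _panel([
            [0, 1, 1, 0],
            [0, 1, 1, 0],
            [1, 1, 0, 1],
            [1, 1, 0, 1],
        ], focal=1)
        assert ehh(p, p.positions[3]) == pytest.approx(1 / 3)

    def test_too_few_carriers(self):
        p = _panel([[1, 1, 0], [0, 0, 0], [0, 0, 1]], focal=1)
        with pytest.raises(InsufficientDataError):
            ehh(p, p.positions[0])

    def test_position_must_be_a_site(self):
        p = _panel([[1, 1, 0], [1, 1, 0]], focal=1)
        with pytest.raises(ValidationError):
            ehh(p, 123456)


class TestEhhCurve:
    def test_complete_ld_is_flat(self):
        rows = [[1, 1, 1, 1, 1]] * 3 + [[0, 0, 0, 0, 0]] * 3
        curves = ehh_curve(_panel(rows, focal=2))
        for curve in curves.values():
            assert all(v == 1.0 for _, v in curve)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_nonincreasing_outward(self, seed):
        panel = simulate_haplotypes(n_haps=40, n_sites=21, sweep=False,
                                    seed=seed)
        curves = ehh_curve(panel)
        f = panel.focal_position
        for curve in curves.values():
            left = [v for pos, v in curve if pos <= f]
            right = [v for pos, v in curve if pos >= f]
            assert all(x <= y + 1e-12 for x, y in zip(left, left[1:]))
            assert all(x >= y - 1e-12 for x, y in zip(right, right[1:]))
            assert dict(curve)[f] == 1.0

    def test_sweep_carriers_dominate_within_span(self):
        sweep = simulate_haplotypes(n_haps=100, n_sites=41, sweep=True,
                                    sweep_span=500_000, seed=5)
        curves = ehh_curve(sweep)
        f = sweep.focal_position
        carrier = dict(curves[1])
        noncar = dict(curves[0])
        span = [p for p in carrier
                if 0 < abs(p - f) <= 250_000 and p in noncar]
        assert span, "no comparison sites inside the sweep span"
        assert all(carrier[p] >= noncar[p] for p in span)
        assert np.mean([carrier[p] - noncar[p] for p in span]) > 0.3

    def test_roundtrip_tsv(self, tmp_path):
        panel = simulate_haplotypes(n_haps=20, n_sites=11, seed=3)
        write_haplotypes(panel, tmp_path / "h.tsv")
        back = read_haplotypes(tmp_path / "h.tsv")
        np.testing.assert_array_equal(back.haplotypes, panel.haplotypes)
        np.testing.assert_array_equal(back.positions, panel.positions)
        assert back.focal_index == panel.focal_index


def _matrix_and_traits(n=60, beta=2.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, n).astype(float)
    y = beta * dosage + rng.normal(0, noise, n) if noise else beta * dosage
    g = GenotypeMatrix(
        [f"s{i}" for i in range(n)], ["locus"], dosage[:, None],
        {f"s{i}": "P" for i in range(n)},
    )
    t = PhenotypeTable([f"s{i}" for i in range(n)], ["trait"], y[:, None])
    return g, t


class TestAssociate:
    def test_exact_linear_relation(self):
        g, t = _matrix_and_traits(beta=2.0, noise=0.0)
        (res,) = associate(g, "locus", t)
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.p_value < 1e-20
        assert res.direction == 1

    def test_beta_equivariant_under_trait_scaling(self):
        g, t = _matrix_and_traits(beta=1.5, noise=1.0, seed=3)
        (res1,) = associate(g, "locus", t)
        t2 = PhenotypeTable(t.sample_ids, t.traits, t.values * 10)
        (res2,) = associate(g, "locus", t2)
        assert res2.beta == pytest.approx(10 * res1.beta)
        assert res2.p_value == pytest.approx(res1.p_value, rel=1e-9)

    def test_constant_dosage_errors(self):
        g, t = _matrix_and_traits()
        g.values[:] = 1.0
        with pytest.raises(UndefinedStatisticError):
            associate(g, "locus", t)

    def test_too_few_samples_errors(self):
        g, t = _matrix_and_traits(n=5)
        with pytest.raises(InsufficientDataError):
            associate(g, "locus", t)

    def test_pvalues_uniform_under_permutation(self):
        """Permuting the trait against genotype yields uniform p-values."""
        rng = np.random.default_rng(17)
        n = 120
        dosage = rng.integers(0, 3, n).astype(float)
        y = rng.normal(0, 1, n)
        samples = [f"s{i}" for i in range(n)]
        g = GenotypeMatrix(samples, ["locus"], dosage[:, None],
                           {s: "P" for s in samples})
        pvals = []
        for _ in range(400):
            t = PhenotypeTable(samples, ["trait"],
                               rng.permutation(y)[:, None])
            pvals.append(associate(g, "locus", t)[0].p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_recovers_planted_negative_pap_effect(self):
        """PAP-like trait with a planted beta of -3 per deletion allele is
        recovered within 2 SE."""
        g, _ = simulate_population_svs(n1=868, n2=94, seed=31)
        t = simulate_phenotypes(g, seed=32)
        (res,) = associate(g, "MKL1_del", t, trait_names=["PAP"])
        assert res.direction == -1
        assert abs(res.beta - (-3.0)) < 2 * res.se


class TestJointAssociation:
    def test_constant_second_locus_degenerates(self):
        rng = np.random.default_rng(5)
        n = 80
        d1 = rng.integers(0, 3, n).astype(float)
        d2 = np.ones(n)
        y = 1.2 * d1 + rng.normal(0, 1, n)
        samples = [f"s{i}" for i in range(n)]
        g = GenotypeMatrix(samples, ["a", "b"], np.column_stack([d1, d2]),
                           {s: "P" for s in samples})
        t = PhenotypeTable(samples, ["y"], y[:, None])
        (joint,) = joint_association(g, "a", "b", t)
        (single,) = associate(g, "a", t)
        assert joint.beta == pytest.approx(single.beta, abs=1e-10)
        assert joint.p_value == pytest.approx(single.p_value, rel=1e-9)

    def test_joint_signal_stronger_with_shared_effects(self):
        """Two loci with equal planted effects: the joint additive score is
        a less noisy predictor, so joint p beats the single-locus p on
        average across replicates."""
        logs_joint, logs_a, logs_b = [], [], []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 100
            d1 = rng.binomial(2, 0.4, n).astype(float)
            d2 = rng.binomial(2, 0.4, n).astype(float)
            y = 0.5 * d1 + 0.5 * d2 + rng.normal(0, 1.5, n)
            samples = [f"s{i}" for i in range(n)]
            g = GenotypeMatrix(samples, ["a", "b"],
                               np.column_stack([d1, d2]),
                               {s: "P" for s in samples})
            t = PhenotypeTable(samples, ["y"], y[:, None])
            logs_joint.append(np.log(joint_association(g, "a", "b", t)[0].p_value))
            logs_a.append(np.log(associate(g, "a", t)[0].p_value))
            logs_b.append(np.log(associate(g, "b", t)[0].p_value))
        assert np.mean(logs_joint) < np.mean(logs_a)
        assert np.mean(logs_joint) < np.mean(logs_b)

    def test_null_effects_uniform_under_permutation(self):
        rng = np.random.default_rng(23)
        n = 100
        d1 = rng.binomial(2, 0.5, n).astype(float)
        d2 = rng.binomial(2, 0.5, n).astype(float)
        samples = [f"s{i}" for i in range(n)]
        g = GenotypeMatrix(samples, ["a", "b"], np.column_stack([d1, d2]),
                           {s: "P" for s in samples})
        pvals = []
        y = rng.normal(0, 1, n)
        for _ in range(300):
            t = PhenotypeTable(samples, ["y"], rng.permutation(y)[:, None])
            pvals.append(_joint(g, "a", "b", t)[0].p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_stepup_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_fdr([0.37])[0] == 0.37

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 60))
        ours = bh_fdr(p)
        np.testing.assert_allclose(ours, brute_force_bh(p), atol=1e-12)
        np.testing.assert_allclose(
            ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.random(30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_stepup_property(self, pvals):
        """For arbitrary p-vectors the step-up output matches the direct
        definition, stays in [0,1], and preserves the input ranking."""
        adj = bh_fdr(pvals)
        np.testing.assert_allclose(adj, brute_force_bh(pvals), atol=1e-12)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestAssociationScan:
    def test_grid_scope_equals_flat_bh(self):
        """traits_x_loci correction on the 4x19 grid equals bh_fdr applied
        to the flattened p-vector."""
        g, _ = simulate_population_svs(
            n1=80, n2=80, n_loci=4, seed=41,
            freq_spec={f"l{i}": (0.5, 0.5) for i in range(4)})
        t = simulate_phenotypes(g, effects={}, seed=42)
        df = association_scan(g, [f"l{i}" for i in range(4)], t,
                              correction_scope="traits_x_loci")
        assert len(df) == 4 * 19
        df_key = df.sort_values(["locus", "trait"])
        np.testing.assert_allclose(
            df_key["fdr_bh"].to_numpy(),
            bh_fdr(df_key["p_value"].to_numpy()), atol=1e-12)

    def test_planted_strong_effect_attains_min_fdr(self):
        g, _ = simulate_population_svs(
            n1=150, n2=150, n_loci=3, seed=43,
            freq_spec={f"l{i}": (0.5, 0.5) for i in range(3)})
        t = simulate_phenotypes(
            g, effects={"l1": {"PAP": -8.0}}, seed=44)
        df = association_scan(g, ["l0", "l1", "l2"], t)
        assert (df.iloc[0]["locus"], df.iloc[0]["trait"]) == ("l1", "PAP")
        assert df.iloc[0]["fdr_bh"] == df["fdr_bh"].min()

    def test_errors_recorded_not_fatal(self):
        g, _ = simulate_population_svs(
            n1=20, n2=20, n_loci=2, seed=45,
            freq_spec={"l0": (0.5, 0.5), "l1": (1.0, 1.0)})  # l1 constant
        t = simulate_phenotypes(g, effects={}, seed=46)
        df = association_scan(g, ["l0", "l1"], t)
        bad = df[df["locus"] == "l1"]
        assert (bad["error"] != "").all()
        assert df["p_value"].notna().sum() == 19

    def test_false_discovery_proportion_controlled(self):
        """All-null 4x19 grid: the expected false-discovery proportion at
        FDR 0.05 stays at or below the nominal level (Monte Carlo)."""
        fdps = []
        for seed in range(40):
            g, _ = simulate_population_svs(
                n1=40, n2=40, n_loci=4, seed=500 + seed,
                freq_spec={f"l{i}": (0.5, 0.5) for i in range(4)})
            t = simulate_phenotypes(g, effects={}, seed=600 + seed)
            df = association_scan(g, [f"l{i}" for i in range(4)], t)
            n_disc = int((df["fdr_bh"] < 0.05).sum())
            fdps.append(1.0 if n_disc > 0 else 0.0)  # all discoveries false
        # E[FDP] <= 0.05; allow 3 MC standard errors above the nominal level
        assert np.mean(fdps) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(fdps))
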