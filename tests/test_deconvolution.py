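"""Total-proxy selection, subtraction/NNLS group estimation, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from opnsplice.deconvolution import (
    DeconvolutionError,
    ExpressionMatrix,
    GroupEstimate,
    TotalProxy,
    correlate_groups,
    lsq_estimates,
    select_total_proxy,
    subtraction_estimates,
)
from opnsplice.simulate import SimulationConfig, simulate_cohort, simulate_exon_signals
from opnsplice.spp1 import ST21_OBSERVED_EXONS, spp1_incidence
from opnsplice.transcript_model import ExonDef, IsoformDef, build_incidence


def _by_label(estimates):
    return {g.group_label: g for g in estimates}


class TestSelectTotalProxy:
    def test_least_deviant_copies_selected(self, spp1_M):
        """Three exact copies of a latent profile beat two jittered candidates."""
        rng = np.random.default_rng(42)
        latent = rng.normal(8, 1, 30)
        values = pd.DataFrame(
            {
                "PS01_1": latent,
                "PS02_1": latent,
                "PS07_1": latent,
                "PS07_2": latent + rng.normal(0, 0.4, 30),
                "PS08_1": latent + rng.normal(0, 0.4, 30),
            },
            index=[f"S{i}" for i in range(30)],
        )
        X = ExpressionMatrix(values, {"PS01_1": 1, "PS02_1": 2, "PS07_1": 7, "PS07_2": 7, "PS08_1": 8})
        proxy = select_total_proxy(X, spp1_M, k=3)
        assert sorted(proxy.selected_probesets) == ["PS01_1", "PS02_1", "PS07_1"]
        # exhaustive check: the selected three have strictly the smallest scores
        worst_selected = proxy.deviation_scores[proxy.selected_probesets].max()
        others = proxy.deviation_scores.drop(proxy.selected_probesets)
        assert (others > worst_selected).all()

    def test_single_candidate_linearized(self, spp1_M):
        values = pd.DataFrame({"PS07_1": [1.0, 3.0]}, index=["a", "b"])
        X = ExpressionMatrix(values, {"PS07_1": 7})
        proxy = select_total_proxy(X, spp1_M, k=1)
        assert proxy.selected_probesets == ["PS07_1"]
        assert proxy.total.tolist() == [2.0, 8.0]

    def test_tie_break_by_probeset_id(self, spp1_M):
        values = pd.DataFrame(
            {p: [5.0, 6.0] for p in ["PS08_1", "PS01_1", "PS07_1", "PS02_1"]}, index=["a", "b"]
        )
        X = ExpressionMatrix(values, {"PS08_1": 8, "PS01_1": 1, "PS07_1": 7, "PS02_1": 2})
        proxy = select_total_proxy(X, spp1_M, k=2)
        assert proxy.selected_probesets == ["PS01_1", "PS02_1"]

    def test_k_exceeding_candidates_warns(self, spp1_M):
        values = pd.DataFrame({"PS07_1": [1.0, 2.0]}, index=["a", "b"])
        X = ExpressionMatrix(values, {"PS07_1": 7})
        with pytest.warns(UserWarning, match="selecting all"):
            proxy = select_total_proxy(X, spp1_M, k=3)
        assert proxy.selected_probesets == ["PS07_1"]

    def test_no_common_candidate_errors(self, spp1_M):
        values = pd.DataFrame({"PS04_1": [1.0, 2.0]}, index=["a", "b"])
        X = ExpressionMatrix(values, {"PS04_1": 4})
        with pytest.raises(DeconvolutionError, match="common"):
            select_total_proxy(X, spp1_M)


class TestSubtraction:
    def test_noise_free_worked_example(self, spp1_M, noise_free_expression):
        """a=4, b=3, c=2, o4=1, o5=0.5: total 10.5, exon5 7.5, exon4 0.5
        gives OPN5=0.5, OPNa+b=7.0, OPNc+4=3.0."""
        _, X = noise_free_expression
        proxy = select_total_proxy(X, spp1_M, k=3)
        groups = _by_label(subtraction_estimates(proxy, X, spp1_M, ST21_OBSERVED_EXONS))
        assert np.allclose(groups["OPN5"].abundances, 0.5)
        assert np.allclose(groups["OPNa+OPNb"].abundances, 7.0)
        assert np.allclose(groups["OPNc+OPN4"].abundances, 3.0)
        assert not any(g.clipped.any() for g in groups.values())

    def test_conservation_noise_free(self, spp1_M, noise_free_expression):
        _, X = noise_free_expression
        proxy = select_total_proxy(X, spp1_M, k=3)
        estimates = subtraction_estimates(proxy, X, spp1_M, ST21_OBSERVED_EXONS)
        total = sum(g.abundances for g in estimates)
        assert np.allclose(total, proxy.total, rtol=1e-9)

    def test_negative_difference_clipped(self, spp1_M):
        # exon-5 signal below exon-4 signal: OPNa+b estimate clipped to 0
        values = pd.DataFrame(
            {"PS01_1": [3.0], "PS04_1": [2.0], "PS05_1": [1.5]}, index=["s"]
        )
        X = ExpressionMatrix(values, {"PS01_1": 1, "PS04_1": 4, "PS05_1": 5})
        proxy = select_total_proxy(X, spp1_M, k=1)
        groups = _by_label(subtraction_estimates(proxy, X, spp1_M, [1, 4, 5]))
        assert groups["OPNa+OPNb"].abundances.iloc[0] == 0.0
        assert bool(groups["OPNa+OPNb"].clipped.iloc[0])

    def test_all_zero_expression(self, spp1_M):
        values = pd.DataFrame(
            {"PS01_1": [-np.inf] * 2, "PS04_1": [-np.inf] * 2, "PS05_1": [-np.inf] * 2},
            index=["a", "b"],
        )
        X = ExpressionMatrix(values, {"PS01_1": 1, "PS04_1": 4, "PS05_1": 5})
        proxy = select_total_proxy(X, spp1_M, k=1)
        for g in subtraction_estimates(proxy, X, spp1_M, [1, 4, 5]):
            assert (g.abundances == 0).all()
            assert not g.clipped.any()

    def test_non_triangular_design_errors(self, spp1_M):
        # all 8 exons observed: exon-5 and exon-6 carrier sets do not nest
        values = pd.DataFrame(
            {f"PS{e:02d}_1": [1.0] for e in range(1, 9)}, index=["s"]
        )
        X = ExpressionMatrix(values, {f"PS{e:02d}_1": e for e in range(1, 9)})
        proxy = select_total_proxy(X, spp1_M, k=1)
        with pytest.raises(DeconvolutionError, match="lsq_estimates"):
            subtraction_estimates(proxy, X, spp1_M, range(1, 9))


class TestLsq:
    def test_matches_subtraction_noise_free(self, spp1_M, noise_free_expression):
        _, X = noise_free_expression
        proxy = select_total_proxy(X, spp1_M, k=3)
        sub = _by_label(subtraction_estimates(proxy, X, spp1_M, ST21_OBSERVED_EXONS))
        lsq = _by_label(lsq_estimates(X, spp1_M, ST21_OBSERVED_EXONS))
        assert set(sub) == set(lsq)
        for label in sub:
            np.testing.assert_allclose(
                lsq[label].abundances, sub[label].abundances, rtol=1e-9
            )

    def test_diagonal_design_recovers_exactly(self):
        exons = [ExonDef(i, 10) for i in (1, 2, 3)]
        isoforms = [IsoformDef(f"I{i}", (i,)) for i in (1, 2, 3)]
        M = build_incidence(exons, isoforms)
        abund = np.array([[2.0, 5.0, 9.0], [1.0, 1.0, 4.0]])
        values = pd.DataFrame(
            {f"PS0{e}_1": np.log2(abund[:, e - 1]) for e in (1, 2, 3)}, index=["a", "b"]
        )
        X = ExpressionMatrix(values, {f"PS0{e}_1": e for e in (1, 2, 3)})
        groups = _by_label(lsq_estimates(X, M, [1, 2, 3]))
        for e in (1, 2, 3):
            np.testing.assert_allclose(groups[f"I{e}"].abundances, abund[:, e - 1], rtol=1e-9)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=15, deadline=None)
    def test_scale_equivariance(self, c):
        """Scaling all linear signals by c scales every estimate by c."""
        M = spp1_incidence()
        base = pd.DataFrame(
            {"PS01_1": [3.0, 4.0], "PS04_1": [0.5, 1.0], "PS05_1": [2.5, 3.5]},
            index=["a", "b"],
        )
        pmap = {"PS01_1": 1, "PS04_1": 4, "PS05_1": 5}
        X1 = ExpressionMatrix(base, pmap)
        X2 = ExpressionMatrix(base + np.log2(c), pmap)
        g1 = _by_label(lsq_estimates(X1, M, [1, 4, 5]))
        g2 = _by_label(lsq_estimates(X2, M, [1, 4, 5]))
        for label in g1:
            np.testing.assert_allclose(g2[label].abundances, c * g1[label].abundances, rtol=1e-9)


class TestCorrelations:
    def _proxy(self, series):
        return TotalProxy(["p"], series, pd.Series(dtype=float))

    def _estimate(self, label, series):
        idx = series.index
        return GroupEstimate(label, {}, series, pd.Series(False, index=idx))

    def test_identical_to_total_r_one(self):
        s = pd.Series([1.0, 2.0, 4.0, 8.0], index=list("abcd"))
        (corr,) = correlate_groups([self._estimate("g", s)], self._proxy(s))
        assert corr.computable and corr.pearson_r == pytest.approx(1.0)

    def test_negated_total_r_minus_one(self):
        s = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        (corr,) = correlate_groups([self._estimate("g", -s)], self._proxy(s), scale="linear")
        assert corr.pearson_r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        s = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        flat = pd.Series([3.0, 3.0, 3.0], index=list("abc"))
        (corr,) = correlate_groups([self._estimate("g", flat)], self._proxy(s))
        assert not corr.computable
        assert np.isnan(corr.pearson_r)

    def test_default_cohort_groups_track_total(self, spp1_M):
        """Shared-factor simulation: every identifiable group co-varies
        strongly with total expression."""
        cfg = SimulationConfig(n_per_class=29, seed=1)
        rng = cfg.rng()
        labels, truth = simulate_cohort(cfg, rng)
        X = simulate_exon_signals(truth, spp1_M, cfg, rng)
        proxy = select_total_proxy(X, spp1_M, k=3)
        estimates = subtraction_estimates(proxy, X, spp1_M, ST21_OBSERVED_EXONS)
        for corr in correlate_groups(estimates, proxy):
            assert corr.computable
            assert corr.pearson_r > 0.8, corr.group_label


class TestRecovery:
    @staticmethod
    def _recovery(noise_sd, seed, n_per_class=29):
        M = spp1_incidence()
        cfg = SimulationConfig(n_per_class=n_per_class, probe_noise_sd=noise_sd, seed=seed)
        rng = cfg.rng()
        labels, truth = simulate_cohort(cfg, rng)
        X = simulate_exon_signals(truth, M, cfg, rng)
        proxy = select_total_proxy(X, M, k=3)
        estimates = subtraction_estimates(proxy, X, M, ST21_OBSERVED_EXONS)
        rep = {"OPN5": ["OPN5"], "OPNa+OPNb": ["OPNa", "OPNb"], "OPNc+OPN4": ["OPNc", "OPN4"]}
        out = {}
        for g in estimates:
            true = truth[rep[g.group_label]].sum(axis=1)
            keep = ~g.clipped
            out[g.group_label] = float(
                np.corrcoef(np.log2(true[keep]), np.log2(g.abundances[keep]))[0, 1]
            )
        return out

    def test_high_recovery_at_low_noise(self):
        rs = [self._recovery(0.05, seed) for seed in range(5)]
        for label in ("OPN5", "OPNa+OPNb", "OPNc+OPN4"):
            mean_r = np.mean([r[label] for r in rs])
            assert mean_r > 0.95, (label, mean_r)

    def test_recovery_degrades_with_noise(self):
        """Average recovery falls monotonically as probe noise grows."""
        means = []
        for sd in (0.05, 0.2, 0.5):
            rs = [self._recovery(sd, seed) for seed in range(8)]
            means.append(np.mean([[r[l] for l in r] for r in rs]))
        assert means[0] > means[1] > means[2]

    def test_clipping_vanishes_as_noise_vanishes(self):
        M = spp1_incidence()
        fractions = []
        for sd in (0.5, 0.05, 0.0):
            cfg = SimulationConfig(n_per_class=20, probe_noise_sd=sd, seed=3)
            rng = cfg.rng()
            _, truth = simulate_cohort(cfg, rng)
            X = simulate_exon_signals(truth, M, cfg, rng)
            proxy = select_total_proxy(X, M, k=3)
            estimates = subtraction_estimates(proxy, X, M, ST21_OBSERVED_EXONS)
            fractions.append(np.mean([g.clipped.mean() for g in estimates]))
        assert fractions[0] >= fractions[1] >= fractions[2]
        assert fractions[2] == 0.0
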