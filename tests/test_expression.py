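"""Ratio classification, consensus calling, RPKM, mixture EM, and KS."""

import numpy as np
import pytest

from pyronome.io import CountMatrix
from pyronome.expression import (
    RatioRecord,
    classify_all,
    classify_group,
    consensus_call,
    dev_specific,
    ks_compare,
    mixture_fit,
    normalize_and_ratio,
    rpkm,
)
from pyronome.simulate import SimConfig, simulate_counts, simulate_external_table


def _cm(counts, samples=("sex_1", "sex_2", "DD_1", "DD_2"), lengths=None):
    counts = np.asarray(counts)
    return CountMatrix(
        genes=[f"g{i}" for i in range(counts.shape[0])],
        samples=list(samples),
        counts=counts,
        gene_lengths=np.asarray(lengths) if lengths is not None else np.full(counts.shape[0], 1000),
    )


def brute_force_group(ratios):
    """Literal transcription of the four printed group rules, cascade 4>3>2>1."""
    r = np.asarray(ratios, dtype=float)
    mean = r.mean()
    sd = r.std(ddof=1)
    cv = sd / mean if mean > 0 else float("inf")
    if (r >= 4).all() or (r <= 0.25).all():
        return 4
    if (mean >= 4 or mean <= 0.25) and cv < 0.5:
        return 3
    if (r >= 2).all() or (r <= 0.5).all():
        return 2
    if (mean >= 2 or mean <= 0.5) and cv < 0.5:
        return 1
    return 0


class TestRatios:
    def test_equal_libraries(self):
        # second gene balances the library sizes so normalisation is a no-op
        cm = _cm([[100, 100, 50, 50], [100, 100, 150, 150]])
        (rec, _) = normalize_and_ratio(cm, "sex", "DD")
        assert rec.replicate_ratios == [2.0, 2.0]
        assert rec.mean_ratio == 2.0 and rec.cv == 0.0

    def test_library_size_normalization(self):
        # A libraries twice the size of B with equal raw counts -> ratio 0.5
        cm = _cm([[100, 100, 100, 100], [300, 300, 100, 100]])
        recs = normalize_and_ratio(cm, "sex", "DD")
        assert recs[0].replicate_ratios == [0.5, 0.5]

    def test_zero_denominator_undefines_record(self):
        cm = _cm([[100, 100, 50, 0], [1, 1, 1, 1]])
        recs = normalize_and_ratio(cm, "sex", "DD")
        assert recs[0].defined is False and recs[1].defined is True

    def test_mismatched_replicates_is_error(self):
        cm = _cm([[1, 2, 3]], samples=["sex_1", "sex_2", "DD_1"])
        with pytest.raises(ValueError, match="replicates"):
            normalize_and_ratio(cm, "sex", "DD")


class TestGroups:
    @pytest.mark.parametrize(
        "ratios,expected",
        [
            ((5.0, 4.5), 4),     # both >= 4
            ((3.0, 5.0), 3),     # mean 4.0, cv 0.354
            ((2.5, 0.3), 0),     # directions disagree
            ((0.2, 0.24), 4),    # both <= 0.25
            ((2.0, 2.2), 2),
            ((1.9, 2.5), 1),     # mean 2.2, cv 0.19
            ((1.0, 1.0), 0),
        ],
    )
    def test_printed_rules(self, ratios, expected):
        rec = RatioRecord("g", "sex/DD", list(ratios), defined=True)
        assert classify_group(rec) == expected

    def test_undefined_record_gets_no_label(self):
        assert classify_group(RatioRecord("g", "sex/DD", [], defined=False)) is None

    def test_matches_bruteforce_on_random_ratio_pairs(self):
        rng = np.random.default_rng(17)
        ratios = np.exp(rng.uniform(np.log(0.05), np.log(20), size=(20_000, 2)))
        for pair in ratios:
            rec = RatioRecord("g", "sex/DD", list(pair), defined=True)
            assert classify_group(rec) == brute_force_group(pair)

    def test_monotone_in_upward_scaling(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            base = rng.uniform(1.01, 6.0, size=2)
            scale = rng.uniform(1.0, 3.0)
            g1 = classify_group(RatioRecord("g", "c", list(base), defined=True))
            g2 = classify_group(RatioRecord("g", "c", list(base * scale), defined=True))
            assert g2 >= g1


class TestConsensus:
    def test_stringent_up_call(self):
        c = consensus_call("g", "sex/DD", 3, 4.2, 4.5, 1.0, mode="stringent")
        assert c.call == 1

    def test_external_below_threshold_blocks(self):
        c = consensus_call("g", "sex/DD", 3, 4.2, 3.5, 1.0, mode="stringent")
        assert c.call == 0

    def test_group_zero_gates(self):
        c = consensus_call("g", "sex/DD", 0, 10.0, 10.0, 1.0, mode="normal")
        assert c.call == 0

    def test_probability_gate(self):
        c = consensus_call("g", "sex/DD", 3, 4.2, 4.5, 0.97, mode="stringent")
        assert c.call == 0

    def test_down_call(self):
        c = consensus_call("g", "sex/DD", 4, 0.2, 0.1, 1.0, mode="stringent")
        assert c.call == -1

    def test_missing_external_entry_warns_and_zeroes(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            c = consensus_call("g", "sex/DD", 4, 8.0, None, None)
        assert c.call == 0 and "no external entry" in caplog.text

    def test_stringent_calls_subset_of_normal(self):
        rng = np.random.default_rng(9)
        for _ in range(500):
            ratio = float(np.exp(rng.uniform(np.log(0.05), np.log(20))))
            group = int(rng.integers(0, 5))
            cn = consensus_call("g", "c", group, ratio, ratio, 1.0, mode="normal")
            cs = consensus_call("g", "c", group, ratio, ratio, 1.0, mode="stringent")
            if cs.call != 0:
                assert cn.call == cs.call


class TestDevSpecific:
    def test_gate_over_all_27_triples(self):
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                for c in (-1, 0, 1):
                    verdict = dev_specific({"sex/DD": a, "sex/vegmix": b, "DD/vegmix": c})
                    if (a, b, c) == (1, 1, 0):
                        assert verdict == "up_in_sex"
                    elif (a, b, c) == (-1, -1, 0):
                        assert verdict == "down_in_sex"
                    else:
                        assert verdict == "none"


class TestRpkm:
    def test_unit_definition(self):
        cm = _cm([[10, 0, 0, 0], [10**6 - 10, 0, 0, 0]], lengths=[1000, 1000])
        cm.counts[:, 1:] = 1  # avoid zero library sizes in other samples
        mat, _ = rpkm(cm)
        assert mat[0, 0] == pytest.approx(10.0)

    def test_doubling_library_halves_rpkm(self):
        cm1 = _cm([[10, 1, 1, 1], [90, 1, 1, 1]])
        cm2 = _cm([[10, 1, 1, 1], [190, 1, 1, 1]])
        assert rpkm(cm1)[0][0, 0] == pytest.approx(2 * rpkm(cm2)[0][0, 0])

    def test_condition_mean_and_concat_invariance(self):
        cm = _cm([[40, 60, 5, 5], [60, 40, 5, 5]])
        _, means = rpkm(cm)
        mat, _ = rpkm(cm)
        assert means["sex"][0] == pytest.approx((mat[0, 0] + mat[0, 1]) / 2)
        # concatenating two identical libraries leaves RPKM unchanged
        cm2 = _cm([[80, 120, 10, 10], [120, 80, 10, 10]])
        assert rpkm(cm2)[0] == pytest.approx(mat)

    def test_zero_length_gene_is_error(self):
        with pytest.raises(ValueError):
            CountMatrix(["g0"], ["sex_1"], np.array([[1]]), np.array([0]))


class TestMixture:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 3.0, size=500)
        fit = mixture_fit(x, 1)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert fit.variances[0] == pytest.approx(x.var(), rel=1e-4)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-4, 1, 2000), rng.normal(6, 1, 2000)])
        fit = mixture_fit(x, 2)
        means = sorted(fit.means)
        assert abs(means[0] - (-4)) < 0.2 and abs(means[1] - 6) < 0.2
        assert fit.converged

    def test_log_likelihood_monotone(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(3, 2, 300)])
        fit = mixture_fit(x, 3)
        diffs = np.diff(fit.log_likelihoods)
        assert (diffs >= -1e-9).all()

    def test_matches_sklearn_reference(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-3, 1, 1500), rng.normal(4, 1.5, 1500)])
        fit = mixture_fit(x, 2)
        gm = GaussianMixture(2, covariance_type="full", random_state=0, n_init=3).fit(
            x.reshape(-1, 1)
        )
        assert sorted(fit.means) == pytest.approx(sorted(gm.means_.ravel()), abs=0.1)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            mixture_fit([1.0], 2)


class TestKs:
    def test_identical_samples_zero_statistic(self):
        d, _ = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, p = ks_compare([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert d == 1.0

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestPipeline:
    def test_planted_fold_changes_recovered(self):
        cfg = SimConfig(seed=11, n_genes=400)
        cm, truth = simulate_counts(cfg)
        ext = simulate_external_table(cm)
        res = classify_all(cm, ext, mode="stringent")
        planted = truth["planted_genes"]
        hits = sum(res[g]["dev_specific"] == "up_in_sex" for g in planted)
        assert hits / len(planted) >= 0.9

    def test_null_config_rarely_calls(self):
        cfg = SimConfig(seed=2, n_genes=400, planted_fraction=0.0)
        cm, _ = simulate_counts(cfg)
        ext = simulate_external_table(cm)
        res = classify_all(cm, ext, mode="stringent")
        called = sum(
            any(v not in (0, None) for v in e["calls"].values()) for e in res.values()
        )
        assert called / len(res) < 0.01
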