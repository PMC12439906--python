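"""AP-MS statistics: normalization, mock fold changes, sigma, curved filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cftrdms import interactome as im


def simple_design(n_runs=3):
    rows = []
    for r in range(1, n_runs + 1):
        rows.append((f"r{r}b", f"run{r}", "F508del", "parental", "vehicle", r))
        rows.append((f"r{r}m", f"run{r}", "MOCK", "parental", "vehicle", r))
    return pd.DataFrame(
        rows, columns=["channel", "run", "bait", "cell_line", "treatment", "replicate"]
    )


class TestNormalization:
    def test_fixed_point_unchanged(self):
        design = simple_design(1)
        # mock median 1, bait channel median 1 and bait value at the run's
        # bait/median ratio: already normalized
        mat = pd.DataFrame(
            {"r1b": [0.5, 1.0, 2.0, 3.0], "r1m": [0.5, 1.0, 2.0, 0.1]},
            index=["P1", "P2", "P3", "CFTR"],
        )
        mat.loc["CFTR", "r1b"] = 3.0
        med = mat["r1b"].median()
        mat["r1b"] *= (mat.loc["CFTR", "r1b"] / med) / mat.loc["CFTR", "r1b"]
        mat.loc["CFTR", "r1b"] = mat.loc["CFTR", "r1b"]  # keep explicit
        out = im.normalize_abundances(mat, design)
        out2 = im.normalize_abundances(out, design)
        assert np.allclose(out.values, out2.values, atol=1e-12)

    def test_channel_scale_removed_exactly(self, tmt_sim):
        abundance, design, _ = tmt_sim
        perturbed = abundance.copy()
        perturbed[design["channel"].iloc[0]] *= 10.0
        a = im.normalize_abundances(abundance, design)
        b = im.normalize_abundances(perturbed, design)
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_idempotent(self, tmt_sim):
        abundance, design, _ = tmt_sim
        once = im.normalize_abundances(abundance, design)
        twice = im.normalize_abundances(once, design)
        assert np.nanmax(np.abs(once.values - twice.values)) < 1e-12

    def test_loading_factors_equalize_mock_medians(self, tmt_sim):
        abundance, design, _ = tmt_sim
        norm = im.normalize_abundances(abundance, design)
        mock_ch = design.loc[design["bait"] == "MOCK", "channel"]
        meds = norm[mock_ch].median()
        assert np.allclose(meds, meds.iloc[0], atol=1e-9)

    def test_bait_equal_within_run(self, tmt_sim):
        abundance, design, _ = tmt_sim
        norm = im.normalize_abundances(abundance, design)
        for _, grp in design[design["bait"] != "MOCK"].groupby("run"):
            vals = norm.loc["CFTR", grp["channel"]]
            assert np.allclose(vals, vals.iloc[0], rtol=1e-12)

    def test_missing_bait_is_error(self):
        design = simple_design(1)
        mat = pd.DataFrame({"r1b": [1.0, 2.0], "r1m": [1.0, 2.0]}, index=["P1", "P2"])
        with pytest.raises(ValueError, match="bait"):
            im.normalize_abundances(mat, design)


class TestLog2FcVsMock:
    def test_equal_bait_and_mock_is_null(self):
        design = simple_design(3)
        vals = {ch: [4.0, 8.0] for ch in design["channel"]}
        mat = pd.DataFrame(vals, index=["P1", "P2"])
        out = im.log2fc_vs_mock(mat, design)
        assert np.allclose(out["mean_log2fc"], 0.0)
        # zero-variance paired differences: p undefined, reported NaN
        assert out["p_value"].isna().all()

    def test_exact_fourfold(self):
        design = simple_design(3)
        mat = pd.DataFrame(
            {ch: ([8.0] if ch.endswith("b") else [2.0]) for ch in design["channel"]},
            index=["P1"],
        )
        out = im.log2fc_vs_mock(mat, design)
        assert out.loc["P1", "mean_log2fc"] == pytest.approx(2.0)

    def test_run_matched_mock_means(self):
        # per-run fold changes averaged: run1 4x, run2 1x, run3 1x -> mean 2/3
        design = simple_design(3)
        mat = pd.DataFrame(
            {"r1b": [8.0], "r1m": [2.0], "r2b": [2.0], "r2m": [2.0],
             "r3b": [2.0], "r3m": [2.0]},
            index=["P1"],
        )
        out = im.log2fc_vs_mock(mat, design)
        assert out.loc["P1", "mean_log2fc"] == pytest.approx(2.0 / 3.0)

    def test_absent_from_mock_flagged(self):
        design = simple_design(3)
        mat = pd.DataFrame(
            {ch: ([4.0] if ch.endswith("b") else [np.nan]) for ch in design["channel"]},
            index=["P1"],
        )
        out = im.log2fc_vs_mock(mat, design)
        assert not bool(out.loc["P1", "defined"])

    def test_null_proteins_uniform_p(self):
        """iid replicate noise, no per-protein offset: paired-t p is uniform."""
        rng = np.random.default_rng(71)
        design = simple_design(4)
        n = 2000
        base = 1000.0
        mat = pd.DataFrame(
            {ch: base * 2 ** rng.normal(0, 0.3, n) for ch in design["channel"]},
            index=[f"P{i}" for i in range(n)],
        )
        out = im.log2fc_vs_mock(mat, design)
        fcs = out["mean_log2fc"].dropna()
        assert abs(fcs.mean()) < 3 * fcs.std() / np.sqrt(len(fcs))
        ks_p = stats.kstest(out["p_value"].dropna(), "uniform").pvalue
        assert ks_p > 0.01


class TestEstimateSigma:
    def test_recovery_at_5000(self):
        rng = np.random.default_rng(5)
        fit = im.estimate_sigma(rng.normal(0, 0.5, 5000))
        assert 0.45 <= fit.sigma <= 0.55

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 0.4, 4000)
        s1 = im.estimate_sigma(v).sigma
        s2 = im.estimate_sigma(2 * v).sigma
        assert s2 == pytest.approx(2 * s1, rel=0.05)

    def test_outlier_robustness(self):
        """1% contamination at +5 sigma inflates the peak fit by < 10%."""
        rng = np.random.default_rng(7)
        sigma = 0.5
        v = rng.normal(0, sigma, 5000)
        v[:50] = 5 * sigma + rng.normal(0, 0.05, 50)
        fit = im.estimate_sigma(v)
        assert fit.sigma < 1.10 * sigma

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            im.estimate_sigma(np.zeros(10))


class TestCurvedFilter:
    def _calls(self, x, p):
        return pd.DataFrame({"mean_log2fc": x, "p_value": p})

    def test_boundary_x0_fails_regardless_of_p(self):
        calls = self._calls([1.0], [1e-30])
        out = im.curved_filter(calls, sigma=0.5)  # x0 = 1.0
        assert not out["passes"].iloc[0]

    def test_hand_derived_threshold_point(self):
        # sigma=0.5, c=0.8: at x = 2*sigma + 0.8 the bar is exactly 1, so
        # a protein passes iff -log10(p) > 1, i.e. p < 0.1
        out = im.curved_filter(self._calls([1.8, 1.8], [0.09, 0.11]), sigma=0.5, c=0.8)
        assert out["passes"].tolist() == [True, False]

    def test_literal_p_mode_follows_printed_inequality(self):
        # at x = 2.6, x0 = 1.0: bar = 0.8/1.6 = 0.5, and the literal rule
        # p > bar selects the *large* p-value
        out = im.curved_filter(self._calls([2.6, 2.6], [0.9, 0.05]), sigma=0.5,
                               literal_p=True)
        assert out["passes"].tolist() == [True, False]

    def test_monotonicity_in_p_and_x(self):
        xs = np.linspace(1.05, 4.0, 40)
        ps = np.logspace(-6, -0.01, 40)
        for x in [1.5, 2.0, 3.0]:
            out = im.curved_filter(self._calls([x] * 40, ps), sigma=0.5)
            flags = out["passes"].to_numpy()
            # decreasing p never flips pass -> fail (ps is increasing)
            assert not np.any(~flags[:-1] & flags[1:][::-1] & False)
            assert np.all(flags[np.argsort(ps)] == np.sort(flags)[::-1])
        for p in [1e-2, 1e-4]:
            out = im.curved_filter(self._calls(xs, [p] * 40), sigma=0.5)
            flags = out["passes"].to_numpy()
            assert np.all(flags[np.argsort(xs)] == np.sort(flags))

    def test_undefined_p_never_passes(self):
        out = im.curved_filter(self._calls([5.0], [np.nan]), sigma=0.5)
        assert not out["passes"].iloc[0]


class TestMasterList:
    def test_union_and_provenance(self):
        out = im.master_interactor_list(
            {"parental": {"A", "B", "C"}, "ko": {"D", "E", "F", "G"}}
        )
        assert len(out) == 7
        assert out.loc["A", "conditions"] == "parental"

    def test_idempotent_identical_sets(self):
        out = im.master_interactor_list({"a": {"X", "Y"}, "b": {"X", "Y"}})
        assert set(out.index) == {"X", "Y"}
        assert (out["n_conditions"] == 2).all()

    def test_superset_of_each_condition(self, tmt_sim):
        abundance, design, truth = tmt_sim
        norm = im.normalize_abundances(abundance, design)
        sets = {}
        for line in ("parental", "CANX_KO"):
            fc = im.log2fc_vs_mock(norm, design, cell_line=line)
            fit = im.estimate_sigma(fc["mean_log2fc"].drop("CFTR").dropna())
            calls = im.curved_filter(fc, sigma=fit.sigma)
            sets[line] = set(calls.index[calls["passes"]])
        master = set(im.master_interactor_list(sets).index)
        assert all(s <= master for s in sets.values())


class TestGroupedDelta:
    def test_exact_doubling(self):
        design = pd.DataFrame(
            [
                ("pb", "run1", "F508del", "parental", "vehicle", 1),
                ("pm", "run1", "MOCK", "parental", "vehicle", 1),
                ("kb", "run1k", "F508del", "CANX_KO", "vehicle", 1),
                ("km", "run1k", "MOCK", "CANX_KO", "vehicle", 1),
            ],
            columns=["channel", "run", "bait", "cell_line", "treatment", "replicate"],
        )
        mat = pd.DataFrame(
            {"pb": [4.0], "pm": [1.0], "kb": [8.0], "km": [1.0]}, index=["P1"]
        )
        out = im.grouped_delta(mat, design, ["P1"])
        assert out.loc["P1", "delta_log2"] == pytest.approx(1.0)

    def test_sign_flips_under_label_swap(self, tmt_sim):
        abundance, design, _ = tmt_sim
        norm = im.normalize_abundances(abundance, design)
        prots = list(norm.index[:50])
        a = im.grouped_delta(norm, design, prots)
        b = im.grouped_delta(norm, design, prots, ko_line="parental",
                             parental_line="CANX_KO")
        assert np.allclose(a["delta_log2"], -b["delta_log2"], equal_nan=True)

    def test_null_distribution_centred(self, tmt_sim):
        abundance, design, truth = tmt_sim
        norm = im.normalize_abundances(abundance, design)
        background = truth.loc[~truth["is_interactor"], "protein_id"].tolist()
        out = im.grouped_delta(norm, design, background)
        d = out["delta_log2"].dropna()
        # background latent offsets are shared between lines; only replicate
        # noise remains, so the mean sits near zero
        assert abs(d.mean()) < 3 * d.std() / np.sqrt(len(d)) + 0.02

    def test_spiked_ko_shift_detected(self, tmt_sim):
        abundance, design, truth = tmt_sim
        norm = im.normalize_abundances(abundance, design)
        spiked = truth.loc[truth["is_interactor"], "protein_id"].tolist()
        out = im.grouped_delta(norm, design, spiked)
        assert out["delta_log2"].mean() > 0.5  # generated ko_shift = 0.8


def brute_force_wilcoxon(values):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    v = np.asarray(values, float)
    v = v[v != 0]
    n = len(v)
    ranks = stats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    mu = n * (n + 1) / 4.0
    obs = abs(w_obs - mu)
    hits = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= obs - 1e-12:
            hits += 1
    return hits / 2**n


class TestPathwayTests:
    def test_wilcoxon_matches_enumeration_oracle(self):
        for vals in ([1.2, -0.5, 0.8, 2.0, -0.1], [0.3, 0.4, 0.5, -0.2, 0.1, 0.9, -1.0]):
            p_scipy = stats.wilcoxon(vals, method="exact").pvalue
            assert p_scipy == pytest.approx(brute_force_wilcoxon(vals), abs=1e-12)

    def test_one_sample_t_matches_closed_form(self):
        vals = np.array([0.5, -0.2, 0.9, 1.1, 0.0, 0.3, -0.4, 0.7])
        t_hand = vals.mean() / (vals.std(ddof=1) / np.sqrt(len(vals)))
        from scipy.special import stdtr

        p_hand = 2 * (1 - stdtr(len(vals) - 1, abs(t_hand)))
        res = stats.ttest_1samp(vals, 0.0)
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.pvalue == pytest.approx(p_hand, abs=1e-12)

    def test_per_class_tests_and_undefined_wilcoxon(self):
        deltas = pd.Series(
            {"A": 0.0, "B": 0.0, "C": 0.0, "D": 1.0, "E": 1.2, "F": 0.8, "G": 1.1}
        )
        pathways = pd.Series(
            {"A": "folding", "B": "folding", "C": "folding",
             "D": "translation", "E": "translation", "F": "translation", "G": "translation"}
        )
        out = im.pathway_zero_tests(deltas, pathways)
        assert np.isnan(out.loc["folding", "wilcoxon_p"])  # all-zero deltas
        assert out.loc["translation", "t_p"] < 0.01

    def test_null_classes_calibrated(self):
        """Zero-centred deltas: both tests non-significant in >=93% of nulls."""
        rng = np.random.default_rng(13)
        ok_t = ok_w = 0
        n_sims = 500
        for _ in range(n_sims):
            deltas = pd.Series(rng.normal(0, 1, 20))
            pathways = pd.Series(["folding"] * 20)
            out = im.pathway_zero_tests(deltas, pathways)
            ok_t += out["t_p"].iloc[0] > 0.05
            ok_w += out["wilcoxon_p"].iloc[0] > 0.05
        assert ok_t / n_sims >= 0.93
        assert ok_w / n_sims >= 0.93


class TestRmAnova:
    def _long(self, mat, conditions):
        n, k = mat.shape
        return pd.DataFrame(
            {
                "protein_id": np.repeat([f"P{i}" for i in range(n)], k),
                "condition": conditions * n,
                "delta_log2": mat.ravel(),
            }
        )

    def test_two_conditions_epsilon_is_one(self):
        rng = np.random.default_rng(17)
        mat = rng.normal(0, 1, (12, 2))
        out = im.rm_anova_gg(self._long(mat, ["a", "b"]))
        assert out["epsilon"] == pytest.approx(1.0)
        assert out["p_gg"] == pytest.approx(out["p_uncorrected"], rel=1e-6)

    def test_spherical_data_correction_vacuous(self):
        rng = np.random.default_rng(18)
        base = rng.normal(0, 1, (40, 1))
        mat = base + rng.normal(0, 1, (40, 3))  # iid errors: spherical
        out = im.rm_anova_gg(self._long(mat, ["a", "b", "c"]))
        assert out["epsilon"] > 0.9
        assert out["p_gg"] == pytest.approx(out["p_uncorrected"], abs=0.05)

    def test_shifted_condition_detected_and_tukey_reports_it(self):
        rng = np.random.default_rng(19)
        mat = rng.normal(0, 0.3, (15, 3))
        mat[:, 2] += 2.0
        out = im.rm_anova_gg(self._long(mat, ["a", "b", "c"]))
        assert out["p_gg"] < 1e-4
        tk = out["tukey"]
        sig = tk[tk["reject"] == True]  # noqa: E712
        assert len(sig) == 2  # a-c and b-c
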