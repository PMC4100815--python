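"""Stepwise DFA, leave-one-out validation, permuted DFA, LMM layer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vocalid import (
    compare_call_types,
    hochberg_adjust,
    lmm_parameter_significance,
    loo_classification,
    pdfa,
    stepwise_dfa,
)
from vocalid.synth import SignatureSpec, synth_feature_table


def gauss_table(rng, n_per_caller, offsets, n_params=5, sd=1.0, param_names=None):
    """Gaussian feature rows: ``offsets`` maps caller -> per-parameter mean shift."""
    if param_names is None:
        param_names = [f"x{j}" for j in range(n_params)]
    rows = []
    for caller, shift in offsets.items():
        shift = np.broadcast_to(np.asarray(shift, float), (n_params,))
        for i in range(n_per_caller):
            vals = shift + sd * rng.standard_normal(n_params)
            rows.append({"caller_id": caller, **dict(zip(param_names, vals))})
    return pd.DataFrame(rows), param_names


class TestStepwiseDFA:
    def test_planted_parameter_selected_perfect_separation(self, rng):
        # +10 pooled-SD on x2 only; other parameters pure noise
        offsets = {"A": [0, 0, 0, 0, 0], "B": [0, 0, 10, 0, 0]}
        table, params = gauss_table(rng, 30, offsets)
        res = stepwise_dfa(table, parameters=params)
        assert res.selected_parameters[0] == "x2"
        assert res.resub_overall == 100.0
        assert res.chance == 50.0

    def test_single_caller_rejected(self, rng):
        table, params = gauss_table(rng, 10, {"A": 0.0})
        with pytest.raises(ValueError):
            stepwise_dfa(table, parameters=params)

    def test_pure_noise_has_no_discriminating_parameters(self, rng):
        table, params = gauss_table(rng, 4, {"A": 0.0, "B": 0.0}, n_params=1)
        with pytest.raises(ValueError, match="no discriminating"):
            stepwise_dfa(table, parameters=params)

    def test_wilks_matches_eigendecomposition_oracle(self, rng):
        offsets = {"A": [0, 0, 0], "B": [2, 0, 0], "C": [0, 1.5, 0]}
        table, params = gauss_table(rng, 25, offsets, n_params=3)
        res = stepwise_dfa(table, parameters=params)
        # independent oracle: eigenvalues of W^-1 B on the selected columns
        cols = res.selected_parameters
        X = table[cols].to_numpy(float)
        y = pd.Categorical(table["caller_id"]).codes
        g = len(set(y))
        means = np.array([X[y == k].mean(axis=0) for k in range(g)])
        Xw = X - means[y]
        W = Xw.T @ Xw
        T = (X - X.mean(0)).T @ (X - X.mean(0))
        lam = np.linalg.eigvals(np.linalg.inv(W) @ (T - W)).real
        lam = np.sort(lam)[::-1][: res.n_functions]
        assert res.wilks_lambda == pytest.approx(float(np.prod(1 / (1 + lam))), rel=1e-8)
        # and the determinant-ratio route agrees too
        assert res.wilks_lambda == pytest.approx(
            np.linalg.det(W) / np.linalg.det(T), rel=1e-8
        )

    def test_affine_rescaling_invariance(self, rng):
        offsets = {"A": [0, 0, 0, 0], "B": [1.5, 0.5, 0, 0], "C": [0, 1.5, 0.5, 0]}
        table, params = gauss_table(rng, 20, offsets, n_params=4)
        base = stepwise_dfa(table, parameters=params)
        scaled = table.copy()
        scaled["x0"] = scaled["x0"] * 1e4 - 37.0
        scaled["x2"] = scaled["x2"] * 1e-3 + 0.5
        res = stepwise_dfa(scaled, parameters=params)
        assert res.selected_parameters == base.selected_parameters
        assert res.wilks_lambda == pytest.approx(base.wilks_lambda, rel=1e-6)
        assert res.resub_overall == base.resub_overall
        assert res.loo_overall == base.loo_overall

    def test_loadings_highlight_the_separating_parameter(self, rng):
        offsets = {"A": [0, 0, 0], "B": [3, 0, 0]}
        table, params = gauss_table(rng, 40, offsets, n_params=3)
        res = stepwise_dfa(table, parameters=params)
        assert abs(res.loadings.loc["x0", "function_1"]) > 0.45

    def test_parameter_recovery_rate(self):
        # planted 3-SD signatures on two known parameters recovered in >=90%
        planted = {"pfmean", "dfa1mean"}
        hits = 0
        for seed in range(50):
            spec = SignatureSpec(
                n_callers=3,
                calls_per_caller=20,
                call_types=("hum",),
                effect_size=3.0,
                signature_parameters=tuple(planted),
                seed=seed,
            )
            res = stepwise_dfa(synth_feature_table(spec))
            if planted <= set(res.selected_parameters):
                hits += 1
        assert hits >= 45


class TestLeaveOneOut:
    def test_well_separated_clusters_perfect(self, rng):
        table, params = gauss_table(rng, 30, {"A": [0, 0], "B": [8, 0]}, n_params=2)
        overall, per = loo_classification(table, params)
        assert overall == 100.0
        assert per == {"A": 100.0, "B": 100.0}

    def test_identical_callers_at_chance(self, rng):
        table, params = gauss_table(rng, 50, {"A": 0.0, "B": 0.0, "C": 0.0}, n_params=3)
        overall, _ = loo_classification(table, params)
        lo = stats.binom.ppf(0.025, 150, 1 / 3) / 150 * 100
        hi = stats.binom.ppf(0.975, 150, 1 / 3) / 150 * 100
        assert lo <= overall <= hi

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_refit_loop(self, seed):
        # oracle: explicit refit of an equal-prior linear discriminant per
        # held-out row, written independently of the package implementation
        rng = np.random.default_rng(seed)
        table, params = gauss_table(
            rng, 10, {"A": [0, 0, 0], "B": [1, 0.5, 0]}, n_params=3
        )
        X = table[params].to_numpy(float)
        callers = sorted(table["caller_id"].unique())
        y = table["caller_id"].map({c: i for i, c in enumerate(callers)}).to_numpy()
        correct, used = 0, 0
        for i in range(len(y)):
            keep = np.ones(len(y), bool)
            keep[i] = False
            Xi, yi = X[keep], y[keep]
            if np.min(np.bincount(yi)) < 2:
                continue
            means = np.array([Xi[yi == k].mean(0) for k in range(len(callers))])
            Sw = sum(
                (Xi[yi == k] - means[k]).T @ (Xi[yi == k] - means[k])
                for k in range(len(callers))
            )
            Winv = np.linalg.inv(Sw)
            scores = [
                X[i] @ Winv @ means[k] - 0.5 * means[k] @ Winv @ means[k]
                for k in range(len(callers))
            ]
            used += 1
            correct += int(np.argmax(scores) == y[i])
        oracle = 100.0 * correct / used
        overall, _ = loo_classification(table, params)
        assert overall == pytest.approx(oracle, abs=1e-9)

    def test_resubstitution_optimism(self):
        # on average resubstitution is at least as good as leave-one-out
        from vocalid.distinctiveness import _design, _loo_predict, _rates, _resubstitution

        diffs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            table, params = gauss_table(
                rng, 8, {"A": [0] * 4, "B": [0.5] + [0] * 3, "C": [0, 0.5, 0, 0]}, n_params=4
            )
            X, y, _ = _design(table, params)
            resub, _ = _rates(y, _resubstitution(X, y, 3), 3)
            loo, _ = _rates(y, _loo_predict(X, y, 3), 3)
            diffs.append(resub - loo)
        assert np.mean(diffs) >= 0.0

    def test_agrees_with_sklearn_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        table, params = gauss_table(
            rng, 25, {"A": [0, 0, 0], "B": [1.2, 0, 0], "C": [0, 1.2, 0]}, n_params=3
        )
        X = table[params].to_numpy(float)
        y = table["caller_id"].to_numpy()
        ref = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X, y)
        resub_ref = 100.0 * np.mean(ref.predict(X) == y)
        res = stepwise_dfa(table, parameters=params, f_to_enter=0.0, f_to_remove=0.0)
        assert res.resub_overall == pytest.approx(resub_ref)


class TestPDFA:
    def test_separable_table_hits_p_floor(self, rng):
        table, params = gauss_table(rng, 10, {"A": [0], "B": [15]}, n_params=1)
        res = pdfa(table, parameters=params, n_permutations=199, seed=7)
        assert res.p1 == pytest.approx(1 / 200)

    def test_strong_signature_detected(self):
        spec = SignatureSpec(
            n_callers=3,
            calls_per_caller=20,
            call_types=("hum",),
            effect_size=3.0,
            signature_parameters=("pfmean", "dfa1mean"),
            seed=1,
        )
        res = pdfa(synth_feature_table(spec), n_permutations=500, seed=1)
        assert res.p1 <= 0.01

    def test_unbalanced_design_uses_balanced_selections(self, rng):
        table, params = gauss_table(rng, 20, {"A": [2, 0], "B": [0, 0]}, n_params=2)
        extra, _ = gauss_table(rng, 9, {"C": [0, 2]}, n_params=2)
        table = pd.concat([table, extra], ignore_index=True)
        res = pdfa(table, parameters=params, n_selections=10, n_permutations=100, seed=3)
        assert not res.balanced
        assert res.n_per_selection == 9
        assert 0 < res.p1 <= 1

    def test_sequence_blocks_stay_together(self, rng):
        # a caller-confounded sequence effect must NOT look significant when
        # permutation respects sequence blocks: each caller's calls come in
        # few blocks, and block-level permutation preserves block cohesion
        n_seq, per_seq = 4, 5
        rows = []
        for caller in ("A", "B"):
            for s in range(n_seq):
                shift = rng.standard_normal() * 3.0  # big sequence effect
                for i in range(per_seq):
                    rows.append(
                        {
                            "caller_id": caller,
                            "sequence_id": f"{caller}-s{s}",
                            "x0": shift + rng.standard_normal(),
                        }
                    )
        table = pd.DataFrame(rows)
        res = pdfa(table, parameters=["x0"], n_permutations=200, seed=5)
        assert res.p1 > 0.01  # sequence-driven separation is not caller identity

    def test_low_permutation_count_warns(self, rng):
        table, params = gauss_table(rng, 5, {"A": [0], "B": [1]}, n_params=1)
        with pytest.warns(UserWarning, match="permutations"):
            pdfa(table, parameters=params, n_permutations=50, seed=1)

    def test_tiny_groups_rejected(self, rng):
        table, params = gauss_table(rng, 1, {"A": [0], "B": [1]}, n_params=1)
        with pytest.raises(ValueError):
            pdfa(table, parameters=params, n_permutations=100, seed=1)


class TestHochberg:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.04], [True, True]),  # p(2)=0.04 <= 0.05/1
            ([0.03, 0.06], [False, False]),  # 0.06 > 0.05 and 0.03 > 0.025
            ([0.2], [False]),
            ([0.01, 0.02, 0.2], [True, True, False]),
        ],
    )
    def test_step_up_decisions(self, pvals, expected):
        reject, adjusted = hochberg_adjust(pvals, alpha=0.05)
        assert list(reject) == expected
        assert np.all((adjusted >= np.asarray(pvals) - 1e-12) & (adjusted <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hochberg_adjust([0.5, 1.5])


class TestLMM:
    def _seq_table(self, rng, shift_by_caller, n_seq=6, per_seq=3, seq_sd=0.5):
        rows = []
        for caller, shift in shift_by_caller.items():
            for s in range(n_seq):
                b = seq_sd * rng.standard_normal()
                for i in range(per_seq):
                    rows.append(
                        {
                            "caller_id": caller,
                            "sequence_id": f"{caller}-s{s}",
                            "x": shift + b + rng.standard_normal(),
                            "flat": 1.0,
                        }
                    )
        return pd.DataFrame(rows)

    def test_planted_caller_effect_is_significant(self, rng):
        table = self._seq_table(rng, {"A": 0.0, "B": 5.0, "C": 10.0})
        res = lmm_parameter_significance(table, ["x"])
        assert res.loc["x", "p_raw"] < 0.001
        assert bool(res.loc["x", "reject"])

    def test_constant_parameter_gives_missing_p(self, rng):
        table = self._seq_table(rng, {"A": 0.0, "B": 1.0})
        res = lmm_parameter_significance(table, ["x", "flat"])
        assert np.isnan(res.loc["flat", "p_raw"])
        assert not bool(res.loc["flat", "reject"])

    def test_null_type_one_error_rate(self):
        # pure-noise parameter: LRT rejects at ~alpha
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                {
                    "caller_id": np.repeat(["A", "B", "C"], 20),
                    "x": rng.standard_normal(60),
                }
            )
            res = lmm_parameter_significance(table, ["x"])
            hits += int(res.loc["x", "p_raw"] < 0.05)
        assert 0.01 <= hits / 200 <= 0.11


class TestCompareCallTypes:
    def _acc(self, rng, shift_type=None, shift=0.0):
        rows = []
        for caller in ("A", "B", "C", "D", "E", "F"):
            base = rng.uniform(0.55, 0.65)
            for ctype in ("hum", "scream", "grumble", "hoot_series"):
                p = base + rng.normal(0, 0.03)
                if ctype == shift_type:
                    p += shift
                rows.append(
                    {
                        "caller_id": caller,
                        "call_type": ctype,
                        "proportion": float(np.clip(p, 0.01, 0.99)),
                        "n_calls": int(rng.integers(5, 60)),
                    }
                )
        return pd.DataFrame(rows)

    def test_equal_proportions_not_significant(self):
        acc = pd.DataFrame(
            {
                "caller_id": list("ABC") * 3,
                "call_type": np.repeat(["hum", "scream", "grumble"], 3),
                "proportion": 0.7,
                "n_calls": 10,
            }
        )
        f, (df1, df2), p = compare_call_types(acc)
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_shifted_call_type_detected(self, rng):
        f, _, p = compare_call_types(self._acc(rng, shift_type="scream", shift=0.3))
        assert p < 0.05

    def test_needs_two_call_types(self, rng):
        acc = self._acc(rng)
        with pytest.raises(ValueError):
            compare_call_types(acc[acc["call_type"] == "hum"])
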