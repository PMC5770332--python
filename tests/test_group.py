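import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearmvpa.group import (mixed_anova, volume_learning_correlation,
                            wilcoxon_posthoc)


def balanced_table(n_subjects, factors, n_per_cell=1, seed=0, effects=None):
    """Random balanced within-subject table; optional planted cell effects."""
    rng = np.random.default_rng(seed)
    rows = []
    levels = {f: ("a", "b") for f in factors}
    subj_int = rng.normal(0, 1.0, size=n_subjects)
    for s in range(n_subjects):
        for cell in itertools.product(*(levels[f] for f in factors)):
            mu = subj_int[s]
            if effects:
                for f, lev in zip(factors, cell):
                    mu += effects.get(f, 0.0) * (1 if lev == "a" else -1)
            for _ in range(n_per_cell):
                row = {"subject": f"s{s}", "value": mu + rng.normal(0, 1.0)}
                row.update(dict(zip(factors, cell)))
                rows.append(row)
    return pd.DataFrame(rows)


def rm_anova_oracle(tbl, factors):
    """Independent pooled-error repeated-measures ANOVA on a one-obs-per-cell
    table, via classical cell-mean contrast formulas:

    SS_effect = N * (sum over marginal cells of sign * cell mean / 2^order)^2
    pooled error SS = sum (y - subject mean)^2 - sum of all effect SS
    """
    df = tbl.copy()
    n_subj = df["subject"].nunique()
    k = len(factors)
    n_cells = 2 ** k
    N = len(df)
    yv = df["value"].to_numpy()

    def cell_mean(assign):
        sel = df
        for f, lev in assign.items():
            sel = sel[sel[f] == lev]
        return sel["value"].mean()

    ss = {}
    for order in range(1, k + 1):
        for combo in itertools.combinations(factors, order):
            contrast = 0.0
            for levs in itertools.product(("a", "b"), repeat=len(combo)):
                sign = np.prod([1.0 if lev == "a" else -1.0 for lev in levs])
                contrast += sign * cell_mean(dict(zip(combo, levs)))
            contrast /= 2 ** len(combo)
            ss[" x ".join(combo)] = N * contrast ** 2

    subj_means = df.groupby("subject")["value"].transform("mean").to_numpy()
    ss_within_resid = ((yv - subj_means) ** 2).sum() - sum(ss.values())
    df_den = N - n_subj - (n_cells - 1)
    out = {name: s / (ss_within_resid / df_den) for name, s in ss.items()}
    return out, df_den


class TestDfArithmetic:
    def test_hg_model_df_119(self):
        tbl = balanced_table(18, ["context", "complexity", "hemisphere"], seed=1)
        ft = mixed_anova(tbl, ["context", "complexity", "hemisphere"])
        assert (ft["df_den"] == 119).all()
        assert len(ft) == 7
        assert (ft["df_num"] == 1).all()

    def test_amygdala_model_df_51(self):
        tbl = balanced_table(18, ["context", "complexity"], seed=2)
        ft = mixed_anova(tbl, ["context", "complexity"])
        assert (ft["df_den"] == 51).all()

    def test_trialwise_scr_model_df_2665(self):
        # 16 subjects x 168 trials in a 2x2x2 design: 21 trials per cell
        tbl = balanced_table(16, ["cs", "context", "complexity"],
                             n_per_cell=21, seed=3)
        assert len(tbl) == 16 * 168
        ft = mixed_anova(tbl, ["cs", "context", "complexity"])
        assert (ft["df_den"] == 2665).all()


class TestAgainstOracle:
    @pytest.mark.parametrize("factors", [["f1"], ["f1", "f2"],
                                         ["f1", "f2", "f3"]])
    def test_f_matches_rm_anova_oracle(self, factors):
        tbl = balanced_table(6, factors, seed=11,
                             effects={f: 0.4 for f in factors})
        ft = mixed_anova(tbl, factors).set_index("effect")
        oracle_f, oracle_df = rm_anova_oracle(tbl, factors)
        for name, f_expected in oracle_f.items():
            assert ft.loc[name, "F"] == pytest.approx(f_expected, abs=1e-6)
            assert ft.loc[name, "df_den"] == oracle_df

    def test_invariant_to_relabeling(self):
        factors = ["context", "complexity"]
        tbl = balanced_table(8, factors, seed=12, effects={"context": 0.5})
        ft1 = mixed_anova(tbl, factors)
        relabeled = tbl.copy()
        relabeled["subject"] = relabeled["subject"].map(lambda s: f"zz{s[::-1]}")
        relabeled["context"] = relabeled["context"].map({"a": "x", "b": "w"})
        ft2 = mixed_anova(relabeled, factors)
        assert np.allclose(ft1["F"], ft2["F"])

    def test_detects_planted_main_effect(self):
        tbl = balanced_table(18, ["context", "complexity"], seed=13,
                             effects={"context": 1.0})
        ft = mixed_anova(tbl, ["context", "complexity"]).set_index("effect")
        assert ft.loc["context", "p"] < 0.001
        assert ft.loc["complexity", "p"] > 0.05


class TestValidation:
    def test_unbalanced_rejected_with_cell_report(self):
        tbl = balanced_table(4, ["context"], seed=4)
        tbl = tbl.iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(tbl, ["context"])

    def test_non_two_level_factor_rejected(self):
        tbl = balanced_table(4, ["context"], seed=5)
        tbl.loc[0, "context"] = "c"
        with pytest.raises(ValueError):
            mixed_anova(tbl, ["context"])


@settings(max_examples=10, deadline=None)
@given(k=st.integers(1, 3), n_subj=st.integers(3, 10),
       seed=st.integers(0, 1000))
def test_containment_df_identity(k, n_subj, seed):
    factors = [f"f{i}" for i in range(k)]
    tbl = balanced_table(n_subj, factors, seed=seed)
    ft = mixed_anova(tbl, factors)
    n_obs = n_subj * 2 ** k
    assert (ft["df_den"] == n_obs - n_subj - (2 ** k - 1)).all()


class TestEndToEndPositiveControl:
    def test_shared_threat_regime_yields_context_main_effect(
            self, feature_subject):
        """Decoding a shared-threat-pattern group and fitting the factorial
        mixed model reproduces the expected qualitative pattern (context
        main effect significant, context x complexity not) in most
        simulated experiments."""
        from fearmvpa.decoding import roi_decoding

        def experiment(base_seed):
            rows = []
            for s in range(6):
                betas = feature_subject(base_seed + s, noise_sd=1.0,
                                        stim_amplitude=1.0,
                                        threat_shared_amplitude=2.0)
                for o in roi_decoding(betas, n_perm=40, n_rep=4,
                                      seed=base_seed + s):
                    rows.append({"subject": s, "context": o.condition[0],
                                 "complexity": o.condition[1],
                                 "value": o.corrected_accuracy})
            ft = mixed_anova(pd.DataFrame(rows),
                             ["context", "complexity"]).set_index("effect")
            return bool(ft.loc["context", "p"] < 0.05
                        and ft.loc["context x complexity", "p"] >= 0.05)

        hits = sum(experiment(9000 + 1000 * e) for e in range(5))
        assert hits >= 4


class TestWilcoxon:
    def test_identical_samples_error(self):
        a = np.arange(6, dtype=float)
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_posthoc(a, a)

    def test_exact_one_sided_p_all_positive_n6(self):
        """Oracle: all 6 positive differences is 1 of 2^6 sign patterns."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.5, 0.4, 0.3, 0.2, 0.6, 0.7])
        p = wilcoxon_posthoc(a, b, alternative="greater")
        assert p == pytest.approx(1.0 / 64.0)

    def test_type_i_calibration(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_runs = 1000
        for _ in range(n_runs):
            a = rng.standard_normal(15)
            b = rng.standard_normal(15)
            rejections += wilcoxon_posthoc(a, b) < 0.05
        assert 0.03 <= rejections / n_runs <= 0.07

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_posthoc(np.ones(3), np.zeros(3))


class TestVolumeCorrelation:
    @staticmethod
    def _records(rng, n, partial_r=0.0):
        gm = rng.normal(1000.0, 100.0, size=n)
        resid = rng.standard_normal(n)
        hg = 0.05 * gm + 10.0 * resid
        noise = rng.standard_normal(n)
        learning = partial_r * resid + np.sqrt(1 - partial_r ** 2) * noise
        return pd.DataFrame({"subject": range(n), "hg_voxels": hg,
                             "total_gm_voxels": gm,
                             "learning_complex": learning,
                             "learning_simple": rng.standard_normal(n)})

    def test_collinear_volumes_error(self):
        rng = np.random.default_rng(7)
        rec = self._records(rng, 10)
        rec["hg_voxels"] = 0.1 * rec["total_gm_voxels"]
        with pytest.raises(ValueError, match="collinear"):
            volume_learning_correlation(rec)

    def test_planted_partial_correlation_recovered(self):
        """Oracle: brute-force partial correlation from the 3-variable
        correlation matrix matches the residual-based estimate."""
        rng = np.random.default_rng(8)
        est, oracle = [], []
        for _ in range(300):
            rec = self._records(rng, 18, partial_r=0.6)
            r, _p = volume_learning_correlation(
                rec, ["learning_complex"])["learning_complex"]
            est.append(r)
            rxy = np.corrcoef(rec["hg_voxels"], rec["learning_complex"])[0, 1]
            rxz = np.corrcoef(rec["hg_voxels"], rec["total_gm_voxels"])[0, 1]
            ryz = np.corrcoef(rec["learning_complex"],
                              rec["total_gm_voxels"])[0, 1]
            # correlation of learning with hg after removing gm from hg only
            oracle.append((rxy - rxz * ryz)
                          / np.sqrt((1 - rxz ** 2)))
        assert abs(np.mean(est) - np.mean(oracle)) < 0.02
        assert abs(np.mean(est) - 0.6) < 0.1

    def test_null_correlation_near_zero(self):
        rng = np.random.default_rng(9)
        rs = [volume_learning_correlation(
            self._records(rng, 18), ["learning_complex"])["learning_complex"][0]
            for _ in range(300)]
        assert abs(np.mean(rs)) < 0.05

    def test_too_few_subjects(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="4 subjects"):
            volume_learning_correlation(self._records(rng, 3))
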