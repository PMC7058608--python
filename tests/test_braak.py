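import math

import numpy as np
import pandas as pd
import pytest

from braakmap.braak import (
    BraakGeneModel,
    region_fold_change,
    select_brgs,
    stage_correlation,
    summarize_genes,
)
from braakmap.stats import fisher_z, inverse_fisher, meta_random_effects
from conftest import make_donor


class TestStageCorrelation:
    def test_gene_equal_to_labels(self, toy_donor):
        expr, samples = toy_donor
        labels = samples.set_index("sample_id")["braak_region"].astype(float)
        frame = expr.data.copy()
        frame.iloc[0] = labels.reindex(frame.columns).to_numpy()
        frame.iloc[1] = -frame.iloc[0]
        frame.iloc[2] = 5.0  # constant
        r = stage_correlation(frame, samples)
        assert r.iloc[0] == pytest.approx(1.0)
        assert r.iloc[1] == pytest.approx(-1.0)
        assert np.isnan(r.iloc[2])

    def test_matches_textbook_formula(self, rng):
        expr, samples = make_donor(rng, n_genes=10, samples_per_region=4)
        r = stage_correlation(expr.data, samples)
        y = samples["braak_region"].astype(float).to_numpy()
        for i in range(10):
            x = expr.data.iloc[i].to_numpy()
            expected = (
                np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
            )
            assert r.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_error(self, rng):
        expr, samples = make_donor(rng, n_genes=4, samples_per_region=3)
        samples = samples.iloc[:3]
        with pytest.raises(ValueError, match=">= 4"):
            stage_correlation(expr.data.iloc[:, :3], samples)


class TestRegionFoldChange:
    def test_planted_difference(self, rng):
        expr, samples = make_donor(rng, n_genes=5, samples_per_region=3)
        frame = expr.data * 0.0
        in6 = samples.set_index("sample_id")["braak_region"].reindex(frame.columns) == 6
        frame.loc[:, in6.to_numpy()] = 1.0
        frame += rng.normal(0, 1e-6, frame.shape)
        out = region_fold_change(frame, samples, 1, 6)
        np.testing.assert_allclose(out["fc"], 1.0, atol=1e-5)

    def test_group_size_error(self, rng):
        expr, samples = make_donor(rng, n_genes=4)
        samples = samples[samples["braak_region"] != 6]
        with pytest.raises(ValueError, match="R1/R6"):
            region_fold_change(expr.data, samples, 1, 6)


class TestSummarize:
    def test_two_donor_toy_matches_hand_chain(self, rng):
        donor_expr, frames = {}, []
        for donor in ("donorA", "donorB"):
            expr, samples = make_donor(rng, n_genes=6, samples_per_region=3, donor=donor)
            donor_expr[donor] = expr.data
            frames.append(samples)
        samples = pd.concat(frames, ignore_index=True)
        out = summarize_genes(donor_expr, samples)

        gene = out.index[0]
        zs, vzs = [], []
        for donor in ("donorA", "donorB"):
            sub = samples[samples["donor_id"] == donor]
            r = stage_correlation(donor_expr[donor], sub).loc[gene]
            zs.append(fisher_z(r))
            vzs.append(1.0 / (18 - 3))
        meta = meta_random_effects(zs, vzs)
        assert out.loc[gene, "r"] == pytest.approx(inverse_fisher(meta.effect), abs=1e-12)
        assert out.loc[gene, "p_r"] == pytest.approx(meta.p, abs=1e-12)

    def test_donor_permutation_invariance(self, rng):
        donor_expr, frames = {}, []
        for donor in ("d1", "d2", "d3"):
            expr, samples = make_donor(rng, n_genes=8, donor=donor)
            donor_expr[donor] = expr.data
            frames.append(samples)
        samples = pd.concat(frames, ignore_index=True)
        a = summarize_genes(donor_expr, samples)
        reordered = {k: donor_expr[k] for k in ("d3", "d1", "d2")}
        b = summarize_genes(reordered, samples)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_r_across_donors_is_preserved(self, rng):
        donor_expr, frames = {}, []
        for donor in ("d1", "d2"):
            expr, samples = make_donor(rng, n_genes=3, donor=donor)
            labels = samples.set_index("sample_id")["braak_region"].astype(float)
            frame = expr.data
            # plant identical noise pattern relative to labels in both donors
            base = labels.reindex(frame.columns).to_numpy()
            frame.iloc[0] = base + np.sin(np.arange(len(base)))
            donor_expr[donor] = frame
            frames.append(samples)
        samples = pd.concat(frames, ignore_index=True)
        out = summarize_genes(donor_expr, samples)
        sub = samples[samples["donor_id"] == "d1"]
        r1 = stage_correlation(donor_expr["d1"], sub).iloc[0]
        assert out.iloc[0]["r"] == pytest.approx(r1, abs=1e-10)
        assert out.iloc[0]["tau2_r"] == 0.0


class TestSelectBRGs:
    @staticmethod
    def _summary(r, fc, q_fc):
        genes = [f"G{i:02d}" for i in range(len(r))]
        return pd.DataFrame({"r": r, "fc": fc, "q_fc": q_fc}, index=genes)

    def test_identical_rankings_select_shared_top(self):
        r = np.linspace(0.9, 0.0, 10)
        summary = self._summary(r, r * 2, np.linspace(0.001, 0.5, 10))
        sel = select_brgs(summary, fraction=0.2)
        assert sorted(sel.genes) == ["G00", "G01"]
        assert len(sel.positive_genes) == 2

    def test_conflicting_rankings_match_enumeration(self, rng):
        for _ in range(20):
            summary = self._summary(
                rng.uniform(-1, 1, 10), rng.normal(0, 2, 10), rng.uniform(0, 1, 10)
            )
            frac = 0.3
            sel = select_brgs(summary, fraction=frac)
            n_top = int(math.floor(frac * 10))
            def top(series, ascending):
                ordered = series.sort_values(ascending=ascending, kind="mergesort")
                return set(ordered.index[:n_top])
            expected = (
                top(summary["r"].abs(), False)
                & top(summary["fc"].abs(), False)
                & top(summary["q_fc"], True)
            )
            assert set(sel.genes) == expected
            assert len(sel) <= n_top
            # every member re-passes all three criteria against the thresholds
            for g in sel.genes:
                assert abs(summary.loc[g, "r"]) >= sel.r_cut
                assert abs(summary.loc[g, "fc"]) >= sel.fc_cut
                assert summary.loc[g, "q_fc"] <= sel.p_cut

    def test_sign_split_and_fraction_validation(self):
        summary = self._summary([0.9, -0.8], [2.0, -2.0], [0.01, 0.02])
        sel = select_brgs(summary, fraction=1.0)
        assert set(sel.positive_genes) == {"G00"}
        assert set(sel.negative_genes) == {"G01"}
        with pytest.raises(ValueError):
            select_brgs(summary, fraction=0.0)


def test_brg_sensitivity_monotone_in_effect_size():
    """Recovery of planted gradient genes improves with the planted effect."""
    from braakmap.simulate import SimulationConfig, generate_atlas

    sens = []
    for effect in (0.0, 0.2, 0.5):
        config = SimulationConfig(
            n_genes=600, n_pos_gradient=30, n_neg_gradient=30,
            gradient_effect=effect, noise_sd=0.5, seed=11,
        )
        donor_expr, samples, truth = generate_atlas(config)
        results = BraakGeneModel(
            {d: e.data for d, e in donor_expr.items()}, samples
        ).fit()
        sel = results.select_brgs(0.10)
        planted = set(truth.genes_of_class("pos_gradient")) | set(
            truth.genes_of_class("neg_gradient")
        )
        sens.append(len(set(sel.genes) & planted) / len(planted))
    assert sens[0] <= sens[1] <= sens[2]
    assert sens[0] < 0.3  # zero effect: recovery near chance
    assert sens[2] > 0.9
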