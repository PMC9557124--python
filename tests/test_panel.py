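"""Panel intersection, UV classification of panel spectra, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from melasig.contexts import CONTEXT_LABELS, MutationCatalog, build_context_matrix
from melasig.errors import AlignmentError, ParameterError
from melasig.io import PanelRegions
from melasig.panel import (
    average_context,
    classify_panel_cohort,
    classify_panel_sample,
    intersect_panel,
    pre_post_concordance,
)
from melasig.references import sbs1_like, sbs7a_like
from melasig.simulate import simulate_panel


def _catalog(positions, chrom="1", sample="s1"):
    df = pd.DataFrame(
        {
            "sample_id": sample,
            "chrom": chrom,
            "pos": positions,
            "ref": "C",
            "alt": "T",
            "variant_class": "SNV",
        }
    )
    return MutationCatalog(df, [sample])


class TestIntersectPanel:
    def test_half_open_coordinate_arithmetic(self):
        panel = PanelRegions.from_intervals([("1", 99, 100)])
        kept = intersect_panel(_catalog([100]), panel)
        assert len(kept) == 1
        dropped = intersect_panel(_catalog([101]), panel)
        assert len(dropped) == 0
        assert dropped.sample_ids == ["s1"]  # sample survives with zero records

    def test_idempotent(self, cohorts):
        c = cohorts[0]
        once = intersect_panel(c["catalog"], c["panel"])
        twice = intersect_panel(once, c["panel"])
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_commutes_with_sample_subsetting(self, cohorts):
        c = cohorts[0]
        keep = c["catalog"].sample_ids[:40]
        a = intersect_panel(c["catalog"].subset_samples(keep), c["panel"])
        b = intersect_panel(c["catalog"], c["panel"]).subset_samples(keep)
        pd.testing.assert_frame_equal(
            a.records.reset_index(drop=True), b.records.reset_index(drop=True)
        )

    def test_empty_panel_rejected(self, cohorts):
        with pytest.raises(ParameterError):
            PanelRegions.from_intervals([])

    def test_uniform_positions_retained_at_binomial_rate(self, toy_genome):
        """3%-coverage panel retains ~3% of uniformly placed mutations."""
        panel = simulate_panel(toy_genome, coverage_fraction=0.03, seed=3)
        rng = np.random.default_rng(8)
        n = 20000
        cat = _catalog(rng.integers(3, 999_998, size=n) + 1)
        kept = len(intersect_panel(cat, panel))
        lo, hi = stats.binom.ppf([0.005, 0.995], n, panel.total_bases / 1_000_000)
        assert lo <= kept <= hi


class TestClassifyPanelSample:
    sig_a = sbs1_like()
    sig_b = sbs7a_like()

    def test_uv_dominant_spectrum_is_uv_high(self):
        spectrum = np.round(20 * self.sig_b)
        res = classify_panel_sample(spectrum, self.sig_a, self.sig_b)
        assert res.label == "UV-high" and res.sigb_weight > 0.5 and not res.excluded

    def test_clock_dominant_spectrum_is_uv_low(self):
        spectrum = np.round(30 * self.sig_a)
        res = classify_panel_sample(spectrum, self.sig_a, self.sig_b)
        assert res.label == "UV-low" and res.sigb_weight < 0.5

    def test_exact_half_weight_is_uv_low(self):
        """The UV-high rule is strictly greater-than 0.5."""
        spectrum = 10 * (0.5 * self.sig_a + 0.5 * self.sig_b)
        res = classify_panel_sample(spectrum, self.sig_a, self.sig_b)
        assert res.sigb_weight == pytest.approx(0.5, abs=1e-9)
        assert res.label == "UV-low"

    def test_fewer_than_five_snvs_excluded_without_label(self):
        spectrum = np.zeros(96)
        spectrum[40] = 4
        res = classify_panel_sample(spectrum, self.sig_a, self.sig_b)
        assert res.excluded and res.label is None and res.sigb_weight is None
        assert res.n_snv_panel == 4
        boundary = np.zeros(96)
        boundary[40] = 5
        assert not classify_panel_sample(boundary, self.sig_a, self.sig_b).excluded


class TestPrePostConcordance:
    def test_identity_panel_gives_unit_cosine_and_retention(self, small_cohort, small_genome):
        wes = build_context_matrix(small_cohort["catalog"], small_genome)
        cc = pre_post_concordance(wes, wes.copy())
        np.testing.assert_allclose(cc["cosine"], 1.0, atol=1e-12)
        np.testing.assert_allclose(cc["retention"], 1.0)

    def test_empty_panel_spectrum_reported_missing(self):
        wes = pd.DataFrame([np.ones(96), np.ones(96)], index=["a", "b"],
                           columns=list(CONTEXT_LABELS))
        panel = wes.copy()
        panel.loc["b"] = 0
        cc = pre_post_concordance(wes, panel)
        assert np.isnan(cc.loc["b", "cosine"])
        assert cc.loc["b", "retention"] == 0

    def test_mismatched_samples_rejected(self):
        wes = pd.DataFrame([np.ones(96)], index=["a"], columns=list(CONTEXT_LABELS))
        panel = pd.DataFrame([np.ones(96)], index=["b"], columns=list(CONTEXT_LABELS))
        with pytest.raises(AlignmentError):
            pre_post_concordance(wes, panel)

    def test_retention_matches_generator_bookkeeping(self, cohorts, toy_genome):
        """Panel retention equals the exact per-record interval placement count."""
        c = cohorts[0]
        sub = intersect_panel(c["catalog"], c["panel"])
        wes = build_context_matrix(c["catalog"], toy_genome)
        pm = build_context_matrix(sub, toy_genome)
        cc = pre_post_concordance(wes, pm)
        by_sample = sub.snv_counts()
        np.testing.assert_allclose(
            cc["retention"].to_numpy(),
            by_sample.to_numpy() / c["truth"]["n_snv"].to_numpy(),
        )


class TestAverageContext:
    def test_single_sample_group_is_its_own_profile(self):
        m = pd.DataFrame([np.arange(96.0) + 1], index=["a"], columns=list(CONTEXT_LABELS))
        avg = average_context(m, {"a": "UV-high"})
        np.testing.assert_allclose(
            avg.loc["UV-high"], (np.arange(96.0) + 1) / m.sum(axis=1).iloc[0]
        )
        assert avg.loc["UV-high"].sum() == pytest.approx(1.0)

    def test_identical_samples_average_to_same_profile(self):
        row = np.random.default_rng(1).multinomial(100, np.ones(96) / 96).astype(float)
        m = pd.DataFrame([row, 3 * row], index=["a", "b"], columns=list(CONTEXT_LABELS))
        avg = average_context(m, {"a": "g", "b": "g"})
        np.testing.assert_allclose(avg.loc["g"], row / row.sum(), atol=1e-12)

    def test_uv_high_group_mean_matches_generating_uv_mixture(
        self, fitted_cohorts, generator_signatures
    ):
        from melasig.nmf import cosine_similarity

        c = fitted_cohorts[0]
        heavy = c["truth"]["n_snv"] >= 50
        labels = {
            s: c["truth"].loc[s, "cluster"]
            for s in c["truth"].index[heavy]
        }
        avg = average_context(c["tally"], labels)
        mix = (
            0.85 * generator_signatures.uv_like + 0.15 * generator_signatures.flat_clock
        )
        assert cosine_similarity(avg.loc["UV-high"].to_numpy(), mix) >= 0.98


def test_panel_labels_agree_with_wes_at_ten_snvs(fitted_cohorts, toy_genome):
    """With >= 10 panel SNVs, panel calls agree with WES k-means labels >= 90%."""
    agree = total = 0
    for c in fitted_cohorts[:4]:
        sub = intersect_panel(c["catalog"], c["panel"])
        pm = build_context_matrix(sub, toy_genome)
        W, uv = c["nmf"].signatures, c["uv_index"]
        calls = classify_panel_cohort(pm, W[:, 1 - uv], W[:, uv])
        wes = c["clusters"].label_of()
        kept = calls.index[(~calls["excluded"]) & (calls["n_snv_panel"] >= 10)]
        agree += sum(calls.loc[s, "label"] == wes[s] for s in kept)
        total += len(kept)
    assert total > 50
    assert agree / total >= 0.90
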