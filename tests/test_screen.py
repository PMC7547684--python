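"""Differential methylation screen, classification, and meta-profile."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epilnc.annotation import SiteMap
from epilnc.screen import (
    DiffMethRecord,
    bh_adjust,
    classify_epigenetic,
    differential_expression,
    differential_methylation,
    promoter_beta,
    rank_top_silenced,
    recurrence_summary,
    tss_meta_profile,
    validate_beta,
)


def _sm(site, gene, offset=0):
    return SiteMap(site, "c", 0, gene, offset)


def _beta(data, samples):
    return pd.DataFrame(data, columns=samples)


# ---------------------------------------------------------------- oracles


def mannwhitney_permutation_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group splits."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    obs = abs(u_stat(range(n)) - len(x) * len(y) / 2)
    devs = [
        abs(u_stat(idx) - len(x) * len(y) / 2)
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    return sum(d >= obs - 1e-12 for d in devs) / len(devs)


def bh_stepup_bruteforce(pvals):
    """Literal BH step-up: q_(i) = min_{j>=i} m * p_(j) / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------- tests


class TestPromoterBeta:
    def test_mean_over_assigned_sites(self):
        beta = _beta({"A": [0.2, 0.4]}, ["A"]).rename(index={0: "s1", 1: "s2"})
        out = promoter_beta(beta, [_sm("s1", "g"), _sm("s2", "g")])
        assert out.loc["g", "A"] == pytest.approx(0.3)

    def test_missing_value_ignored_pairwise(self):
        beta = pd.DataFrame(
            [[0.2, 0.2], [np.nan, 0.4]], index=["s1", "s2"], columns=["A", "B"]
        )
        out = promoter_beta(beta, [_sm("s1", "g"), _sm("s2", "g")])
        assert out.loc["g", "A"] == pytest.approx(0.2)
        assert out.loc["g", "B"] == pytest.approx(0.3)

    def test_gene_without_sites_absent(self):
        beta = pd.DataFrame([[0.5]], index=["s1"], columns=["A"])
        out = promoter_beta(beta, [_sm("s1", "g1"), SiteMap("s2", "c", 0, None, None)])
        assert list(out.index) == ["g1"]

    def test_beta_range_validation(self):
        with pytest.raises(ValueError):
            validate_beta(pd.DataFrame([[1.2]]))


class TestDifferentialMethylation:
    groups = {"T1": "tumor", "T2": "tumor", "T3": "tumor",
              "N1": "normal", "N2": "normal", "N3": "normal"}
    samples = ["T1", "T2", "T3", "N1", "N2", "N3"]

    def test_delta_beta_is_group_mean_difference(self):
        pb = _beta([[0.8, 0.8, 0.8, 0.2, 0.2, 0.2]], self.samples)
        (rec,) = differential_methylation(pb, self.groups)
        assert rec.delta_beta == pytest.approx(0.6)
        assert rec.log2fc_meth == pytest.approx(np.log2(0.81 / 0.21))

    def test_identical_groups_give_p_one(self):
        pb = _beta([[0.5] * 6], self.samples)
        (rec,) = differential_methylation(pb, self.groups)
        assert rec.delta_beta == 0.0 and rec.p_value == 1.0

    def test_complete_separation_matches_enumeration_oracle(self):
        tumor, normal = [0.9, 0.8, 0.7], [0.1, 0.2, 0.3]
        pb = _beta([tumor + normal], self.samples)
        (rec,) = differential_methylation(pb, self.groups)
        expected = mannwhitney_permutation_p(np.array(tumor), np.array(normal))
        assert expected == pytest.approx(0.1)  # 2 of the 20 splits are as extreme
        assert rec.p_value == pytest.approx(expected)

    def test_small_group_yields_missing_p(self):
        groups = {"T1": "tumor", "N1": "normal", "N2": "normal"}
        pb = _beta([[0.9, 0.1, 0.2]], ["T1", "N1", "N2"])
        (rec,) = differential_methylation(pb, groups)
        assert np.isnan(rec.p_value) and np.isnan(rec.q_value)
        assert rec.delta_beta == pytest.approx(0.75)


class TestDifferentialExpression:
    groups = TestDifferentialMethylation.groups
    samples = TestDifferentialMethylation.samples

    def test_log2fc_uses_pseudocount(self):
        expr = _beta([[8.0, 8.0, 8.0, 1.0, 1.0, 1.0]], self.samples)
        out = differential_expression(expr, self.groups, pseudocount=1)
        assert out["log2fc"].iloc[0] == pytest.approx(np.log2(9 / 2))

    def test_equal_means_zero_log2fc(self):
        expr = _beta([[3.0, 4.0, 5.0, 5.0, 4.0, 3.0]], self.samples)
        assert differential_expression(expr, self.groups)["log2fc"].iloc[0] == 0.0

    def test_separated_groups_match_enumeration_oracle(self):
        expr = _beta([[9.0, 8.0, 7.0, 1.0, 2.0, 3.0]], self.samples)
        out = differential_expression(expr, self.groups)
        assert out["p_value"].iloc[0] == pytest.approx(0.1)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=20)
)
def test_bh_matches_bruteforce_stepup(pvals):
    np.testing.assert_allclose(
        bh_adjust(np.array(pvals)), bh_stepup_bruteforce(pvals), atol=1e-12
    )


def _meth_record(gene, delta, q):
    return DiffMethRecord(gene, 0.5, 0.5 - delta, delta, 0.0, q, q)


def _expr_table(entries):
    return pd.DataFrame(
        [{"gene_id": g, "log2fc": lfc, "q_value": q} for g, lfc, q in entries],
        columns=["gene_id", "log2fc", "q_value"],
    ).set_index("gene_id")


class TestClassification:
    def test_concordant_hypermethylated_down_gene_is_silenced(self):
        calls = classify_epigenetic(
            [_meth_record("g", 0.4, 0.001)], _expr_table([("g", -2.0, 0.001)])
        )
        assert calls[0].label == "silenced"

    def test_discordant_gene_is_unaltered(self):
        calls = classify_epigenetic(
            [_meth_record("g", 0.4, 0.001)], _expr_table([("g", 2.0, 0.001)])
        )
        assert calls[0].label == "unaltered"

    def test_subthreshold_delta_beta_is_unaltered(self):
        calls = classify_epigenetic(
            [_meth_record("g", 0.05, 0.001)], _expr_table([("g", -2.0, 0.001)])
        )
        assert calls[0].label == "unaltered"

    def test_gene_missing_from_expression_flagged(self):
        calls = classify_epigenetic([_meth_record("g", 0.4, 0.001)], _expr_table([]))
        assert calls[0].label == "unaltered" and calls[0].reason == "no_expression_data"

    def test_label_swap_symmetry_on_simulated_cohort(self, default_cohort):
        """Swapping the tumor/normal assignment maps silenced<->activated exactly."""
        from epilnc.annotation import map_sites, promoter_interval

        beta, groups, expr = (
            default_cohort["beta"], default_cohort["groups"], default_cohort["expr"],
        )
        promoters = {
            g.gene_id: promoter_interval(g) for g in default_cohort["genes"]
        }
        sitemap = map_sites(default_cohort["sites"], default_cohort["genes"],
                            promoters=promoters)
        pb = promoter_beta(beta, sitemap)
        swapped = {s: ("tumor" if g == "normal" else "normal") for s, g in groups.items()}

        def labels(grp):
            meth = differential_methylation(pb, grp)
            de = differential_expression(expr, grp)
            return {c.gene_id: c.label for c in classify_epigenetic(meth, de)}

        direct, flipped = labels(groups), labels(swapped)
        swap = {"silenced": "activated", "activated": "silenced", "unaltered": "unaltered"}
        assert flipped == {g: swap[lab] for g, lab in direct.items()}


class TestRecurrenceAndRanking:
    def _calls(self):
        from epilnc.screen import EpiCall

        mk = lambda g, ct, lab: EpiCall(g, ct, lab, 0.3, -1.0, 0.01, 0.01)
        return [
            mk("gA", "ct1", "silenced"), mk("gA", "ct2", "silenced"),
            mk("gB", "ct1", "silenced"), mk("gB", "ct2", "unaltered"),
            mk("gC", "ct1", "unaltered"), mk("gC", "ct2", "unaltered"),
            mk("gD", "ct1", "activated"),
        ]

    def test_recurrence_counts_and_any_altered(self):
        summary = recurrence_summary(self._calls())
        assert summary.loc["gA", "n_types_silenced"] == 2
        assert summary.loc["gB", "n_types_silenced"] == 1
        assert bool(summary.loc["gC", "any_altered"]) is False
        assert bool(summary.loc["gD", "any_altered"]) is True
        assert int(summary["any_altered"].sum()) == 3

    def test_rank_orders_by_count_then_fold_change_then_name(self):
        from epilnc.screen import EpiCall

        mk = lambda g, ct, lab: EpiCall(g, ct, lab, 0.3, -1.0, 0.01, 0.01)
        calls = [
            mk("gA", "ct1", "silenced"), mk("gB", "ct1", "silenced"),
            mk("gC", "ct1", "silenced"), mk("gD", "ct1", "silenced"),
            mk("gA", "ct2", "silenced"),
        ]
        meth = {
            "ct1": [
                DiffMethRecord("gA", 0, 0, 0.3, 0.5, 0.01, 0.01),
                DiffMethRecord("gB", 0, 0, 0.3, 1.2, 0.01, 0.01),
                DiffMethRecord("gC", 0, 0, 0.3, 0.8, 0.01, 0.01),
                DiffMethRecord("gD", 0, 0, 0.3, 0.8, 0.01, 0.01),
            ],
            "ct2": [DiffMethRecord("gA", 0, 0, 0.3, 0.5, 0.01, 0.01)],
        }
        order, lfc = rank_top_silenced(calls, meth)
        # gA silenced twice; then by mean log2fc 1.2 > 0.8; gC/gD tie -> lexicographic
        assert order == ["gA", "gB", "gC", "gD"]
        assert list(lfc.index) == order

    def test_k_truncates(self):
        order, _ = rank_top_silenced(self._calls(), {"ct1": [], "ct2": []}, k=1)
        assert order == ["gA"]


class TestMetaProfile:
    groups = {"T1": "tumor", "N1": "normal", "T2": "tumor", "N2": "normal"}

    def _beta(self, site_deltas):
        rows, index = [], []
        for site, d in site_deltas.items():
            rows.append([0.2 + d, 0.2 + d, 0.2, 0.2])
            index.append(site)
        return pd.DataFrame(rows, index=index, columns=["T1", "T2", "N1", "N2"])

    def test_uniform_delta_fills_every_populated_bin(self):
        sitemap = [_sm(f"s{i}", "g", off) for i, off in enumerate([-2500, -100, 0, 800])]
        beta = self._beta({f"s{i}": 0.5 for i in range(4)})
        prof = tss_meta_profile(beta, self.groups, sitemap, ["g"], bin_width=100)
        populated = prof.bin_counts > 0
        np.testing.assert_allclose(prof.bin_values[populated], 0.5)
        assert populated.sum() == 4

    def test_unpopulated_bins_undefined(self):
        sitemap = [_sm("s0", "g", -1500)]
        prof = tss_meta_profile(self._beta({"s0": 0.3}), self.groups, sitemap, ["g"])
        downstream = prof.bin_centers > 0
        assert (prof.bin_counts[downstream] == 0).all()
        assert np.isnan(prof.bin_values[downstream]).all()

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            tss_meta_profile(self._beta({"s0": 0.3}), self.groups, [_sm("s0", "g", 0)], [])

    def test_planted_central_peak_recovered(self, default_cohort):
        """TSS-peaked simulation puts the maximum bin near offset zero."""
        from epilnc.annotation import map_sites

        truth = default_cohort["truth"]
        silenced = [g for g, lab in truth.labels.items() if lab == "silenced"]
        sitemap = map_sites(default_cohort["sites"], default_cohort["genes"],
                            tss_window=3000)
        prof = tss_meta_profile(
            default_cohort["beta"], default_cohort["groups"], sitemap, silenced
        )
        assert abs(prof.peak_offset()) <= 500
        # flanks carry essentially no differential methylation
        flank = np.abs(prof.bin_centers) > 2000
        assert np.nanmean(np.abs(prof.bin_values[flank])) < 0.05
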