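"""Three-stage candidate funnel: toy oracle, monotonicity, determinism."""

import io as _io

import numpy as np
import pandas as pd
import pytest

from adatscan.codon_analysis import BiasScore
from adatscan.errors import ConfigurationError, NoOverlapError
from adatscan.funnel import (
    FunnelConfig,
    evaluate_overexpression,
    funnel_report,
    run_funnel,
)
from adatscan.simulate import simulate_bundle
from adatscan.translation import TranslationRecord, translation_efficiency
from adatscan.codon_analysis import aggregate_usage, bias_score, build_adat_codon_model


def _te_record(gene, concordant, te_oe=1.0):
    s = 1.0 if concordant else -1.0
    return TranslationRecord(
        gene_id=gene,
        te_by_condition={c: 1.0 for c in ("control_oe", "adat2_oe", "control_ko", "adat2_ko")},
        log2fc_te_oe=te_oe if concordant else s * te_oe,
        log2fc_te_ko=-1.0 * s,
        log2fc_ribo_oe=1.0 * s,
        log2fc_ribo_ko=-1.0 * s,
        concordant=concordant,
    )


@pytest.fixture()
def toy():
    """Ten genes with evidence fixed by construction: 4 concordant; of those,
    2 pass bias 1.5; of those, 1 overexpressed."""
    concordant = {"g01", "g02", "g03", "g04"}
    folds = {"g01": 2.5, "g02": 1.8, "g03": 1.2, "g04": 0.9,
             "g05": 3.0, "g06": 1.6, "g07": 1.0, "g08": 0.5, "g09": 2.0, "g10": 1.1}
    over = {"g01", "g05", "g07"}
    te = [_te_record(g, g in concordant) for g in sorted(folds)]
    bias = [BiasScore(g, folds[g] * 0.15, 0.15, folds[g]) for g in sorted(folds)]
    tumor = pd.DataFrame(
        {"gene_id": sorted(folds), "overexpressed": [g in over for g in sorted(folds)]}
    )
    return te, bias, tumor, concordant, folds, over


class TestToyOracle:
    def test_stage_sizes_match_brute_force(self, toy):
        te, bias, tumor, concordant, folds, over = toy
        result = run_funnel(te, bias, tumor, FunnelConfig())
        # brute-force application of the three predicates
        s1 = {g for g in folds if g in concordant}
        s2 = {g for g in s1 if folds[g] > 1.5}
        s3 = {g for g in s2 if g in over}
        assert set(result.stage1_genes) == s1 and len(s1) == 4
        assert set(result.stage2_genes) == s2 and len(s2) == 2
        assert set(result.stage3_genes) == s3 and len(s3) == 1
        assert result.ranked_candidates == sorted(s3)

    def test_nesting_invariant(self, toy):
        te, bias, tumor, *_ = toy
        r = run_funnel(te, bias, tumor, FunnelConfig())
        assert set(r.stage3_genes) <= set(r.stage2_genes) <= set(r.stage1_genes)
        assert sorted(r.ranked_candidates) == sorted(r.stage3_genes)

    def test_zero_threshold_makes_stage2_equal_stage1(self, toy):
        te, bias, tumor, *_ = toy
        r = run_funnel(te, bias, tumor, FunnelConfig(bias_threshold=0.0))
        assert set(r.stage2_genes) == set(r.stage1_genes)

    def test_no_tumor_table_flags_and_passes_through(self, toy):
        te, bias, *_ = toy
        r = run_funnel(te, bias, None, FunnelConfig())
        assert not r.tumor_filter_applied
        assert r.stage3_genes == r.stage2_genes

    def test_byte_identical_report_across_runs(self, toy):
        te, bias, tumor, *_ = toy
        outs = []
        for _ in range(2):
            _, df = funnel_report(run_funnel(te, bias, tumor, FunnelConfig()))
            buf = _io.StringIO()
            df.to_csv(buf, sep="\t", index=False)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_report_counts_and_row_conservation(self, toy):
        te, bias, tumor, *_ = toy
        text, df = funnel_report(run_funnel(te, bias, tumor, FunnelConfig()))
        assert len(df) == 10
        assert ": 4" in text and ": 2" in text and ": 1" in text

    def test_missing_bias_score_excluded_with_reason(self, toy):
        te, bias, tumor, *_ = toy
        bias = [b for b in bias if b.gene_id != "g01"]
        r = run_funnel(te, bias, tumor, FunnelConfig())
        assert "g01" in r.exclusions
        assert "g01" not in r.stage2_genes and "g01" in r.stage1_genes


class TestMonotonicity:
    def test_raising_threshold_shrinks_stage2(self, toy):
        te, bias, tumor, *_ = toy
        sizes = []
        for thr in np.linspace(1.0, 2.0, 6):
            r = run_funnel(te, bias, tumor, FunnelConfig(bias_threshold=float(thr)))
            sizes.append(len(r.stage2_genes))
        assert sizes == sorted(sizes, reverse=True)

    def test_tumor_filter_never_grows_stage3(self, toy):
        te, bias, tumor, *_ = toy
        without = run_funnel(te, bias, None, FunnelConfig())
        with_t = run_funnel(te, bias, tumor, FunnelConfig())
        assert set(with_t.stage3_genes) <= set(without.stage3_genes)


class TestEmptyAndErrors:
    def test_empty_stage1_report(self):
        te = [_te_record(f"g{i}", False) for i in range(5)]
        bias = [BiasScore(f"g{i}", 0.1, 0.1, 1.0) for i in range(5)]
        r = run_funnel(te, bias, None, FunnelConfig())
        text, df = funnel_report(r)
        assert r.stage_sizes == (0, 0, 0)
        assert len(df) == 5 and "(none)" in text

    def test_no_overlap_raises(self):
        te = [_te_record("g1", True)]
        bias = [BiasScore("other", 0.1, 0.1, 1.0)]
        with pytest.raises(NoOverlapError):
            run_funnel(te, bias, None, FunnelConfig())

    def test_bad_config(self):
        with pytest.raises(ConfigurationError):
            FunnelConfig(ranking_key="alphabetical")
        with pytest.raises(ConfigurationError):
            FunnelConfig(codon_subset=frozenset({"AAA"}))


class TestOverexpression:
    def test_rank_sum_path_calls_planted_genes(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(50)]
        base = rng.lognormal(3, 1, 50)
        up = np.array([i < 5 for i in range(50)])
        tumor = base[:, None] * np.exp2(2.0 * up[:, None] + rng.normal(0, 0.4, (50, 10)))
        normal = base[:, None] * np.exp2(rng.normal(0, 0.4, (50, 10)))
        df = pd.DataFrame({"gene_id": genes})
        for j in range(10):
            df[f"tumor_{j+1}"] = tumor[:, j]
        for j in range(10):
            df[f"normal_{j+1}"] = normal[:, j]
        calls = evaluate_overexpression(df, alpha=0.05)
        assert calls.loc[[f"g{i}" for i in range(5)], "overexpressed"].all()
        assert calls["overexpressed"].sum() <= 8  # essentially only the planted genes

    def test_mean_columns_direction_only(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b"], "mean_tumor": [10.0, 1.0], "mean_normal": [5.0, 2.0]}
        )
        calls = evaluate_overexpression(df)
        assert calls.loc["a", "overexpressed"] and not calls.loc["b", "overexpressed"]


def test_planted_target_gene_reaches_stage3_and_ranks_first():
    """A single planted responder (high dependent-codon usage, planted TE
    response and tumor overexpression) among 500 genes survives all three
    filters and tops the ranking — the screen's HDAC7-recovery behaviour.

    Stage 3 relies on a BH-adjusted rank-sum test with a single true positive
    among 500 hypotheses, so an occasional seed can miss the q cutoff; the
    property is asserted over five seeds (>= 4/5 full recoveries, and the
    planted gene ranks first whenever it reaches stage 3)."""
    model = build_adat_codon_model({"TCC", "CTC", "CGC"})
    hits = 0
    for seed in (40, 41, 42, 43, 44):
        b = simulate_bundle(seed=seed, n_genes=500, n_responders=1)
        te = translation_efficiency(b.rna, b.ribo)
        bg = aggregate_usage(b.cds)
        scores = [bias_score(s, bg, model) for s in b.cds]
        r = run_funnel(te, scores, b.tumor, FunnelConfig())
        (planted,) = b.truth.planted_responders
        if planted in r.stage3_genes:
            assert r.ranked_candidates[0] == planted
            hits += 1
    assert hits >= 4
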