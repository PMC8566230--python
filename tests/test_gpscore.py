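"""Gene prognostic calls, GPScore, null calibration, and sample-level scores."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from nbgf.gpscore import (
    GenePrognosis,
    gene_prognosis,
    gpscore,
    null_calibration,
    prognosis_scan,
    sample_set_score,
    score_significance,
    shared_sets,
)
from nbgf.matrix import normalize_fold_from_mean
from nbgf.simulate import SyntheticConfig, generate_cohort
from nbgf.stats import logrank_test

from conftest import gpscore_cohort_config, toy_clinical, toy_expression


def _make_prognoses(n_unfav, n_fav, n_ns, prefix="g"):
    out = {}
    i = 0
    for direction, count in (
        ("unfavorable", n_unfav),
        ("favorable", n_fav),
        ("ns", n_ns),
    ):
        for _ in range(count):
            p = 1e-6 if direction != "ns" else 0.5
            out[f"{prefix}{i}"] = GenePrognosis(f"{prefix}{i}", direction, p, p * 100)
            i += 1
    return out


class TestGenePrognosis:
    def test_planted_hazard_genes_called_with_correct_direction(self):
        cfg = gpscore_cohort_config(seed=42)
        expr, clinical, truth = generate_cohort(cfg)
        prognoses = prognosis_scan(expr, clinical)
        unfav = [g for g, b in truth.prognostic_betas.items() if b > 0]
        fav = [g for g, b in truth.prognostic_betas.items() if b < 0]
        assert sum(prognoses[g].direction == "unfavorable" for g in unfav) >= 16
        assert sum(prognoses[g].direction == "favorable" for g in fav) >= 16

    def test_null_gene_ns_under_heavy_correction(self):
        hits = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                n_samples=100, n_genes=5, de_genes_per_cluster=0, seed=300 + seed
            )
            expr, clinical, _ = generate_cohort(cfg)
            gp = gene_prognosis(expr, clinical, expr.gene_ids[0], n_tests=1000)
            hits += int(gp.direction != "ns")
        assert hits == 0

    def test_constant_gene_warns_ns(self):
        m = toy_expression(np.ones((25, 2)))
        clin = toy_clinical(
            times=np.arange(1, 26, dtype=float), events=[True] * 25,
            index=list(m.data.index),
        )
        with pytest.warns(UserWarning, match="constant"):
            gp = gene_prognosis(m, clin, "g0", n_tests=10)
        assert gp.direction == "ns"

    def test_scan_mode_applies_extra_bonferroni(self):
        cfg = gpscore_cohort_config(seed=7)
        expr, clinical, truth = generate_cohort(cfg)
        gene = next(g for g, b in truth.prognostic_betas.items() if b > 0)
        med = gene_prognosis(expr, clinical, gene, n_tests=200, cutoff="median")
        scan = gene_prognosis(expr, clinical, gene, n_tests=200, cutoff="scan")
        assert scan.p <= med.p  # scan picks the best cutoff
        assert scan.p_adj >= scan.p * 200 * 9 - 1e-12 or scan.p_adj == 1.0

    def test_too_few_samples_rejected(self):
        m = toy_expression(np.ones((5, 1)))
        clin = toy_clinical([1] * 5, [True] * 5, index=list(m.data.index))
        with pytest.raises(ValueError, match="20 samples"):
            gene_prognosis(m, clin, "g0", n_tests=1)


class TestGPScore:
    def test_three_to_one_gives_three_quarters(self):
        prognoses = _make_prognoses(3, 1, 2)
        rec = gpscore([f"g{i}" for i in range(6)], prognoses)
        assert (rec.nu, rec.nf) == (3, 1)
        assert rec.score == pytest.approx(0.75)

    def test_all_unfavorable_scores_one(self):
        rec = gpscore(["g0", "g1"], _make_prognoses(2, 0, 0))
        assert rec.score == 1.0

    def test_balanced_set_scores_half(self):
        rec = gpscore(["g0", "g1", "g2", "g3"], _make_prognoses(2, 2, 0))
        assert rec.score == 0.5

    def test_no_prognostic_genes_flagged(self):
        with pytest.warns(UserWarning, match="no prognostic genes"):
            rec = gpscore(["g0"], _make_prognoses(0, 0, 1))
        assert rec.score is None

    def test_direction_flip_complements_score(self):
        prognoses = _make_prognoses(3, 2, 1)
        flipped = {
            g: GenePrognosis(
                g,
                {"unfavorable": "favorable", "favorable": "unfavorable"}.get(
                    gp.direction, "ns"
                ),
                gp.p,
                gp.p_adj,
            )
            for g, gp in prognoses.items()
        }
        genes = list(prognoses)
        assert gpscore(genes, prognoses).score == pytest.approx(
            1 - gpscore(genes, flipped).score
        )


class TestNullCalibration:
    def test_seeded_draws_are_reproducible(self):
        prognoses = _make_prognoses(30, 20, 100)
        a = null_calibration(prognoses, n_random=10, size_range=(10, 40), seed=5)
        b = null_calibration(prognoses, n_random=10, size_range=(10, 40), seed=5)
        assert np.array_equal(a.scores, b.scores)

    def test_mean_tracks_global_unfavorable_fraction(self):
        prognoses = _make_prognoses(60, 40, 200)
        means = [
            null_calibration(prognoses, n_random=20, size_range=(30, 90), seed=s).mean
            for s in range(50)
        ]
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - 0.6) < 3 * se + 0.01

    def test_all_unfavorable_degenerate(self):
        prognoses = _make_prognoses(50, 0, 0)
        null = null_calibration(prognoses, n_random=5, size_range=(5, 20), seed=1)
        assert null.mean == 1.0
        assert null.sd == 0.0

    def test_size_range_beyond_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            null_calibration(_make_prognoses(5, 5, 5), size_range=(5, 100), seed=0)


class TestScoreSignificance:
    def test_null_scoring_set_not_significant(self):
        scores = pd.DataFrame(
            {"d1": [0.52], "d2": [0.48], "d3": [0.51]}, index=["SET"]
        )
        nulls = pd.Series({"d1": 0.50, "d2": 0.49, "d3": 0.52})
        out = score_significance(scores, nulls)
        assert out.loc["SET", "q"] > 0.4
        assert not out.loc["SET", "significant"]

    def test_planted_high_scoring_set_significant(self):
        rng = np.random.default_rng(0)
        idx = [f"S{i}" for i in range(10)]
        null_level = pd.Series({"d1": 0.5, "d2": 0.5, "d3": 0.5})
        data = {d: rng.normal(0.5, 0.02, 10) for d in null_level.index}
        scores = pd.DataFrame(data, index=idx)
        scores.loc["S0"] = [0.95, 0.93, 0.96]
        out = score_significance(scores, null_level)
        assert out.loc["S0", "q"] < 0.01
        assert out.loc["S0", "significant"]

    def test_single_dataset_rejected(self):
        scores = pd.DataFrame({"d1": [0.5]}, index=["S"])
        with pytest.raises(ValueError, match="2 datasets"):
            score_significance(scores, pd.Series({"d1": 0.5}))


class TestSharedSets:
    def test_set_shared_by_all_genes_counted(self):
        shared, pairwise = shared_sets(
            {"EPOR": ["A"], "KIT": ["A"], "MET": ["A"]}, k_min=2
        )
        assert shared.loc[0, "set_name"] == "A"
        assert shared.loc[0, "n_genes"] == 3
        assert (pairwise["n_shared"] == 1).all()

    def test_disjoint_enrichments_empty(self):
        shared, _ = shared_sets({"a": ["X"], "b": ["Y"]}, k_min=2)
        assert shared.empty

    def test_pairwise_counts_match_intersections(self):
        enriched = {
            "g1": ["A", "B", "C"],
            "g2": ["B", "C", "D"],
            "g3": ["C", "D", "E"],
        }
        _, pairwise = shared_sets(enriched, k_min=1)
        lookup = {
            (r["gene_a"], r["gene_b"]): r["n_shared"] for _, r in pairwise.iterrows()
        }
        for (a, b), n in lookup.items():
            assert n == len(set(enriched[a]) & set(enriched[b]))


class TestSampleSetScore:
    def test_mean_squared_expression(self):
        raw = toy_expression(np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 2.0]]))
        folded = normalize_fold_from_mean(raw)
        scores, _, _ = sample_set_score(folded, ["g0", "g1"])
        # first sample has fold values (2, 0): mean squared = (4 + 0) / 2
        assert scores.iloc[0] == pytest.approx(2.0)

    def test_identical_samples_flagged_degenerate(self):
        m = toy_expression(np.ones((8, 3)), norm_state="fold_from_mean")
        with pytest.warns(UserWarning, match="degenerate"):
            _, _, degenerate = sample_set_score(m, ["g0", "g1"])
        assert degenerate

    def test_empty_overlap_rejected(self):
        m = toy_expression(np.ones((4, 2)), norm_state="fold_from_mean")
        with pytest.raises(ValueError, match="no overlap"):
            sample_set_score(m, ["nope"])

    def test_quartile_q1_has_worst_survival(self):
        cfg = replace(gpscore_cohort_config(seed=77), n_samples=400)
        expr, clinical, truth = generate_cohort(cfg)
        folded = normalize_fold_from_mean(expr)
        risk_set = [g for g, b in truth.prognostic_betas.items() if b > 0]
        scores, quartiles, degenerate = sample_set_score(folded, risk_set)
        assert not degenerate
        t = clinical.df["os_time"]
        e = clinical.df["os_event"]
        q1 = quartiles == "Q1"
        q4 = quartiles == "Q4"
        res = logrank_test(t[q1], e[q1], t[q4], e[q4])
        assert res.p < 0.01
        assert res.direction > 0  # Q1 (highest scores) dies first
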