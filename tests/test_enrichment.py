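"""Ranking construction and enrichment metrics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from brnib import MetricReport, auc, bedroc, efd, make_ranking, metric_report, roc_curve
from brnib.enrichment import Ranking, write_roc_curve
from brnib.errors import UndefinedMetricError


def table_from(scores, labels, skipped=None):
    n = len(scores)
    skipped = skipped or [False] * n
    return pd.DataFrame(
        {
            "compound_id": [f"c{i}" for i in range(n)],
            "label": labels,
            "skipped": skipped,
            "shape": scores,
            "esp": scores,
            "combined": scores,
            "best_pose_index": [0] * n,
        }
    )


def ranking_from_labels(label_seq):
    """Ranking directly from a top-to-bottom label sequence ('a' or 'd')."""
    return Ranking(
        compound_ids=tuple(f"c{i}" for i in range(len(label_seq))),
        is_active=np.array([c == "a" for c in label_seq]),
        n_scored=len(label_seq),
        seed=0,
    )


def brute_force_auc(ranking):
    """Pair-counting definition, O(n^2)."""
    labels = ranking.is_active
    wins = total = 0
    for i, ai in enumerate(labels):
        if not ai:
            continue
        for j, dj in enumerate(labels):
            if dj:
                continue
            total += 1
            wins += i < j
    return wins / total


# ---------------------------------------------------------------------------
# make_ranking

def test_ranking_is_stable_descending(small_fixture):
    from brnib import score_library

    table = score_library(small_fixture.model, small_fixture.library, small_fixture.labels)
    ranking = make_ranking(table, seed=0)
    scores = table.set_index("compound_id").loc[list(ranking.compound_ids)].combined
    assert (np.diff(scores.to_numpy()) <= 1e-15).all()


def test_tied_scores_keep_input_order():
    table = table_from([0.5, 0.5, 0.9], ["active", "decoy", "decoy"])
    ranking = make_ranking(table, seed=0)
    assert list(ranking.compound_ids) == ["c2", "c0", "c1"]


def test_skipped_appended_after_scored_and_seed_deterministic():
    scores = [0.9, 0.8, np.nan, np.nan, np.nan, np.nan]
    labels = ["active", "decoy", "active", "decoy", "decoy", "decoy"]
    skipped = [False, False, True, True, True, True]
    r1 = make_ranking(table_from(scores, labels, skipped), seed=5)
    r2 = make_ranking(table_from(scores, labels, skipped), seed=5)
    assert r1.compound_ids == r2.compound_ids
    assert set(r1.compound_ids[:2]) == {"c0", "c1"}
    assert set(r1.compound_ids[2:]) == {"c2", "c3", "c4", "c5"}
    r3 = make_ranking(table_from(scores, labels, skipped), seed=6)
    assert r3.compound_ids[:2] == r1.compound_ids[:2]


# ---------------------------------------------------------------------------
# AUC

def test_perfect_separation_auc_one():
    a, se = auc(ranking_from_labels("aaddd"))
    assert a == 1.0
    assert se == 0.0


def test_auc_interleaved_example():
    a, _ = auc(ranking_from_labels("adad"))
    assert a == pytest.approx(0.75)


@pytest.mark.parametrize("seed", range(6))
def test_auc_matches_pair_counting_on_random_rankings(seed):
    rng = np.random.default_rng(seed)
    labels = "".join(rng.choice(list("ad"), size=50, p=[0.2, 0.8]))
    if "a" not in labels or "d" not in labels:
        pytest.skip("degenerate draw")
    ranking = ranking_from_labels(labels)
    assert auc(ranking)[0] == pytest.approx(brute_force_auc(ranking), abs=1e-12)


def test_label_inversion_mirrors_auc():
    rng = np.random.default_rng(10)
    labels = "".join(rng.choice(list("ad"), size=40))
    swapped = labels.translate(str.maketrans("ad", "da"))
    assert auc(ranking_from_labels(labels))[0] == pytest.approx(
        1.0 - auc(ranking_from_labels(swapped))[0]
    )


def test_auc_standard_error_hanley_mcneil():
    ranking = ranking_from_labels("adadad")
    a, se = auc(ranking)
    q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
    n_a = n_d = 3
    expected = math.sqrt(
        (a * (1 - a) + (n_a - 1) * (q1 - a * a) + (n_d - 1) * (q2 - a * a)) / (n_a * n_d)
    )
    assert se == pytest.approx(expected)


def test_single_class_auc_undefined():
    with pytest.raises(UndefinedMetricError):
        auc(ranking_from_labels("aaa"))


# ---------------------------------------------------------------------------
# EFd

def test_perfect_and_worst_efd():
    assert efd(ranking_from_labels("aaaddd"), 0.01) == 100.0
    assert efd(ranking_from_labels("dddaaa"), 1.0) == 0.0


def test_efd_counts_actives_strictly_before_threshold_decoy():
    # 10 actives, 1000 decoys; 4 actives precede the 10th decoy
    labels = "ad" * 4 + "d" * 6 + "aaaaaa" + "d" * 990
    ranking = ranking_from_labels(labels)
    assert ranking.n_actives == 10 and ranking.n_decoys == 1000
    assert efd(ranking, 0.01) == pytest.approx(40.0)


def test_efd_monotone_in_fraction():
    rng = np.random.default_rng(2)
    labels = "".join(rng.choice(list("ad"), size=200, p=[0.1, 0.9]))
    ranking = ranking_from_labels(labels)
    values = [efd(ranking, f) for f in (0.001, 0.01, 0.05, 0.2, 1.0)]
    assert values == sorted(values)


# ---------------------------------------------------------------------------
# BEDROC

def truchon_bailey(label_seq, alpha):
    """Independent direct evaluation of the closed form."""
    big_n = len(label_seq)
    ranks = [i + 1 for i, c in enumerate(label_seq) if c == "a"]
    n = len(ranks)
    ra = n / big_n
    rie = sum(math.exp(-alpha * r / big_n) for r in ranks) / (
        n / big_n * (1 - math.exp(-alpha)) / (math.exp(alpha / big_n) - 1)
    )
    return rie * ra * math.sinh(alpha / 2) / (
        math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra)
    ) + 1 / (1 - math.exp(alpha * (1 - ra)))


def test_bedroc_top_ranked_single_active():
    labels = "a" + "d" * 99
    assert bedroc(ranking_from_labels(labels), 20.0) == pytest.approx(
        truchon_bailey(labels, 20.0), abs=1e-12
    )


@pytest.mark.parametrize("seed", range(4))
def test_bedroc_matches_formula_oracle(seed):
    rng = np.random.default_rng(seed)
    labels = "".join(rng.choice(list("ad"), size=120, p=[0.15, 0.85]))
    assert bedroc(ranking_from_labels(labels), 20.0) == pytest.approx(
        truchon_bailey(labels, 20.0), abs=1e-12
    )


def test_bedroc_worst_ranking_near_zero():
    labels = "d" * 995 + "a" * 5
    assert bedroc(ranking_from_labels(labels), 20.0) < 0.01


def test_bedroc_small_alpha_approaches_auc():
    rng = np.random.default_rng(123)
    labels = "".join(rng.choice(list("ad"), size=10_000, p=[0.05, 0.95]))
    ranking = ranking_from_labels(labels)
    assert abs(bedroc(ranking, 0.1) - auc(ranking)[0]) <= 0.05


def test_bedroc_promoting_an_active_increases_value():
    labels = list("ddadadadd")
    i = labels.index("a")
    swapped = labels.copy()
    swapped[i - 1], swapped[i] = swapped[i], swapped[i - 1]
    assert bedroc(ranking_from_labels("".join(swapped)), 20.0) > bedroc(
        ranking_from_labels("".join(labels)), 20.0
    )


def test_bedroc_invalid_alpha():
    with pytest.raises(ValueError):
        bedroc(ranking_from_labels("ad"), 0.0)


# ---------------------------------------------------------------------------
# ROC curve and report

def test_roc_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(5)
    labels = "".join(rng.choice(list("ad"), size=60))
    curve = roc_curve(ranking_from_labels(labels))
    assert tuple(curve[0]) == (0.0, 0.0)
    assert tuple(curve[-1]) == (1.0, 1.0)
    assert (np.diff(curve[:, 0]) >= 0).all() and (np.diff(curve[:, 1]) >= 0).all()


@pytest.mark.parametrize("seed", range(5))
def test_trapezoid_area_under_roc_equals_auc(seed):
    rng = np.random.default_rng(seed)
    labels = "".join(rng.choice(list("ad"), size=80, p=[0.3, 0.7]))
    ranking = ranking_from_labels(labels)
    curve = roc_curve(ranking)
    area = np.trapezoid(curve[:, 1], curve[:, 0])
    assert area == pytest.approx(auc(ranking)[0], abs=1e-12)


def test_metrics_invariant_to_positive_score_rescaling():
    rng = np.random.default_rng(77)
    scores = rng.uniform(0, 1, size=60)
    labels = list(rng.choice(["active", "decoy"], size=60, p=[0.25, 0.75]))
    r1 = make_ranking(table_from(list(scores), labels), seed=0)
    r2 = make_ranking(table_from(list(scores * 7.3), labels), seed=0)
    assert auc(r1)[0] == auc(r2)[0]
    assert bedroc(r1, 20.0) == bedroc(r2, 20.0)
    assert efd(r1, 0.05) == efd(r2, 0.05)


def test_metric_report_round_trips_and_matches_components():
    rng = np.random.default_rng(9)
    scores = list(rng.uniform(0, 1, size=50))
    labels = list(rng.choice(["active", "decoy"], size=50, p=[0.3, 0.7]))
    table = table_from(scores, labels)
    report = metric_report(table, fractions=(0.01, 0.05), alphas=(20.0,), seed=3)
    ranking = make_ranking(table, seed=3)
    assert report.auc == auc(ranking)[0]
    assert report.efd[0.05] == efd(ranking, 0.05)
    assert report.bedroc[20.0] == bedroc(ranking, 20.0)
    again = MetricReport.from_json(report.to_json())
    assert again == report


def test_roc_tsv_export(tmp_path):
    curve = roc_curve(ranking_from_labels("adadad"))
    path = tmp_path / "roc.tsv"
    write_roc_curve(curve, path)
    back = np.loadtxt(path, skiprows=1)
    assert np.allclose(back, curve)
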