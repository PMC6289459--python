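"""Detection analysis: assignment, matrices, OTU filter, Fisher, concordance."""

import datetime as dt
import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gofish.detect import (
    CONFIRMED,
    NONTARGET,
    DetectionMatrix,
    OtuTable,
    QueryRecord,
    assign_species,
    build_detection_matrix,
    compare_seasons,
    concordance,
    filter_otu_detections,
    fisher_exact_2x2,
    meteorological_season,
)
from gofish.iupac import revcomp
from helpers import detection_matrix_from_bools, fisher_oracle
from gofish.refpanel import ReferencePanel, ReferenceSequence


@pytest.fixture
def small_panel():
    return ReferencePanel(
        [
            ReferenceSequence(id="A", taxon="Alpha one", sequence="AAAACGTACGTACGTAAGGCCTT"),
            ReferenceSequence(id="B", taxon="Beta two", sequence="TTTTGCAGCAGCAGCAATTGGCC"),
            # two references sharing an identical segment (menhaden scenario)
            ReferenceSequence(id="C1", taxon="Gamma three", sequence="GGGGCCCCAAAATTTTGGGGCCCC"),
            ReferenceSequence(id="C2", taxon="Gamma four", sequence="GGGGCCCCAAAATTTTGGGGCCCC"),
        ]
    )


def test_assign_exact_substring(small_panel):
    assert assign_species("ACGTACGTACGT", small_panel) == {"Alpha one"}


def test_assign_is_revcomp_invariant(small_panel):
    q = "ACGTACGTACGT"
    assert assign_species(q, small_panel) == assign_species(revcomp(q), small_panel)


def test_assign_one_mismatch_is_unassigned(small_panel):
    assert assign_species("ACGTACGAACGT", small_panel) == frozenset()


def test_assign_shared_sequence_returns_both_taxa(small_panel):
    assert assign_species("CCCCAAAATTTTGGGG", small_panel) == {
        "Gamma three",
        "Gamma four",
    }


def test_assign_empty_query_rejected(small_panel):
    with pytest.raises(ValueError):
        assign_species("", small_panel)


def _rec(sid, taxon, gel, seq, day=1, site="east"):
    return QueryRecord(
        sample_id=sid,
        date=dt.date(2017, 6, day),
        site=site,
        assay_taxon=taxon,
        gel_positive=gel,
        sequence=seq,
    )


def test_build_detection_matrix_rules(small_panel):
    records = [
        _rec("s1", "Alpha one", True, "ACGTACGTACGT"),
        _rec("s1", "Beta two", False, None),
        _rec("s2", "Alpha one", False, None, day=8),
        # gel-positive but the sequence belongs to another taxon
        _rec("s2", "Beta two", True, "ACGTACGTACGT", day=8),
    ]
    m = build_detection_matrix(records, small_panel)
    assert bool(m.values.loc["s1", "Alpha one"]) is True
    assert m.provenance.loc["s1", "Alpha one"] == CONFIRMED
    assert bool(m.values.loc["s2", "Beta two"]) is False
    assert m.provenance.loc["s2", "Beta two"] == NONTARGET
    # per-date species counts equal column sums over the grid
    assert m.counts_by_sample().sum() == m.n_detections


def test_conflicting_duplicate_records_rejected(small_panel):
    records = [
        _rec("s1", "Alpha one", True, "ACGTACGTACGT"),
        _rec("s1", "Alpha one", False, None),
    ]
    with pytest.raises(ValueError, match="conflicting"):
        build_detection_matrix(records, small_panel)


def test_otu_filter_boundary_and_identity():
    counts = pd.DataFrame(
        {"s1": [9, 10, 500], "s2": [9991, 9990, 500]},
        index=["otu1", "otu2", "otu3"],
    )
    t = OtuTable(counts)
    f = filter_otu_detections(t, threshold=0.001)
    # otu1 total 10000: 9 reads is < 0.1% -> zeroed
    assert f.counts.loc["otu1", "s1"] == 0
    # otu2 total 10000: 10 reads is exactly 0.1% -> retained
    assert f.counts.loc["otu2", "s1"] == 10
    # all counts at/above threshold -> row unchanged
    assert (f.counts.loc["otu3"] == counts.loc["otu3"]).all()


def test_otu_filter_is_idempotent():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(
        rng.integers(0, 5000, size=(12, 8)),
        index=[f"otu{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(8)],
    )
    once = filter_otu_detections(OtuTable(counts))
    twice = filter_otu_detections(once)
    assert (once.counts == twice.counts).all().all()


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        OtuTable(pd.DataFrame({"s": [-1]}, index=["o"]))


def test_fisher_modal_and_empty_tables():
    assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)
    assert fisher_exact_2x2(0, 0, 0, 0) == 1.0
    with pytest.raises(ValueError):
        fisher_exact_2x2(-1, 0, 0, 0)


def test_fisher_matches_enumeration_for_all_small_margins():
    # every table with all margins <= 12 (cells 0..6)
    for a, b, c, d in itertools.product(range(7), repeat=4):
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12
        ), (a, b, c, d)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 25)] * 4))
def test_fisher_matches_enumeration_on_random_tables(table):
    assert fisher_exact_2x2(*table) == pytest.approx(
        fisher_oracle(*table), rel=1e-6, abs=1e-12
    )


def test_compare_seasons_recovers_planted_skew():
    # 20 spring and 20 summer samples, one taxon: 5 spring vs 15 summer positives
    idx = [f"s{i}" for i in range(40)]
    dates = [dt.date(2017, 4, 2) + dt.timedelta(days=3 * i) for i in range(40)]
    seasons = [meteorological_season(d) for d in dates]
    pos = set()
    spring_ids = [i for i, s in enumerate(seasons) if s == "spring"]
    summer_ids = [i for i, s in enumerate(seasons) if s == "summer"]
    pos.update(spring_ids[:5])
    pos.update(summer_ids[:15])
    values = pd.DataFrame({"Taxon x": [i in pos for i in range(40)]}, index=idx)
    m = detection_matrix_from_bools(values, dates=dates)
    cmp_ = compare_seasons(m, ("spring", "summer"))
    a, b, c, d = cmp_.table
    assert (a, c) == (5, 15)
    assert cmp_.positive_share["summer"] == pytest.approx(0.75)
    assert cmp_.p_value == pytest.approx(fisher_exact_2x2(a, b, c, d))


def test_compare_seasons_exclusion_removes_exactly_that_taxon():
    idx = [f"s{i}" for i in range(10)]
    dates = [dt.date(2017, 4, 2) + dt.timedelta(days=20 * i) for i in range(10)]
    values = pd.DataFrame(
        {"keep": [True] * 10, "drop": [True] * 10}, index=idx
    )
    m = detection_matrix_from_bools(values, dates=dates)
    both = compare_seasons(m, ("spring", "summer"))
    one = compare_seasons(m, ("spring", "summer"), exclude=("drop",))
    assert sum(both.table) == 2 * sum(one.table)


def test_compare_seasons_empty_season_rejected():
    idx = ["s0", "s1"]
    dates = [dt.date(2017, 7, 1), dt.date(2017, 7, 8)]  # summer only
    values = pd.DataFrame({"t": [True, False]}, index=idx)
    m = detection_matrix_from_bools(values, dates=dates)
    with pytest.raises(ValueError, match="spring"):
        compare_seasons(m, ("spring", "summer"))


def test_concordance_identical_matrices():
    values = pd.DataFrame(
        {"t1": [True, False, True], "t2": [False, False, True]},
        index=["s1", "s2", "s3"],
    )
    m = detection_matrix_from_bools(values)
    rep = concordance(m, m)
    assert rep.sensitivity_a == rep.sensitivity_b == 1.0
    assert rep.a_only == rep.b_only == 0


def test_concordance_disjoint_matrices():
    va = pd.DataFrame({"t": [True, False]}, index=["s1", "s2"])
    vb = pd.DataFrame({"t": [False, True]}, index=["s1", "s2"])
    rep = concordance(detection_matrix_from_bools(va), detection_matrix_from_bools(vb))
    assert rep.shared == 0
    assert rep.union == 2
    assert rep.sensitivity_a == pytest.approx(0.5)
    assert rep.sensitivity_b == pytest.approx(0.5)


def test_concordance_conservation_and_grid_mismatch():
    rng = np.random.default_rng(11)
    idx = [f"s{i}" for i in range(20)]
    cols = [f"t{j}" for j in range(5)]
    va = pd.DataFrame(rng.random((20, 5)) < 0.4, index=idx, columns=cols)
    vb = pd.DataFrame(rng.random((20, 5)) < 0.4, index=idx, columns=cols)
    rep = concordance(detection_matrix_from_bools(va), detection_matrix_from_bools(vb))
    assert rep.shared + rep.a_only + rep.b_only == rep.union
    assert rep.n_a == rep.shared + rep.a_only
    assert rep.n_b == rep.shared + rep.b_only
    assert 0 <= rep.sensitivity_a <= 1 and 0 <= rep.sensitivity_b <= 1

    vc = va.iloc[:, :4]
    with pytest.raises(ValueError, match="symmetric difference"):
        concordance(detection_matrix_from_bools(va), detection_matrix_from_bools(vc))


def test_concordance_read_bin_stratification():
    idx = ["s1", "s2", "s3"]
    va = pd.DataFrame({"t": [True, False, False]}, index=idx)
    vb = pd.DataFrame({"t": [True, True, True]}, index=idx)
    reads = pd.DataFrame({"t": [150, 5000, 20000]}, index=idx)
    rep = concordance(
        detection_matrix_from_bools(va), detection_matrix_from_bools(vb), reads=reads
    )
    assert rep.read_bins == {
        "0.1K": {"a_positive": 1, "a_negative": 0},
        "1K": {"a_positive": 0, "a_negative": 1},
        "10K": {"a_positive": 0, "a_negative": 1},
    }
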