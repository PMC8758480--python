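import logging
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from splicecons.setstats import (
    compare_sets,
    conservation_rate,
    fisher_exact_2x2,
    patristic_distances,
)


def enumeration_oracle(table):
    """Exhaustive two-sided Fisher p over all tables with the same margins,
    in exact rational arithmetic (fully independent of the implementation)."""
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    probs = {
        x: Fraction(math.comb(n1, x) * math.comb(n2, k - x), math.comb(n1 + n2, k))
        for x in range(max(0, k - n2), min(k, n1) + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def test_balanced_table_has_p_one():
    assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0


def test_perfect_association_matches_closed_form():
    assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
        2 / math.comb(20, 10), abs=1e-15
    )


def test_unbalanced_margins_match_enumeration_oracle():
    table = [[3, 7], [50, 50]]
    assert fisher_exact_2x2(table) == pytest.approx(
        enumeration_oracle(table), abs=1e-12
    )


def test_zero_margin_rejected():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[0, 0], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact_2x2([[-1, 2], [3, 4]])


@given(
    entries=st.tuples(*[st.integers(min_value=0, max_value=15)] * 4)
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_fisher_agrees_with_oracle_and_scipy(entries):
    a, b, c, d = entries
    table = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        return
    p = fisher_exact_2x2(table)
    assert 0 < p <= 1
    assert p == pytest.approx(enumeration_oracle(table), abs=1e-12)
    assert p == pytest.approx(scipy.stats.fisher_exact(table)[1], abs=1e-7)


def test_patristic_distances_sum_branch_lengths():
    d = patristic_distances("(A:1.0,(B:2.0,hg:3.0):4.0);", "hg")
    assert d == pytest.approx({"hg": 0.0, "B": 5.0, "A": 8.0})
    with pytest.raises(ValueError, match="reference"):
        patristic_distances("(A:1,B:2);", "hg")


def _toy_table():
    rows = []
    for i in range(10):
        rows.append(
            {
                "transcript_id": f"t{i}",
                "species": "mm10",
                "n_sites": 4,
                "n_conserved": 4 if i < 7 else 1,
                "n_alignable": 4,
                "fraction_conserved": 1.0 if i < 7 else 0.25,
                "fraction_alignable": 1.0,
                "present": True,
                "complete": i < 7,
                "frac_ge_0.5": i < 7,
            }
        )
    return pd.DataFrame(rows)


def test_conservation_rate_counts_level_attainment():
    k, n, rate = conservation_rate(_toy_table(), [f"t{i}" for i in range(10)],
                                   "mm10", "complete")
    assert (k, n, rate) == (7, 10, 0.7)


def test_conservation_rate_missing_ids_listed():
    with pytest.raises(ValueError, match="tX"):
        conservation_rate(_toy_table(), ["t0", "tX"], "mm10", "complete")
    with pytest.raises(ValueError, match="empty"):
        conservation_rate(_toy_table(), [], "mm10", "complete")


def test_conditioned_mode_drops_poorly_alignable_transcripts():
    table = _toy_table()
    table.loc[table["transcript_id"] == "t0", "fraction_alignable"] = 0.25
    k, n, _ = conservation_rate(
        table, [f"t{i}" for i in range(10)], "mm10", "complete", mode="conditioned"
    )
    assert n == 9 and k == 6


def _sim_table_and_tree():
    rng = np.random.default_rng(5)
    tree = "(hg:0.0,near:0.2,far:1.0);"
    rows = []
    for sp, p in (("near", 0.8), ("far", 0.3)):
        for i in range(120):
            tid = f"g{i}"
            complete = bool(rng.random() < p)
            rows.append(
                {
                    "transcript_id": tid, "species": sp, "n_sites": 4,
                    "n_conserved": 4 if complete else 2, "n_alignable": 4,
                    "fraction_conserved": 1.0 if complete else 0.5,
                    "fraction_alignable": 1.0, "present": True,
                    "complete": complete, "frac_ge_0.5": True,
                }
            )
    return pd.DataFrame(rows), tree


def test_compare_sets_orders_species_by_distance():
    table, tree = _sim_table_and_tree()
    target = [f"g{i}" for i in range(30)]
    background = [f"g{i}" for i in range(30, 120)]
    rates, comp = compare_sets(table, target, background, tree, "hg")
    assert list(comp[comp["level"] == "complete"]["species"]) == ["near", "far"]
    assert (comp["p"] > 0).all() and (comp["p"] <= 1).all()
    assert set(rates["set"]) == {"target", "background"}


def test_compare_sets_removes_overlap_with_warning(caplog):
    table, tree = _sim_table_and_tree()
    target = [f"g{i}" for i in range(30)]
    background = [f"g{i}" for i in range(120)]  # includes the whole target
    with caplog.at_level(logging.WARNING):
        rates, comp = compare_sets(table, target, background, tree, "hg")
    assert "removed from background" in caplog.text
    assert (comp["n_background"] == 90).all()


def test_identical_sets_error_after_overlap_removal():
    table, tree = _sim_table_and_tree()
    ids = [f"g{i}" for i in range(120)]
    with pytest.raises(ValueError, match="background set is empty"):
        compare_sets(table, ids, ids, tree, "hg")


def test_species_missing_from_tree_rejected():
    table, _ = _sim_table_and_tree()
    with pytest.raises(ValueError, match="missing from tree"):
        compare_sets(
            table, ["g0"], ["g1", "g2"], "(hg:0.0,near:0.2);", "hg"
        )


def test_rates_monotone_in_level_stringency(small_sim):
    rates = pd.read_csv(small_sim["outdir"] / "rates.tsv", sep="\t")
    pivot = rates.pivot_table(
        index=["species", "set"], columns="level", values="rate"
    )
    assert (pivot["complete"] <= pivot["present"] + 1e-12).all()
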