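"""Conservation-rate curves and per-species target-vs-background tests.

For each species (ordered by patristic distance from the reference
leaf) and each conservation level, the fraction of a transcript set
attaining the level is compared between a target set and a background
set with a two-sided Fisher's exact test, computed independently per
species. Raw p < alpha drives the significance flag; Benjamini-
Hochberg-adjusted p-values across species within a level are reported
alongside.

``fisher_exact_2x2`` sums hypergeometric probabilities over tables at
most as probable as the observed one, in exact integer arithmetic, so
tied tables are handled without floating-point ambiguity.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .conservation import level_column

log = logging.getLogger(__name__)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed
    table. Weights C(n1, x) * C(n2, k - x) are carried as exact
    integers via the standard ratio recurrence, so "as probable as"
    is decided exactly.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(
        not float(x).is_integer() for x in (a, b, c, d)
    ):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1, n2 = a + b, c + d  # row margins
    k, m = a + c, b + d  # column margins
    if min(n1, n2, k, m) == 0:
        raise ValueError("both margins must be positive")
    x_min = max(0, k - n2)
    x_max = min(k, n1)
    # w(x) = C(n1, x) * C(n2, k - x); w(x+1) from w(x) by exact integer ratio
    from math import comb

    w = comb(n1, x_min) * comb(n2, k - x_min)
    weights = [w]
    for x in range(x_min, x_max):
        w = w * (n1 - x) * (k - x) // ((x + 1) * (n2 - k + x + 1))
        weights.append(w)
    w_obs = weights[a - x_min]
    total = sum(weights)
    numer = sum(wi for wi in weights if wi <= w_obs)
    return float(Fraction(numer, total))


def patristic_distances(
    tree: dendropy.Tree | str, reference: str
) -> dict[str, float]:
    """Patristic distance of every leaf from the reference leaf."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if reference not in taxa:
        raise ValueError(f"reference leaf {reference!r} not in tree")
    ref = taxa[reference]
    return {
        label: (0.0 if label == reference else float(pdm.patristic_distance(ref, t)))
        for label, t in taxa.items()
    }


def load_tree(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def conservation_rate(
    table: pd.DataFrame,
    ids: Sequence[str],
    species: str,
    level: str | float,
    mode: str = "strict",
    min_alignable_fraction: float = 0.5,
) -> tuple[int, int, float]:
    """(k, n, rate) of a transcript set attaining a level in one species.

    In mode "conditioned", transcripts with fewer than
    ``min_alignable_fraction`` alignable sites in this species are
    dropped from the denominator (alignment-quality control).
    """
    ids = list(dict.fromkeys(ids))
    if not ids:
        raise ValueError("empty transcript set")
    sub = table[(table["species"] == species)]
    present_ids = set(sub["transcript_id"])
    missing = [i for i in ids if i not in present_ids]
    if missing:
        raise ValueError(
            f"transcript ids absent from conservation table for {species}: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    sub = sub[sub["transcript_id"].isin(ids)]
    if mode == "conditioned":
        sub = sub[sub["fraction_alignable"] >= min_alignable_fraction]
    n = len(sub)
    if n == 0:
        raise ValueError(
            f"no transcripts left in denominator for {species} (mode={mode})"
        )
    k = int(sub[level_column(level)].sum())
    return k, n, k / n


def compare_sets(
    table: pd.DataFrame,
    target_ids: Sequence[str],
    background_ids: Sequence[str],
    tree: dendropy.Tree | str,
    reference: str,
    levels: Sequence[str | float] = ("present", "complete"),
    alpha: float = 0.05,
    mode: str = "strict",
    min_alignable_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rate curves and per-species Fisher comparisons for two sets.

    Returns (rates, comparisons). Species are ordered by patristic
    distance from the reference leaf, ties broken by name. Transcripts
    in both sets are removed from the background with a warning. The
    significance flag follows raw p < alpha; BH-adjusted p-values
    across species within each level are reported alongside.
    """
    target_ids = list(dict.fromkeys(target_ids))
    background_ids = list(dict.fromkeys(background_ids))
    overlap = set(target_ids) & set(background_ids)
    if overlap:
        log.warning(
            "%d transcript(s) in both sets; removed from background", len(overlap)
        )
        background_ids = [i for i in background_ids if i not in overlap]
    if not target_ids:
        raise ValueError("target set is empty")
    if not background_ids:
        raise ValueError("background set is empty (after overlap removal)")

    distances = patristic_distances(tree, reference)
    species = sorted(set(table["species"]))
    missing = [s for s in species if s not in distances]
    if missing:
        raise ValueError(f"species in table missing from tree: {missing}")
    species.sort(key=lambda s: (distances[s], s))

    rate_rows = []
    comp_rows = []
    for level in levels:
        for sp in species:
            k_t, n_t, r_t = conservation_rate(
                table, target_ids, sp, level, mode, min_alignable_fraction
            )
            k_b, n_b, r_b = conservation_rate(
                table, background_ids, sp, level, mode, min_alignable_fraction
            )
            lvl = level_column(level)
            rate_rows.append((sp, distances[sp], lvl, "target", k_t, n_t, r_t))
            rate_rows.append((sp, distances[sp], lvl, "background", k_b, n_b, r_b))
            ctab = [[k_t, n_t - k_t], [k_b, n_b - k_b]]
            if k_t + k_b == 0 or (n_t - k_t) + (n_b - k_b) == 0:
                # single table in the margin-conditioned support
                p = 1.0
            else:
                p = fisher_exact_2x2(ctab)
            comp_rows.append(
                (sp, distances[sp], lvl, k_t, n_t, r_t, k_b, n_b, r_b, p)
            )

    rates = pd.DataFrame(
        rate_rows,
        columns=["species", "distance", "level", "set", "k", "n", "rate"],
    )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=[
            "species", "distance", "level", "k_target", "n_target", "rate_target",
            "k_background", "n_background", "rate_background", "p",
        ],
    )
    comparisons["p_bh"] = np.nan
    for lvl in comparisons["level"].unique():
        mask = comparisons["level"] == lvl
        comparisons.loc[mask, "p_bh"] = multipletests(
            comparisons.loc[mask, "p"].to_numpy(), method="fdr_bh"
        )[1]
    comparisons["significant"] = comparisons["p"] < alpha
    return rates, comparisons


def plot_rate_curves(
    rates: pd.DataFrame,
    comparisons: pd.DataFrame,
    path: str | None = None,
    alpha: float = 0.05,
):
    """Two-panel rate-vs-distance figure (one panel per level).

    Filled markers flag species where the per-species test rejects at
    ``alpha``. Optional; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = list(dict.fromkeys(rates["level"]))
    fig, axes = plt.subplots(1, len(levels), figsize=(6 * len(levels), 4.5),
                             squeeze=False)
    for ax, lvl in zip(axes[0], levels):
        sub = rates[rates["level"] == lvl]
        comp = comparisons[comparisons["level"] == lvl].set_index("species")
        for set_name, color in (("target", "tab:red"), ("background", "tab:gray")):
            s = sub[sub["set"] == set_name].sort_values(["distance", "species"])
            ax.plot(s["distance"], s["rate"], "-", color=color, label=set_name,
                    zorder=1)
            sig = s["species"].map(comp["significant"]).fillna(False).astype(bool)
            ax.scatter(s["distance"][sig], s["rate"][sig], marker="o", color=color,
                       zorder=2)
            ax.scatter(s["distance"][~sig], s["rate"][~sig], marker="o",
                       facecolors="white", edgecolors=color, zorder=2)
        ax.set_xlabel("patristic distance from reference")
        ax.set_ylabel(f"conservation rate ({lvl})")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
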