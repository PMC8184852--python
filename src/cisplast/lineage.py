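"""Phylogenetic origin of cis-acting variants and lineage-rate tests.

Both F1 hybrids share the outgroup parent, so a cis signal detected in only
one hybrid is, by parsimony, a derived variant of the corresponding sister
lineage; a signal shared by both hybrids predates their split or arose in
the outgroup and is left "undetermined".  A gene with a basal and a plastic
cis signal still counts once (the layers may well reflect one mutation).

Rates of derived-variant accumulation are compared across the eight modes
of plasticity evolution with a 2 x 8 homogeneity chi-squared (df = 7), plus
a per-mode 1-df "partial" decomposition: each mode's contribution
sum((O - E)^2 / E) over its two lineage cells, with expected counts from
the lineage marginals.  Modes whose expected count falls below 1 fall back
to an exact binomial test with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .classify import MODES_8


def has_cis(classification: pd.DataFrame) -> pd.Series:
    """True where the gene carries a cis signal in either layer."""
    return (classification["cis_basal_status"] == "cis") | (
        classification["cis_plastic_status"] == "cis"
    )


def assign_origin(class1: pd.DataFrame, class2: pd.DataFrame) -> pd.DataFrame:
    """Parsimony origin of each gene's cis variant from the two hybrids.

    ``class1``/``class2`` are the per-lineage classification tables (from
    ``classify_lineage``) for hybrid1 and hybrid2.  Returns per gene:
    origin in {derived1, derived2, undetermined, none} and the layer that
    carried the signal in the hybrid(s) where it was seen (basal, plastic,
    both, none).
    """
    genes = class1.index.union(class2.index)
    c1 = has_cis(class1).reindex(genes, fill_value=False)
    c2 = has_cis(class2).reindex(genes, fill_value=False)
    origin = np.select(
        [c1 & c2, c1 & ~c2, ~c1 & c2],
        ["undetermined", "derived1", "derived2"],
        default="none",
    )

    def layer_of(cls: pd.DataFrame) -> pd.Series:
        b = (cls["cis_basal_status"] == "cis").reindex(genes, fill_value=False)
        p = (cls["cis_plastic_status"] == "cis").reindex(genes, fill_value=False)
        return pd.Series(
            np.select([b & p, b, p], ["both", "basal", "plastic"], default="none"),
            index=genes,
        )

    l1, l2 = layer_of(class1), layer_of(class2)
    layer = np.select(
        [origin == "derived1", origin == "derived2"],
        [l1, l2],
        default=np.where(
            origin == "undetermined", np.where(l1 == l2, l1, "both"), "none"
        ),
    )
    return pd.DataFrame({"origin": origin, "layer": layer}, index=genes)


def mode_count_table(class1: pd.DataFrame, class2: pd.DataFrame,
                     origin: pd.DataFrame | None = None) -> pd.DataFrame:
    """8 x 2 table of derived cis variants per mode and lineage."""
    if origin is None:
        origin = assign_origin(class1, class2)
    table = pd.DataFrame(0, index=list(MODES_8), columns=["derived1", "derived2"])
    for lin, cls in (("derived1", class1), ("derived2", class2)):
        genes = origin.index[origin["origin"] == lin]
        modes = cls.reindex(genes)["mode"]
        vc = modes[modes.isin(MODES_8)].value_counts()
        table.loc[vc.index, lin] = vc.to_numpy()
    return table


def mode_rate_test(table: pd.DataFrame, method: str = "homogeneity") -> dict:
    """Chi-squared comparison of mode distributions between lineages.

    ``table`` is modes x 2 lineages.  ``method="homogeneity"`` (default) is
    the standard 2 x k homogeneity test, df = k - 1.  ``method="expectation"``
    instead scores only the first lineage's counts against expectations
    derived from the marginal mode distribution (the "expected from the
    other lineage" reading).  The per-mode partial statistics (df = 1) are
    the mode's cells' (O - E)^2 / E contributions; expected counts below 1
    trigger an exact binomial fallback for that mode.
    """
    obs = np.asarray(table, dtype=float)
    k = obs.shape[0]
    total = obs.sum()
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    expected = np.outer(row_tot, col_tot) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        cell = (obs - expected) ** 2 / expected
    cell[~np.isfinite(cell)] = 0.0

    if method == "homogeneity":
        chi2 = float(cell.sum())
    elif method == "expectation":
        chi2 = float(cell[:, 0].sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))

    partial = []
    p1 = col_tot[0] / total if total else np.nan
    for i in range(k):
        row = obs[i]
        e_row = expected[i]
        if row.sum() > 0 and e_row.min() < 1.0:
            warnings.warn(
                f"expected count below 1 for mode {table.index[i]!r}; "
                "using exact binomial",
                RuntimeWarning,
            )
            res = stats.binomtest(int(row[0]), int(row.sum()), p1)
            partial.append((table.index[i], np.nan, res.pvalue))
            continue
        stat_i = float(cell[i].sum())
        partial.append((table.index[i], stat_i, float(stats.chi2.sf(stat_i, 1))))
    partial_df = pd.DataFrame(
        partial, columns=["mode", "chi2", "p"]
    ).set_index("mode")
    return {"chi2": chi2, "df": df, "p": p, "partial": partial_df}


def derived_vs_shared_test(derived_counts, undetermined_counts) -> dict:
    """2 x 2 comparison of derived vs undetermined variants per lineage.

    ``derived_counts``/``undetermined_counts`` are length-2 sequences
    (lineage1, lineage2).  Uses the chi-squared test without continuity
    correction, falling back to Fisher's exact test when any cell is zero.
    """
    table = np.asarray([list(derived_counts), list(undetermined_counts)], dtype=float)
    if (table == 0).any():
        odds, p = stats.fisher_exact(table)
        return {"method": "fisher", "chi2": np.nan, "p": float(p), "odds": float(odds)}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"method": "chi2", "chi2": float(chi2), "p": float(p), "odds": np.nan}
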