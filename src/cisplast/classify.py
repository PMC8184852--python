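"""Evolutionary classification of expression changes.

A gene's interspecific change is classified relative to the plastic
direction of the outgroup, used as a proxy for the ancestral response:

* basal layer — a significant basal difference in the *same* direction as
  the outgroup's plastic response is **orthoplastic**, in the opposite
  direction **paraplastic**;
* plastic layer — a significant interspecific slope difference whose sign
  matches the outgroup slope is a **magnified** response, an opposite sign
  (weaker or reversed response) is **mitigated**.

The cross of basal class (none/ortho/para) and plastic class
(none/magnified/mitigated) defines the eight modes of plasticity evolution
(plus "none").  Genes where the parental difference is mirrored by a
significant, same-signed allelic imbalance in the F1 hybrid carry a
cis-acting variant; parental-only changes are trans-only; ASE without a
parental difference, or with a discordant sign, is excluded from the
cis/trans classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

BASAL_CLASSES = ("ortho", "para", "none")
PLASTIC_CLASSES = ("magnified", "mitigated", "none")
CIS_STATUSES = ("cis", "trans_only", "excluded_ase_only", "excluded_discordant", "none")

MODE_OF = {
    ("none", "none"): "none",
    ("ortho", "none"): "Only-Ortho",
    ("para", "none"): "Only-Para",
    ("none", "magnified"): "Only-Mag",
    ("none", "mitigated"): "Only-Mit",
    ("ortho", "magnified"): "Ortho-Mag",
    ("ortho", "mitigated"): "Ortho-Mit",
    ("para", "magnified"): "Para-Mag",
    ("para", "mitigated"): "Para-Mit",
}

MODES_8 = (
    "Only-Ortho",
    "Only-Para",
    "Only-Mag",
    "Only-Mit",
    "Ortho-Mag",
    "Ortho-Mit",
    "Para-Mag",
    "Para-Mit",
)


def _signs(est: pd.Series) -> np.ndarray:
    return np.sign(est.to_numpy(dtype=float))


def classify_basal(
    basal: pd.DataFrame, outgroup_plast: pd.DataFrame, alpha_basal: float = 0.05
) -> pd.Series:
    """Orthoplastic / paraplastic / none for the basal-expression layer.

    ``basal`` is a ``test_basal_difference`` frame (derived vs outgroup);
    ``outgroup_plast`` a ``test_plasticity`` frame for the outgroup at the
    reference timepoint.  A boundary estimate of exactly 0 with significant
    q is classified none (a probability-zero event in floats).
    """
    basal, outgroup_plast = basal.align(outgroup_plast, join="inner", axis=0)
    sig_b = (basal["q"] <= alpha_basal).fillna(False).to_numpy()
    plast_dir = outgroup_plast["direction"].to_numpy()
    s_sign = _signs(outgroup_plast["estimate"])
    b_sign = _signs(basal["estimate"])
    ortho = sig_b & (plast_dir != "none") & (b_sign == s_sign) & (b_sign != 0)
    para = sig_b & (plast_dir != "none") & (b_sign == -s_sign) & (b_sign != 0)
    out = np.where(ortho, "ortho", np.where(para, "para", "none"))
    return pd.Series(out, index=basal.index, name="basal_class")


def classify_plastic(
    delta: pd.DataFrame, outgroup_plast: pd.DataFrame, alpha_delta: float = 0.1
) -> pd.Series:
    """Magnified / mitigated / none for the plasticity layer.

    Magnified iff the interspecific slope difference Delta has the sign of
    the outgroup slope (the stated "positive value = magnification" reading,
    generalized so it holds for down-regulated genes too); opposite sign —
    which covers both weakening and reversal — is mitigated.
    """
    delta, outgroup_plast = delta.align(outgroup_plast, join="inner", axis=0)
    sig_d = (delta["q"] <= alpha_delta).fillna(False).to_numpy()
    plast_dir = outgroup_plast["direction"].to_numpy()
    s_sign = _signs(outgroup_plast["estimate"])
    d_sign = _signs(delta["estimate"])
    mag = sig_d & (plast_dir != "none") & (d_sign == s_sign) & (d_sign != 0)
    mit = sig_d & (plast_dir != "none") & (d_sign == -s_sign) & (d_sign != 0)
    out = np.where(mag, "magnified", np.where(mit, "mitigated", "none"))
    return pd.Series(out, index=delta.index, name="plastic_class")


def assign_cis_trans(
    parental: pd.DataFrame,
    ase: pd.DataFrame,
    alpha_parental: float = 0.05,
    alpha_ase: float = 0.05,
    ase_col: str = "r0",
) -> pd.Series:
    """Cis/trans architecture of one layer (basal or plastic).

    cis — parental and allelic contrasts both significant with the same
    sign; trans_only — parental significant, allelic not; excluded_ase_only
    — allelic only (more power in the hybrid, not interpretable);
    excluded_discordant — both significant with opposite signs (the
    preferred allele does not belong to the higher-expressing parent).
    """
    parental, ase = parental.align(ase, join="inner", axis=0)
    sig_p = (parental["q"] <= alpha_parental).fillna(False).to_numpy()
    sig_a = (ase["q"] <= alpha_ase).fillna(False).to_numpy()
    p_sign = _signs(parental["estimate"])
    a_sign = _signs(ase[ase_col])
    concord = p_sign == a_sign
    out = np.select(
        [
            sig_p & sig_a & concord,
            sig_p & sig_a & ~concord,
            sig_p & ~sig_a,
            ~sig_p & sig_a,
        ],
        ["cis", "excluded_discordant", "trans_only", "excluded_ase_only"],
        default="none",
    )
    return pd.Series(out, index=parental.index, name="cis_status")


def assign_mode(basal_class, plastic_class):
    """Cross basal and plastic classes into one of the 8 modes (or none)."""
    if isinstance(basal_class, str):
        return MODE_OF[(basal_class, plastic_class)]
    out = [MODE_OF[(b, p)] for b, p in zip(basal_class, plastic_class)]
    return pd.Series(out, index=basal_class.index, name="mode")


def classify_lineage(
    basal: pd.DataFrame,
    delta: pd.DataFrame,
    outgroup_plast: pd.DataFrame,
    ase_basal: pd.DataFrame,
    ase_plastic_t: pd.DataFrame,
    alpha_basal: float = 0.05,
    alpha_delta: float = 0.1,
    alpha_ase_basal: float = 0.05,
    alpha_ase_plastic: float = 0.1,
) -> pd.DataFrame:
    """Full per-gene classification for one derived lineage at one timepoint.

    Inputs are the frames produced by the expression and ASE stages for the
    same lineage/hybrid; ``ase_plastic_t`` must already be sliced to the
    reference timepoint (index = gene).  Returns one row per gene with
    outgroup_direction, basal_class, plastic_class, mode, cis_basal_status
    and cis_plastic_status.
    """
    basal_class = classify_basal(basal, outgroup_plast, alpha_basal)
    plastic_class = classify_plastic(delta, outgroup_plast, alpha_delta)
    cis_basal = assign_cis_trans(
        basal, ase_basal, alpha_basal, alpha_ase_basal, ase_col="r0"
    )
    cis_plastic = assign_cis_trans(
        delta, ase_plastic_t, alpha_delta, alpha_ase_plastic, ase_col="delta"
    )
    frame = pd.DataFrame(
        {
            "outgroup_direction": outgroup_plast["direction"],
            "basal_class": basal_class,
            "plastic_class": plastic_class,
            "cis_basal_status": cis_basal,
            "cis_plastic_status": cis_plastic,
            "basal_log2": basal["estimate"],
            "basal_q": basal["q"],
            "delta_log2": delta["estimate"],
            "delta_q": delta["q"],
        }
    )
    frame["basal_class"] = frame["basal_class"].fillna("none")
    frame["plastic_class"] = frame["plastic_class"].fillna("none")
    frame["cis_basal_status"] = frame["cis_basal_status"].fillna("none")
    frame["cis_plastic_status"] = frame["cis_plastic_status"].fillna("none")
    frame["mode"] = assign_mode(frame["basal_class"], frame["plastic_class"])
    return frame


# ---------------------------------------------------------------------------
# quadrant tests and reporting arithmetic


def quadrant_test(n_ortho: int, n_total: int, method: str = "gof", table=None):
    """Chi-squared test on the ortho/para quadrant counts (df = 1).

    Default is the goodness-of-fit of ortho vs para against 1:1,
    chi2 = (2 * n_ortho - n_total)^2 / n_total.  ``method="independence"``
    instead runs a 2x2 test of outgroup direction x derived side on the
    supplied quadrant ``table`` (conditioning on the up/down marginal).
    Returns (chi2, df, p).
    """
    if method == "gof":
        if n_total <= 0:
            raise ValueError("n_total must be positive")
        chi2 = (2.0 * n_ortho - n_total) ** 2 / n_total
        return chi2, 1, float(stats.chi2.sf(chi2, 1))
    if method == "independence":
        if table is None:
            raise ValueError("independence method needs the 2x2 quadrant table")
        chi2, p, df, _ = stats.chi2_contingency(np.asarray(table), correction=False)
        return float(chi2), int(df), float(p)
    raise ValueError(f"unknown method {method!r}")


def odds_ratio(k: int, n: int) -> float:
    """Odds of success within a group of n: k / (n - k)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == n:
        return np.inf
    return k / (n - k)


def summarize_proportions(classification: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Counts and one-decimal percentages per mode (or any label column)."""
    labels = (
        classification["mode"]
        if isinstance(classification, pd.DataFrame)
        else classification
    )
    counts = labels.value_counts()
    total = int(counts.sum())
    pct = (
        np.round(100.0 * counts / total, 1)
        if total
        else counts.astype(float)
    )
    return pd.DataFrame({"count": counts, "percent": pct})


def percent(k: int, n: int) -> float:
    """One-decimal percentage as printed in summary tables."""
    if n == 0:
        return 0.0
    return round(100.0 * k / n, 1)


def per_gene(n_items: int, n_genes: int) -> float:
    """One-decimal per-gene rate (e.g. retained SNPs per ortholog)."""
    if n_genes == 0:
        return 0.0
    return round(n_items / n_genes, 1)
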