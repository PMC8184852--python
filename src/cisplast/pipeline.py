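"""End-to-end orchestration and reporting.

``run_synthetic`` drives the full chain on simulated inputs: simulate ->
parental expression fits and contrasts -> ASE against the DNA baseline ->
per-lineage classification -> parsimony origin assignment and lineage-rate
tests -> summary report.  Every stage is deterministic given the master
seed, and the results bundle records a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import pandas as pd

from . import ase as ase_mod
from . import classify as classify_mod
from . import expression as expr_mod
from . import lineage as lineage_mod
from .simdata import SimConfig, simulate_experiment


@dataclass
class RunConfig:
    """Thresholds and settings of one pipeline run."""

    alpha_basal: float = 0.05
    alpha_plast: float = 0.05
    alpha_delta: float = 0.1
    alpha_ase_basal: float = 0.05
    alpha_ase_plastic: float = 0.1
    t_ref: float = 6.0
    min_mean_count: float = 10.0
    bootstrap_B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "alpha_basal",
            "alpha_plast",
            "alpha_delta",
            "alpha_ase_basal",
            "alpha_ase_plastic",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


LINEAGES = (("derived1", "hybrid1"), ("derived2", "hybrid2"))


def analyze(matrix, alleles, config: RunConfig | None = None) -> dict:
    """Run the inference chain on an expression matrix + allele table."""
    cfg = config or RunConfig()
    if cfg.t_ref not in set(matrix.samples["timepoint_h"].dropna()):
        raise ValueError(f"reference timepoint {cfg.t_ref} not in the design")

    fit = expr_mod.fit_nested_model(matrix, min_mean_count=cfg.min_mean_count)
    out_plast = expr_mod.test_plasticity(fit, "outgroup", cfg.t_ref, cfg.alpha_plast)
    norm_alleles, factors = ase_mod.normalize_alleles(alleles)

    classifications = {}
    ase_results = {}
    expr_results = {"outgroup_plasticity": out_plast}
    for lin, hyb in LINEAGES:
        basal = expr_mod.test_basal_difference(fit, (lin, "outgroup"), cfg.alpha_basal)
        delta = expr_mod.test_plasticity_difference(
            fit, (lin, "outgroup"), cfg.t_ref, cfg.alpha_delta
        )
        ase_res = ase_mod.test_ase(
            norm_alleles,
            hyb,
            alpha_basal=cfg.alpha_ase_basal,
            alpha_plastic=cfg.alpha_ase_plastic,
            min_mean_count=cfg.min_mean_count,
        )
        ase_t = (
            ase_res.plastic.xs(cfg.t_ref, level="timepoint_h")
            if len(ase_res.plastic)
            else pd.DataFrame(columns=["delta", "q"])
        )
        classifications[lin] = classify_mod.classify_lineage(
            basal,
            delta,
            out_plast,
            ase_res.basal,
            ase_t,
            alpha_basal=cfg.alpha_basal,
            alpha_delta=cfg.alpha_delta,
            alpha_ase_basal=cfg.alpha_ase_basal,
            alpha_ase_plastic=cfg.alpha_ase_plastic,
        )
        ase_results[hyb] = ase_res
        expr_results[f"basal_{lin}"] = basal
        expr_results[f"delta_{lin}"] = delta

    origin = lineage_mod.assign_origin(
        classifications["derived1"], classifications["derived2"]
    )
    mode_table = lineage_mod.mode_count_table(
        classifications["derived1"], classifications["derived2"], origin
    )
    bundle = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.hash(),
        "fit": fit,
        "expression": expr_results,
        "ase": ase_results,
        "size_factors_alleles": factors,
        "classification": classifications,
        "origin": origin,
        "mode_table": mode_table,
    }
    if mode_table.to_numpy().sum() > 0:
        bundle["mode_rate_test"] = lineage_mod.mode_rate_test(mode_table)
    return bundle


def run_synthetic(sim_config: SimConfig, run_config: RunConfig | None = None) -> dict:
    """Simulate the experiment and analyze it; truth rides along."""
    matrix, alleles, truth = simulate_experiment(sim_config)
    bundle = analyze(matrix, alleles, run_config)
    bundle["truth"] = truth
    bundle["matrix"] = matrix
    bundle["alleles"] = alleles
    bundle["sim_config"] = sim_config.to_dict()
    return bundle


# ---------------------------------------------------------------------------
# reporting


def _layer_summary(cls: pd.DataFrame, layer: str) -> dict:
    """Quadrant counts, percentage, chi-squared and odds ratio for one layer."""
    if layer == "basal":
        labels, pos = cls["basal_class"], "ortho"
        cis_col = "cis_basal_status"
    else:
        labels, pos = cls["plastic_class"], "magnified"
        cis_col = "cis_plastic_status"
    classified = cls[labels != "none"]
    n_total = len(classified)
    n_pos = int((labels == pos).sum())
    out = {
        "n_total": n_total,
        f"n_{pos}": n_pos,
        f"percent_{pos}": classify_mod.percent(n_pos, n_total),
    }
    if n_total:
        chi2, df, p = classify_mod.quadrant_test(n_pos, n_total)
        out.update(
            chi2=round(chi2, 2),
            df=df,
            p=p,
            odds_ratio=round(classify_mod.odds_ratio(n_pos, n_total), 2),
        )
    cis = classified[classified[cis_col] == "cis"]
    n_cis = len(cis)
    n_cis_pos = int(
        (
            (cis["basal_class"] if layer == "basal" else cis["plastic_class"]) == pos
        ).sum()
    )
    out.update(
        n_cis=n_cis,
        **{f"n_cis_{pos}": n_cis_pos},
        **{f"percent_cis_{pos}": classify_mod.percent(n_cis_pos, n_cis)},
    )
    if n_cis:
        chi2, df, p = classify_mod.quadrant_test(n_cis_pos, n_cis)
        out.update(
            cis_chi2=round(chi2, 2),
            cis_p=p,
            cis_odds_ratio=round(classify_mod.odds_ratio(n_cis_pos, n_cis), 2),
        )
    return out


def report(bundle: dict) -> dict:
    """Human-readable summary tables from a results bundle.

    Returns a dict with per-lineage quadrant summaries (counts, one-decimal
    percentages, odds ratios), per-lineage mode proportions, and the mode x
    lineage matrix with its tests.  An empty classification yields all-zero
    tables rather than an error.
    """
    out = {"config_hash": bundle.get("config_hash", "")}
    for lin, cls in bundle.get("classification", {}).items():
        out[lin] = {
            "basal": _layer_summary(cls, "basal"),
            "plastic": _layer_summary(cls, "plastic"),
            "modes": classify_mod.summarize_proportions(
                cls[cls["mode"] != "none"]["mode"]
            )
            .reindex(classify_mod.MODES_8)
            .fillna(0)
            .astype({"count": int}),
        }
    if "mode_table" in bundle:
        out["mode_table"] = bundle["mode_table"]
    if "mode_rate_test" in bundle:
        t = bundle["mode_rate_test"]
        out["mode_rate_test"] = {"chi2": t["chi2"], "df": t["df"], "p": t["p"]}
    return out


def format_report(rep: dict) -> str:
    """Render the report dict as aligned text tables."""
    lines = []
    for key, val in rep.items():
        if isinstance(val, dict) and "basal" in val:
            lines.append(f"== {key} ==")
            for layer in ("basal", "plastic"):
                d = val[layer]
                lines.append(
                    f"  {layer}: "
                    + ", ".join(f"{k}={v}" for k, v in d.items())
                )
            lines.append("  modes:")
            lines.extend(
                "    " + line for line in val["modes"].to_string().splitlines()
            )
        elif isinstance(val, pd.DataFrame):
            lines.append(f"== {key} ==")
            lines.extend("  " + line for line in val.to_string().splitlines())
        else:
            lines.append(f"{key}: {val}")
    return "\n".join(lines) + "\n"
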