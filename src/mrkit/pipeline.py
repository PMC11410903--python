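"""End-to-end analyses: drug-target MR with colocalization, genome-wide
clustered MR, and cohort-summary arithmetic.

Reports are plain dictionaries with full-precision numbers (JSON-ready);
for a binary outcome the report layer also carries odds ratios
(exponentiated slopes). Every threshold used is echoed into the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import fit_mixture, report_clusters
from .coloc import ColocConfig, colocalize
from .estimators import (MethodInapplicableError, MREstimate, egger, ivw,
                         ivw_correlated, lowering_orientation, wald_ratios,
                         weighted_median)
from .instruments import (GENOME_WIDE_P, GeneRegion, apply_exclusions,
                          select_cis_instruments,
                          select_genomewide_instruments)
from .sumstats import LDMatrix, SummaryDataset, harmonize, retained

logger = logging.getLogger(__name__)

REPORT_SCHEMA = "mrkit-report/1"


@dataclass
class AnalysisConfig:
    """Thresholds and knobs for the pipeline runs (defaults = study settings)."""

    p_max: float = GENOME_WIDE_P
    r2_cis: float = 0.1
    r2_gw: float = 0.001
    flank_kb: float = 100.0
    proxy_r2_min: float = 0.8
    het_alpha: float = 0.05
    min_inclusion: float = 0.80
    min_size: int = 4
    k_max: int = 10
    n_restarts: int = 20
    n_boot: int = 1000
    coloc: ColocConfig = field(default_factory=ColocConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_max < 1 and 0 < self.r2_cis <= 1 and 0 < self.r2_gw <= 1):
            raise ValueError("thresholds out of range")
        if self.flank_kb < 0 or not (0 <= self.proxy_r2_min <= 1):
            raise ValueError("thresholds out of range")

    def thresholds(self) -> dict:
        d = asdict(self)
        d["coloc"] = asdict(self.coloc)
        return d


def _estimate_entry(e: MREstimate | None, binary_outcome: bool) -> dict | None:
    if e is None:
        return None
    d = e.to_dict()
    if binary_outcome:
        or_, lo, hi = e.odds_ratio()
        d["odds_ratio"] = or_
        d["or_ci_low"] = lo
        d["or_ci_high"] = hi
    return d


def _mr_battery(instruments, ld: LDMatrix | None, cfg: AnalysisConfig,
                binary_outcome: bool, lowering: bool = True) -> dict:
    """IVW (correlated when LD given), weighted median and Egger on one set."""
    out: dict = {"n_snps": len(instruments)}
    orient = lowering_orientation if lowering else (lambda e: e)
    est_ivw = (ivw_correlated(instruments, ld) if ld is not None
               else ivw(instruments))
    out["ivw"] = _estimate_entry(orient(est_ivw), binary_outcome)
    try:
        out["weighted_median"] = _estimate_entry(
            orient(weighted_median(instruments, n_boot=cfg.n_boot, seed=cfg.seed)),
            binary_outcome)
    except MethodInapplicableError as exc:
        logger.info("weighted median skipped: %s", exc)
        out["weighted_median"] = None
    try:
        out["egger"] = _estimate_entry(orient(egger(instruments, ld)), binary_outcome)
    except MethodInapplicableError as exc:
        logger.info("Egger skipped: %s", exc)
        out["egger"] = None
    return out


def run_drug_target(exposure: SummaryDataset, outcome: SummaryDataset,
                    target: GeneRegion, ld: LDMatrix | None = None,
                    cfg: AnalysisConfig = AnalysisConfig()) -> dict:
    """Cis-MR for one drug-target gene plus regional colocalization."""
    target = GeneRegion(target.gene_name, target.chromosome, target.start,
                        target.end, int(cfg.flank_kb * 1000))
    report: dict = {"schema": REPORT_SCHEMA, "version": __version__,
                    "analysis": "drug_target", "target": target.gene_name,
                    "thresholds": cfg.thresholds()}

    inst_set = select_cis_instruments(exposure, target, ld, cfg.p_max, cfg.r2_cis)
    report["selection"] = {"n_selected": len(inst_set),
                           "variant_ids": inst_set.variant_ids,
                           "min_f_statistic": inst_set.min_f,
                           "rule": inst_set.selection_rule}
    if len(inst_set) == 0:
        report["status"] = "not_instrumentable"
        return report
    report["status"] = "ok"

    harmonized = harmonize(exposure.subset(inst_set.variant_ids), outcome,
                           ld, cfg.proxy_r2_min)
    kept = retained(harmonized)
    report["harmonization"] = {
        "n_input": len(harmonized), "n_retained": len(kept),
        "actions": {a: sum(1 for h in harmonized if h.harmonization_action == a)
                    for a in sorted({h.harmonization_action for h in harmonized})},
    }
    binary = outcome.trait_type == "binary"
    report["mr"] = _mr_battery(kept, ld, cfg, binary)

    try:
        res = colocalize(exposure, outcome, target, cfg.coloc)
        report["coloc"] = res.to_dict()
    except Exception as exc:  # no shared variants etc.
        logger.warning("%s: colocalization failed: %s", target.gene_name, exc)
        report["coloc"] = {"error": str(exc)}
    return report


def run_clustered(exposure: SummaryDataset, outcome: SummaryDataset,
                  ld: LDMatrix | None = None, exclusions: list[str] | None = None,
                  cfg: AnalysisConfig = AnalysisConfig()) -> dict:
    """Genome-wide MR with mixture clustering of variant-level estimates."""
    report: dict = {"schema": REPORT_SCHEMA, "version": __version__,
                    "analysis": "clustered", "thresholds": cfg.thresholds()}
    inst_set = select_genomewide_instruments(exposure, ld, cfg.p_max, cfg.r2_gw)
    report["selection"] = {"n_selected": len(inst_set),
                           "min_f_statistic": inst_set.min_f,
                           "rule": inst_set.selection_rule}
    if len(inst_set) < 5:
        report["status"] = "too_few_instruments"
        return report
    report["status"] = "ok"
    binary = outcome.trait_type == "binary"

    def _run(ids: list[str]) -> dict:
        kept = retained(harmonize(exposure.subset(ids), outcome, ld, cfg.proxy_r2_min))
        section = {"all_snps": _mr_battery(kept, None, cfg, binary)}
        ratios = wald_ratios(kept)
        sol = fit_mixture(ratios, k_max=cfg.k_max, n_restarts=cfg.n_restarts,
                          seed=cfg.seed)
        clusters = report_clusters(sol, kept, cfg.min_inclusion, cfg.min_size,
                                   n_boot=cfg.n_boot, seed=cfg.seed)
        section["mixture"] = {
            "k_substantive": sol.k_substantive,
            "means": sol.means.tolist(),
            "proportions": sol.proportions.tolist(),
            "bic": sol.bic, "loglik": sol.loglik,
        }
        section["clusters"] = [
            {"cluster_id": c.cluster_id, "mean": c.mean,
             "n_members": len(c.member_variant_ids),
             "member_variant_ids": c.member_variant_ids,
             "estimates": {name: _estimate_entry(
                 lowering_orientation(e) if e else None, binary)
                 for name, e in c.estimates.items()}}
            for c in clusters
        ]
        return section

    report["main"] = _run(inst_set.variant_ids)
    if exclusions:
        sens_set = apply_exclusions(inst_set, exclusions)
        report["sensitivity"] = _run(sens_set.variant_ids)
        report["sensitivity"]["n_excluded"] = len(inst_set) - len(sens_set)
    return report


# ---------------------------------------------------------------------------
# cohort summary arithmetic

@dataclass
class CohortTable:
    """Per-study categorical counts.

    ``counts`` is {study: {group: {characteristic: {category: count}}}};
    groups are e.g. "cases"/"controls" and each characteristic (sex,
    smoking, ...) is a full partition of the group, so every
    characteristic's categories must sum to the same group total.
    """

    counts: dict[str, dict[str, dict[str, dict[str, int]]]]

    def __post_init__(self) -> None:
        for study, groups in self.counts.items():
            for group, chars in groups.items():
                totals = set()
                for char, cats in chars.items():
                    for cat, n in cats.items():
                        if n < 0:
                            raise ValueError(
                                f"{study}/{group}/{char}/{cat}: negative count")
                    totals.add(sum(cats.values()))
                if len(totals) > 1:
                    raise ValueError(
                        f"{study}/{group}: characteristics disagree on the "
                        f"group total ({sorted(totals)})")

    def group_total(self, study: str, group: str) -> int:
        chars = self.counts[study][group]
        first = next(iter(chars.values()))
        return sum(first.values())


def cohort_summary(table: CohortTable, ndigits: int = 1) -> dict:
    """Percentages per category within each group, plus grand totals.

    Percentages are 100 * count / group total rounded to ``ndigits``; a zero
    group total yields missing percentages. Also emits per-study totals, the
    all-study case total and the all-study individual total.
    """
    out: dict = {"studies": {}, "totals": {}}
    grand_total = 0
    grand_cases = 0
    for study, groups in table.counts.items():
        study_entry: dict = {}
        study_total = 0
        for group, chars in groups.items():
            total = table.group_total(study, group)
            study_total += total
            entry: dict = {"total": total, "characteristics": {}}
            for char, cats in chars.items():
                entry["characteristics"][char] = {
                    cat: {"count": n,
                          "percent": (round(100.0 * n / total, ndigits)
                                      if total > 0 else None)}
                    for cat, n in cats.items()}
            study_entry[group] = entry
            if group.lower().startswith("case"):
                grand_cases += total
        study_entry["total_individuals"] = study_total
        out["studies"][study] = study_entry
        grand_total += study_total
    out["totals"]["individuals"] = grand_total
    out["totals"]["cases"] = grand_cases
    return out


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
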