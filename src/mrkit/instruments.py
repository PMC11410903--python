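"""Instrument selection for drug-target (cis) and genome-wide MR.

Cis instruments are variants within a flank (default 100 kb) of a target
gene that pass genome-wide significance (p < 5e-8 by default) and survive
greedy p-value-ranked LD pruning at an r^2 threshold (clumping-style:
repeatedly keep the most significant remaining candidate and discard
everything correlated with it at r^2 >= the threshold). Genome-wide
instruments use the same rule with a stricter r^2 threshold; variants on
different chromosomes are treated as uncorrelated.

Instrument strength is the per-variant F-statistic (beta/se)^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .sumstats import LDMatrix, SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class GeneRegion:
    """A gene's span plus the cis flank used for instrument and coloc windows."""

    gene_name: str
    chromosome: str
    start: int
    end: int
    flank: int = 100_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_name}: start > end")
        if self.flank < 0:
            raise ValueError(f"{self.gene_name}: negative flank")

    def contains(self, chromosome: str, position: int) -> bool:
        return (str(chromosome) == self.chromosome
                and self.start - self.flank <= position <= self.end + self.flank)


def read_gene_regions(path, flank: int = 100_000, sep: str | None = None) -> list[GeneRegion]:
    """Read a gene-region table (gene, chr, start, end); 1-based inclusive."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    cols = {c.lower(): c for c in df.columns}
    for need in ("gene", "chr", "start", "end"):
        if need not in cols:
            raise ValueError(f"gene-region table missing column {need!r}")
    return [GeneRegion(str(r[cols["gene"]]), str(r[cols["chr"]]),
                       int(r[cols["start"]]), int(r[cols["end"]]), flank)
            for _, r in df.iterrows()]


@dataclass
class InstrumentSet:
    """An ordered, LD-pruned set of instruments with per-variant F-statistics."""

    label: str
    variant_ids: list[str]
    selection_rule: dict = field(default_factory=dict)
    f_statistics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids in instrument set")
        if any(f < 0 for f in self.f_statistics.values()):
            raise ValueError("negative F-statistic")

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def min_f(self) -> float:
        return min(self.f_statistics.values()) if self.f_statistics else float("nan")


def f_statistic(v: VariantAssociation | float, se: float | None = None) -> float:
    """Instrument strength (beta/se)^2 for one variant-exposure association."""
    if isinstance(v, VariantAssociation):
        beta, se = v.beta, v.se
    else:
        beta = float(v)
    if se is None or not se > 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def _greedy_prune(candidates: pd.DataFrame, ld: LDMatrix | None, r2_max: float) -> list[str]:
    """Greedy clumping: keep best p, discard everything with r^2 >= r2_max to a kept variant.

    Ties in p break by position, then variant_id; missing LD entries and
    cross-chromosome pairs count as r^2 = 0.
    """
    ranked = candidates.sort_values(
        ["p_value", "position", "variant_id"], kind="mergesort")
    remaining = list(ranked.itertuples(index=False))
    kept: list[str] = []
    kept_chrom: list[str] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best.variant_id)
        kept_chrom.append(str(best.chromosome))

        def correlated(row) -> bool:
            if ld is None:
                return False
            if str(row.chromosome) != kept_chrom[-1]:
                return False
            if row.variant_id not in ld or kept[-1] not in ld:
                return False
            return ld.r_between(row.variant_id, kept[-1]) ** 2 >= r2_max

        remaining = [row for row in remaining if not correlated(row)]
    return kept


def _build_set(label: str, candidates: pd.DataFrame, ld: LDMatrix | None,
               p_max: float, r2_max: float, rule_extra: dict) -> InstrumentSet:
    sig = candidates[candidates["p_value"] <= p_max]
    if sig.empty:
        logger.info("%s: no variant reaches p <= %g — not instrumentable", label, p_max)
        return InstrumentSet(label, [], {"p_max": p_max, "r2_max": r2_max, **rule_extra})
    kept = _greedy_prune(sig, ld, r2_max)
    fstats = {row.variant_id: f_statistic(float(row.beta), float(row.se))
              for row in sig.itertuples(index=False) if row.variant_id in set(kept)}
    return InstrumentSet(label, kept,
                         {"p_max": p_max, "r2_max": r2_max, **rule_extra},
                         {v: fstats[v] for v in kept})


def select_cis_instruments(exposure: SummaryDataset, region: GeneRegion,
                           ld: LDMatrix | None = None,
                           p_max: float = GENOME_WIDE_P, r2_max: float = 0.1,
                           ) -> InstrumentSet:
    """Select instruments within ``region.flank`` of a target gene (r^2 < 0.1)."""
    df = exposure.df
    in_region = ((df["chromosome"].astype(str) == region.chromosome)
                 & (df["position"] >= region.start - region.flank)
                 & (df["position"] <= region.end + region.flank))
    return _build_set(region.gene_name, df[in_region], ld, p_max, r2_max,
                      {"region": f"{region.chromosome}:{region.start}-{region.end}"
                                 f"+/-{region.flank}"})


def select_genomewide_instruments(exposure: SummaryDataset,
                                  ld: LDMatrix | None = None,
                                  p_max: float = GENOME_WIDE_P,
                                  r2_max: float = 0.001) -> InstrumentSet:
    """Select approximately independent (r^2 < 0.001) genome-wide instruments."""
    return _build_set(exposure.trait_name, exposure.df, ld, p_max, r2_max,
                      {"region": "genome-wide"})


def apply_exclusions(s: InstrumentSet, excluded: list[str]) -> InstrumentSet:
    """Remove listed variants (e.g. confounder-associated) from an instrument set."""
    removed = [v for v in s.variant_ids if v in set(excluded)]
    kept = [v for v in s.variant_ids if v not in set(excluded)]
    rule = dict(s.selection_rule)
    rule["excluded_variants"] = removed
    return InstrumentSet(s.label, kept, rule,
                         {v: f for v, f in s.f_statistics.items() if v in set(kept)})


def read_exclusion_list(path) -> list[str]:
    """One variant_id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh
                if ln.strip() and not ln.lstrip().startswith("#")]
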