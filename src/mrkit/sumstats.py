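"""GWAS summary-statistics containers, file IO and allele harmonization.

Summary statistics are carried as a :class:`SummaryDataset`, a thin wrapper
around a pandas DataFrame with one row per variant (unique ``variant_id``)
and the conventional per-variant association fields: effect/other allele,
effect-allele frequency, beta, standard error, p-value and sample size.
Betas are on the per-effect-allele-copy scale (SD units for quantitative
traits, log-odds for binary traits).

Harmonization aligns an outcome dataset onto the exposure's effect alleles,
flipping signs for swapped alleles, resolving strand flips via base
complements, dropping ambiguous palindromic variants by an allele-frequency
window, and substituting LD proxies for variants missing from the outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = {"A", "C", "G", "T"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names for delimited summary-statistic files, plus
#: GWAS-SSF-style aliases accepted without an explicit column map
DEFAULT_COLUMNS = ("variant_id", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n")
COLUMN_ALIASES: Mapping[str, str] = {
    "variant_id": "variant_id", "rsid": "variant_id", "snp": "variant_id", "id": "variant_id",
    "chr": "chromosome", "chromosome": "chromosome",
    "pos": "position", "position": "position", "base_pair_location": "position", "bp": "position",
    "ea": "effect_allele", "effect_allele": "effect_allele", "a1": "effect_allele",
    "oa": "other_allele", "other_allele": "other_allele", "a2": "other_allele",
    "eaf": "eaf", "effect_allele_frequency": "eaf", "freq": "eaf", "maf": "eaf",
    "beta": "beta", "b": "beta",
    "se": "se", "standard_error": "se",
    "p": "p_value", "p_value": "p_value", "pval": "p_value", "pvalue": "p_value",
    "n": "n", "sample_size": "n",
}

#: canonical internal column order
CANONICAL = ("variant_id", "chromosome", "position", "effect_allele", "other_allele",
             "eaf", "beta", "se", "p_value", "n")
MANDATORY = ("variant_id", "chromosome", "position", "effect_allele", "other_allele",
             "beta", "se", "p_value")


class ConfigurationError(ValueError):
    """A required column or configuration value is missing or invalid."""


class InputError(ValueError):
    """An input file or dataset violates a precondition."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    p_value: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.variant_id}: effect and other allele identical")
        if not self.se > 0:
            raise InputError(f"{self.variant_id}: se must be positive")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise InputError(f"{self.variant_id}: eaf must lie strictly in (0,1)")


@dataclass
class SummaryDataset:
    """A GWAS for one trait: per-variant associations plus trait metadata.

    ``df`` holds one row per variant with the canonical columns; variant ids
    are unique. ``case_fraction`` is required for binary traits.
    """

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise InputError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.case_fraction is None or not (0 < self.case_fraction < 1):
                raise InputError("binary trait requires case_fraction in (0,1)")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"].tolist()
            raise InputError(f"duplicate variant ids: {dups[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[VariantAssociation]:
        out = []
        for row in self.df.itertuples(index=False):
            eaf = None if pd.isna(row.eaf) else float(row.eaf)
            n = None if pd.isna(row.n) else int(row.n)
            out.append(VariantAssociation(
                variant_id=row.variant_id, chromosome=str(row.chromosome),
                position=int(row.position), effect_allele=row.effect_allele,
                other_allele=row.other_allele, eaf=eaf, beta=float(row.beta),
                se=float(row.se), p_value=float(row.p_value), n=n))
        return out

    def subset(self, variant_ids: Iterable[str]) -> "SummaryDataset":
        ids = list(variant_ids)
        sub = self.df[self.df["variant_id"].isin(set(ids))].copy()
        # preserve the requested ordering
        order = {v: i for i, v in enumerate(ids)}
        sub = sub.sort_values("variant_id", key=lambda s: s.map(order)).reset_index(drop=True)
        return SummaryDataset(self.trait_name, self.trait_type, sub, self.case_fraction)

    def lookup(self, variant_id: str) -> pd.Series | None:
        hit = self.df[self.df["variant_id"] == variant_id]
        return hit.iloc[0] if len(hit) else None


@dataclass
class LDMatrix:
    """Signed LD correlations (dosage scale) for an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise InputError("LD matrix dimension does not match variant list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal must be 1")
        np.fill_diagonal(self.r, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def submatrix(self, variant_ids: Sequence[str]) -> np.ndarray:
        idx = [self._index[v] for v in variant_ids]
        return self.r[np.ix_(idx, idx)]


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome effects for one instrument on a common effect allele."""

    variant_id: str
    exposure_beta: float
    exposure_se: float
    outcome_beta: float
    outcome_se: float
    effect_allele: str
    other_allele: str
    proxy_of: str | None = None
    harmonization_action: str = "kept"

    def __post_init__(self) -> None:
        if self.harmonization_action in RETAINED_ACTIONS:
            if not (self.exposure_se > 0 and self.outcome_se > 0):
                raise InputError(f"{self.variant_id}: standard errors must be positive")


RETAINED_ACTIONS = frozenset({"kept", "flipped", "strand_flipped", "proxy"})
DROPPED_ACTIONS = frozenset({"dropped_palindromic", "dropped_missing"})


# ---------------------------------------------------------------------------
# file IO

def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map file columns onto canonical names; ``column_map`` is canonical->file."""
    resolved: dict[str, str] = {}
    if column_map:
        alias_of = {
            "variant_id": "variant_id", "chr": "chromosome", "pos": "position",
            "ea": "effect_allele", "oa": "other_allele", "eaf": "eaf",
            "beta": "beta", "se": "se", "p": "p_value", "n": "n",
        }
        for key, col in column_map.items():
            canon = alias_of.get(key, COLUMN_ALIASES.get(key.lower(), key))
            resolved[canon] = col
    for col in header:
        canon = COLUMN_ALIASES.get(col.lower())
        if canon and canon not in resolved:
            resolved[canon] = col
    return resolved


def read_sumstats(path, column_map: Mapping[str, str] | None = None, *,
                  trait_name: str = "trait", trait_type: str = "quantitative",
                  case_fraction: float | None = None, sep: str | None = None) -> SummaryDataset:
    """Read a delimited summary-statistics file into a :class:`SummaryDataset`.

    Rows violating the per-variant invariants (non-ACGT or identical alleles,
    non-positive se, p outside (0,1], eaf outside (0,1)) are dropped and
    counted in the log. Alleles are uppercased.
    """
    import csv
    try:
        raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except (pd.errors.EmptyDataError, csv.Error):
        raise InputError(f"{path}: empty or undelimited summary-statistics file") from None
    if raw.empty:
        raise InputError(f"{path}: no data rows")

    colmap = _resolve_columns(raw.columns, column_map)
    missing = [c for c in MANDATORY if c not in colmap]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory column(s) {missing}")

    df = pd.DataFrame({canon: raw[col] for canon, col in colmap.items() if col in raw.columns})
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan
    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for num in ("position", "eaf", "beta", "se", "p_value", "n"):
        df[num] = pd.to_numeric(df[num], errors="coerce")

    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["se"] > 0)
        & (df["p_value"] > 0) & (df["p_value"] <= 1)
        & df["beta"].notna() & df["position"].notna()
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d row(s) violating invariants", path, n_dropped)
    df = df.loc[ok, list(CANONICAL)].reset_index(drop=True)
    df["position"] = df["position"].astype(int)
    ds = SummaryDataset(trait_name, trait_type, df, case_fraction)
    ds.n_dropped_rows = n_dropped  # type: ignore[attr-defined]
    return ds


def write_sumstats(dataset: SummaryDataset, path, sep: str = "\t") -> None:
    dataset.df.to_csv(path, sep=sep, index=False)


def read_ld_matrix(path, sep: str | None = None) -> LDMatrix:
    """Read an LD matrix: square with a header row of ids, or long (id1,id2,r)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.shape[1] == 3 and set(c.lower() for c in df.columns) >= {"id1", "id2"}:
        df.columns = [c.lower() for c in df.columns]
        ids = sorted(set(df["id1"]).union(df["id2"]))
        index = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        rcol = [c for c in df.columns if c not in ("id1", "id2")][0]
        for row in df.itertuples(index=False):
            i, j = index[row.id1], index[row.id2]
            val = float(getattr(row, rcol))
            r[i, j] = r[j, i] = val
        return LDMatrix(ids, r)
    ids = [str(c) for c in df.columns]
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path, sep: str = "\t") -> None:
    pd.DataFrame(ld.r, columns=ld.variant_ids).to_csv(path, sep=sep, index=False)


HARMONIZED_COLUMNS = ("variant_id", "exposure_beta", "exposure_se", "outcome_beta",
                      "outcome_se", "effect_allele", "other_allele", "proxy_of",
                      "harmonization_action")


def write_harmonized(instruments: Sequence[HarmonizedInstrument], path, sep: str = "\t") -> None:
    """Write harmonized instruments as delimited text (lossless round-trip)."""
    if not instruments:
        raise InputError("cannot write an empty instrument list")
    rows = [{c: getattr(inst, c) for c in HARMONIZED_COLUMNS} for inst in instruments]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_harmonized(path, sep: str = "\t") -> list[HarmonizedInstrument]:
    df = pd.read_csv(path, sep=sep)
    out = []
    for row in df.itertuples(index=False):
        out.append(HarmonizedInstrument(
            variant_id=str(row.variant_id),
            exposure_beta=float(row.exposure_beta), exposure_se=float(row.exposure_se),
            outcome_beta=float(row.outcome_beta), outcome_se=float(row.outcome_se),
            effect_allele=str(row.effect_allele), other_allele=str(row.other_allele),
            proxy_of=None if pd.isna(row.proxy_of) else str(row.proxy_of),
            harmonization_action=str(row.harmonization_action)))
    return out


# ---------------------------------------------------------------------------
# harmonization

def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def _ambiguous_eaf(eaf: float | None, lo: float, hi: float) -> bool:
    return eaf is None or np.isnan(eaf) or (lo < eaf < hi)


def harmonize(exposure: SummaryDataset, outcome: SummaryDataset,
              ld: LDMatrix | None = None, proxy_r2_min: float = 0.8, *,
              palindromic_window: tuple[float, float] = (0.42, 0.58),
              ) -> list[HarmonizedInstrument]:
    """Align outcome associations onto the exposure's effect alleles.

    For each exposure variant, in order: matching alleles are kept; swapped
    alleles negate the outcome beta (``flipped``); strand-complement alleles
    are complemented first (``strand_flipped``); palindromic (A/T, G/C)
    variants are retained only when both allele frequencies fall on the same
    side of 0.5 and outside ``palindromic_window``, else dropped; variants
    absent from the outcome are substituted by the best LD proxy with
    r^2 >= ``proxy_r2_min``, the proxy's outcome beta sign-corrected by the
    signed LD r, else dropped. Dropped variants are returned with their
    drop action so that retained + dropped counts equal the input count.
    """
    lo, hi = palindromic_window
    out: list[HarmonizedInstrument] = []
    outcome_ids = set(outcome.df["variant_id"])
    outcome_by_id = outcome.df.set_index("variant_id", drop=False)
    warned_no_ld = False

    for exp in exposure.records():
        o = outcome_by_id.loc[exp.variant_id] if exp.variant_id in outcome_ids else None
        if o is None:
            inst = _proxy_instrument(exp, exposure, outcome, outcome_ids, ld, proxy_r2_min)
            if inst is None and ld is None and not warned_no_ld:
                logger.warning("no LD matrix supplied: proxy substitution skipped")
                warned_no_ld = True
            out.append(inst if inst is not None else HarmonizedInstrument(
                exp.variant_id, exp.beta, exp.se, float("nan"), float("nan"),
                exp.effect_allele, exp.other_allele,
                harmonization_action="dropped_missing"))
            continue

        o_ea, o_oa = str(o["effect_allele"]), str(o["other_allele"])
        o_beta, o_se = float(o["beta"]), float(o["se"])
        o_eaf = None if pd.isna(o["eaf"]) else float(o["eaf"])

        if _is_palindromic(exp.effect_allele, exp.other_allele):
            same_alleles = {o_ea, o_oa} == {exp.effect_allele, exp.other_allele}
            # textual alignment first; the frequency of the exposure's effect
            # allele in the outcome is complemented when the labels are swapped
            aligned_eaf = o_eaf if o_ea == exp.effect_allele else (
                None if o_eaf is None else 1 - o_eaf)
            if (not same_alleles or _ambiguous_eaf(exp.eaf, lo, hi)
                    or _ambiguous_eaf(aligned_eaf, lo, hi)
                    or (exp.eaf - 0.5) * (aligned_eaf - 0.5) <= 0):
                out.append(HarmonizedInstrument(
                    exp.variant_id, exp.beta, exp.se, float("nan"), float("nan"),
                    exp.effect_allele, exp.other_allele,
                    harmonization_action="dropped_palindromic"))
                continue
            # same-side frequencies confirm the textual alignment
            action = "kept" if o_ea == exp.effect_allele else "flipped"
            beta = o_beta if action == "kept" else -o_beta
            out.append(HarmonizedInstrument(
                exp.variant_id, exp.beta, exp.se, beta, o_se,
                exp.effect_allele, exp.other_allele, harmonization_action=action))
            continue

        if (o_ea, o_oa) == (exp.effect_allele, exp.other_allele):
            out.append(HarmonizedInstrument(
                exp.variant_id, exp.beta, exp.se, o_beta, o_se,
                exp.effect_allele, exp.other_allele, harmonization_action="kept"))
        elif (o_ea, o_oa) == (exp.other_allele, exp.effect_allele):
            out.append(HarmonizedInstrument(
                exp.variant_id, exp.beta, exp.se, -o_beta, o_se,
                exp.effect_allele, exp.other_allele, harmonization_action="flipped"))
        else:
            c_ea, c_oa = COMPLEMENT.get(o_ea), COMPLEMENT.get(o_oa)
            if (c_ea, c_oa) == (exp.effect_allele, exp.other_allele):
                out.append(HarmonizedInstrument(
                    exp.variant_id, exp.beta, exp.se, o_beta, o_se,
                    exp.effect_allele, exp.other_allele,
                    harmonization_action="strand_flipped"))
            elif (c_ea, c_oa) == (exp.other_allele, exp.effect_allele):
                out.append(HarmonizedInstrument(
                    exp.variant_id, exp.beta, exp.se, -o_beta, o_se,
                    exp.effect_allele, exp.other_allele,
                    harmonization_action="strand_flipped"))
            else:
                logger.info("%s: allele mismatch with outcome, dropped", exp.variant_id)
                out.append(HarmonizedInstrument(
                    exp.variant_id, exp.beta, exp.se, float("nan"), float("nan"),
                    exp.effect_allele, exp.other_allele,
                    harmonization_action="dropped_missing"))
    return out


def _proxy_instrument(exp: VariantAssociation, exposure: SummaryDataset,
                      outcome: SummaryDataset, outcome_ids: set[str],
                      ld: LDMatrix | None, proxy_r2_min: float,
                      ) -> HarmonizedInstrument | None:
    """Best-r^2 proxy for an exposure variant missing from the outcome.

    Ties in r^2 break by smaller base-pair distance, then lexicographic id.
    The proxy's outcome beta is sign-corrected by the signed LD r so the
    effect refers to the original variant's effect allele.
    """
    if ld is None or exp.variant_id not in ld:
        return None
    candidates = []
    for vid in ld.variant_ids:
        if vid == exp.variant_id or vid not in outcome_ids:
            continue
        r = ld.r_between(exp.variant_id, vid)
        if r * r >= proxy_r2_min:
            prox = outcome.lookup(vid)
            pos = exposure.lookup(vid)
            dist = abs(int(pos["position"]) - exp.position) if pos is not None else np.inf
            candidates.append((r * r, -dist, vid, r, prox))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    _, _, vid, r, prox = candidates[0]
    sign = 1.0 if r >= 0 else -1.0
    logger.info("%s: substituting proxy %s (signed r=%.3f)", exp.variant_id, vid, r)
    return HarmonizedInstrument(
        exp.variant_id, exp.beta, exp.se,
        sign * float(prox["beta"]), float(prox["se"]),
        exp.effect_allele, exp.other_allele,
        proxy_of=vid, harmonization_action="proxy")


def retained(instruments: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Instruments that survived harmonization."""
    return [i for i in instruments if i.harmonization_action in RETAINED_ACTIONS]
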