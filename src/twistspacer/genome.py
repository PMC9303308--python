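"""Genome-scale statistics linking spacer length to supercoiling response.

Takes a curated promoter map (EcoCyc-style TSV dialect) and a differential
response table (log fold-change + adjusted p-value per promoter), classifies
promoters as activated / unaffected / repressed, and tests whether the spacer
length differs between classes: group means with Student CIs and a
two-sample t-test, the proportion of activated promoters per spacer length
with a linear regression, and the discriminator G/C comparison that singles
out the anomalous 16-nt class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InsufficientDataError, PromoterMapFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterRecord",
    "PromoterMapResult",
    "read_promoter_map",
    "classify_response",
    "classify_responses",
    "filter_promoters",
    "spacer_mean_comparison",
    "activation_proportion_regression",
    "discriminator_gc_comparison",
    "gc_fraction",
    "SpacerComparison",
    "ProportionRegression",
    "GcComparison",
]

MAP_REQUIRED_COLUMNS = (
    "promoter_id",
    "sigma_factor",
    "tss",
    "strand",
    "m10_start",
    "m10_end",
    "m10_seq",
    "spacer_len",
)


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter of the map: element coordinates, spacer and discriminator.

    Coordinates are 1-based inclusive genomic positions (start <= end on the
    forward axis regardless of strand).  On the + strand the -35 element lies
    upstream (lower coordinates) of the -10; on the - strand the order is
    mirrored.
    """

    promoter_id: str
    sigma_factor: str
    tss: int
    strand: str
    minus10: tuple[int, int, str]
    spacer_length: int
    minus35: tuple[int, int, str] | None = None
    spacer_seq: str | None = None
    discriminator_seq: str | None = None


def _hexamer_ok(start: int, end: int, seq: str) -> bool:
    return end - start + 1 == 6 and len(seq) == 6


def _spacer_gap(row) -> int | None:
    """Gap between hexamers under the declared convention, or None if no -35."""
    if pd.isna(row.get("m35_start")) or pd.isna(row.get("m35_end")):
        return None
    if row["strand"] == "+":
        return int(row["m10_start"]) - int(row["m35_end"]) - 1
    return int(row["m35_start"]) - int(row["m10_end"]) - 1


@dataclass
class PromoterMapResult:
    """Validated promoter records plus per-reason drop counts."""

    records: list[PromoterRecord]
    drop_counts: Counter

    @property
    def n_dropped(self) -> int:
        return sum(self.drop_counts.values())


def read_promoter_map(path) -> PromoterMapResult:
    """Read and validate a promoter-map TSV.

    Rows violating structural invariants (bad strand, non-hexamer elements,
    duplicated promoter ids) are dropped with a logged reason and counted.
    An explicit ``spacer_len`` column takes precedence over the hexamer gap;
    a mismatch between the two is kept but logged as a consistency warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"promoter_id": str})
    missing = [c for c in MAP_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PromoterMapFormatError(f"promoter map is missing columns {missing}")

    records: list[PromoterRecord] = []
    drops: Counter = Counter()
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = str(row["promoter_id"])
        if pid in seen:
            drops["duplicate_promoter_id"] += 1
            logger.info("dropping duplicated promoter id %s", pid)
            continue
        if row["strand"] not in ("+", "-"):
            drops["bad_strand"] += 1
            logger.info("dropping %s: strand %r", pid, row["strand"])
            continue
        if not _hexamer_ok(int(row["m10_start"]), int(row["m10_end"]), str(row["m10_seq"])):
            drops["bad_minus10"] += 1
            logger.info("dropping %s: -10 element is not a hexamer", pid)
            continue
        minus35 = None
        has_m35 = "m35_seq" in row and not pd.isna(row.get("m35_seq"))
        if has_m35:
            if not _hexamer_ok(
                int(row["m35_start"]), int(row["m35_end"]), str(row["m35_seq"])
            ):
                drops["bad_minus35"] += 1
                logger.info("dropping %s: -35 element is not a hexamer", pid)
                continue
            minus35 = (int(row["m35_start"]), int(row["m35_end"]), str(row["m35_seq"]))
        spacer_len = int(row["spacer_len"])
        gap = _spacer_gap(row) if minus35 is not None else None
        if gap is not None and gap != spacer_len:
            logger.warning(
                "promoter %s: curated spacer_len %d disagrees with hexamer gap %d "
                "(curated value kept)",
                pid,
                spacer_len,
                gap,
            )
        seen.add(pid)
        records.append(
            PromoterRecord(
                promoter_id=pid,
                sigma_factor=str(row["sigma_factor"]),
                tss=int(row["tss"]),
                strand=str(row["strand"]),
                minus10=(int(row["m10_start"]), int(row["m10_end"]), str(row["m10_seq"])),
                spacer_length=spacer_len,
                minus35=minus35,
                spacer_seq=None if pd.isna(row.get("spacer_seq")) else str(row["spacer_seq"]),
                discriminator_seq=None
                if pd.isna(row.get("discriminator_seq"))
                else str(row["discriminator_seq"]),
            )
        )
    return PromoterMapResult(records=records, drop_counts=drops)


def promoter_records_from_frame(df: pd.DataFrame) -> list[PromoterRecord]:
    """Build records from an in-memory promoter-map frame (already validated,
    e.g. the output of the synthetic cohort generator)."""
    out = []
    has_m35 = "m35_seq" in df.columns
    for row in df.itertuples(index=False):
        out.append(
            PromoterRecord(
                promoter_id=str(row.promoter_id),
                sigma_factor=str(row.sigma_factor),
                tss=int(row.tss),
                strand=str(row.strand),
                minus10=(int(row.m10_start), int(row.m10_end), str(row.m10_seq)),
                spacer_length=int(row.spacer_len),
                minus35=(int(row.m35_start), int(row.m35_end), str(row.m35_seq))
                if has_m35
                else None,
                spacer_seq=getattr(row, "spacer_seq", None),
                discriminator_seq=getattr(row, "discriminator_seq", None),
            )
        )
    return out


def classify_response(logfc: float, padj: float, alpha: float = 0.05) -> str:
    """Classify one promoter: 'activated', 'repressed' or 'none'.

    Activated if ``padj < alpha`` and ``logfc > 0``; repressed if
    ``padj < alpha`` and ``logfc < 0``; otherwise 'none'.
    """
    if not 0.0 <= padj <= 1.0:
        raise ValueError(f"padj must be in [0, 1], got {padj}")
    if padj < alpha:
        if logfc > 0:
            return "activated"
        if logfc < 0:
            return "repressed"
    return "none"


def classify_responses(responses: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Vectorized classification; adds a ``response_class`` column."""
    df = responses.copy()
    padj = df["padj"].to_numpy(dtype=float)
    if np.any((padj < 0) | (padj > 1)):
        raise ValueError("padj values must be in [0, 1]")
    logfc = df["logfc"].to_numpy(dtype=float)
    cls = np.where(
        (padj < alpha) & (logfc > 0),
        "activated",
        np.where((padj < alpha) & (logfc < 0), "repressed", "none"),
    )
    df["response_class"] = cls
    return df


@dataclass
class FilterResult:
    records: list[PromoterRecord]
    removed: Counter


def filter_promoters(
    records: list[PromoterRecord],
    sigma_factor: str | None = "sigma70",
    length_range: tuple[int, int] = (15, 19),
    exclude_16: bool = True,
) -> FilterResult:
    """Retain sigma70 promoters with spacers in the modelled length range.

    16-nt spacers behave oppositely to the model (their supercoiling response
    is likely dominated by open-complex effects) and are excluded from the
    statistical analyses by default; keep them for the discriminator analysis
    with ``exclude_16=False``.
    """
    removed: Counter = Counter()
    kept = []
    lo, hi = length_range
    for r in records:
        if sigma_factor is not None and r.sigma_factor != sigma_factor:
            removed["sigma_factor"] += 1
            continue
        if not (lo <= r.spacer_length <= hi):
            removed["length_range"] += 1
            continue
        if exclude_16 and r.spacer_length == 16:
            removed["spacer_16"] += 1
            continue
        kept.append(r)
    return FilterResult(records=kept, removed=removed)


def _merge(records: list[PromoterRecord], responses: pd.DataFrame, alpha: float) -> pd.DataFrame:
    lengths = pd.DataFrame(
        {
            "promoter_id": [r.promoter_id for r in records],
            "spacer_len": [r.spacer_length for r in records],
        }
    )
    df = lengths.merge(responses, on="promoter_id", how="inner")
    return classify_responses(df, alpha=alpha)


def _group_stats(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    m = float(x.mean())
    if len(x) >= 2 and x.std(ddof=1) > 0:
        half = stats.t.ppf(0.975, len(x) - 1) * x.std(ddof=1) / np.sqrt(len(x))
    else:
        half = 0.0
    return m, (m - half, m + half)


@dataclass(frozen=True)
class SpacerComparison:
    """Mean spacer length per response class, and activated-vs-repressed t-test."""

    means: dict
    ci95: dict
    counts: dict
    t_welch: float
    p_welch: float
    t_pooled: float
    p_pooled: float


def spacer_mean_comparison(
    records: list[PromoterRecord],
    responses: pd.DataFrame,
    alpha: float = 0.05,
) -> SpacerComparison:
    """Compare mean spacer lengths of activated vs repressed promoters.

    Reports class means with Student 95% CIs and both the Welch and the
    pooled-variance two-sample t-test between the activated and repressed
    groups.
    """
    df = _merge(records, responses, alpha)
    groups = {c: df.loc[df["response_class"] == c, "spacer_len"].to_numpy(float)
              for c in ("activated", "none", "repressed")}
    for name in ("activated", "repressed"):
        if len(groups[name]) == 0:
            raise InsufficientDataError(f"no promoters in the {name!r} group")
    means, cis, counts = {}, {}, {}
    for name, x in groups.items():
        if len(x):
            means[name], cis[name] = _group_stats(x)
        else:
            means[name], cis[name] = float("nan"), (float("nan"), float("nan"))
        counts[name] = int(len(x))
    a, r = groups["activated"], groups["repressed"]
    tw, pw = stats.ttest_ind(a, r, equal_var=False)
    tp, pp = stats.ttest_ind(a, r, equal_var=True)
    return SpacerComparison(
        means=means,
        ci95=cis,
        counts=counts,
        t_welch=float(tw),
        p_welch=float(pw),
        t_pooled=float(tp),
        p_pooled=float(pp),
    )


@dataclass(frozen=True)
class ProportionRegression:
    """Per-length activated proportions and the linear trend over length."""

    table: pd.DataFrame
    slope: float
    intercept: float
    slope_se: float
    p_value: float


def activation_proportion_regression(
    records: list[PromoterRecord],
    responses: pd.DataFrame,
    alpha: float = 0.05,
    exclude_16: bool = True,
    weighted: bool = False,
    ci_method: str = "wilson",
) -> ProportionRegression:
    """Proportion of activated promoters among responsive ones, per length.

    "Responsive" means ``padj < alpha`` regardless of sign.  Proportions carry
    binomial 95% CIs; the trend over spacer length is an (by default
    unweighted) OLS regression with a two-sided slope p-value.
    """
    df = _merge(records, responses, alpha)
    df = df[df["response_class"] != "none"]
    if exclude_16:
        df = df[df["spacer_len"] != 16]
    rows = []
    for n, g in df.groupby("spacer_len"):
        k = int((g["response_class"] == "activated").sum())
        tot = int(len(g))
        lo, hi = proportion_confint(k, tot, alpha=0.05, method=ci_method)
        rows.append(
            {"spacer_len": int(n), "n_responsive": tot, "n_activated": k,
             "proportion": k / tot, "ci_low": float(lo), "ci_high": float(hi)}
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise InsufficientDataError(
            "need >= 2 spacer lengths with responsive promoters"
        )
    x = sm.add_constant(table["spacer_len"].to_numpy(float))
    y = table["proportion"].to_numpy(float)
    if weighted:
        fit = sm.WLS(y, x, weights=table["n_responsive"].to_numpy(float)).fit()
    else:
        fit = sm.OLS(y, x).fit()
    return ProportionRegression(
        table=table,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
    )


def gc_fraction(seq: str) -> float:
    """G+C fraction of a sequence."""
    from Bio.SeqUtils import gc_fraction as _gc

    return float(_gc(seq))


@dataclass(frozen=True)
class GcComparison:
    """Discriminator G/C content of one spacer-length class vs all others."""

    group_length: int
    mean_gc_group: float
    mean_gc_other: float
    n_group: int
    n_other: int
    t: float
    p_value: float


def discriminator_gc_comparison(
    records: list[PromoterRecord],
    group_length: int = 16,
) -> GcComparison:
    """Compare discriminator G/C content of ``group_length``-nt promoters vs the rest.

    Stringently controlled promoters (16-nt spacers) are expected to carry
    G/C-richer discriminators; tested with a Welch two-sample t-test on
    per-promoter GC fractions.
    """
    with_disc = [r for r in records if r.discriminator_seq]
    group = [gc_fraction(r.discriminator_seq) for r in with_disc
             if r.spacer_length == group_length]
    other = [gc_fraction(r.discriminator_seq) for r in with_disc
             if r.spacer_length != group_length]
    if len(group) < 2 or len(other) < 2:
        raise InsufficientDataError(
            "need >= 2 promoters with discriminator sequences in each group"
        )
    t, p = stats.ttest_ind(group, other, equal_var=False)
    return GcComparison(
        group_length=group_length,
        mean_gc_group=float(np.mean(group)),
        mean_gc_other=float(np.mean(other)),
        n_group=len(group),
        n_other=len(other),
        t=float(t),
        p_value=float(p),
    )
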