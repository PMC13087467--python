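"""Cohort-level evaluation statistics.

Category summaries over annotation tables; enrichment odds ratios with
Fisher's exact test and Benjamini-Hochberg correction; allele-frequency
shift tests (two-tailed Wilcoxon rank-sum with the Hodges-Lehmann estimator
of the median pairwise difference); signed-score Spearman correlation for
effect-size validation; and log2 mean-ribosome-load fold changes for
reporter-assay comparisons.

Odds ratios are the sample cross-product ratio (a*d)/(b*c) with a normal
approximation CI on the log scale; the p value comes from the exact
hypergeometric test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotate import CONSEQUENCES

#: Priority used to deduplicate multi-consequence variants in summaries.
CATEGORY_PRIORITY = ["uStart_gain", "uStop_loss", "uStop_gain", "uStart_loss", "uKozak", "mKozak"]


@dataclass
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass
class StatResult:
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: float
    method: str


def dedup_records(records: pd.DataFrame, priority: Sequence[str] = CATEGORY_PRIORITY) -> pd.DataFrame:
    """Keep one row per (variant, transcript), by category priority."""
    rank = {c: i for i, c in enumerate(priority)}
    records = records.copy()
    records["_prio"] = records["CSQ"].map(lambda c: rank.get(c, len(rank)))
    keys = ["CHROM", "POS", "REF", "ALT", "TRANSCRIPT"]
    out = (
        records.sort_values(keys + ["_prio"], kind="mergesort")
        .drop_duplicates(subset=keys, keep="first")
        .drop(columns="_prio")
    )
    return out.reset_index(drop=True)


def category_summary(records_or_counts) -> pd.DataFrame:
    """Per-consequence counts and one-decimal percentages.

    Accepts either an annotation DataFrame (with a CSQ column) or a mapping
    of category -> count. Percentages are computed over the sum of the
    reported category counts.
    """
    if isinstance(records_or_counts, pd.DataFrame):
        counts = records_or_counts["CSQ"].value_counts().to_dict()
    else:
        counts = dict(records_or_counts)
    rows = []
    total = sum(counts.values())
    for csq in CONSEQUENCES:
        n = int(counts.get(csq, 0))
        pct = round(100.0 * n / total, 1) if total else 0.0
        rows.append({"CSQ": csq, "count": n, "percent": pct})
    return pd.DataFrame(rows)


def fisher_enrichment(t: ContingencyTable) -> StatResult:
    """Cross-product odds ratio with exact p and log-normal CI."""
    table = [[t.a, t.b], [t.c, t.d]]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    if t.b * t.c == 0:
        return StatResult(None, None, None, float(p), "fisher_exact (OR undefined: zero margin)")
    odds = (t.a * t.d) / (t.b * t.c)
    if min(t.a, t.b, t.c, t.d) == 0:
        lo = hi = None
    else:
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        lo = math.exp(math.log(odds) - 1.96 * se)
        hi = math.exp(math.log(odds) + 1.96 * se)
    return StatResult(odds, lo, hi, float(p), "fisher_exact")


def hodges_lehmann(a: Sequence[float], b: Sequence[float]) -> float:
    """Median of all pairwise differences a_i - b_j."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.median(np.subtract.outer(a, b)))


def maf_compare(group_a: Sequence[float], group_b: Sequence[float]) -> StatResult:
    """Two-tailed Wilcoxon rank-sum with Hodges-Lehmann location shift."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both samples must be non-empty")
    stat = sps.mannwhitneyu(group_a, group_b, alternative="two-sided")
    shift = hodges_lehmann(group_a, group_b)
    return StatResult(shift, None, None, float(stat.pvalue), "wilcoxon_rank_sum + hodges_lehmann")


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values, capped at 1."""
    pvals = list(pvals)
    if any(not 0 <= p <= 1 for p in pvals):
        raise ValueError("p values must lie in [0, 1]")
    if not pvals:
        return []
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(x) for x in adj]


def signed_score_correlation(
    scores: Sequence[float], directions: Sequence[str], effects: Sequence[float]
) -> StatResult:
    """Spearman correlation between direction-signed scores and effect sizes.

    Scores are negated where the predicted translational direction is
    'decreased', so that sign encodes the predicted direction of the protein-
    level change.
    """
    if not (len(scores) == len(directions) == len(effects)):
        raise ValueError("scores, directions, and effects must have equal length")
    bad = set(directions) - {"increased", "decreased"}
    if bad:
        raise ValueError(f"unknown directions: {sorted(bad)}")
    signed = [s if d == "increased" else -s for s, d in zip(scores, directions)]
    rho, p = sps.spearmanr(signed, effects)
    return StatResult(float(rho), None, None, float(p), "spearman")


def delta_mrl(mrl_ref: float, mrl_alt: float) -> float:
    """log2 fold change of variant vs reference mean ribosome load."""
    if mrl_ref <= 0 or mrl_alt <= 0:
        raise ValueError("mean ribosome loads must be positive")
    return math.log2(mrl_alt / mrl_ref)


def mechanism_concordance(csq_labels: Sequence[str]) -> tuple[int, int, float]:
    """Fraction of curated variant mechanisms falling in the six
    translational consequence categories (vs transcription-level mechanisms
    such as promoter/TFBS disruption).

    Returns (n_concordant, n_total, percent rounded to integer).
    """
    labels = list(csq_labels)
    n_conc = sum(1 for c in labels if c in CONSEQUENCES)
    pct = round(100.0 * n_conc / len(labels)) if labels else 0.0
    return n_conc, len(labels), pct
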