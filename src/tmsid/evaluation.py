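"""Identification metrics: top-k accuracy, ARP, RRP and grouped summaries.

For a query whose candidate set contains the truth:

* ARP (absolute ranking position) = number of candidates scored strictly
  better than the correct candidate, plus 1 (ties are not "better").
* RRP (relative ranking position) = (1 + (BC - WC)/(TC - 1)) / 2, where BC
  and WC count candidates ranked better resp. worse than the correct one
  and TC is the candidate-set size; RRP is 0 when the truth is first and
  1 when it is last. A singleton candidate set (TC = 1) leaves RRP
  undefined by the formula; the convention here is 0 (the sole candidate
  is the correct one, hence trivially first) and its use is flagged.

Queries whose candidate set lacks the truth are "missing". Missing
queries stay in the top-k denominator but are excluded from mean ARP/RRP
— the accounting that reconciles with published summary tables (e.g.
39 of 104 queries in the top 10 reported as 37.5% with 32 missing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .iokr import RankingResult

__all__ = ["EvaluationSummary", "arp", "rrp", "topk", "summarize"]

MISSING = "missing"


def arp(r: RankingResult) -> int | str:
    """Absolute ranking position; propagates "missing"."""
    if r.rank_of_true is None:
        return MISSING
    return r.n_strictly_better + 1


def rrp(bc: int, wc: int, tc: int) -> float:
    """Relative ranking position from better/worse/total candidate counts."""
    if tc < 1 or bc < 0 or wc < 0:
        raise ValueError("counts must be non-negative with TC >= 1")
    if bc + wc != tc - 1:
        raise ValueError(f"inconsistent counts: BC + WC = {bc + wc} != TC - 1 = {tc - 1}")
    if tc == 1:
        return 0.0  # singleton convention, flagged by summarize()
    return 0.5 * (1.0 + (bc - wc) / (tc - 1))


def _rrp_of_result(r: RankingResult) -> float | str:
    if r.rank_of_true is None:
        return MISSING
    tc = len(r.ranking)
    bc = r.n_strictly_better
    return rrp(bc, tc - 1 - bc, tc)


def topk(results: list[RankingResult], k: int) -> float:
    """Percentage of queries with the truth in the top k; missing queries
    count in the denominator."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not results:
        raise ValueError("topk needs at least one ranking result")
    hits = sum(1 for r in results if r.rank_of_true is not None and r.rank_of_true <= k)
    return 100.0 * hits / len(results)


@dataclass
class EvaluationSummary:
    """Per-group identification summary mirroring the published table layout."""

    group: str
    n_queries: int
    n_missing: int
    top_k: dict[int, tuple[int, float]]  # k -> (count, percent)
    mean_arp: float
    mean_rrp: float
    singleton_rrp_used: int = 0

    def to_row(self) -> dict:
        row = {
            "group": self.group,
            "n": self.n_queries,
            "missing_n": self.n_missing,
            "missing_pct": round(100.0 * self.n_missing / self.n_queries, 1)
            if self.n_queries else math.nan,
        }
        for k, (count, pct) in sorted(self.top_k.items()):
            row[f"top{k}_n"] = count
            row[f"top{k}_pct"] = round(pct, 1)
        row["mean_ARP"] = round(self.mean_arp, 1) if not math.isnan(self.mean_arp) else math.nan
        row["mean_RRP"] = round(self.mean_rrp, 2) if not math.isnan(self.mean_rrp) else math.nan
        return row


def _summarize_one(group: str, results: list[RankingResult], ks) -> EvaluationSummary:
    n = len(results)
    missing = sum(1 for r in results if r.rank_of_true is None)
    top = {}
    for k in ks:
        count = sum(1 for r in results if r.rank_of_true is not None and r.rank_of_true <= k)
        top[k] = (count, 100.0 * count / n if n else math.nan)
    arps = [arp(r) for r in results if r.rank_of_true is not None]
    rrps = [_rrp_of_result(r) for r in results if r.rank_of_true is not None]
    singles = sum(1 for r in results if r.rank_of_true is not None and len(r.ranking) == 1)
    return EvaluationSummary(
        group=group, n_queries=n, n_missing=missing, top_k=top,
        mean_arp=sum(arps) / len(arps) if arps else math.nan,
        mean_rrp=sum(rrps) / len(rrps) if rrps else math.nan,
        singleton_rrp_used=singles,
    )


def summarize(
    results: list[RankingResult],
    groups: dict[str, str] | None = None,
    ks: tuple[int, ...] = (1, 10, 20),
) -> list[EvaluationSummary]:
    """Per-group summaries plus a merged one.

    ``groups`` maps query id -> group label and must cover every query when
    given. Mean ARP/RRP average over non-missing queries only; missing
    queries are reported as count and percentage and stay in the top-k
    denominators.
    """
    if not results:
        raise ValueError("summarize needs at least one ranking result")
    out = []
    if groups is not None:
        absent = [r.query_id for r in results if r.query_id not in groups]
        if absent:
            raise ValueError(f"queries missing from grouping: {absent[:5]}")
        for label in sorted(set(groups.values())):
            members = [r for r in results if groups[r.query_id] == label]
            out.append(_summarize_one(label, members, ks))
    out.append(_summarize_one("Merged", results, ks))
    return out


def summary_table(summaries: list[EvaluationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
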