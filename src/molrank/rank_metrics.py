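"""Per-group rankings and the four-metric evaluation suite.

For every conformer group the trained scorer assigns each member one
scalar; sorting those scores (ascending or descending, depending on
whether the "best" structure has the lowest or highest property) yields
the predicted ranking, which is compared against the true
property-derived ranking with four metrics:

* rank MAE — mean absolute difference between predicted and true rank
  positions,
* Spearman correlation — Pearson correlation of the two rank vectors
  (average ranks on ties),
* nDCG — discounted cumulative gain of the predicted order, with linear
  gain (item of true rank r gets relevance n - r) and 1/log2(position+1)
  discount, normalised by the ideal ordering's gain,
* top-1 frequency — fraction of groups whose predicted best member truly
  has the best property value.

Group-level values are aggregated into a mean, sample standard deviation
and a normal-approximation 95% confidence-interval half-width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .moldata import ConformerGroup

__all__ = [
    "RankingResult",
    "MetricSummary",
    "MetricReport",
    "rank_group",
    "rank_groups",
    "rank_mae",
    "spearman",
    "ndcg",
    "top1_frequency",
    "summarize",
    "evaluate_rankings",
    "write_report",
]


@dataclass
class RankingResult:
    """Predicted order of one group with scores and rank positions."""

    group_id: str
    structure_ids: List[str]       # predicted best first
    scores: np.ndarray             # aligned with group member order
    predicted_ranks: np.ndarray    # 1-based, aligned with member order
    true_ranks: np.ndarray         # 1-based (min = best), member order
    true_values: np.ndarray

    def __len__(self) -> int:
        return len(self.structure_ids)

    @property
    def top1_correct(self) -> bool:
        """True when the predicted best member has (a tied-)minimal true rank."""
        best = int(np.argmin(self.predicted_ranks))
        return bool(self.true_ranks[best] == self.true_ranks.min())


@dataclass
class MetricSummary:
    mean: float
    sd: float
    ci95: float
    n: int
    n_missing: int = 0


@dataclass
class MetricReport:
    """Aggregated four-metric evaluation over a set of groups."""

    rank_mae: MetricSummary
    spearman: MetricSummary
    ndcg: MetricSummary
    top1: float
    n_groups: int

    def as_dict(self) -> Dict[str, object]:
        out: Dict[str, object] = {}
        for name in ("rank_mae", "spearman", "ndcg"):
            s: MetricSummary = getattr(self, name)
            out[name] = {"mean": s.mean, "sd": s.sd, "ci95": s.ci95,
                         "n": s.n, "n_missing": s.n_missing}
        out["top1"] = self.top1
        out["n_groups"] = self.n_groups
        return out


def _competition_ranks(values: np.ndarray, ascending: bool) -> np.ndarray:
    """1-based ranks, best first; ties share the smallest position."""
    v = values if ascending else -values
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=np.int64)
    ranks[order] = np.arange(1, len(v) + 1)
    # collapse ties to the first position of the tie run (competition style)
    sorted_v = v[order]
    pos = np.arange(1, len(v) + 1)
    for i in range(1, len(v)):
        if sorted_v[i] == sorted_v[i - 1]:
            pos[i] = pos[i - 1]
    ranks[order] = pos
    return ranks


def rank_group(scorer: Callable[[ConformerGroup], np.ndarray],
               group: ConformerGroup, property_name: str,
               orientation: str = "ascending") -> RankingResult:
    """Rank one group by scoring each member once with the shared branch.

    ``orientation="ascending"`` means the best structure has the *lowest*
    property value (energies); the model's score is sorted in the same
    direction, with a stable structure_id tiebreak. Thanks to the
    antisymmetric Siamese head this is equivalent to aggregating all
    pairwise outranking probabilities.
    """
    if orientation not in ("ascending", "descending"):
        raise ValueError(f"unknown orientation {orientation!r}")
    scores = np.asarray(scorer(group), dtype=np.float64)
    if scores.shape != (len(group),):
        raise ValueError("scorer must return one score per member")
    truth = group.property_values(property_name)
    asc = orientation == "ascending"
    sids = [s.structure_id for s in group.structures]
    key = scores if asc else -scores
    order = sorted(range(len(group)), key=lambda i: (key[i], sids[i]))
    predicted_ranks = np.empty(len(group), dtype=np.int64)
    for pos, i in enumerate(order, start=1):
        predicted_ranks[i] = pos
    return RankingResult(
        group_id=group.group_id,
        structure_ids=[sids[i] for i in order],
        scores=scores,
        predicted_ranks=predicted_ranks,
        true_ranks=_competition_ranks(truth, ascending=asc),
        true_values=truth,
    )


def rank_groups(scorer, groups: Sequence[ConformerGroup], property_name: str,
                orientation: str = "ascending") -> List[RankingResult]:
    return [rank_group(scorer, g, property_name, orientation) for g in groups]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rank_mae(predicted_ranks: Sequence[float],
             true_ranks: Sequence[float]) -> float:
    """Mean absolute difference of rank positions."""
    p = np.asarray(predicted_ranks, dtype=np.float64)
    t = np.asarray(true_ranks, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("rank vectors must have equal length")
    return float(np.mean(np.abs(p - t)))


def spearman(predicted_ranks: Sequence[float],
             true_ranks: Sequence[float]) -> Optional[float]:
    """Spearman correlation (Pearson on ranks, average ranks for ties).

    Returns None when either vector has zero variance (undefined).
    """
    p = np.asarray(predicted_ranks, dtype=np.float64)
    t = np.asarray(true_ranks, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        return None
    rho = stats.spearmanr(p, t).statistic
    return float(rho)


def ndcg(predicted_order: Sequence[int], true_ranks: Sequence[float]) -> float:
    """Normalised DCG of a predicted ordering.

    ``predicted_order`` lists member indices, best first; the member with
    true rank r has relevance n - r (ties share an average true rank and
    hence a common relevance). Discount is 1/log2(position + 1).
    """
    order = np.asarray(predicted_order, dtype=np.int64)
    t = np.asarray(true_ranks, dtype=np.float64)
    n = len(t)
    if n == 0:
        raise ValueError("empty group")
    rel = n - t
    discounts = 1.0 / np.log2(np.arange(1, n + 1) + 1.0)
    dcg = float(np.sum(rel[order] * discounts))
    ideal = float(np.sum(np.sort(rel)[::-1] * discounts))
    if ideal == 0.0:
        return 1.0  # all relevances equal: any order is ideal
    return dcg / ideal


def top1_frequency(rankings: Sequence[RankingResult]) -> float:
    """Fraction of groups whose predicted first member is truly best."""
    if not rankings:
        raise ValueError("need at least one group")
    return float(np.mean([r.top1_correct for r in rankings]))


def summarize(values: Sequence[Optional[float]]) -> MetricSummary:
    """Mean, sample sd and 1.96 sd/sqrt(n) CI half-width; None dropped."""
    kept = np.asarray([v for v in values if v is not None], dtype=np.float64)
    n_missing = len(values) - len(kept)
    n = len(kept)
    if n == 0:
        return MetricSummary(np.nan, np.nan, np.nan, 0, n_missing)
    mean = float(kept.mean())
    if n < 2:
        return MetricSummary(mean, np.nan, np.nan, n, n_missing)
    sd = float(kept.std(ddof=1))
    return MetricSummary(mean, sd, 1.96 * sd / np.sqrt(n), n, n_missing)


def evaluate_rankings(rankings: Sequence[RankingResult]) -> MetricReport:
    """Compute all four metrics over per-group ranking results."""
    maes = [rank_mae(r.predicted_ranks, r.true_ranks) for r in rankings]
    rhos = [spearman(r.predicted_ranks, r.true_ranks) if len(r) >= 2 else None
            for r in rankings]
    # nDCG consumes the predicted visiting order (positions of members)
    ndcgs = []
    for r in rankings:
        order = np.argsort(r.predicted_ranks, kind="stable")
        # average true ranks for tie-friendly relevance
        t = stats.rankdata(r.true_ranks, method="average")
        ndcgs.append(ndcg(order, t))
    return MetricReport(
        rank_mae=summarize(maes),
        spearman=summarize(rhos),
        ndcg=summarize(ndcgs),
        top1=top1_frequency(rankings),
        n_groups=len(rankings),
    )


def write_report(report: MetricReport, rankings: Sequence[RankingResult],
                 out_dir: Union[str, Path],
                 dump_rankings: bool = True) -> None:
    """Write the metric table (TSV + JSON) and optionally the rankings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in ("rank_mae", "spearman", "ndcg"):
        s: MetricSummary = getattr(report, name)
        rows.append((name, s.mean, s.sd, s.ci95, s.n))
    rows.append(("top1", report.top1, np.nan, np.nan, report.n_groups))
    pd.DataFrame(rows, columns=["metric", "mean", "sd", "ci95", "n"]).to_csv(
        out_dir / "metrics.tsv", sep="\t", index=False)
    (out_dir / "metrics.json").write_text(
        json.dumps(report.as_dict(), indent=2, sort_keys=True) + "\n")
    if dump_rankings:
        member_rows = []
        for r in rankings:
            # structure_ids is predicted-best-first, so member i (with
            # predicted rank p_i) is structure_ids[p_i - 1]
            for i in range(len(r)):
                member_rows.append((
                    r.group_id,
                    r.structure_ids[int(r.predicted_ranks[i]) - 1],
                    float(r.scores[i]),
                    int(r.predicted_ranks[i]),
                    int(r.true_ranks[i]),
                ))
        pd.DataFrame(member_rows, columns=[
            "group_id", "structure_id", "score", "pred_rank", "true_rank",
        ]).to_csv(out_dir / "rankings.tsv", sep="\t", index=False)
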