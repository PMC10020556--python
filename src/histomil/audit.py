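"""Interpretation layer: attention by morphology, top-k patch review,
bag summaries, significance tests, and association-rules mining.

The audit mirrors how the genotype predictions are verified biologically:
attention weights are grouped by predicted tissue morphology (all patches,
median per slide, or maximum per slide); the top-k highest-attention patches
per bag (default 25) are reviewed; reviews are summarised per bag (numeric
mean / standard deviation / minimum / maximum, categorical mode with a
deterministic lexicographic tie-break); numeric summaries are compared
between predicted-status groups by a two-sided two-sample t-test with
Benjamini-Hochberg FDR correction and a point-biserial Pearson correlation;
categorical summaries by a chi-square test (no continuity correction); and
association rules are mined apriori-style from the bag-level categorical
items with the predicted status as the consequent, ranked by lift.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import CATEGORICAL_REVIEW_FIELDS, NUMERIC_REVIEW_FIELDS

# ---------------------------------------------------------------------------
# attention distributions
# ---------------------------------------------------------------------------

_GROUPINGS = ("all_patches", "median_per_slide", "max_per_slide")


def attention_by_morphology(records: pd.DataFrame,
                            grouping: str = "all_patches") -> pd.DataFrame:
    """Attention-weight distribution summaries per morphology class.

    ``records`` needs columns ``slide_id``, ``weight``, ``morphology_call``.
    ``median_per_slide`` / ``max_per_slide`` first collapse each slide's
    weights per class to their median / maximum.  Returns one row per class
    with ``median``, ``max`` and ``n`` of the grouped values.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {_GROUPINGS}")
    if records.empty:
        raise ValueError("no attention records")
    if grouping == "all_patches":
        values = records[["morphology_call", "weight"]]
    else:
        agg = "median" if grouping == "median_per_slide" else "max"
        values = (records.groupby(["slide_id", "morphology_call"],
                                  sort=True)["weight"]
                  .agg(agg).reset_index()[["morphology_call", "weight"]])
    out = (values.groupby("morphology_call")["weight"]
           .agg(median="median", max="max", n="size").reset_index())
    return out


def top_k_patches(bag_records: pd.DataFrame, k: int = 25,
                  weight_col: str = "weight") -> pd.DataFrame:
    """The k highest-attention rows of one bag, in descending weight order;
    ties broken by ascending patch index (row order)."""
    if len(bag_records) < k:
        raise ValueError(f"bag has {len(bag_records)} patches, need >= {k}")
    order = sorted(range(len(bag_records)),
                   key=lambda i: (-bag_records[weight_col].iloc[i], i))
    return bag_records.iloc[order[:k]]


# ---------------------------------------------------------------------------
# bag summaries
# ---------------------------------------------------------------------------


def _mode_with_tiebreak(values) -> tuple[str, bool]:
    counts = pd.Series(list(values)).value_counts()
    top = counts.max()
    winners = sorted(counts[counts == top].index)
    return winners[0], len(winners) > 1


def summarize_bag(reviews: pd.DataFrame, predicted_status: str) -> dict:
    """Per-bag summary of reviewed patches: numeric mean/sd/min/max and the
    categorical mode (lexicographic tie-break, flagged under ``*_tie``)."""
    if reviews.empty:
        raise ValueError("cannot summarise an empty review set")
    out: dict = {"predicted_status": predicted_status,
                 "n_patches": len(reviews)}
    for fld in NUMERIC_REVIEW_FIELDS:
        v = reviews[fld].to_numpy(dtype=float)
        out[f"{fld}_mean"] = float(v.mean())
        out[f"{fld}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        out[f"{fld}_min"] = float(v.min())
        out[f"{fld}_max"] = float(v.max())
    for fld in CATEGORICAL_REVIEW_FIELDS:
        mode, tie = _mode_with_tiebreak(reviews[fld])
        out[fld] = mode
        out[f"{fld}_tie"] = tie
    return out


def summarize_bags(review_table: pd.DataFrame, k: int | None = None) -> pd.DataFrame:
    """Summaries for every bag in a review table (optionally keeping only
    each bag's top-k rows by ``weight`` if present, else by ``patch_rank``)."""
    rows = []
    for bag_id, grp in review_table.groupby("bag_id", sort=True):
        if k is not None:
            if "weight" in grp.columns:
                grp = top_k_patches(grp, k)
            else:
                grp = grp.nsmallest(k, "patch_rank")
        status = grp["predicted_status"].iloc[0]
        rows.append({"bag_id": bag_id, **summarize_bag(grp, status)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# significance tests
# ---------------------------------------------------------------------------


def compare_numeric(summaries: pd.DataFrame, variable: str,
                    statistic: str = "mean") -> dict:
    """Two-sided two-sample t-test between predicted groups on one numeric
    bag summary, plus Pearson's r against status coded mutant=1."""
    col = f"{variable}_{statistic}"
    status = summaries["predicted_status"]
    a = summaries.loc[status == "mutant", col].to_numpy(dtype=float)
    b = summaries.loc[status == "wildtype", col].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both predicted groups must be non-empty")
    t, p = stats.ttest_ind(a, b)
    coded = (status == "mutant").astype(int)
    values = summaries[col].to_numpy(dtype=float)
    if values.std() == 0:  # constant summary: correlation undefined
        r = np.nan
    else:
        r, _ = stats.pearsonr(values, coded)
    return {"variable": variable, "statistic": statistic, "t": float(t),
            "p": float(p), "r": float(r),
            "n_mutant": len(a), "n_wildtype": len(b)}


def compare_all_numeric(summaries: pd.DataFrame) -> pd.DataFrame:
    """All numeric variable x statistic comparisons with Benjamini-Hochberg
    FDR q-values across the whole family of tests."""
    rows = [compare_numeric(summaries, var, st)
            for var in NUMERIC_REVIEW_FIELDS
            for st in ("mean", "sd", "min", "max")]
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def compare_categorical(summaries: pd.DataFrame, variable: str) -> dict:
    """Chi-square test (no continuity correction) on the predicted-status x
    category contingency table of one categorical bag summary."""
    table = pd.crosstab(summaries["predicted_status"], summaries[variable])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table is degenerate")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(),
                                                    correction=False)
    return {"variable": variable, "chi2": float(chi2), "p": float(p),
            "dof": int(dof), "table": table,
            "zero_expected_cells": int(np.sum(expected == 0))}


# ---------------------------------------------------------------------------
# association rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    antecedent: frozenset
    consequent: frozenset
    support: float     # support of antecedent + consequent
    confidence: float  # support(A u C) / support(A)
    lift: float        # confidence / support(C)


def transactions_from_summaries(summaries: pd.DataFrame,
                                fields=tuple(CATEGORICAL_REVIEW_FIELDS),
                                status_col: str = "predicted_status"):
    """Bag summaries -> transactions of ``field=value`` items plus the
    ``status=...`` consequent item."""
    out = []
    for _, row in summaries.iterrows():
        items = {f"{fld}={row[fld]}" for fld in fields}
        items.add(f"status={row[status_col]}")
        out.append(frozenset(items))
    return out


def _support(itemset: frozenset, transactions) -> float:
    return sum(1 for t in transactions if itemset <= t) / len(transactions)


def mine_rules(transactions, consequent: str, min_support: float = 0.1,
               min_confidence: float = 0.5,
               max_len: int | None = None) -> list[Rule]:
    """Apriori-style rules with the status item as the sole consequent.

    Frequent item-sets are enumerated level-wise at ``min_support``; for
    every frequent set containing the consequent item, the rule
    (set minus consequent) -> consequent is scored.  Rules are ranked by
    lift descending, ties by support descending, then lexicographically.
    """
    if min_support <= 0:
        raise ValueError("min_support must be positive")
    transactions = [frozenset(t) for t in transactions]
    if not transactions:
        raise ValueError("no transactions")
    items = sorted({i for t in transactions for i in t})
    supports: dict[frozenset, float] = {}
    level = []
    for it in items:
        s = _support(frozenset([it]), transactions)
        if s >= min_support:
            fs = frozenset([it])
            supports[fs] = s
            level.append(fs)
    all_frequent = list(level)
    size = 1
    while level and (max_len is None or size < max_len):
        size += 1
        candidates = sorted({a | b for a, b in combinations(level, 2)
                             if len(a | b) == size},
                            key=lambda fs: sorted(fs))
        level = []
        for cand in candidates:
            if any(cand - frozenset([i]) not in supports for i in cand):
                continue  # a subset is infrequent
            s = _support(cand, transactions)
            if s >= min_support:
                supports[cand] = s
                level.append(cand)
        all_frequent.extend(level)
    c_item = frozenset([consequent])
    supp_c = _support(c_item, transactions)
    rules = []
    for fs in all_frequent:
        if consequent not in fs or len(fs) == 1:
            continue
        antecedent = fs - c_item
        conf = supports[fs] / supports[antecedent]
        if conf >= min_confidence and supp_c > 0:
            rules.append(Rule(antecedent=antecedent, consequent=c_item,
                              support=supports[fs], confidence=conf,
                              lift=conf / supp_c))
    rules.sort(key=lambda r: (-r.lift, -r.support, sorted(r.antecedent)))
    return rules


def rules_to_frame(rules: list[Rule]) -> pd.DataFrame:
    return pd.DataFrame([{
        "antecedent": " & ".join(sorted(r.antecedent)),
        "consequent": " & ".join(sorted(r.consequent)),
        "support": r.support, "confidence": r.confidence, "lift": r.lift,
    } for r in rules])
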