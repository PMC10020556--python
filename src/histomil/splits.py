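"""Registry handling and the cross-validation split design.

Training sets are class-balanced by majority under-sampling (an equal number
of non-mutant slides is drawn to match the mutant training slides) and
validation sets are prevalence-matched: enough non-mutant slides are added
so the mutant fraction equals ``val_prevalence`` (default 15%, the
real-world EGFR short-variant prevalence in NSCLC).

Arithmetic, per fold, for ``n_mut`` mutant specimens:

* ``mutant_train = round_half_up(mutant_train_frac * n_mut)``
* ``mutant_val   = n_mut - mutant_train``
* ``nonmutant_train = mutant_train`` (balanced)
* ``nonmutant_val   = floor(mutant_val / val_prevalence) - mutant_val``

Round-half-up on the mutant training count and floor on the total validation
size are the only rounding scheme reproducing the published cohort's printed
sizes (716 mutants at 0.8 -> 573 train / 143 validation; with 1383
non-mutants this gives 1146-slide training and 953-slide validation sets at
143/953 = 15.0% prevalence).

Mutant validation blocks are disjoint across folds.  When ``n_folds *
mutant_val < n_mut`` (5 does not divide the mutant cohort) the remainder of
the shuffled mutants appears in every training set and is never validated;
exact tiling holds whenever the sizes divide.  Non-mutant draws are disjoint
within a fold but may recur across folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SplitPlan:
    fold: int  # 1-based
    train_ids: list[str]
    val_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.val_ids)
        if overlap:
            raise ValueError(f"{len(overlap)} specimens in both partitions")


def make_folds(registry: pd.DataFrame, n_folds: int = 5,
               mutant_train_frac: float = 0.8, val_prevalence: float = 0.15,
               seed: int = 0) -> list[SplitPlan]:
    """Build ``n_folds`` balanced-training / prevalence-matched-validation
    splits from a registry with ``specimen_id`` and ``is_mutant`` columns."""
    if not 0 < mutant_train_frac < 1:
        raise ValueError("mutant_train_frac must be in (0, 1)")
    if not 0 < val_prevalence <= 1:
        raise ValueError("val_prevalence must be in (0, 1]")
    mutants = registry.loc[registry["is_mutant"], "specimen_id"].tolist()
    others = registry.loc[~registry["is_mutant"], "specimen_id"].tolist()
    n_mut = len(mutants)
    if n_mut == 0:
        raise ValueError("registry contains no mutant specimens")
    m_train = round_half_up(mutant_train_frac * n_mut)
    m_val = n_mut - m_train
    if m_val == 0:
        raise ValueError("mutant_train_frac leaves no mutant validation slides")
    if n_folds * m_val > n_mut:
        raise ValueError(
            f"{n_folds} disjoint mutant validation blocks of {m_val} need "
            f"{n_folds * m_val} mutants but only {n_mut} exist")
    nm_val = math.floor(m_val / val_prevalence) - m_val
    need = m_train + nm_val
    if len(others) < need:
        raise ValueError(
            f"insufficient non-mutant pool: need {need} "
            f"({m_train} train + {nm_val} validation), have {len(others)}")
    rng = np.random.default_rng(seed)
    shuffled_mut = list(np.array(mutants)[rng.permutation(n_mut)])
    params = {"n_folds": n_folds, "mutant_train_frac": mutant_train_frac,
              "val_prevalence": val_prevalence, "seed": seed}
    plans = []
    for fold in range(n_folds):
        val_mut = shuffled_mut[fold * m_val:(fold + 1) * m_val]
        train_mut = [s for s in shuffled_mut if s not in set(val_mut)]
        pool = np.array(others)[rng.permutation(len(others))]
        train_nm = list(pool[:m_train])
        val_nm = list(pool[m_train:m_train + nm_val])
        plans.append(SplitPlan(fold=fold + 1,
                               train_ids=train_mut + train_nm,
                               val_ids=val_mut + val_nm,
                               params=dict(params)))
    return plans


def folds_to_frame(plans: list[SplitPlan]) -> pd.DataFrame:
    """Long-format fold assignments (specimen_id, fold, partition)."""
    rows = []
    for plan in plans:
        rows += [{"specimen_id": s, "fold": plan.fold, "partition": "train"}
                 for s in plan.train_ids]
        rows += [{"specimen_id": s, "fold": plan.fold, "partition": "validation"}
                 for s in plan.val_ids]
    return pd.DataFrame(rows)
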