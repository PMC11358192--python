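"""Knowledgeability scoring from multiple-choice answers and the split-half
discrimination ceiling.

A participant's knowledgeability theta in a category is their accuracy on
that category's multiple-choice questions (30 by default; unanswered
questions count as incorrect).  The split-half ceiling estimates the best
discrimination accuracy achievable for a pair of informants when the judge
sees each informant's score on a random half of the questions and predicts
who scores higher on the unseen half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bayes import BayesFactorResult, InvalidInputError
from .default_bf import TestSummary, jzs_ttest_bf10, ttest_summary_from_data

logger = logging.getLogger("knowjudge")

ANSWER_COLUMNS = ["participant_id", "category_id", "question_index",
                  "correct", "selection"]


@dataclass(frozen=True)
class KnowledgeProfile:
    """One participant's answers and accuracy in one category."""

    participant_id: str
    category_id: str
    answers: tuple[int, ...]  # 1 correct / 0 incorrect, question order
    selection: str            # self_selected | assigned

    @property
    def theta(self) -> float:
        return float(np.mean(self.answers))

    @property
    def n_questions(self) -> int:
        return len(self.answers)


@dataclass(frozen=True)
class CeilingEstimate:
    """Monte-Carlo split-half discrimination ceiling."""

    probability: float
    n_splits: int
    n_pairs: int
    seed: int


def score_knowledge(answers: pd.DataFrame,
                    questions_per_category: int | None = None) -> list[KnowledgeProfile]:
    """One KnowledgeProfile per participant x category.

    ``answers`` has columns participant_id, category_id, question_index,
    correct (0/1; timed-out questions are recorded as 0), selection.
    """
    missing = [c for c in ANSWER_COLUMNS if c not in answers.columns]
    if missing:
        raise InvalidInputError(f"answers table missing columns {missing}")
    dup = answers.duplicated(["participant_id", "category_id", "question_index"])
    if dup.any():
        raise InvalidInputError(
            f"{int(dup.sum())} duplicate (participant, category, question) rows")
    profiles = []
    for (pid, cat), grp in answers.groupby(["participant_id", "category_id"],
                                           sort=True):
        grp = grp.sort_values("question_index")
        vec = tuple(int(v) for v in grp["correct"])
        if questions_per_category is not None and len(vec) != questions_per_category:
            raise InvalidInputError(
                f"participant {pid} category {cat}: {len(vec)} answers, "
                f"expected {questions_per_category}")
        sel = grp["selection"].iloc[0]
        profiles.append(KnowledgeProfile(str(pid), str(cat), vec, str(sel)))
    return profiles


def selection_contrast(profiles: Sequence[KnowledgeProfile]) -> dict:
    """Self-selected vs. assigned category accuracy, with a paired JZS BF.

    Each participant contributes one mean accuracy per selection condition;
    participants missing a condition are excluded with a logged warning.
    """
    per = {}
    for p in profiles:
        per.setdefault(p.participant_id, {}).setdefault(p.selection, []).append(p.theta)
    sel, asg = [], []
    for pid, conds in sorted(per.items()):
        if "self_selected" not in conds or "assigned" not in conds:
            logger.warning("participant %s lacks a selection condition; excluded", pid)
            continue
        sel.append(float(np.mean(conds["self_selected"])))
        asg.append(float(np.mean(conds["assigned"])))
    if len(sel) < 3:
        raise InvalidInputError("need at least 3 complete participants")
    sel_arr, asg_arr = np.asarray(sel), np.asarray(asg)
    diff = sel_arr - asg_arr
    if np.allclose(diff, diff.mean()):
        # zero-variance differences: t is degenerate; the data either satisfy
        # the null exactly or separate the conditions perfectly
        from .bayes import BF_DISPLAY_CAP
        bf = (BayesFactorResult(bf10=1e-6, method="jzs_ttest")
              if np.allclose(diff, 0)
              else BayesFactorResult(bf10=BF_DISPLAY_CAP + 1, method="jzs_ttest",
                                     capped=True))
    else:
        bf = jzs_ttest_bf10(ttest_summary_from_data(sel_arr, asg_arr, "paired"))
    return {
        "mean_self_selected": float(sel_arr.mean()),
        "mean_assigned": float(asg_arr.mean()),
        "difference": float(diff.mean()),
        "n_participants": len(sel),
        "bf10": bf.bf10,
        "bf_display": bf.display,
    }


def _validate_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.size != b.size:
        raise InvalidInputError("pair answer vectors must have equal length")
    if a.size % 2 != 0:
        raise InvalidInputError("answer vectors must have even length")
    if int(a.sum()) == int(b.sum()):
        raise InvalidInputError(
            "pair members have identical accuracy; the discrimination "
            "ground truth is undefined")


def split_half_pair(a: Sequence[int], b: Sequence[int], n_splits: int,
                    rng: np.random.Generator) -> float:
    """Mean split-half prediction credit for one informant pair.

    For each split, half the question indices are sampled without
    replacement; the member with more correct answers on that half is
    predicted to win the unseen half.  Ties at either stage earn 0.5 credit.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    _validate_pair(a, b)
    q = a.size
    half = q // 2
    d = a - b  # per-question advantage of A
    total = int(d.sum())
    # vectorised over splits: random permutation per split via argsort of
    # uniforms, first `half` columns are the seen indices
    u = rng.random((n_splits, q))
    order = np.argsort(u, axis=1)
    seen = order[:, :half]
    seen_adv = d[seen].sum(axis=1)
    unseen_adv = total - seen_adv
    credit = np.where(
        seen_adv == 0, 0.5,
        np.where(np.sign(seen_adv) == np.sign(unseen_adv), 1.0,
                 np.where(unseen_adv == 0, 0.5, 0.0)))
    return float(credit.mean())


def split_half_ceiling(pairs: Iterable[tuple[Sequence[int], Sequence[int]]],
                       n_splits: int = 10_000,
                       seed: int = 0) -> CeilingEstimate:
    """Split-half discrimination ceiling averaged over informant pairs.

    Each pair is weighted once regardless of how many trials used it; splits
    are drawn independently per pair.
    """
    rng = np.random.default_rng(seed)
    vals = [split_half_pair(a, b, n_splits, rng) for a, b in pairs]
    if not vals:
        raise InvalidInputError("no informant pairs supplied")
    return CeilingEstimate(probability=float(np.mean(vals)),
                           n_splits=n_splits, n_pairs=len(vals), seed=seed)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_answers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "category_id": str,
                                  "selection": str})
    missing = [c for c in ANSWER_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"answers table {path} missing columns {missing}")
    if not df["correct"].isin([0, 1]).all():
        raise InvalidInputError("correct column must be 0/1")
    return df


def write_answers(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=ANSWER_COLUMNS)


def profiles_by_key(profiles: Sequence[KnowledgeProfile]) -> dict:
    return {(p.participant_id, p.category_id): p for p in profiles}
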