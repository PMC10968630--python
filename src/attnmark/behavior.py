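"""Attentional Control Scale scoring and flanker behavioral summaries.

The ACS is a 20-item self-report scale, each item rated 1–4; reverse-keyed
items are mapped x -> 5 - x before summing, so totals span 20–80 with higher
scores meaning stronger belief in one's attentional control.  Which items
are reverse-keyed varies between scale versions, so the reverse set is an
argument rather than a constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["N_ITEMS", "score_acs", "summarize_behavior"]

N_ITEMS = 20
ITEM_MIN, ITEM_MAX = 1, 4


def score_acs(item_scores, reverse_items: frozenset[int] | set[int] = frozenset()) -> int:
    """Total ACS score from 20 item responses.

    ``reverse_items`` holds 0-based indices of reverse-keyed items.  Raises
    with the full list of offending items on invalid input.
    """
    items = list(item_scores)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {len(items)}")
    bad = [
        i
        for i, x in enumerate(items)
        if not (isinstance(x, (int, np.integer)) and ITEM_MIN <= x <= ITEM_MAX)
    ]
    if bad:
        raise ValueError(f"items out of range [{ITEM_MIN}, {ITEM_MAX}] at indices {bad}")
    bad_rev = sorted(i for i in reverse_items if not 0 <= i < N_ITEMS)
    if bad_rev:
        raise ValueError(f"reverse-item indices out of range: {bad_rev}")
    total = sum(
        (ITEM_MAX + 1 - x) if i in reverse_items else x for i, x in enumerate(items)
    )
    return int(total)


def summarize_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean RT over correct trials, accuracy, and their SEs.

    RT summaries use correct trials only (incorrect-response RTs reflect a
    different process and are conventionally excluded); accuracy uses all
    trials.  Returns one row per condition with columns
    ``rt_mean, rt_se, accuracy, accuracy_se, n_trials, n_correct``.
    """
    rows = []
    for cond, grp in trials.groupby("condition", sort=True):
        correct = grp[grp["correct"].astype(bool)]
        if correct.empty:
            raise ValueError(f"condition {cond!r} has no correct trials")
        rts = correct["rt_ms"].astype(float).to_numpy()
        n, k = len(grp), len(correct)
        acc = k / n
        rows.append(
            {
                "condition": cond,
                "rt_mean": float(rts.mean()),
                "rt_se": float(rts.std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
                "accuracy": acc,
                "accuracy_se": float(np.sqrt(acc * (1 - acc) / n)),
                "n_trials": n,
                "n_correct": k,
            }
        )
    return pd.DataFrame(rows).set_index("condition")
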