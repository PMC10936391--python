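"""Per-synapse aggregation, per-neuron voting, and evaluation.

A synapse spans several consecutive z-frames; its call is the majority
class over the frame-level argmax predictions, with ties broken by the
higher mean probability.  Per presynaptic neuron, synapse calls are
tallied as votes: the majority valence is the neuron's prediction unless
the evidence is weak — fewer than ``min_votes`` total votes, or the
larger count not strictly more than ``ratio_threshold`` times the smaller
— in which case the call is *inconclusive*.

Precision here is the standard TP / (TP + FP) and recall TP / (TP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VoteTally", "aggregate_synapse", "vote_neuron", "evaluate"]

EXC, INH = "excitatory", "inhibitory"


@dataclass(frozen=True)
class VoteTally:
    pre_cell_id: str
    n_excitatory: int
    n_inhibitory: int
    decision: str                  # excitatory | inhibitory | inconclusive
    ratio_threshold: float = 1.5
    min_votes: int = 3


def aggregate_synapse(frame_probs) -> str:
    """Synapse-level class from per-frame probability 2-vectors.

    Majority over frame argmaxes (index 1 = excitatory); a tie goes to the
    class with the higher mean probability.
    """
    probs = np.asarray(frame_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("aggregate_synapse requires at least one frame")
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError(f"expected (n_frames, 2) probabilities, got {probs.shape}")
    votes_exc = int((probs.argmax(axis=1) == 1).sum())
    votes_inh = len(probs) - votes_exc
    if votes_exc != votes_inh:
        return EXC if votes_exc > votes_inh else INH
    mean = probs.mean(axis=0)
    return EXC if mean[1] >= mean[0] else INH


def vote_neuron(
    synapse_calls,
    pre_cell_id: str | None = None,
    ratio_threshold: float = 1.5,
    min_votes: int = 3,
) -> VoteTally:
    """Tally synapse calls of one presynaptic neuron into a decision.

    ``synapse_calls`` is either a sequence of class strings or of
    (pre_cell_id, class) pairs; mixed cell IDs are an error.  Conclusive
    requires total votes >= ``min_votes`` AND the winning count strictly
    greater than ``ratio_threshold`` x the losing count (so 6 vs 4 at 1.5
    is inconclusive).
    """
    calls = list(synapse_calls)
    cells = set()
    labels = []
    for c in calls:
        if isinstance(c, str):
            labels.append(c)
        else:
            cells.add(c[0])
            labels.append(c[1])
    if pre_cell_id is not None:
        cells.add(pre_cell_id)
    if len(cells) > 1:
        raise ValueError(f"synapse calls from multiple cells: {sorted(cells)}")
    cell = next(iter(cells)) if cells else ""
    bad = {l for l in labels if l not in (EXC, INH)}
    if bad:
        raise ValueError(f"unknown valence labels: {sorted(bad)}")
    n_exc = labels.count(EXC)
    n_inh = labels.count(INH)
    hi, lo = max(n_exc, n_inh), min(n_exc, n_inh)
    if n_exc + n_inh < min_votes or hi <= ratio_threshold * lo:
        decision = "inconclusive"
    else:
        decision = EXC if n_exc > n_inh else INH
    return VoteTally(cell, n_exc, n_inh, decision,
                     ratio_threshold=ratio_threshold, min_votes=min_votes)


def evaluate(calls: dict, truth: dict, positive_class: str = EXC) -> dict:
    """Precision/recall per class plus the confusion matrix.

    ``calls`` and ``truth`` map the same IDs (synapse or cell) to class
    labels; a key mismatch is an error rather than a silent join.
    Inconclusive calls are excluded from the confusion matrix but counted.
    """
    if set(calls) != set(truth):
        missing = set(truth) ^ set(calls)
        raise ValueError(f"calls/truth ID mismatch: {sorted(missing)[:5]} ...")
    ids = sorted(calls)
    y_pred = [calls[i] for i in ids]
    y_true = [truth[i] for i in ids]
    classes = [INH, EXC]
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    n_inconclusive = 0
    for t, p in zip(y_true, y_pred):
        if p == "inconclusive":
            n_inconclusive += 1
            continue
        cm.loc[t, p] += 1
    metrics = {}
    for c in classes:
        tp = int(cm.loc[c, c])
        fp = int(cm[c].sum()) - tp
        fn = int(cm.loc[c].sum()) - tp
        metrics[c] = {
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "recall": tp / (tp + fn) if tp + fn else 0.0,
        }
    return {
        "per_class": metrics,
        "confusion_matrix": cm,
        "accuracy": float(np.trace(cm.values) / cm.values.sum())
        if cm.values.sum() else 0.0,
        "n_inconclusive": n_inconclusive,
    }
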