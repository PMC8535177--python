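"""Time-normalized attention saliency curves.

Sessions differ in length, so per-utterance attention weights are first
mapped onto a fixed grid of relative-position bins (utterance t of a
length-L profile lands in bin floor(t * n_bins / L)).  Binned mass is
rescaled by n_bins so a perfectly uniform attention profile maps to the
constant 1.0 — curves from sessions of any length share a common "uniform
level" and can be averaged and compared directly.  Aggregating the held-out
(test-fold) profiles of one attention head across sessions gives that
code's mean saliency curve: where in the session the model looks when
scoring the code.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .models import AttentionProfile

MEAN_OF_CODES = "mean-of-codes"


@dataclass
class SaliencyCurve:
    head_id: str
    bins: np.ndarray  # (n_bins,), uniform attention ~ 1.0 everywhere
    n_sessions: int


def normalize_attention_time(profile: AttentionProfile, n_bins: int = 100) -> np.ndarray:
    """Bin one attention profile onto the relative-position grid.

    The result sums to n_bins (i.e., averages to 1.0), so a uniform profile
    gives every bin value 1.0 regardless of session length.
    """
    w = np.asarray(profile.weights, dtype=float)
    L = w.size
    if L < 1:
        raise ValueError("empty attention profile")
    idx = (np.arange(L) * n_bins) // L
    binned = np.bincount(idx, weights=w, minlength=n_bins)
    return binned * n_bins


def aggregate_saliency(
    profiles_by_head: Dict[str, Sequence[AttentionProfile]],
    n_bins: int = 100,
    add_mean_of_codes: bool = True,
) -> List[SaliencyCurve]:
    """Element-wise mean of binned curves per head, over sessions.

    Heads with no profiles are omitted with a warning.  When the 11
    per-code heads are all present, an extra "mean-of-codes" curve — the
    unweighted average of the 11 per-code curves — is appended.
    """
    from .transcript_io import CTRS_CODES

    curves: List[SaliencyCurve] = []
    for head_id, profiles in profiles_by_head.items():
        if not profiles:
            warnings.warn(f"attention head {head_id!r} has no profiles; omitted")
            continue
        binned = np.stack([normalize_attention_time(p, n_bins) for p in profiles])
        curves.append(SaliencyCurve(head_id=head_id, bins=binned.mean(axis=0),
                                    n_sessions=len(profiles)))
    by_id = {c.head_id: c for c in curves}
    if add_mean_of_codes and all(c in by_id for c in CTRS_CODES):
        stackc = np.stack([by_id[c].bins for c in CTRS_CODES])
        curves.append(SaliencyCurve(
            head_id=MEAN_OF_CODES, bins=stackc.mean(axis=0),
            n_sessions=by_id[CTRS_CODES[0]].n_sessions,
        ))
    return curves


def decile_means(curve: SaliencyCurve) -> np.ndarray:
    """Mean saliency in each tenth of the session (10 values)."""
    return np.asarray(curve.bins).reshape(10, -1).mean(axis=1)


def collect_profiles(predictions: Iterable) -> Dict[str, List[AttentionProfile]]:
    """Group the attention profiles of a prediction set by head id."""
    out: Dict[str, List[AttentionProfile]] = {}
    for p in predictions:
        for prof in p.attention:
            out.setdefault(prof.head_id, []).append(prof)
    return out


def curves_to_csv(curves: Sequence[SaliencyCurve], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["head_id", "bin", "value"])
        for c in curves:
            for i, v in enumerate(c.bins):
                w.writerow([c.head_id, i, f"{v:.6g}"])


def plot_curves(curves: Sequence[SaliencyCurve], path, heads: Sequence[str] = None) -> None:
    """Line plot of selected saliency curves (all heads by default)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chosen = [c for c in curves if heads is None or c.head_id in heads]
    fig, ax = plt.subplots(figsize=(7, 4))
    x = None
    for c in chosen:
        x = np.linspace(0, 1, len(c.bins), endpoint=False)
        ax.plot(x, c.bins, label=c.head_id)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--", label="uniform level")
    ax.set_xlabel("relative position in session")
    ax.set_ylabel("mean normalized attention")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
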