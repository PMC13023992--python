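"""Label construction from spirometry ratios, vote fusion and the S index.

Each subject carries three ratios v_k = measured/predicted for FEF25-75,
FEF50 and FEF75.  An index is abnormal when v_k < 0.65 (strict); the
subject-level hard label is SAD when at least two of the three are abnormal.
Training targets are sigmoid-smoothed soft labels

    y_soft(k) = sigmoid(lambda * (v_th - v_k)),   lambda = 20, v_th = 0.65,

which equal 0.5 exactly at the clinical cutoff.  At inference the three head
probabilities are binarised at tau = 0.5 (the >= side counts as abnormal) and
fused by majority vote.  The impairment index

    S = y1*y2 + y2*y3 + y1*y3 - 2*y1*y2*y3

is the multilinear extension of that majority vote to the unit cube; it is
used for reporting and embedding analysis only, never in the loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LabelConfig", "hard_label", "soft_labels", "vote", "impairment_index"]


@dataclass(frozen=True)
class LabelConfig:
    vth: float = 0.65
    lam: float = 20.0
    tau: float = 0.5

    def __post_init__(self) -> None:
        if self.vth <= 0 or self.lam <= 0:
            raise ValueError("vth and lam must be positive")
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def hard_label(v1: float, v2: float, v3: float, cfg: LabelConfig = LabelConfig()) -> int:
    """1 (SAD) iff at least two ratios fall strictly below the threshold."""
    v = np.asarray([v1, v2, v3], dtype=float)
    if np.any(v <= 0):
        raise ValueError("spirometry ratios must be positive")
    return int(np.sum(v < cfg.vth) >= 2)


def soft_labels(v1: float, v2: float, v3: float, cfg: LabelConfig = LabelConfig()) -> np.ndarray:
    """Element-wise sigmoid(lam * (vth - v_k)); 0.5 exactly at v_k = vth."""
    v = np.asarray([v1, v2, v3], dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("spirometry ratios must be finite")
    return _sigmoid(cfg.lam * (cfg.vth - v))


def vote(probabilities, cfg: LabelConfig = LabelConfig()) -> tuple[np.ndarray, int]:
    """Binarise the three head probabilities at tau (>= counts abnormal) and
    take the majority as the SAD decision."""
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (3,):
        raise ValueError("expected exactly three subtask probabilities")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    votes = (p >= cfg.tau).astype(int)
    return votes, int(votes.sum() >= 2)


def impairment_index(y_soft) -> float:
    """S = y1*y2 + y2*y3 + y1*y3 - 2*y1*y2*y3, in [0, 1] on the unit cube.

    Reduces to the majority-vote indicator on binary inputs.
    """
    y = np.asarray(y_soft, dtype=float)
    if y.shape != (3,):
        raise ValueError("expected three soft-label components")
    if np.any(y < 0.0) or np.any(y > 1.0):
        raise ValueError("soft-label components must lie in [0, 1]")
    y1, y2, y3 = y
    return float(y1 * y2 + y2 * y3 + y1 * y3 - 2.0 * y1 * y2 * y3)
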