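"""Confidence-gated fusion of model probabilities with a reader verdict.

The machine-learning-aided diagnosis (MLAD) rule cascades the primary
model (SVM), the sub-model (RF) and the radiologist's binary call. Each
model's confidence is its distance from maximal uncertainty,
``S = |0.5 - P|`` in [0, 0.5]. The fused score is the nested convex
combination

    S_MLAD = w1 * P_SVM + (1 - w1) * [ w2 * P_RF + (1 - w2) * V_R ]

with gates ``w1 = S_SVM / 0.5 = 2*S_SVM`` and ``w2 = 2*S_RF``: a confident
SVM dominates, an uncertain SVM defers to the RF, and when both models sit
at P = 0.5 the reader decides outright. Note the rule is deliberately
non-monotone in P_RF — the sub-model's contribution ``2|0.5-P_RF|*P_RF``
peaks inside (0, 0.5) — which is a property of the published rule, not a
defect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FusionCase", "FusionResult", "mlad_score", "mlad_classify", "fuse_cohort"]


@dataclass(frozen=True)
class FusionCase:
    """One patient's inputs to the fusion rule."""

    p_svm: float
    p_rf: float
    v_r: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_svm <= 1:
            raise ValueError(f"p_svm must be in [0, 1], got {self.p_svm}")
        if not 0 <= self.p_rf <= 1:
            raise ValueError(f"p_rf must be in [0, 1], got {self.p_rf}")
        if self.v_r not in (0, 1):
            raise ValueError(f"v_r must be 0 or 1, got {self.v_r}")


@dataclass(frozen=True)
class FusionResult:
    """Confidence gates and the fused malignancy score for one case."""

    s_svm: float
    s_rf: float
    s_mlad: float
    call: int


def mlad_score(case: FusionCase) -> FusionResult:
    """Apply the fusion rule to one case (threshold 0.5, ties malignant)."""
    s_svm = abs(0.5 - case.p_svm)
    s_rf = abs(0.5 - case.p_rf)
    w1 = 2.0 * s_svm
    w2 = 2.0 * s_rf
    inner = w2 * case.p_rf + (1.0 - w2) * case.v_r
    s_mlad = w1 * case.p_svm + (1.0 - w1) * inner
    return FusionResult(s_svm, s_rf, s_mlad, mlad_classify(s_mlad))


def mlad_classify(s_mlad: float, threshold: float = 0.5) -> int:
    """Binary call from the fused score: 1 iff score >= threshold.

    A score exactly at the threshold is called malignant — the
    conservative direction for a cancer screen.
    """
    return int(s_mlad >= threshold)


def fuse_cohort(
    p_svm: np.ndarray, p_rf: np.ndarray, v_r: np.ndarray,
    threshold: float = 0.5,
) -> dict[str, np.ndarray]:
    """Vectorised fusion of a cohort.

    Returns arrays ``s_svm``, ``s_rf``, ``s_mlad`` and ``call``. Inputs
    are validated, never clamped: calibrating the upstream probabilities
    is the caller's responsibility.
    """
    p_svm = np.asarray(p_svm, dtype=float)
    p_rf = np.asarray(p_rf, dtype=float)
    v_r = np.asarray(v_r)
    if not (len(p_svm) == len(p_rf) == len(v_r)):
        raise ValueError(
            f"length mismatch: p_svm={len(p_svm)}, p_rf={len(p_rf)}, v_r={len(v_r)}"
        )
    for name, arr in (("p_svm", p_svm), ("p_rf", p_rf)):
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError(f"{name} contains values outside [0, 1]")
    if not np.isin(v_r, (0, 1)).all():
        raise ValueError("v_r must be binary 0/1")
    s_svm = np.abs(0.5 - p_svm)
    s_rf = np.abs(0.5 - p_rf)
    w1 = 2.0 * s_svm
    w2 = 2.0 * s_rf
    inner = w2 * p_rf + (1.0 - w2) * v_r
    s_mlad = w1 * p_svm + (1.0 - w1) * inner
    return {
        "s_svm": s_svm,
        "s_rf": s_rf,
        "s_mlad": s_mlad,
        "call": (s_mlad >= threshold).astype(int),
    }
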