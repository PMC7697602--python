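"""Exactly specified phenotype and qPCR calculators.

Two small formulas used alongside the genomic analyses: nitrogen use
efficiency (NUE) from dry weight and nitrogen accumulation, and relative
gene expression from RT-qPCR cycle thresholds by the 2^−ΔΔCT method with
multi-reference-gene normalization.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def nue(total_dry_weight_g: float, total_n_accumulation_g: float) -> float:
    """Nitrogen use efficiency: g dry weight produced per g plant N.

    NUE = total plant dry weight (g) / total plant N accumulation (g).
    """
    if total_n_accumulation_g <= 0:
        raise ValueError("N accumulation must be positive")
    if total_dry_weight_g < 0:
        raise ValueError("dry weight must be nonnegative")
    return total_dry_weight_g / total_n_accumulation_g


def _ref_ct(ref: float | Sequence[float]) -> float:
    """Combine reference-gene CT values by geometric mean."""
    arr = np.atleast_1d(np.asarray(ref, dtype=float))
    if np.any(arr <= 0):
        raise ValueError("CT values must be positive")
    return float(np.exp(np.mean(np.log(arr))))


def relative_expression(
    treated_target_ct: float,
    treated_ref_ct: float | Sequence[float],
    control_target_ct: float,
    control_ref_ct: float | Sequence[float],
) -> float:
    """Relative expression by 2^−ΔΔCT.

    ΔCT = CT_target − CT_reference within each condition; ΔΔCT is the
    treated ΔCT minus the control ΔCT, and the fold change is 2^−ΔΔCT.
    When several reference genes are supplied their CT values are combined
    by geometric mean before forming ΔCT.
    """
    if treated_target_ct <= 0 or control_target_ct <= 0:
        raise ValueError("CT values must be positive")
    d_treated = treated_target_ct - _ref_ct(treated_ref_ct)
    d_control = control_target_ct - _ref_ct(control_ref_ct)
    return float(2.0 ** -(d_treated - d_control))
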