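"""Shared physical constants and substate label conventions."""

from __future__ import annotations

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

#: Joint zeta substate labels, Watson strand first ("g-g-" is the BI/BI
#: reference, "tt" is BII/BII).  Order is fixed and used for transition
#: matrices and thermodynamic tables.
SUBSTATES = ("g-g-", "tg-", "g-t", "tt")

#: Number of strands in the t (BII) conformer for each joint label.
N_T_STRANDS = {"g-g-": 0, "tg-": 1, "g-t": 1, "tt": 2}

#: Allowed single-flip edges of the joint-substate graph.  Direct
#: g-g- <-> tt jumps require both strands to flip in the same picosecond
#: and are excluded by construction.
SUBSTATE_EDGES = (("g-g-", "tg-"), ("g-g-", "g-t"), ("tg-", "tt"), ("g-t", "tt"))


def kt_kcal(temperature_K: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature."""
    if not temperature_K > 0:
        raise ValueError(f"temperature_K must be positive, got {temperature_K}")
    return R_KCAL * temperature_K
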