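"""Named parameter presets for the synthetic generator.

Each preset fixes the generator at the published statistics of one
tetranucleotide/cation system: the two-component twist mixture (means, SDs
and weights in degrees), the minor-groove occupancy fraction and mean
residence time of the cation at the central CG step, and (for sodium
systems, where the full substate table is available) the substate free
energies and per-substate mean twist.

"TCGA-K" is the most polymorphic system (LT weight 0.70, occupancy 30.8%,
residence 11.3 ps) and is the default simulation preset.  "CHOREO" is the
study condition for event-aligned kinetics: strong ion -> backbone coupling
with a programmed 45 ps mean ion lead, a low-baseline BII/BII substate
ladder, and a 25 ps mean residence standing in for the long-lived binding
events (real residence distributions are heavy-tailed, with stays up to
~1 ns, which a geometric run model cannot reproduce at a short mean).
"""

from __future__ import annotations

from dataclasses import replace

from .synthgen import SyntheticModelParams

__all__ = ["PRESETS", "get_preset"]


def _p(**kw) -> SyntheticModelParams:
    return SyntheticModelParams(**kw)


PRESETS = {
    # potassium, most polymorphic tetranucleotide
    "TCGA-K": _p(
        lt_mean=18.0, lt_sd=6.7, lt_weight=0.70, ht_mean=32.3, ht_sd=5.0,
        substate_dG={"g-g-": 0.0, "tg-": 0.3, "g-t": 0.3, "tt": -0.2},
        substate_twist_mean={"g-g-": 33.4, "tg-": 26.2, "g-t": 26.3, "tt": 16.3},
        ion_mean_residence_ps=11.3, ion_occupancy_frac=0.308,
        ion_species="K+", p_bii_given_ion=0.80,
    ),
    "TCGA-Na": _p(
        lt_mean=20.1, lt_sd=7.0, lt_weight=0.69, ht_mean=33.5, ht_sd=5.0,
        substate_dG={"g-g-": 0.0, "tg-": 0.3, "g-t": 0.3, "tt": -0.2},
        substate_twist_mean={"g-g-": 33.4, "tg-": 26.2, "g-t": 26.3, "tt": 16.3},
        ion_mean_residence_ps=5.8, ion_occupancy_frac=0.240,
        ion_species="Na+", p_bii_given_ion=0.65,
    ),
    "ACGA-K": _p(
        lt_mean=26.5, lt_sd=8.2, lt_weight=0.47, ht_mean=34.2, ht_sd=5.0,
        substate_dG={"g-g-": 0.0, "tg-": 0.5, "g-t": 1.8, "tt": 1.3},
        substate_twist_mean={"g-g-": 35.2, "tg-": 28.0, "g-t": 27.1, "tt": 17.3},
        ion_mean_residence_ps=6.0, ion_occupancy_frac=0.128,
        ion_species="K+", p_bii_given_ion=0.80,
    ),
    "ACGA-Na": _p(
        lt_mean=28.0, lt_sd=7.6, lt_weight=0.48, ht_mean=35.0, ht_sd=5.2,
        substate_dG={"g-g-": 0.0, "tg-": 0.5, "g-t": 1.8, "tt": 1.3},
        substate_twist_mean={"g-g-": 35.2, "tg-": 28.0, "g-t": 27.1, "tt": 17.3},
        ion_mean_residence_ps=6.7, ion_occupancy_frac=0.181,
        ion_species="Na+", p_bii_given_ion=0.65,
    ),
    "GCGA-Na": _p(
        lt_mean=21.4, lt_sd=6.4, lt_weight=0.52, ht_mean=32.7, ht_sd=5.5,
        substate_dG={"g-g-": 0.0, "tg-": 0.2, "g-t": 1.0, "tt": 0.3},
        substate_twist_mean={"g-g-": 33.7, "tg-": 26.2, "g-t": 26.5, "tt": 17.3},
        ion_mean_residence_ps=6.5, ion_occupancy_frac=0.238,
        ion_species="Na+", p_bii_given_ion=0.65,
    ),
    # event-aligned kinetics study condition (see module docstring)
    "CHOREO": _p(
        lt_mean=28.0, lt_sd=7.6, lt_weight=0.48, ht_mean=35.0, ht_sd=5.2,
        substate_dG={"g-g-": 0.0, "tg-": 0.5, "g-t": 1.8, "tt": 1.3},
        substate_twist_mean={"g-g-": 35.2, "tg-": 28.0, "g-t": 27.1, "tt": 17.3},
        ion_mean_residence_ps=25.0, ion_occupancy_frac=0.30,
        ion_species="K+", ion_lead_time_ps=45.0, p_bii_given_ion=0.80,
    ),
}


def get_preset(name: str, **overrides) -> SyntheticModelParams:
    """Look up a preset by name, optionally overriding fields."""
    try:
        params = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(params, **overrides) if overrides else params
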