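"""Reference parameter sets for the published switch benchmarks.

Each preset is a flat key/value mapping in the same schema the config
reader accepts; keys carry explicit units.  Dissociation constants are
stored as the published table entries together with the notation convention
under which they are resolved to raw concentrations (see
:func:`txswitch.models.resolve_constant`).

Preset notes
------------
* ``fig1`` — four-binding-site cooperative switch, operating point
  RT = c^1.5 * Omega * Kr = 100 (transcriptional activity ~ 0.5).
* ``fig2_hill4`` / ``fig3_hill50`` — indirect-repression switches matched to
  effective Hill responses of ~4 and ~50 respectively.
* ``fig4_nfl`` — negative-feedback oscillator.  The activator total here is
  10^3: the feedback's repressor production saturates near 7e3 copies, so
  the titration threshold must sit below that for the loop to oscillate
  (see docs/methods.md).
* ``fig5_multitarget`` — shared-activator competition, same constants as
  ``fig2_hill4`` with the faster mRNA turnover of the oscillator setting.
"""

from __future__ import annotations

import math

LN2 = math.log(2.0)

PRESETS: dict[str, dict] = {
    "fig1": {
        "model": "cooperative",
        "omega_aL": 1e7,
        "kf_aL_per_ymol_min": 600.0,
        "halflife_min": 984.5,
        "alpha_over_beta": 100.0,
        "cooperativity_c": 1e-2,
        "Kr_ymol_per_aL": 1e-2,
        "RT_count": 100.0,
        "mode": "repressor_inhibits",
    },
    "fig2_hill4": {
        "model": "indirect",
        "mechanisms": "SBD",
        "omega_aL": 1e7,
        "kf_aL_per_ymol_min": 600.0,
        "halflife_min": 984.5,
        "alpha_over_beta": 100.0,
        "AT_count": 1e3,
        "RT_count": 0.0,
        "constant_convention": "per_activator",
        "Ks_printed": 4.5e-10,
        "Ka_printed": 7e-9,
        "Kb_printed": 1e-6,
    },
    "fig3_hill50": {
        "model": "indirect",
        "mechanisms": "SBD",
        "omega_aL": 1e7,
        "kf_aL_per_ymol_min": 600.0,
        "halflife_min": 984.5,
        "alpha_over_beta": 100.0,
        "AT_count": 1e3,
        "RT_count": 0.0,
        "constant_convention": "per_activator",
        "Ks_printed": 6e-13,
        "Ka_printed": 6e-11,
        "Kb_printed": 1e-6,
    },
    "fig4_nfl": {
        "model": "nfl",
        "mechanisms": "SBD",
        "omega_aL": 1e7,
        "kf_aL_per_ymol_min": 600.0,
        "halflife_min": 120.0,
        "alpha_over_beta": 100.0,
        "alpha2_per_min": 5.0 / 12.0,
        "alpha3_per_min": 5.0 / 12.0,
        "AT_count": 1e3,
        "constant_convention": "per_activator",
        "Ks_printed": 9e-12,
        "Ka_printed": 2e-9,
        "Kb_printed": 5e-9,
        "table_literal": False,
    },
    "fig5_multitarget": {
        "model": "multitarget",
        "mechanisms": "SBD",
        "omega_aL": 1e7,
        "kf_aL_per_ymol_min": 600.0,
        "halflife_min": 120.0,
        "alpha_over_beta": 100.0,
        "AT_count": 1e3,
        "RT_count": 0.0,
        "DT_count": 0,
        "constant_convention": "per_activator",
        "Ks_printed": 4.5e-10,
        "Ka_printed": 7e-9,
        "Kb_printed": 1e-6,
    },
}
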