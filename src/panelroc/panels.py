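"""The default biomarker panel and its functional-domain structure.

The screening model groups its markers into six functional domains:

* ``visual`` — symbol attention span, visual processing-speed discrepancy,
  right-eye distance acuity (3 markers);
* ``auditory`` — reverse digit span, competing-words (dichotic listening)
  discrepancy, auditory processing-speed discrepancy (3 markers);
* ``catecholamine`` — urinary dopamine, noradrenaline, adrenaline (3);
* ``oxidative_stress`` — urinary HPL normalised to creatinine (1);
* ``biochemistry_nutrition`` — free-copper:zinc ratio, activated B6, red-cell
  folate, serum B12, vitamin D (5);
* ``middle_ear`` — six acoustic-reflex / tympanometry parameters, a
  supplementary domain that extends the 15-marker model to 21 markers.

Each marker's simulated discriminative strength (``target_auc``) and MCAR
missingness rate reproduce the published case-control characteristics of
the corresponding measurement; control means/SDs are plausible clinical
scales and only anchor units (the cascade is scale-free).
"""

from __future__ import annotations

from .cohort import CohortConfig, VariableSpec
from .roc import Direction
from .scoring import DomainMap

__all__ = [
    "DOMAIN_ORDER",
    "default_variables",
    "default_panel_config",
    "default_domain_map",
]

DOMAIN_ORDER = (
    "visual",
    "auditory",
    "catecholamine",
    "oxidative_stress",
    "biochemistry_nutrition",
    "middle_ear",
)

# name, domain, direction, control_mean, control_sd, target_auc, n_obs/134
_PANEL = [
    ("visual_span", "visual", Direction.LOW, 5.8, 1.1, 0.862, 126),
    ("visual_speed_discrepancy", "visual", Direction.HIGH, 8.0, 14.0, 0.875, 122),
    ("distance_vision_right", "visual", Direction.LOW, 0.95, 0.25, 0.597, 128),
    ("reverse_digit_span", "auditory", Direction.LOW, 4.9, 1.3, 0.810, 127),
    ("competing_words_discrepancy", "auditory", Direction.HIGH, 5.0, 12.0, 0.799, 124),
    ("auditory_speed_discrepancy", "auditory", Direction.HIGH, 6.0, 13.0, 0.874, 121),
    ("dopamine", "catecholamine", Direction.HIGH, 160.0, 55.0, 0.702, 133),
    ("noradrenaline", "catecholamine", Direction.HIGH, 30.0, 11.0, 0.851, 133),
    ("adrenaline", "catecholamine", Direction.HIGH, 5.5, 2.4, 0.844, 133),
    ("hpl_creatinine", "oxidative_stress", Direction.HIGH, 0.65, 0.30, 0.696, 133),
    ("free_copper_zinc_ratio", "biochemistry_nutrition", Direction.HIGH, 1.0, 0.35, 0.611, 133),
    ("b6_activation", "biochemistry_nutrition", Direction.LOW, 48.0, 16.0, 0.638, 129),
    ("red_cell_folate", "biochemistry_nutrition", Direction.LOW, 780.0, 210.0, 0.654, 133),
    ("serum_b12", "biochemistry_nutrition", Direction.HIGH, 330.0, 110.0, 0.565, 134),
    ("vitamin_d", "biochemistry_nutrition", Direction.LOW, 72.0, 22.0, 0.651, 132),
    ("ear_canal_volume", "middle_ear", Direction.HIGH, 1.25, 0.35, 0.603, 123),
    ("middle_ear_pressure_peak", "middle_ear", Direction.LOW, -20.0, 35.0, 0.617, 124),
    ("middle_ear_pressure_gradient", "middle_ear", Direction.HIGH, 95.0, 40.0, 0.580, 124),
    ("stapes_amplitude", "middle_ear", Direction.HIGH, 0.45, 0.15, 0.626, 123),
    ("stapes_offset_base_ratio", "middle_ear", Direction.LOW, 1.9, 0.6, 0.659, 122),
    ("stapes_base_duration_pct", "middle_ear", Direction.HIGH, 55.0, 14.0, 0.657, 122),
]

_N_REFERENCE = 134  # cohort size the observed-count missingness rates refer to


def default_variables(n_markers: int = 15) -> tuple[VariableSpec, ...]:
    """The 15-marker (5-domain) or 21-marker (6-domain) panel specs.

    Missingness rates are derived from the observed per-marker case counts
    (1 - n_obs/134), spanning roughly 0-10% with lab markers near 0-1.5% and
    sensory-processing markers near 5-10%.
    """
    if n_markers not in (15, 21):
        raise ValueError("panel comes in 15- and 21-marker versions")
    rows = _PANEL[:n_markers]
    return tuple(
        VariableSpec(
            name=name,
            domain=domain,
            direction=direction,
            control_mean=mean,
            control_sd=sd,
            target_auc=auc,
            missing_rate=round(1.0 - n_obs / _N_REFERENCE, 4),
        )
        for name, domain, direction, mean, sd, auc, n_obs in rows
    )


def default_panel_config(
    n_markers: int = 15,
    n_cases: int = 67,
    n_controls: int = 67,
    seed: int = 0,
    **kwargs,
) -> CohortConfig:
    """Cohort recipe matching the study conditions (67 cases, 67 controls)."""
    return CohortConfig(
        variables=default_variables(n_markers),
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
        **kwargs,
    )


def default_domain_map(n_markers: int = 15) -> DomainMap:
    """Variable-to-domain assignment for the default panel.

    Domain sizes are 3, 3, 3, 1, 5 for the 15-marker model, plus the
    6-marker middle-ear domain in the 21-marker model.
    """
    specs = default_variables(n_markers)
    return DomainMap.from_assignment(
        {v.name: v.domain for v in specs},
        domain_order=[d for d in DOMAIN_ORDER if any(v.domain == d for v in specs)],
        directions={v.name: v.direction for v in specs},
    )
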