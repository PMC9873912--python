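"""Covariate registry: the sixteen model covariates and default interactions.

Covariates fall into four thematic groups (traits, land-use, climate,
governance).  Seven "core" main effects enter every model; the remaining
nine are "optional" and, together with seven interactions, are subject to
Kuo-Mallick variable selection.  All covariates are z-transformed before
modelling, so a coefficient is the change in annual population growth
(% per year) per standard deviation of the covariate.
"""

from __future__ import annotations

# name -> thematic group
COVARIATE_GROUPS: dict[str, str] = {
    # traits
    "body_mass": "traits",
    "max_longevity": "traits",
    "niche_breadth": "traits",
    "litter_size": "traits",
    # land-use
    "primary_land_loss": "land_use",
    "seminatural_conversion": "land_use",
    "change_human_density": "land_use",
    "population_area": "land_use",
    # climate
    "change_extreme_heat": "climate",
    "change_drought": "climate",
    "baseline_extreme_heat": "climate",
    "baseline_drought": "climate",
    # governance / socioeconomics
    "governance": "governance",
    "protected_area": "governance",
    "human_development": "governance",
    "change_human_development": "governance",
}

COVARIATES: tuple[str, ...] = tuple(COVARIATE_GROUPS)

#: Main effects included in every model (never under selection).
CORE_TERMS: tuple[str, ...] = (
    "change_human_density",
    "primary_land_loss",
    "population_area",
    "body_mass",
    "change_extreme_heat",
    "governance",
    "protected_area",
)

#: Main effects subject to Kuo-Mallick selection.
OPTIONAL_TERMS: tuple[str, ...] = tuple(
    name for name in COVARIATES if name not in CORE_TERMS
)

#: Default interaction pairs (all under selection): environmental pressures
#: crossed with traits, protection and governance.
DEFAULT_INTERACTIONS: tuple[tuple[str, str], ...] = (
    ("primary_land_loss", "change_human_density"),
    ("primary_land_loss", "seminatural_conversion"),
    ("primary_land_loss", "niche_breadth"),
    ("primary_land_loss", "governance"),
    ("change_extreme_heat", "protected_area"),
    ("change_extreme_heat", "niche_breadth"),
    ("change_drought", "protected_area"),
)


def interaction_name(a: str, b: str) -> str:
    """Canonical column name for the interaction of covariates *a* and *b*."""
    return f"{a}:{b}"
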