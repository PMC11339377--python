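"""The seven counterfactual conservation scenarios and the loss-update rules.

Scenarios contrast *proactive* placement of new reserves (in the path of
imminent forest loss) with *expedient* placement (in low-risk, low-cost
terrain), each either retaining the existing protected-area network or
redistributing it from scratch, plus three non-selection references:

===  ==========================================  ========================
S1   baseline                                    no loss applied (status quo)
S2   proactive, redistribute PAs                 new reserves only protect
S3   proactive, retain PAs + add new             PAs and new reserves protect
S4   expedient, redistribute PAs                 new reserves only protect
S5   expedient, retain PAs + add new             PAs and new reserves protect
S6   existing PAs only, fully effective          PA mask protects
S7   business-as-usual                           nothing protects
===  ==========================================  ========================

After a scenario fixes which cells are effectively protected, the decade of
modelled forest loss is applied everywhere else in expectation:
resistance rises by the loss probability times the plantation/regrowth
resistance (lost forest transitions to plantation or regrowth), and carbon
falls to its retained fraction. Protection is assumed leak-free: protecting
one cell displaces no loss onto another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GridRaster

__all__ = [
    "ScenarioSpec",
    "scenario_catalog",
    "get_scenario",
    "effective_protection_mask",
    "update_resistance",
    "update_carbon",
    "total_carbon",
]


@dataclass(frozen=True)
class ScenarioSpec:
    id: int
    label: str
    mode: str  # "proactive" | "expedient" | "none"
    retain_existing_pas: bool
    add_new_reserves: bool
    pas_effective: bool


_CATALOG = (
    ScenarioSpec(1, "Baseline (status quo, no loss applied)", "none", True, False, True),
    ScenarioSpec(2, "Proactive conservation redistributing PAs", "proactive", False, True, True),
    ScenarioSpec(3, "Proactive conservation retaining PAs", "proactive", True, True, True),
    ScenarioSpec(4, "Expedient conservation redistributing PAs", "expedient", False, True, True),
    ScenarioSpec(5, "Expedient conservation retaining PAs", "expedient", True, True, True),
    ScenarioSpec(6, "Existing PAs only, fully effective", "none", True, False, True),
    ScenarioSpec(7, "Business-as-usual (PAs not effective)", "none", True, False, False),
)


def scenario_catalog() -> tuple[ScenarioSpec, ...]:
    """The seven scenario configurations, ids 1-7."""
    return _CATALOG


def get_scenario(scenario_id: int) -> ScenarioSpec:
    for s in _CATALOG:
        if s.id == scenario_id:
            return s
    raise ValueError(f"scenario id must be 1..7, got {scenario_id}")


def effective_protection_mask(
    spec: ScenarioSpec, pa_mask: GridRaster, new_reserves: GridRaster | None = None
) -> GridRaster:
    """Cells treated as effectively protected from modelled loss.

    S1 protects everything (the baseline applies no loss at all); S7 protects
    nothing; S6 protects exactly the existing network; redistribute scenarios
    (S2/S4) protect only the new reserve design; retain scenarios (S3/S5)
    protect the union of the existing network and the new design.
    """
    if spec.add_new_reserves:
        if new_reserves is None:
            raise ValueError(f"scenario {spec.id} requires a new-reserve mask")
        pa_mask.require_aligned(new_reserves)

    if spec.id == 1:
        mask = np.ones(pa_mask.shape, dtype=np.int64)
    elif not spec.pas_effective:
        mask = np.zeros(pa_mask.shape, dtype=np.int64)
    elif spec.add_new_reserves and not spec.retain_existing_pas:
        mask = (new_reserves.values > 0).astype(np.int64)
    elif spec.add_new_reserves:
        mask = ((pa_mask.values > 0) | (new_reserves.values > 0)).astype(np.int64)
    else:
        mask = (pa_mask.values > 0).astype(np.int64)
    return pa_mask.like(mask)


def update_resistance(
    resistance: GridRaster,
    risk: GridRaster,
    plantation_resistance: float,
    protection_mask: GridRaster,
) -> GridRaster:
    """Expected post-loss resistance.

    Unprotected cells gain the expected conversion penalty
    ``risk * plantation_resistance`` (lost forest most likely becomes
    plantation or regrowth); protected cells keep their baseline resistance.
    """
    resistance.require_aligned(risk, protection_mask)
    r = resistance.values
    p = risk.values
    if np.any(r < 0):
        raise ValueError("negative resistance")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("risk must lie in [0, 1]")
    protected = protection_mask.values > 0
    out = r + np.where(protected, 0.0, p * plantation_resistance)
    return resistance.like(out)


def update_carbon(
    carbon: GridRaster,
    risk: GridRaster,
    protection_mask: GridRaster,
    *,
    literal_inverse: bool = False,
) -> GridRaster:
    """Expected post-loss above-ground biomass.

    Unprotected cells keep their retained fraction ``carbon * (1 - risk)``
    (expected loss = carbon x loss probability); protected cells keep their
    baseline stock. ``literal_inverse=True`` instead multiplies by the loss
    probability itself (loss = carbon x (1 - risk)) — an alternative reading
    of "reducing carbon by the product of carbon and the inverse probability
    of deforestation" that rewards high-risk cells; it is exposed only for
    sensitivity analysis and is not the default.
    """
    carbon.require_aligned(risk, protection_mask)
    c = carbon.values
    p = risk.values
    if np.any(c < 0):
        raise ValueError("negative carbon")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("risk must lie in [0, 1]")
    protected = protection_mask.values > 0
    retained = p if literal_inverse else (1.0 - p)
    out = np.where(protected, c, c * retained)
    return carbon.like(out)


def total_carbon(carbon: GridRaster) -> float:
    """Total stock in gigatons (1 Gt = 1e9 Mg); nodata cells excluded."""
    valid = carbon.valid_mask()
    return float(carbon.values[valid].sum() / 1.0e9)
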