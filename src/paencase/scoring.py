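"""Degree-of-encasement scoring and relationship resolution.

An encased pulmonary artery is typed by how many arterial bifurcations fall
inside the encased segment and where the narrowest point sits relative to
them:

* **A** — no bifurcation in the encased segment; reference diameter is the
  proximal normal diameter ``AB``.
* **B** — one bifurcation, narrowest point proximal to it; reference ``AB``.
* **C** — one bifurcation, narrowest point distal to it; reference is the
  distal normal diameter ``EF`` (the vessel is expected to be smaller past a
  branch point, so the proximal diameter would overstate the narrowing).
* **D** — at least two bifurcations with the narrowest point between them;
  the expected normal diameter is interpolated linearly along the
  centerline: ``CD' = EF + (EC/EA) * (AB - EF)``.
* **amputation** — the vessel is so narrowed it is barely visualized; the
  degree is 100% by definition and ``CD`` may be unmeasurable.

The degree of encasement is ``(1 - CD/ref) * 100`` in percent, clamped to
[0, 100]: a raw negative value (``CD`` above the reference, e.g. post-stenotic
dilation) is clamped to 0 with a warning, since the score presupposes
narrowing.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .core import NarrowestPosition, RelationType, VesselMeasurement

__all__ = [
    "EncasementType",
    "DegreeResult",
    "GeometrySummary",
    "RelationConfig",
    "ScoringError",
    "classify_encasement_type",
    "expected_diameter",
    "degree_of_encasement",
    "worst_encasement",
    "classify_relation",
    "dominant_relation",
]


class ScoringError(ValueError):
    """A measurement cannot be scored (missing field or inconsistent flags)."""


class EncasementType(enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    AMPUTATION = "amputation"


@dataclass(frozen=True)
class DegreeResult:
    """Degree of encasement for one vessel, with the reference used."""

    degree: float  # percent in [0, 100]
    type: EncasementType
    reference_diameter: float | None  # mm; None for amputation without refs
    vessel_id: str


def classify_encasement_type(m: VesselMeasurement) -> EncasementType:
    """Type an encased vessel from its bifurcation count and narrowest position.

    A narrowest point lying exactly at a bifurcation is mapped to
    ``proximal_to_bifurcation`` by convention (the caller records it as such).
    """
    if m.amputated:
        return EncasementType.AMPUTATION
    nb, pos = m.n_bifurcations, m.narrowest_position
    if nb == 0:
        if pos is not NarrowestPosition.NO_BIFURCATION:
            raise ScoringError(
                f"{m.vessel_id}: narrowest_position={pos.value} inconsistent "
                f"with n_bifurcations=0"
            )
        return EncasementType.A
    if nb == 1:
        if pos is NarrowestPosition.PROXIMAL_TO_BIFURCATION:
            return EncasementType.B
        if pos is NarrowestPosition.DISTAL_TO_BIFURCATION:
            return EncasementType.C
        raise ScoringError(
            f"{m.vessel_id}: narrowest_position={pos.value} inconsistent "
            f"with n_bifurcations=1"
        )
    # nb >= 2
    if pos is NarrowestPosition.BETWEEN_BIFURCATIONS:
        return EncasementType.D
    if pos in (NarrowestPosition.PROXIMAL_TO_BIFURCATION,
               NarrowestPosition.DISTAL_TO_BIFURCATION):
        # narrowest before the first or after the last of several bifurcations
        return (EncasementType.B
                if pos is NarrowestPosition.PROXIMAL_TO_BIFURCATION
                else EncasementType.C)
    raise ScoringError(
        f"{m.vessel_id}: narrowest_position={pos.value} inconsistent "
        f"with n_bifurcations={nb}"
    )


def expected_diameter(m: VesselMeasurement, t: EncasementType) -> float:
    """Expected normal diameter (mm) of the narrowest segment for type ``t``.

    Types A and B use the proximal diameter AB, type C the distal diameter
    EF, and type D interpolates between them along the centerline:
    ``CD' = EF + (EC/EA) * (AB - EF)``.
    """
    if t in (EncasementType.A, EncasementType.B):
        if m.AB is None:
            raise ScoringError(f"{m.vessel_id}: type {t.value} requires AB")
        return m.AB
    if t is EncasementType.C:
        if m.EF is None:
            raise ScoringError(f"{m.vessel_id}: type C requires EF")
        return m.EF
    if t is EncasementType.D:
        if None in (m.AB, m.EF, m.EC, m.EA):
            raise ScoringError(f"{m.vessel_id}: type D requires AB, EF, EC and EA")
        if m.EA == 0:
            raise ScoringError(f"{m.vessel_id}: EA must be positive for type D")
        ref = m.EF + (m.EC / m.EA) * (m.AB - m.EF)
        if not ref > 0:
            raise ScoringError(
                f"{m.vessel_id}: interpolated reference CD' = {ref:.3g} mm not positive"
            )
        return ref
    raise ScoringError(f"{m.vessel_id}: no reference diameter for {t.value}")


def degree_of_encasement(m: VesselMeasurement) -> DegreeResult:
    """Percent luminal narrowing of an encased vessel against its expected diameter.

    Amputation scores 100% regardless of measurements.  Raw values outside
    [0, 100] are clamped (with a warning for negative raw degrees).
    """
    t = classify_encasement_type(m)
    if t is EncasementType.AMPUTATION:
        ref = None
        if m.AB is not None or m.EF is not None:
            try:
                ref = expected_diameter(
                    m, EncasementType.A if m.AB is not None else EncasementType.C
                )
            except ScoringError:
                ref = None
        return DegreeResult(degree=100.0, type=t, reference_diameter=ref,
                            vessel_id=m.vessel_id)
    if m.CD is None:
        raise ScoringError(f"{m.vessel_id}: CD absent without amputation")
    ref = expected_diameter(m, t)
    raw = (1.0 - m.CD / ref) * 100.0
    if raw < 0.0:
        warnings.warn(
            f"{m.vessel_id}: CD ({m.CD} mm) exceeds reference ({ref:.3g} mm); "
            "degree clamped to 0",
            stacklevel=2,
        )
    degree = min(100.0, max(0.0, raw))
    return DegreeResult(degree=degree, type=t, reference_diameter=ref,
                        vessel_id=m.vessel_id)


def worst_encasement(ms: list[VesselMeasurement] | tuple[VesselMeasurement, ...]) -> DegreeResult:
    """Most advanced degree among several encased vessels of one lesion.

    Ties break toward the larger reference diameter (the more proximal
    vessel), then by vessel_id order.
    """
    if not ms:
        raise ScoringError("worst_encasement requires at least one measurement")
    results = [degree_of_encasement(m) for m in ms]

    def key(r: DegreeResult) -> tuple:
        ref = r.reference_diameter if r.reference_diameter is not None else 0.0
        return (-r.degree, -ref, r.vessel_id)

    return min(results, key=key)


# ---------------------------------------------------------------------------
# relationship classification from geometry


@dataclass(frozen=True)
class GeometrySummary:
    """Geometric summary of one vessel--lesion pair.

    ``inside_fraction`` is the fraction of the vessel's arc length inside the
    lesion; ``caliber_ratio`` is CD over the expected normal diameter;
    ``course_deviation`` is the maximal displacement (mm) of the centerline
    from the normal vascular course; ``local_diameter`` scales the deviation
    threshold (one vessel diameter of deviation counts as displacement).
    """

    inside_fraction: float
    caliber_ratio: float
    course_deviation: float
    touches_margin: bool
    contacts: bool
    local_diameter: float = 5.0  # mm, typical segmental pulmonary artery


@dataclass(frozen=True)
class RelationConfig:
    """Thresholds for qualitative relationship rules.

    ``tau_caliber``: fractional caliber loss that counts as "decreasing the
    caliber" (default 10%).  ``tau_deviation_diameters``: course deviation, in
    local vessel diameters, that counts as displacement (default 1).
    """

    tau_caliber: float = 0.10
    tau_deviation_diameters: float = 1.0


def classify_relation(g: GeometrySummary,
                      config: RelationConfig = RelationConfig()) -> RelationType:
    """Map a vessel--lesion geometric summary to a relationship category.

    Rule order mirrors the qualitative definitions: no contact is
    disconnection; envelopment with caliber loss is encasement; course
    deviation (with or without a notch) is displacement; a vessel running
    through the lesion with unchanged course and caliber is penetration; a
    vessel crossing only the margin is in_margin.
    """
    if not (0.0 <= g.inside_fraction <= 1.0):
        raise ValueError(f"inside_fraction must lie in [0, 1], got {g.inside_fraction}")
    if not g.contacts:
        return RelationType.DISCONNECTION
    tau_d = config.tau_deviation_diameters * g.local_diameter
    if g.inside_fraction > 0.0 and g.caliber_ratio < 1.0 - config.tau_caliber:
        return RelationType.ENCASEMENT
    if g.course_deviation > tau_d:
        return RelationType.DISPLACEMENT
    if g.inside_fraction > 0.0:
        return RelationType.PENETRATION
    return RelationType.IN_MARGIN


def dominant_relation(rs: set[RelationType] | frozenset[RelationType]) -> RelationType | None:
    """Relation with the most mass effect; None if only unclassifiable types.

    Lesions whose arteries are all in the margin of, or disconnected from,
    the lesion carry no mass-effect information and are excluded from the
    contingency analysis; those return None.
    """
    if not rs:
        raise ValueError("dominant_relation requires a nonempty set")
    ranked = [r for r in rs if r.mass_effect_rank is not None]
    if not ranked:
        return None
    return max(ranked, key=lambda r: r.mass_effect_rank)
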