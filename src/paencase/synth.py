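"""Synthetic cohorts and geometric vessel phantoms with known ground truth.

No per-patient measurements are published for this kind of study, so the
generator emulates the cohort's *statistical structure*: the relationship
frequencies per diagnosis group, the rate of dual-relationship malignant
lesions, and the degree-of-encasement distribution summarised by its group
mean +/- sd together with the amputation fraction.  The degree law is a
mixture of a point mass at 100% (amputation) and a continuous component on
(0, 100) — scaled Beta by default, truncated normal by flag — calibrated by
the method of moments so the *population* mean and sd match the targets
exactly.

The vessel phantoms realise the measurement geometry: a straight centerline
with a linear diameter taper, a spherical lesion, and a smooth (Gaussian)
stenotic dip whose floor encodes a known true degree, so the landmark
measurement and degree formulas can be verified end to end.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    Cohort,
    LesionRecord,
    NarrowestPosition,
    RelationType,
    VesselMeasurement,
)

__all__ = [
    "MixtureSpec",
    "PhantomVessel",
    "SyntheticConfig",
    "CalibrationError",
    "calibrate_degree_mixture",
    "sample_degrees",
    "sample_cohort",
    "simulate_second_observer",
    "make_vessel_phantom",
    "measure_phantom",
    "default_config",
]

#: diameter below which a vessel is "barely visualized" -> amputation, mm
VISIBILITY_FLOOR_MM = 0.25


class CalibrationError(ValueError):
    """Requested mixture moments are infeasible for the chosen family."""


@dataclass(frozen=True)
class MixtureSpec:
    """Point mass at 100% (amputation) plus a continuous component on (0,100).

    ``w`` is the amputation probability; (``m_c``, ``s_c``) are the mean/sd of
    the continuous part; ``alpha``/``beta`` its Beta shape on the unit scale
    (or mu/sigma of the latent normal for the truncated-normal family).  The
    mixture's population mean and sd equal ``target_mean``/``target_sd``.
    """

    w: float
    m_c: float
    s_c: float
    alpha: float
    beta: float
    target_mean: float
    target_sd: float
    family: str = "beta"  # "beta" | "truncnorm"


def calibrate_degree_mixture(target_mean: float, target_sd: float, w: float,
                             family: str = "beta") -> MixtureSpec:
    """Moment-match the amputation/continuous mixture to (mean, sd, w).

    Solving the mixture moment identities for the continuous part:
    ``m_c = (mean - 100 w)/(1 - w)`` and
    ``s_c^2 = (sd^2 + mean^2 - 10^4 w)/(1 - w) - m_c^2``,
    then fits the component shape by the method of moments.
    """
    if not 0.0 <= w < 1.0:
        raise CalibrationError(f"amputation mass w must lie in [0, 1), got {w}")
    m_c = (target_mean - 100.0 * w) / (1.0 - w)
    second = (target_sd**2 + target_mean**2 - 1e4 * w) / (1.0 - w)
    s2_c = second - m_c**2
    if not 0.0 < m_c < 100.0:
        raise CalibrationError(
            f"continuous mean {m_c:.2f}% outside (0, 100); targets infeasible"
        )
    if s2_c <= 0.0:
        raise CalibrationError(
            f"continuous variance {s2_c:.3f} not positive; sd target too small for w={w}"
        )
    mu = m_c / 100.0  # unit scale
    v = s2_c / 1e4
    if v >= mu * (1.0 - mu):
        raise CalibrationError(
            f"unit-scale variance {v:.4f} >= mu(1-mu) = {mu * (1 - mu):.4f}; "
            "no Beta (or bounded) component can match"
        )
    if family == "beta":
        k = mu * (1.0 - mu) / v - 1.0
        alpha, beta = mu * k, (1.0 - mu) * k
    elif family == "truncnorm":
        alpha, beta = _truncnorm_params(mu, math.sqrt(v))
    else:
        raise CalibrationError(f"unknown component family {family!r}")
    return MixtureSpec(w=w, m_c=m_c, s_c=math.sqrt(s2_c), alpha=alpha, beta=beta,
                       target_mean=target_mean, target_sd=target_sd, family=family)


def _truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) so the normal truncated to (0,1) has the given moments."""
    from scipy import optimize, stats

    def resid(theta):
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(resid, x0=[mean, math.log(max(sd, 1e-3))], method="hybr")
    if not sol.success:
        raise CalibrationError(f"truncated-normal calibration failed: {sol.message}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def sample_degrees(spec: MixtureSpec, n: int,
                   seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` degrees (%): exactly 100 with probability ``w``, else the
    continuous component.  Same (spec, n, seed) -> identical output."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n, dtype=float)
    amputated = rng.random(n) < spec.w
    out[amputated] = 100.0
    k = int(n - amputated.sum())
    if k:
        if spec.family == "beta":
            cont = 100.0 * rng.beta(spec.alpha, spec.beta, size=k)
        else:
            from scipy import stats

            mu, sigma = spec.alpha, spec.beta
            a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
            cont = 100.0 * stats.truncnorm.rvs(a, b, loc=mu, scale=sigma,
                                               size=k, random_state=rng)
        out[~amputated] = cont
    return out


# ---------------------------------------------------------------------------
# cohort sampling


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for cohort simulation.

    Defaults emulate the reference cohort: 23 benign / 77 malignant lesions,
    relationship frequencies proportional to the final observed tallies,
    a 15/74 dual-relationship rate among analyzable malignant lesions, degree
    mixtures calibrated to the published group moments with amputation
    fractions 1/8 (benign) and 11/58 (malignant), and observer-2 agreement
    0.639 (which equals the expected kappa under the symmetric-confusion
    model).
    """

    n_benign: int = 23
    n_malignant: int = 77
    # order: encasement, displacement, penetration, in_margin, disconnection
    benign_relation_probs: tuple[float, ...] = (8 / 23, 2 / 23, 10 / 23, 0.0, 3 / 23)
    malignant_relation_probs: tuple[float, ...] = (58 / 92, 27 / 92, 4 / 92,
                                                   1 / 92, 2 / 92)
    dual_probability: float = 15 / 74
    benign_mixture: MixtureSpec = field(
        default_factory=lambda: calibrate_degree_mixture(52.1, 27.3, 1 / 8))
    malignant_mixture: MixtureSpec = field(
        default_factory=lambda: calibrate_degree_mixture(71.8, 18.8, 11 / 58))
    observer_agreement: float = 0.639
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (("benign_relation_probs", self.benign_relation_probs),
                            ("malignant_relation_probs", self.malignant_relation_probs)):
            if len(probs) != 5 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be 5 nonnegative probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(probs)}")
        if not 0.0 <= self.dual_probability <= 1.0:
            raise ValueError("dual_probability must lie in [0, 1]")
        if not 0.0 <= self.observer_agreement <= 1.0:
            raise ValueError("observer_agreement must lie in [0, 1]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        for key in ("benign_mixture", "malignant_mixture"):
            if key in d:
                d[key] = MixtureSpec(**d[key])
        for key in ("benign_relation_probs", "malignant_relation_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_config(seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(seed=seed)


_RELATION_ORDER = (
    RelationType.ENCASEMENT,
    RelationType.DISPLACEMENT,
    RelationType.PENETRATION,
    RelationType.IN_MARGIN,
    RelationType.DISCONNECTION,
)

# group attribute laws (age yr, size mm, central-location and female fractions)
_GROUP_ATTRS = {
    "benign": dict(age=(57.2, 22.0), size=(51.1, 17.4), p_central=9 / 20,
                   p_female=6 / 20),
    "malignant": dict(age=(67.0, 11.0), size=(48.1, 21.9), p_central=46 / 74,
                      p_female=24 / 74),
}


def _sample_lesion(rng: np.random.Generator, group: str, idx: int,
                   cfg: SyntheticConfig) -> LesionRecord:
    probs = (cfg.benign_relation_probs if group == "benign"
             else cfg.malignant_relation_probs)
    primary = _RELATION_ORDER[rng.choice(5, p=np.asarray(probs))]
    relations = {primary}
    if (group == "malignant"
            and primary in (RelationType.ENCASEMENT, RelationType.DISPLACEMENT)
            and rng.random() < cfg.dual_probability):
        if primary is RelationType.ENCASEMENT:
            secondary = (RelationType.DISPLACEMENT if rng.random() < 0.5
                         else RelationType.PENETRATION)
        else:
            secondary = RelationType.PENETRATION
        relations.add(secondary)

    degree = None
    measurements: tuple[VesselMeasurement, ...] = ()
    if RelationType.ENCASEMENT in relations:
        mixture = (cfg.benign_mixture if group == "benign"
                   else cfg.malignant_mixture)
        degree = float(sample_degrees(mixture, 1, rng)[0])
        ab = float(rng.uniform(4.0, 8.0))
        vessel_id = f"{group[0]}{idx:03d}-a1"
        if degree >= 100.0:
            measurements = (VesselMeasurement(vessel_id=vessel_id, AB=ab,
                                              amputated=True),)
        else:
            measurements = (VesselMeasurement(
                vessel_id=vessel_id, AB=ab, CD=ab * (1.0 - degree / 100.0)),)

    attrs = _GROUP_ATTRS[group]
    age = float(np.clip(rng.normal(*attrs["age"]), 18.0, 95.0))
    size = float(np.clip(rng.normal(*attrs["size"]), 5.0, 150.0))
    return LesionRecord(
        lesion_id=f"{group[0]}{idx:03d}",
        truth=group,
        location="central" if rng.random() < attrs["p_central"] else "peripheral",
        size=round(size, 1),
        final_relations=frozenset(relations),
        obs1_relations=frozenset(relations),
        measurements=measurements,
        degree=degree,
        age=round(age, 1),
        sex="F" if rng.random() < attrs["p_female"] else "M",
    )


def sample_cohort(cfg: SyntheticConfig) -> Cohort:
    """Draw a full cohort under ``cfg``; every record passes validation.

    A hierarchical seed stream (cohort -> lesion) makes per-lesion draws
    reproducible independently of cohort size ordering.
    """
    ss = np.random.SeedSequence(cfg.seed)
    lesion_seeds = ss.spawn(cfg.n_benign + cfg.n_malignant + 1)
    records = []
    i = 0
    for group, n in (("benign", cfg.n_benign), ("malignant", cfg.n_malignant)):
        for j in range(n):
            rng = np.random.default_rng(lesion_seeds[i])
            records.append(_sample_lesion(rng, group, j, cfg))
            i += 1
    cohort = Cohort(records=tuple(records),
                    provenance=f"synthetic cohort, seed={cfg.seed}", seed=cfg.seed)
    obs2 = simulate_second_observer(cohort, cfg.observer_agreement,
                                    np.random.default_rng(lesion_seeds[-1]))
    records = tuple(replace(r, obs2_relations=o)
                    for r, o in zip(cohort.records, obs2))
    return Cohort(records=records, provenance=cohort.provenance, seed=cfg.seed)


def simulate_second_observer(c: Cohort, agreement: float,
                             seed: int | np.random.Generator) -> list[frozenset]:
    """Observer-2 relation labels under a symmetric-confusion model.

    Each lesion keeps observer 1's label set with probability ``agreement``;
    otherwise a label set is redrawn from the cohort's empirical marginal.
    Under this model the expected Cohen kappa equals ``agreement`` (the
    chance-agreement term cancels), so calibrating to a requested kappa is
    the identity map.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    marginal = [r.obs1_relations for r in c.records]
    if not marginal:
        return []
    out = []
    for r in c.records:
        if rng.random() < agreement:
            out.append(r.obs1_relations)
        else:
            out.append(marginal[rng.integers(len(marginal))])
    return out


# ---------------------------------------------------------------------------
# geometric vessel phantoms


@dataclass(frozen=True)
class PhantomVessel:
    """A straight tapered vessel through a spherical lesion with a known dip."""

    centerline: np.ndarray  # (n, 3) mm
    diameter_profile: np.ndarray  # (n,) mm
    lesion_center: np.ndarray  # (3,) mm
    lesion_radius: float  # mm
    truth_degree: float  # %
    truth_relation: RelationType
    bifurcation_arcs: tuple[float, ...] = ()  # x positions, mm

    def to_json(self) -> str:
        return json.dumps({
            "centerline": self.centerline.tolist(),
            "diameter_profile": self.diameter_profile.tolist(),
            "lesion_center": self.lesion_center.tolist(),
            "lesion_radius": self.lesion_radius,
            "truth_degree": self.truth_degree,
            "truth_relation": self.truth_relation.value,
            "bifurcation_arcs": list(self.bifurcation_arcs),
        })

    @classmethod
    def from_json(cls, text: str) -> "PhantomVessel":
        d = json.loads(text)
        return cls(
            centerline=np.asarray(d["centerline"], dtype=float),
            diameter_profile=np.asarray(d["diameter_profile"], dtype=float),
            lesion_center=np.asarray(d["lesion_center"], dtype=float),
            lesion_radius=float(d["lesion_radius"]),
            truth_degree=float(d["truth_degree"]),
            truth_relation=RelationType(d["truth_relation"]),
            bifurcation_arcs=tuple(d["bifurcation_arcs"]),
        )


def make_vessel_phantom(*, base_diameter: float = 6.0, taper_per_mm: float = 0.0,
                        lesion_radius: float = 10.0, stenosis_depth: float = 50.0,
                        stenosis_position: float = 0.0, n_points: int = 401,
                        bifurcation_arcs: tuple[float, ...] = (),
                        seed: int | None = None) -> PhantomVessel:
    """Construct a phantom whose stenotic floor encodes ``stenosis_depth`` %.

    The centerline runs along x through the lesion center (origin); the
    diameter tapers linearly distally; the stenosis is a Gaussian dip
    (sigma = lesion_radius / 3) centered ``stenosis_position`` mm from the
    lesion center, which must lie inside the lesion.  Depth 100 drives the
    minimum diameter below the visibility floor, i.e. amputation.
    """
    if base_diameter <= 0 or lesion_radius <= 0 or n_points < 20:
        raise ValueError("base_diameter, lesion_radius must be positive; n_points >= 20")
    if not 0.0 <= stenosis_depth <= 100.0:
        raise ValueError("stenosis_depth must lie in [0, 100]")
    if stenosis_depth > 0.0 and abs(stenosis_position) >= lesion_radius:
        raise ValueError(
            "stenosis (encasement) requested but its center lies outside the lesion"
        )
    half_len = 3.0 * lesion_radius
    x = np.linspace(-half_len, half_len, n_points)
    baseline = base_diameter - taper_per_mm * (x + half_len)
    if np.any(baseline <= 0):
        raise ValueError("taper drives the diameter nonpositive within the phantom")
    sigma = lesion_radius / 3.0
    dip = (stenosis_depth / 100.0) * np.exp(
        -0.5 * ((x - stenosis_position) / sigma) ** 2)
    diameters = baseline * (1.0 - dip)
    centerline = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    relation = (RelationType.PENETRATION if stenosis_depth == 0.0
                else RelationType.ENCASEMENT)
    return PhantomVessel(
        centerline=centerline,
        diameter_profile=diameters,
        lesion_center=np.zeros(3),
        lesion_radius=float(lesion_radius),
        truth_degree=float(stenosis_depth),
        truth_relation=relation,
        bifurcation_arcs=tuple(float(b) for b in bifurcation_arcs),
    )


def measure_phantom(v: PhantomVessel, *, normal_tolerance: float = 0.05,
                    vessel_id: str = "phantom") -> VesselMeasurement:
    """Measure the landmark diameters/distances from phantom geometry alone.

    The taper baseline is re-estimated by a straight-line fit to diameters
    far from the lesion (beyond 1.3 radii); "normal" means within
    ``normal_tolerance`` of that baseline.  CD is the narrowest in-lesion
    diameter (amputation if below the visibility floor); AB/EF are the
    nearest normal diameters just outside the lesion, EC/EA the centerline
    arc distances from the narrowest point / proximal normal point to the
    distal normal point.
    """
    pts = v.centerline
    d = v.diameter_profile
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    dist = np.linalg.norm(pts - v.lesion_center, axis=1)
    inside = dist <= v.lesion_radius
    if inside.all():
        raise ValueError("vessel entirely inside the lesion; no normal reference")
    if not inside.any():
        raise ValueError("vessel does not intersect the lesion")

    far = dist > 1.3 * v.lesion_radius
    if far.sum() < 2:
        raise ValueError("too little vessel outside the lesion to fit a baseline")
    coeff = np.polyfit(arc[far], d[far], 1)
    baseline = np.polyval(coeff, arc)
    normal = np.abs(d - baseline) <= normal_tolerance * baseline

    idx_in = np.flatnonzero(inside)
    i_min = idx_in[np.argmin(d[idx_in])]
    cd = float(d[i_min])
    amputated = cd < VISIBILITY_FLOOR_MM

    first_in, last_in = idx_in[0], idx_in[-1]
    prox = np.flatnonzero(normal & (np.arange(len(d)) < first_in))
    dista = np.flatnonzero(normal & (np.arange(len(d)) > last_in))
    if prox.size == 0 and dista.size == 0:
        raise ValueError("no normal reference segment on either side of the lesion")
    i_a = prox[-1] if prox.size else None  # nearest normal point, proximal side
    i_e = dista[0] if dista.size else None  # nearest normal point, distal side

    ab = float(d[i_a]) if i_a is not None else None
    ef = float(d[i_e]) if i_e is not None else None
    ec = float(arc[i_e] - arc[i_min]) if i_e is not None else None
    ea = (float(arc[i_e] - arc[i_a])
          if (i_a is not None and i_e is not None) else None)

    x_min = pts[i_min, 0]
    bifs_in = [b for b in v.bifurcation_arcs
               if pts[first_in, 0] <= b <= pts[last_in, 0]]
    nb = len(bifs_in)
    if nb == 0:
        pos = NarrowestPosition.NO_BIFURCATION
    elif all(b >= x_min for b in bifs_in):  # at a bifurcation -> proximal
        pos = NarrowestPosition.PROXIMAL_TO_BIFURCATION
    elif all(b < x_min for b in bifs_in):
        pos = NarrowestPosition.DISTAL_TO_BIFURCATION
    else:
        pos = NarrowestPosition.BETWEEN_BIFURCATIONS

    return VesselMeasurement(
        vessel_id=vessel_id,
        AB=ab,
        CD=None if amputated else cd,
        EF=ef,
        EC=ec,
        EA=ea,
        n_bifurcations=nb,
        narrowest_position=pos,
        amputated=amputated,
    )
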