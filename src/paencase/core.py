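"""Domain types, validation and tabular I/O for lesion/vessel records.

The unit of analysis is a lung lesion (nodule or mass) together with the
pulmonary arteries adjacent to it.  Each artery's relationship to the lesion
is one of five categories; three of them (encasement, displacement,
penetration) carry an ordinal *mass effect* rank, while ``in_margin`` and
``disconnection`` are unclassifiable and excluded from analysis.

Measurements follow the landmark convention of the degree-of-encasement
formulas: ``AB`` is the normal luminal diameter proximal to the lesion,
``CD`` the narrowest diameter inside it, ``EF`` the normal diameter distal to
it, and ``EC``/``EA`` are centerline arc distances used to interpolate an
expected diameter when the narrowest point lies between two bifurcations.
All diameters and distances are millimetres; degrees are percentages on the
0-100 scale (never 0-1).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RelationType",
    "NarrowestPosition",
    "VesselMeasurement",
    "LesionRecord",
    "Cohort",
    "CohortReadError",
    "validate_record",
    "read_cohort",
    "write_cohort",
    "write_report",
    "format_odds_ratio",
    "format_kappa",
]


class RelationType(enum.Enum):
    """Relationship of a pulmonary artery to a lung lesion.

    Mass-effect ordering: encasement > displacement > penetration.
    ``in_margin`` and ``disconnection`` have no mass-effect rank.
    """

    ENCASEMENT = "encasement"
    DISPLACEMENT = "displacement"
    PENETRATION = "penetration"
    IN_MARGIN = "in_margin"
    DISCONNECTION = "disconnection"

    @property
    def mass_effect_rank(self) -> int | None:
        return _MASS_EFFECT.get(self)


_MASS_EFFECT = {
    RelationType.ENCASEMENT: 3,
    RelationType.DISPLACEMENT: 2,
    RelationType.PENETRATION: 1,
}

#: Categories that enter the contingency analysis.
ANALYZABLE_RELATIONS = (
    RelationType.ENCASEMENT,
    RelationType.DISPLACEMENT,
    RelationType.PENETRATION,
)


class NarrowestPosition(enum.Enum):
    """Position of the narrowest encased point relative to bifurcations."""

    NO_BIFURCATION = "no_bifurcation"
    PROXIMAL_TO_BIFURCATION = "proximal_to_bifurcation"
    DISTAL_TO_BIFURCATION = "distal_to_bifurcation"
    BETWEEN_BIFURCATIONS = "between_bifurcations"


@dataclass(frozen=True)
class VesselMeasurement:
    """One artery's diameters and distances relative to one lesion.

    ``CD`` may be absent only for an amputated vessel (one so narrowed it is
    barely visualized; scored as 100% encasement).  ``EC`` and ``EA`` are arc
    lengths along the centerline, measured from the distal normal point.
    """

    vessel_id: str
    AB: float | None = None
    CD: float | None = None
    EF: float | None = None
    EC: float | None = None
    EA: float | None = None
    n_bifurcations: int = 0
    narrowest_position: NarrowestPosition = NarrowestPosition.NO_BIFURCATION
    amputated: bool = False


@dataclass(frozen=True)
class LesionRecord:
    """One lesion: truth label, attributes, observer calls and measurements."""

    lesion_id: str
    truth: str  # "benign" | "malignant"
    location: str  # "central" | "peripheral"
    size: float  # longest diameter, mm
    final_relations: frozenset[RelationType]
    obs1_relations: frozenset[RelationType] = frozenset()
    obs2_relations: frozenset[RelationType] = frozenset()
    measurements: tuple[VesselMeasurement, ...] = ()
    degree: float | None = None  # encasement %, present iff encased
    age: float | None = None
    sex: str | None = None  # "F" | "M", optional


@dataclass(frozen=True)
class Cohort:
    """A list of lesion records plus provenance bookkeeping."""

    records: tuple[LesionRecord, ...]
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [r.lesion_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate lesion_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, truth: str) -> tuple[LesionRecord, ...]:
        return tuple(r for r in self.records if r.truth == truth)


# ---------------------------------------------------------------------------
# validation


def _validate_measurement(m: VesselMeasurement) -> list[str]:
    out: list[str] = []
    for name in ("AB", "CD", "EF", "EC", "EA"):
        v = getattr(m, name)
        if v is not None and not v > 0:
            out.append(f"{m.vessel_id}: {name} must be > 0, got {v}")
    if m.EC is not None and m.EA is not None and m.EC > m.EA:
        out.append(f"{m.vessel_id}: EC exceeds EA ({m.EC} > {m.EA})")
    if m.CD is None and not m.amputated:
        out.append(f"{m.vessel_id}: CD absent without amputation")
    if m.n_bifurcations < 0:
        out.append(f"{m.vessel_id}: n_bifurcations must be >= 0")
    pos, nb = m.narrowest_position, m.n_bifurcations
    if (pos is NarrowestPosition.NO_BIFURCATION) != (nb == 0):
        out.append(
            f"{m.vessel_id}: narrowest_position {pos.value} inconsistent "
            f"with n_bifurcations={nb}"
        )
    if pos is NarrowestPosition.BETWEEN_BIFURCATIONS and nb < 2:
        out.append(
            f"{m.vessel_id}: between_bifurcations requires n_bifurcations >= 2, got {nb}"
        )
    return out


def validate_record(record: LesionRecord) -> list[str]:
    """Check every type invariant; return a description per violation.

    Validation never raises: a well-formed record yields ``[]`` and each
    violation names the offending field and rule.
    """
    out: list[str] = []
    if record.truth not in ("benign", "malignant"):
        out.append(f"truth: unknown label {record.truth!r}")
    if record.location not in ("central", "peripheral"):
        out.append(f"location: unknown label {record.location!r}")
    if not record.size > 0:
        out.append(f"size: must be > 0 mm, got {record.size}")
    if not record.final_relations:
        out.append("final_relations: must be nonempty")
    if len(record.final_relations) > 2:
        out.append("final_relations: at most 2 distinct relations allowed")
    for label, rels in (("obs1_relations", record.obs1_relations),
                        ("obs2_relations", record.obs2_relations)):
        if len(rels) > 2:
            out.append(f"{label}: at most 2 distinct relations allowed")
    encased = RelationType.ENCASEMENT in record.final_relations
    if record.degree is not None and not encased:
        out.append("degree: degree without encasement in final_relations")
    if record.degree is None and encased:
        out.append("degree: encasement without degree")
    if record.degree is not None and not (0.0 <= record.degree <= 100.0):
        out.append(f"degree: must lie in [0, 100], got {record.degree}")
    for m in record.measurements:
        out.extend(_validate_measurement(m))
    return out


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = [
    "lesion_id", "truth", "location", "size_mm",
    "obs1_relations", "obs2_relations", "final_relations",
    "amputated", "AB_mm", "CD_mm", "EF_mm", "EC_mm", "EA_mm",
    "n_bifurcations", "narrowest_position", "degree_pct",
]
_OPTIONAL_COLUMNS = ["vessel_id", "age_yr", "sex"]


class CohortReadError(ValueError):
    """Raised when a cohort table cannot be parsed or fails validation."""


def _parse_relations(cell: object, row: int, column: str) -> frozenset[RelationType]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    out = set()
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            out.add(RelationType(token))
        except ValueError:
            raise CohortReadError(
                f"row {row}: column {column!r}: unknown relation {token!r}"
            ) from None
    return frozenset(out)


def _parse_float(cell: object, row: int, column: str) -> float | None:
    if cell is None or cell == "" or (isinstance(cell, float) and pd.isna(cell)):
        return None
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise CohortReadError(
            f"row {row}: column {column!r}: non-numeric value {cell!r}"
        ) from None


def read_cohort(source: str | io.TextIOBase, provenance: str = "") -> Cohort:
    """Read a cohort from the package's CSV dialect.

    One lesion per row; multiple relations in a cell are separated by ``;``;
    an empty cell means *unknown/absent*, never zero.  Each row carries at
    most one (representative worst) vessel measurement.  Rows are validated
    and rejected with their row number on any violation.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise CohortReadError(f"missing required columns: {missing}")

    records: list[LesionRecord] = []
    seen: set[str] = set()
    for i, raw in enumerate(df.to_dict("records")):
        row = i + 2  # 1-based, after the header line
        lesion_id = str(raw["lesion_id"]).strip()
        if not lesion_id:
            raise CohortReadError(f"row {row}: empty lesion_id")
        if lesion_id in seen:
            raise CohortReadError(f"row {row}: duplicate lesion_id {lesion_id!r}")
        seen.add(lesion_id)

        truth = str(raw["truth"]).strip()
        if truth not in ("benign", "malignant"):
            raise CohortReadError(f"row {row}: column 'truth': unknown label {truth!r}")
        location = str(raw["location"]).strip()
        if location not in ("central", "peripheral"):
            raise CohortReadError(
                f"row {row}: column 'location': unknown label {location!r}"
            )

        size = _parse_float(raw["size_mm"], row, "size_mm")
        if size is None:
            raise CohortReadError(f"row {row}: column 'size_mm': value required")

        amp_cell = str(raw["amputated"]).strip().lower()
        if amp_cell in ("", "0", "false", "no"):
            amputated = False
        elif amp_cell in ("1", "true", "yes"):
            amputated = True
        else:
            raise CohortReadError(
                f"row {row}: column 'amputated': unknown flag {amp_cell!r}"
            )

        numeric = {
            c: _parse_float(raw[c], row, c)
            for c in ("AB_mm", "CD_mm", "EF_mm", "EC_mm", "EA_mm", "degree_pct")
        }
        nbif_cell = str(raw["n_bifurcations"]).strip()
        npos_cell = str(raw["narrowest_position"]).strip()

        measurements: tuple[VesselMeasurement, ...] = ()
        has_measurement = amputated or any(
            numeric[c] is not None for c in ("AB_mm", "CD_mm", "EF_mm", "EC_mm", "EA_mm")
        )
        if has_measurement:
            nbif = 0
            if nbif_cell:
                try:
                    nbif = int(nbif_cell)
                except ValueError:
                    raise CohortReadError(
                        f"row {row}: column 'n_bifurcations': non-integer "
                        f"{nbif_cell!r}"
                    ) from None
            npos = NarrowestPosition.NO_BIFURCATION
            if npos_cell:
                try:
                    npos = NarrowestPosition(npos_cell)
                except ValueError:
                    raise CohortReadError(
                        f"row {row}: column 'narrowest_position': unknown value "
                        f"{npos_cell!r}"
                    ) from None
            vessel_id = str(raw.get("vessel_id", "") or f"{lesion_id}-a1").strip()
            measurements = (
                VesselMeasurement(
                    vessel_id=vessel_id,
                    AB=numeric["AB_mm"], CD=numeric["CD_mm"], EF=numeric["EF_mm"],
                    EC=numeric["EC_mm"], EA=numeric["EA_mm"],
                    n_bifurcations=nbif, narrowest_position=npos,
                    amputated=amputated,
                ),
            )

        age = _parse_float(raw.get("age_yr", ""), row, "age_yr")
        sex = str(raw.get("sex", "")).strip() or None

        record = LesionRecord(
            lesion_id=lesion_id,
            truth=truth,
            location=location,
            size=size,
            final_relations=_parse_relations(raw["final_relations"], row, "final_relations"),
            obs1_relations=_parse_relations(raw["obs1_relations"], row, "obs1_relations"),
            obs2_relations=_parse_relations(raw["obs2_relations"], row, "obs2_relations"),
            measurements=measurements,
            degree=numeric["degree_pct"],
            age=age,
            sex=sex,
        )
        violations = validate_record(record)
        if violations:
            raise CohortReadError(
                f"row {row}: invalid record {lesion_id!r}: " + "; ".join(violations)
            )
        records.append(record)
    return Cohort(records=tuple(records), provenance=provenance or "read_cohort")


def _relations_cell(rels: frozenset[RelationType]) -> str:
    return ";".join(sorted(r.value for r in rels))


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Render a cohort into the CSV dialect's column layout."""
    rows = []
    for r in cohort.records:
        if len(r.measurements) > 1:
            raise ValueError(
                f"{r.lesion_id}: the tabular dialect carries one representative "
                "measurement per lesion; reduce with worst_encasement first"
            )
        m = r.measurements[0] if r.measurements else None

        def num(v: float | None) -> str:
            return "" if v is None else format(v, "g")

        rows.append({
            "lesion_id": r.lesion_id,
            "truth": r.truth,
            "location": r.location,
            "size_mm": num(r.size),
            "obs1_relations": _relations_cell(r.obs1_relations),
            "obs2_relations": _relations_cell(r.obs2_relations),
            "final_relations": _relations_cell(r.final_relations),
            "amputated": "true" if (m and m.amputated) else "false",
            "AB_mm": num(m.AB) if m else "",
            "CD_mm": num(m.CD) if m else "",
            "EF_mm": num(m.EF) if m else "",
            "EC_mm": num(m.EC) if m else "",
            "EA_mm": num(m.EA) if m else "",
            "n_bifurcations": str(m.n_bifurcations) if m else "",
            "narrowest_position": m.narrowest_position.value if m else "",
            "degree_pct": num(r.degree),
            "vessel_id": m.vessel_id if m else "",
            "age_yr": num(r.age),
            "sex": r.sex or "",
        })
    return pd.DataFrame(rows, columns=_COLUMNS + _OPTIONAL_COLUMNS)


def write_cohort(cohort: Cohort, target: str | io.TextIOBase) -> None:
    """Write a cohort as UTF-8, LF-terminated CSV (read_cohort round-trips it)."""
    cohort_to_frame(cohort).to_csv(target, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# report rendering


def _fmt_pct(x: float) -> str:
    return f"{x:.1f}"


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def format_odds_ratio(odds_ratio: float, ci_low: float, ci_high: float) -> str:
    """Render an odds ratio as printed in radiology reports: '18.1 (95% CI: 4.6-71.7)'."""
    return f"{odds_ratio:.1f} (95% CI: {ci_low:.1f}-{ci_high:.1f})"


def format_kappa(kappa: float, grade: str) -> str:
    return f"{kappa:.3f} ({grade})"


def _render_value(value: object) -> str:
    """Dispatch on result type; percentages and ORs at 1 decimal, else 3."""
    if hasattr(value, "odds_ratio"):  # OddsRatioResult
        return format_odds_ratio(value.odds_ratio, value.ci_low, value.ci_high)
    if hasattr(value, "kappa"):  # KappaResult
        return format_kappa(value.kappa, value.grade)
    if hasattr(value, "sensitivity"):  # ConfusionMetrics
        return (
            f"sens {_fmt_pct(value.sensitivity)}% spec {_fmt_pct(value.specificity)}% "
            f"ppv {_fmt_pct(value.ppv)}% npv {_fmt_pct(value.npv)}%"
        )
    if isinstance(value, float):
        return _fmt(value)
    return str(value)


def write_report(results: Mapping[str, object]) -> tuple[str, str]:
    """Render analysis results as (TSV table, human-readable summary).

    Column order is deterministic (insertion order of ``results``).  Keys
    whose value is a percentage should already be on the 0-100 scale.
    """
    lines_tsv = ["quantity\tvalue"]
    lines_md = ["# Analysis report", ""]
    for key, value in results.items():
        rendered = _render_value(value)
        lines_tsv.append(f"{key}\t{rendered}")
        lines_md.append(f"- **{key}**: {rendered}")
    return "\n".join(lines_tsv) + "\n", "\n".join(lines_md) + "\n"
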