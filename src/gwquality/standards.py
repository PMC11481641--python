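"""Parameter standards: identities, units, ideal values and permissible limits.

A :class:`ParameterSpec` carries everything the two indices need to know about
one physicochemical parameter: its ideal value ``Vi`` (the concentration at
which the quality rating is zero), the standard permissible limit ``Vs`` used
by the weighted-arithmetic WQI, an optional lower permissible bound (pH only),
and the upper permissible concentration ``CNi`` used by the contamination
degree (defaulting to ``Vs``).

The shipped default profile ``hu_6_2009`` holds the groundwater contamination
limits of the Hungarian joint decree 6/2009 (IV. 14.) KvVM-EüM-FVM for the
eight parameters routinely measured in municipal monitoring wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ParameterSpec",
    "StandardsError",
    "default_specs",
    "load_standards",
    "save_standards",
    "DEFAULT_PROFILE",
]

DEFAULT_PROFILE = "hu_6_2009"

_DATA_DIR = Path(__file__).parent / "data"


class StandardsError(ValueError):
    """Invalid parameter standards (non-positive limit, empty set, ...)."""


@dataclass(frozen=True)
class ParameterSpec:
    """Identity, unit and regulatory limits of one water-quality parameter.

    Parameters
    ----------
    code:
        Short ASCII identifier (``pH``, ``EC``, ``NH4``, ``NO2``, ``NO3``,
        ``PO4``, ``COD``, ``Na``); the set is extensible.
    unit:
        ``μS/cm`` for EC, dimensionless for pH, ``mg/L`` otherwise.
    ideal_value:
        ``Vi`` — the value at which the quality rating is zero. Zero for all
        concentrations; 7 for pH (neutrality).
    standard_permissible:
        ``Vs`` — the (upper) permissible limit entering the WQI weights.
    lower_permissible:
        Optional lower bound; only pH has one (6.5).
    cd_upper:
        ``CNi`` — upper permissible concentration for the contamination
        degree. Defaults to ``standard_permissible``.
    """

    code: str
    unit: str
    ideal_value: float
    standard_permissible: float
    lower_permissible: float | None = None
    cd_upper: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cd_upper is None:
            object.__setattr__(self, "cd_upper", self.standard_permissible)
        if self.standard_permissible <= 0:
            raise StandardsError(
                f"{self.code}: permissible limit must be positive, "
                f"got {self.standard_permissible}"
            )
        if self.standard_permissible <= self.ideal_value:
            raise StandardsError(
                f"{self.code}: permissible limit ({self.standard_permissible}) "
                f"must exceed the ideal value ({self.ideal_value})"
            )
        if self.cd_upper <= 0:
            raise StandardsError(f"{self.code}: cd_upper must be positive")
        if (
            self.lower_permissible is not None
            and self.lower_permissible >= self.standard_permissible
        ):
            raise StandardsError(
                f"{self.code}: lower permissible bound must lie below the upper"
            )


def default_specs() -> list[ParameterSpec]:
    """The eight-parameter ``hu_6_2009`` profile."""
    return load_standards(DEFAULT_PROFILE)


def load_standards(profile: str | Path = DEFAULT_PROFILE) -> list[ParameterSpec]:
    """Load a standards profile from a shipped name or a YAML/JSON file path.

    The file maps parameter codes to ``{unit, ideal_value,
    standard_permissible, lower_permissible?, cd_upper?}``.
    """
    path = Path(profile)
    if not path.suffix:  # bare profile name -> shipped registry
        path = _DATA_DIR / f"{profile}.yaml"
    if not path.exists():
        raise StandardsError(f"standards profile not found: {profile}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise StandardsError(f"empty standards profile: {profile}")
    specs = []
    for code, entry in raw.items():
        specs.append(
            ParameterSpec(
                code=code,
                unit=entry.get("unit", "mg/L"),
                ideal_value=float(entry.get("ideal_value", 0.0)),
                standard_permissible=float(entry["standard_permissible"]),
                lower_permissible=(
                    float(entry["lower_permissible"])
                    if entry.get("lower_permissible") is not None
                    else None
                ),
                cd_upper=(
                    float(entry["cd_upper"])
                    if entry.get("cd_upper") is not None
                    else None
                ),
            )
        )
    return specs


def save_standards(specs: list[ParameterSpec], path: str | Path) -> None:
    """Write a standards registry as YAML (inverse of :func:`load_standards`)."""
    out: dict[str, dict] = {}
    for s in specs:
        entry: dict = {
            "unit": s.unit,
            "ideal_value": s.ideal_value,
            "standard_permissible": s.standard_permissible,
        }
        if s.lower_permissible is not None:
            entry["lower_permissible"] = s.lower_permissible
        if s.cd_upper != s.standard_permissible:
            entry["cd_upper"] = s.cd_upper
        out[s.code] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
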