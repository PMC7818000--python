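"""Declarative optical-system descriptions (YAML/JSON documents).

A system config is a single mapping with a ``label``, an optional
``object`` block (full height in mm and refractive index) and an ordered
``elements`` list.  Units are implied: millimetres and radians.  Example::

    label: Simple example
    object: {height: 10}
    elements:
      - {kind: space, d: 50}
      - {kind: lens, f: 50, diameter: 25, label: First lens}
      - {kind: space, d: 100}
      - {kind: lens, f: 50, diameter: 25, label: Second lens}
      - {kind: space, d: 50}

Compound kinds (``system2f``, ``system4f``) expand to their primitive
space/lens sequences when the path is built.  Parsing is strict: unknown
kinds and unknown or missing parameters are rejected with the element's
position in the message, and a parsed config serializes back to an
equivalent document (parse . serialize = identity on the normalized
form).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import yaml

from .examples import ObjectiveModel, system_2f, system_4f
from .matrices import (
    make_aperture,
    make_dielectric_interface,
    make_space,
    make_thick_lens,
    make_thin_lens,
)
from .path import ImagingPath

__all__ = [
    "SystemConfig",
    "ConfigError",
    "parse_config",
    "serialize_config",
    "build_path",
    "parse_system_config",
]


class ConfigError(ValueError):
    """A malformed system description."""


#: allowed parameter names per element kind (required, optional)
_KIND_PARAMS: dict[str, tuple[set[str], set[str]]] = {
    "space": ({"d"}, {"n", "label"}),
    "lens": ({"f"}, {"diameter", "label"}),
    "thicklens": ({"n", "R1", "R2", "t"}, {"diameter", "label"}),
    "interface": ({"n1", "n2"}, {"R", "diameter", "label"}),
    "aperture": ({"diameter"}, {"label"}),
    "objective": (
        {"f", "focusToFocusLength", "backAperture"},
        {"na", "workingDistance", "magnification", "fieldNumber", "label"},
    ),
    "system2f": ({"f"}, {"diameter", "label"}),
    "system4f": ({"f1", "f2"}, {"diameter1", "diameter2", "label"}),
}


@dataclass
class SystemConfig:
    """Normalized form of a system description document."""

    label: str = ""
    object_height: float = 10.0
    object_index: float = 1.0
    elements: list[dict] = dc_field(default_factory=list)

    def to_document(self) -> dict:
        return {
            "label": self.label,
            "object": {"height": self.object_height, "index": self.object_index},
            "elements": [dict(el) for el in self.elements],
        }


def _check_element(i: int, el: object) -> dict:
    if not isinstance(el, dict):
        raise ConfigError(f"element {i}: expected a mapping, got {type(el).__name__}")
    kind = el.get("kind")
    if kind not in _KIND_PARAMS:
        known = ", ".join(sorted(_KIND_PARAMS))
        raise ConfigError(f"element {i}: unknown kind {kind!r} (known kinds: {known})")
    required, optional = _KIND_PARAMS[kind]
    keys = set(el) - {"kind"}
    missing = required - keys
    if missing:
        raise ConfigError(
            f"element {i} ({kind}): missing parameter(s) {sorted(missing)}"
        )
    extra = keys - required - optional
    if extra:
        raise ConfigError(
            f"element {i} ({kind}): unknown parameter(s) {sorted(extra)}"
        )
    for key in keys:
        value = el[key]
        if key == "label":
            if not isinstance(value, str):
                raise ConfigError(f"element {i} ({kind}): label must be a string")
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(
                f"element {i} ({kind}): parameter {key!r} must be a number"
            )
    return dict(el)


def parse_config(text: str) -> SystemConfig:
    """Parse and validate a YAML/JSON system description."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(doc) - {"label", "object", "elements"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    obj = doc.get("object", {}) or {}
    if not isinstance(obj, dict) or set(obj) - {"height", "index"}:
        raise ConfigError("object block must be a mapping with height/index")
    elements = doc.get("elements")
    if not isinstance(elements, list) or not elements:
        raise ConfigError("config must contain a non-empty 'elements' list")
    return SystemConfig(
        label=str(doc.get("label", "")),
        object_height=float(obj.get("height", 10.0)),
        object_index=float(obj.get("index", 1.0)),
        elements=[_check_element(i, el) for i, el in enumerate(elements)],
    )


def serialize_config(config: SystemConfig) -> str:
    """Render a config back to YAML (lossless round-trip with
    :func:`parse_config`)."""
    return yaml.safe_dump(config.to_document(), sort_keys=False)


def _build_element(i: int, el: dict):
    kind = el["kind"]
    label = el.get("label", "")
    diameter = el.get("diameter", math.inf)
    if kind == "space":
        return [make_space(el["d"], n=el.get("n", 1.0), label=label)]
    if kind == "lens":
        return [make_thin_lens(el["f"], diameter=diameter, label=label)]
    if kind == "thicklens":
        return [
            make_thick_lens(
                el["n"], el["R1"], el["R2"], el["t"], diameter=diameter, label=label
            )
        ]
    if kind == "interface":
        return [
            make_dielectric_interface(
                el.get("R", math.inf), el["n1"], el["n2"],
                diameter=diameter, label=label,
            )
        ]
    if kind == "aperture":
        return [make_aperture(el["diameter"], label=label)]
    if kind == "objective":
        model = ObjectiveModel(
            f=el["f"],
            na=el.get("na", 0.0),
            focus_to_focus_length=el["focusToFocusLength"],
            back_aperture=el["backAperture"],
            working_distance=el.get("workingDistance", 0.0),
            magnification=el.get("magnification", 0.0),
            field_number=el.get("fieldNumber", 0.0),
            label=label,
        )
        return [model.as_matrix()]
    if kind == "system2f":
        return system_2f(el["f"], diameter=diameter, label=label)
    if kind == "system4f":
        return system_4f(
            el["f1"], el["f2"],
            diameter1=el.get("diameter1", math.inf),
            diameter2=el.get("diameter2", math.inf),
            label=label,
        )
    raise ConfigError(f"element {i}: unknown kind {kind!r}")


def build_path(config: SystemConfig) -> ImagingPath:
    """Instantiate the described system as an :class:`ImagingPath`."""
    path = ImagingPath(
        object_height=config.object_height,
        object_index=config.object_index,
        label=config.label,
    )
    for i, el in enumerate(config.elements):
        try:
            path.append(_build_element(i, el))
        except (ValueError, TypeError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"element {i} ({el.get('kind')}): {exc}") from exc
    return path


def parse_system_config(text: str) -> ImagingPath:
    """Parse a document and build the equivalent imaging path."""
    return build_path(parse_config(text))
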