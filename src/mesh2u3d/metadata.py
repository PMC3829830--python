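"""String-encoded per-patch export properties.

Each patch carries a free-text description that encodes its U3D export
properties as ``Key=Value`` entries separated by ``;``:

    ModelName=Femur;GroupName=Skeleton/Left;ObjectColor=0.8,0.1,0.1,1

Allowed keys are ``ModelName``, ``GroupName``, ``GroupColor``,
``ObjectColor`` and ``SpecularColor``.  Color values are comma-separated
decimals in [0, 1] — four components (RGBA) for ObjectColor/GroupColor,
three (RGB) for SpecularColor.  ``/`` separates path levels inside
GroupName and is reserved everywhere else; ``;`` and ``=`` are reserved in
all name values.
"""

from __future__ import annotations

import logging
from typing import List, Sequence, Tuple

from .scene_model import Scene, U3DProperties

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptionError",
    "compose_description",
    "parse_description",
    "resolve_scene_properties",
    "DEFAULT_OBJECT_RGBA",
    "DEFAULT_SPECULAR_RGB",
    "DEFAULT_MODEL_NAME",
]

DEFAULT_OBJECT_RGBA = (0.7, 0.7, 0.7, 1.0)
DEFAULT_SPECULAR_RGB = (0.1, 0.1, 0.1)
DEFAULT_MODEL_NAME = "Model"

_KEYS = ("ModelName", "GroupName", "GroupColor", "ObjectColor", "SpecularColor")
_COLOR_ARITY = {"ObjectColor": 4, "GroupColor": 4, "SpecularColor": 3}


class DescriptionError(ValueError):
    """Raised for a malformed or out-of-grammar description string."""


def _format_color(components: Sequence[float]) -> str:
    # repr() gives the shortest decimal that round-trips through float()
    return ",".join(repr(float(c)) for c in components)


def _check_name(key: str, value: str) -> None:
    reserved = ";=" if key == "GroupName" else ";=/"
    for ch in reserved:
        if ch in value:
            raise DescriptionError(f"{key} value {value!r} contains reserved character {ch!r}")


def compose_description(props: U3DProperties) -> str:
    """Encode properties as a canonical description string.

    Fields appear in the fixed order ModelName, GroupName, GroupColor,
    ObjectColor, SpecularColor; unset fields are omitted; colors are
    rendered with round-trip precision so ``parse_description`` recovers
    them exactly.
    """
    entries: List[str] = []
    if props.model_name is not None:
        _check_name("ModelName", props.model_name)
        entries.append(f"ModelName={props.model_name}")
    if props.group_name is not None:
        _check_name("GroupName", props.group_name)
        entries.append(f"GroupName={props.group_name}")
    if props.group_rgba is not None:
        entries.append(f"GroupColor={_format_color(props.group_rgba)}")
    if props.object_rgba is not None:
        entries.append(f"ObjectColor={_format_color(props.object_rgba)}")
    if props.specular_rgb is not None:
        entries.append(f"SpecularColor={_format_color(props.specular_rgb)}")
    return ";".join(entries)


def _parse_color(key: str, value: str) -> Tuple[float, ...]:
    parts = value.split(",")
    want = _COLOR_ARITY[key]
    if len(parts) != want:
        raise DescriptionError(
            f"{key} needs {want} comma-separated components, got {len(parts)}: {value!r}"
        )
    try:
        comps = tuple(float(p) for p in parts)
    except ValueError as exc:
        raise DescriptionError(f"{key}: non-numeric component in {value!r}") from exc
    for c in comps:
        if not (0.0 <= c <= 1.0):
            raise DescriptionError(f"{key}: component {c!r} outside [0, 1]")
    return comps


def parse_description(text: str) -> U3DProperties:
    """Parse a description string; unknown or malformed entries raise.

    The empty string yields a properties object with every field unset.
    Every entry in the input is either reflected in the result or raises a
    :class:`DescriptionError` — nothing is silently dropped.
    """
    props = U3DProperties()
    if not text.strip():
        return props
    seen = set()
    for raw in text.split(";"):
        entry = raw.strip()
        if not entry:
            continue
        if "=" not in entry:
            raise DescriptionError(f"malformed entry (no '='): {entry!r}")
        key, _, value = entry.partition("=")
        key = key.strip()
        if key not in _KEYS:
            raise DescriptionError(f"unknown key {key!r} (allowed: {', '.join(_KEYS)})")
        if key in seen:
            raise DescriptionError(f"duplicate key {key!r}")
        seen.add(key)
        if key == "ModelName":
            _check_name(key, value)
            props.model_name = value
        elif key == "GroupName":
            _check_name(key, value)
            props.group_name = value
        elif key == "GroupColor":
            props.group_rgba = _parse_color(key, value)
        elif key == "ObjectColor":
            props.object_rgba = _parse_color(key, value)
        elif key == "SpecularColor":
            props.specular_rgb = _parse_color(key, value)
    return props


def resolve_scene_properties(scene: Scene):
    """Parse every patch description and apply scene-level defaults.

    Returns ``(per_patch_properties, model_name)``.  The model name is the
    first non-empty ModelName in patch order (conflicting later values are
    logged and ignored), falling back to the scene's own ``model_name`` and
    finally to ``"Model"``.  Each patch gets a concrete object color
    (default mid-gray, opaque) and specular color (default dim gray).
    """
    resolved: List[U3DProperties] = []
    model_name = ""
    for patch in scene.patches:
        props = parse_description(patch.description)
        if props.model_name:
            if not model_name:
                model_name = props.model_name
            elif props.model_name != model_name:
                logger.warning(
                    "conflicting ModelName %r on patch %r; keeping %r",
                    props.model_name, patch.label, model_name,
                )
        if props.object_rgba is None:
            props.object_rgba = DEFAULT_OBJECT_RGBA
        if props.specular_rgb is None:
            props.specular_rgb = DEFAULT_SPECULAR_RGB
        resolved.append(props)
    if not model_name:
        model_name = scene.model_name or DEFAULT_MODEL_NAME
    return resolved, model_name
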