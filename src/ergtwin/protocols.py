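"""Stimulus protocol definitions, loaded from the packaged YAML config."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Dict, List, Tuple

import yaml

from ergtwin.forward_model import StimulusSpec

__all__ = [
    "standard_protocol",
    "protocol_by_label",
    "xenon_pairs",
    "XENON_STRENGTHS",
]

#: Xenon flash strengths delivered both in the dark and on the blue
#: rod-saturating background (photopic cd·m⁻²·s).
XENON_STRENGTHS: Tuple[float, ...] = (0.67, 4.0, 13.0, 67.0)


def _strength_tag(strength: float) -> str:
    return f"{strength:g}"


@lru_cache(maxsize=1)
def standard_protocol() -> List[StimulusSpec]:
    """The full stimulus set, in delivery order."""
    text = resources.files("ergtwin").joinpath("data/protocols.yaml").read_text()
    cfg = yaml.safe_load(text)
    backgrounds = cfg["backgrounds"]
    out = []
    for item in cfg["stimuli"]:
        bg = backgrounds[item["background"]]
        out.append(
            StimulusSpec(
                label=item["label"],
                flash_strength=float(item["flash_strength"]),
                background_kind=bg["kind"],
                background_scotopic_luminance=float(bg["scotopic"]),
                background_photopic_luminance=float(bg["photopic"]),
                mode=item["mode"],
            )
        )
    return out


def protocol_by_label() -> Dict[str, StimulusSpec]:
    return {s.label: s for s in standard_protocol()}


def xenon_pairs() -> List[Tuple[float, StimulusSpec, StimulusSpec]]:
    """(flash_strength, dark stimulus, blue-background stimulus) for each
    xenon strength — the input pairs of the rod-isolation subtraction."""
    by_label = protocol_by_label()
    out = []
    for strength in XENON_STRENGTHS:
        tag = _strength_tag(strength)
        out.append((strength, by_label[f"X{tag}-dark"], by_label[f"X{tag}-blue"]))
    return out
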