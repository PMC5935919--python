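"""VOC feature panels.

An IMR-MS breath panel is an ordered list of feature labels. Twelve compounds
carry a direct calibration and are named; every other channel is reported as
``M<MW>`` where ``<MW>`` is the integer molecular weight of the detected ion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "VOCPanel",
    "CALIBRATED_COMPOUNDS",
    "ENV_EXCESS_MASSES",
    "FINAL_MODEL_VOCS",
    "STUDY_PANEL",
    "mass_weight",
]

#: Compounds with a direct instrument calibration (all others are mass labels).
CALIBRATED_COMPOUNDS: tuple[str, ...] = (
    "methanol",
    "acetonitrile",
    "ethanol",
    "MEK",
    "acetone",
    "isoprene",
    "n-propanol",
    "benzene",
    "toluene",
    "n-heptane",
    "ammonia",
    "sulfur dioxide",
)

#: The 22 mass channels whose environmental (room-air) concentration exceeded
#: the alveolar one in the study cohort; they are of exogenous origin and are
#: dropped before modelling.  "M18" is carried as printed in the source table;
#: "M118" is accepted as an alias (see ``normalize_label``).
ENV_EXCESS_MASSES: tuple[str, ...] = (
    "M19", "M26", "M27", "M28", "M31", "M32", "M45", "M48", "M49", "M73",
    "M92", "M97", "M98", "M102", "M103", "M104", "M105", "M116", "M117",
    "M18", "M120", "M121",
)

#: Mass channels that entered the published first-stage screen.
_SCREEN_MASSES: tuple[str, ...] = (
    "M34", "M37", "M42", "M43", "M44", "M46", "M60", "M62", "M66", "M71",
    "M74", "M75", "M88", "M89", "M91", "M106", "M111", "M112",
)

#: The ten VOCs of the final published diagnostic model.
FINAL_MODEL_VOCS: tuple[str, ...] = (
    "ammonia", "M34", "M43", "M44", "M62", "sulfur dioxide",
    "M71", "M74", "M89", "M112",
)

# Unnamed trace channels filling the panel out to the instrument's 92
# reported features.  The study names only 40 of its 80 mass labels; these 40
# molecular weights are a synthetic reconstruction chosen not to collide with
# any named channel.
_FILLER_MASSES: tuple[str, ...] = (
    "M30", "M33", "M35", "M36", "M39", "M40", "M47", "M50", "M52", "M53",
    "M54", "M55", "M56", "M57", "M59", "M61", "M63", "M65", "M67", "M69",
    "M70", "M76", "M77", "M79", "M80", "M81", "M82", "M83", "M84", "M85",
    "M86", "M87", "M90", "M93", "M94", "M95", "M96", "M99", "M101", "M107",
)

_MASS_RE = re.compile(r"^M(\d+)$")


def mass_weight(label: str) -> int | None:
    """Integer molecular weight of an ``M<MW>`` label, or None for a name."""
    m = _MASS_RE.match(label)
    return int(m.group(1)) if m else None


def normalize_label(label: str, known: "set[str] | frozenset[str]") -> str:
    """Resolve a label against a panel, honouring the M18/M118 alias."""
    if label in known:
        return label
    alias = {"M118": "M18", "M18": "M118"}.get(label)
    if alias is not None and alias in known:
        return alias
    raise KeyError(f"label {label!r} not in panel")


@dataclass(frozen=True)
class VOCPanel:
    """Ordered, duplicate-free list of VOC feature labels."""

    names: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate panel labels: {dupes}")
        for n in names:
            mw = mass_weight(n)
            if n not in CALIBRATED_COMPOUNDS and mw is None:
                raise ValueError(
                    f"label {n!r} is neither a calibrated compound nor an M<MW> mass"
                )
            if mw is not None and mw <= 0:
                raise ValueError(f"mass label {n!r} must carry a positive MW")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def count(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        return self._index[normalize_label(label, self._index.keys())]

    def subset(self, labels) -> "VOCPanel":
        """Sub-panel in this panel's order (labels may use the M18/M118 alias)."""
        keep = {normalize_label(l, self._index.keys()) for l in labels}
        return VOCPanel(tuple(n for n in self.names if n in keep))

    def drop(self, labels) -> "VOCPanel":
        out = {normalize_label(l, self._index.keys()) for l in labels}
        return VOCPanel(tuple(n for n in self.names if n not in out))


#: The full 92-feature study panel: 12 calibrated compounds + 80 mass labels.
STUDY_PANEL = VOCPanel(
    CALIBRATED_COMPOUNDS + _SCREEN_MASSES + ENV_EXCESS_MASSES + _FILLER_MASSES
)

assert STUDY_PANEL.count == 92
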