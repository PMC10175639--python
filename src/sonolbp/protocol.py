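"""Acquisition protocol and feature naming.

The study protocol images four lumbar structures — multifidus (MF), erector
spinae (ES), thoracolumbar fascia (TLF) and transversus abdominis (TrA) —
at up to two vertebral levels (L2-L3, L4-L5), on both sides, in one or two
patient positions (prone, tabletop).  MF is imaged at both levels, both
sides and both positions (8 regions of interest); ES, TLF and TrA are imaged
at L2-L3, both sides, prone only (6 ROIs), for 14 ROIs per subject.

Each ROI yields 57 features (2 spectral MFAF + 7 first-order + 24 Haralick +
20 Galloway + 2 LBP + 2 shear-wave elasticity values); two muscle-thickness
features (TLF and TrA, averaged over sides) complete the 800-feature vector.

This module owns the structured identity of one feature (:class:`FeatureName`),
its serialized form (``L2-L3_R_MF_SWE.Std (prone position)``), the canonical
feature ordering, and the full 800-name universe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

LEVELS = ("L2-L3", "L4-L5")
SIDES = ("L", "R", "LR")  # "LR" marks a side-averaged (global) feature
MUSCLES = ("MF", "ES", "TLF", "TrA")
POSITIONS = ("prone", "tabletop")
FAMILIES = ("morphological", "mfaf", "fos", "haralick", "galloway", "lbp", "swe")

DIRECTIONS = ("0°", "45°", "90°", "135°")
MFAF_METHODS = ("maxent", "multiwindow")

FOS_STATS = ("IOD", "Mean", "Std", "Variance", "Skewness", "Kurtosis", "Energy")
HARALICK_STATS = ("Contrast", "Correlation", "Energy", "Entropy", "Homogeneity", "Symmetry")
GALLOWAY_STATS = ("SRE", "LRE", "GLNU", "RLNU", "RP")
LBP_STATS = ("Energy", "Entropy")
SWE_STATS = ("Mean", "Std")

_FAMILY_LABEL = {
    "morphological": "Morphological",
    "mfaf": "MFAF",
    "fos": "FirstOrderFeature",
    "haralick": "HaralickFeature",
    "galloway": "GallowayFeature",
    "lbp": "LBP",
    "swe": "SWE",
}
_LABEL_FAMILY = {v: k for k, v in _FAMILY_LABEL.items()}

_METHOD_PHRASE = {"maxent": "maximum entropy", "multiwindow": "multi-window"}
_PHRASE_METHOD = {v: k for k, v in _METHOD_PHRASE.items()}

_FAMILY_STATS = {
    "morphological": ("Thickness",),
    "mfaf": ("",),
    "fos": FOS_STATS,
    "haralick": HARALICK_STATS,
    "galloway": GALLOWAY_STATS,
    "lbp": LBP_STATS,
    "swe": SWE_STATS,
}


class ProtocolError(ValueError):
    """Raised when data violates the 14-ROI acquisition protocol."""


@dataclass(frozen=True, order=False)
class ROIKey:
    """Identity of one imaged region: vertebral level, side, muscle, position."""

    level: str
    side: str
    muscle: str
    position: str

    def __post_init__(self) -> None:
        if (self.level, self.side, self.muscle, self.position) not in _VALID_KEY_TUPLES:
            raise ProtocolError(
                f"({self.level}, {self.side}, {self.muscle}, {self.position}) "
                "is not one of the 14 protocol ROIs: MF at L2-L3/L4-L5 x L/R x "
                "prone/tabletop; ES, TLF, TrA at L2-L3 x L/R, prone only"
            )

    def site_label(self) -> str:
        """Compact site tag used in the per-site comparison table, e.g. L2-L3_L_MF_TBT."""
        tag = f"{self.level}_{self.side}_{self.muscle}"
        return tag + "_TBT" if self.position == "tabletop" else tag


def _build_protocol_keys() -> tuple[tuple[str, str, str, str], ...]:
    keys = []
    for level in LEVELS:
        for side in ("L", "R"):
            for position in POSITIONS:
                keys.append((level, side, "MF", position))
    for muscle in ("ES", "TLF", "TrA"):
        for side in ("L", "R"):
            keys.append(("L2-L3", side, muscle, "prone"))
    return tuple(keys)


_VALID_KEY_TUPLES = frozenset(_build_protocol_keys())

#: The 14 protocol ROIs (MF x 8, then ES/TLF/TrA x 2 each).
PROTOCOL_KEYS: tuple[ROIKey, ...] = tuple(
    ROIKey(*t) for t in _build_protocol_keys()
)


@dataclass(frozen=True)
class FeatureName:
    """Structured identity of one feature.

    ``side == "LR"`` marks a side-averaged feature (the two thickness
    features); those are attributed to level L2-L3 and the prone position,
    matching the protocol denominators (572 features at L2-L3 and prone,
    399 per side plus the 2 side-averaged ones).

    ``qualifier`` is a direction (``"0°"`` ... ``"135°"``) for Haralick and
    Galloway features, an MFAF method (``"maxent"``/``"multiwindow"``), and
    ``None`` otherwise.
    """

    level: str
    side: str
    muscle: str
    position: str
    family: str
    statistic: str
    qualifier: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ProtocolError(f"unknown feature family {self.family!r}")
        if self.family in ("haralick", "galloway"):
            if self.qualifier not in DIRECTIONS:
                raise ProtocolError(f"{self.family} feature needs a direction qualifier")
        elif self.family == "mfaf":
            if self.qualifier not in MFAF_METHODS:
                raise ProtocolError("mfaf feature needs a method qualifier")
        elif self.qualifier is not None:
            raise ProtocolError(f"{self.family} feature takes no qualifier")

    def serialize(self) -> str:
        """Render the conventional name, e.g.
        ``L2-L3_R_TLF_GallowayFeature.RLNU (prone position, direction = 0°)``."""
        base = f"{self.level}_{self.side}_{self.muscle}_{_FAMILY_LABEL[self.family]}"
        if self.family != "mfaf":
            base += f".{self.statistic}"
        extras = [f"{self.position} position"]
        if self.family in ("haralick", "galloway"):
            extras.append(f"direction = {self.qualifier}")
        elif self.family == "mfaf":
            extras.append(f"calculated by {_METHOD_PHRASE[self.qualifier]} method")
        return f"{base} ({', '.join(extras)})"

    def sort_key(self) -> tuple:
        family = self.family
        stats = _FAMILY_STATS[family]
        if family in ("haralick", "galloway"):
            qual_idx = DIRECTIONS.index(self.qualifier)
        elif family == "mfaf":
            qual_idx = MFAF_METHODS.index(self.qualifier)
        else:
            qual_idx = 0
        return (
            LEVELS.index(self.level),
            SIDES.index(self.side),
            MUSCLES.index(self.muscle),
            POSITIONS.index(self.position),
            FAMILIES.index(family),
            stats.index(self.statistic) if self.statistic in stats else len(stats),
            qual_idx,
        )


_NAME_RE = re.compile(
    r"^(?P<level>L2-L3|L4-L5)_(?P<side>LR|L|R)_(?P<muscle>MF|ES|TLF|TrA)_"
    r"(?P<famlabel>[A-Za-z]+)(?:\.(?P<stat>[A-Za-z]+))?"
    r" \((?P<position>prone|tabletop) position"
    r"(?:, direction = (?P<direction>0°|45°|90°|135°))?"
    r"(?:, calculated by (?P<method>maximum entropy|multi-window) method)?\)$"
)


def parse_feature_name(text: str) -> FeatureName:
    """Inverse of :meth:`FeatureName.serialize`."""
    m = _NAME_RE.match(text)
    if m is None:
        raise ProtocolError(f"unparseable feature name: {text!r}")
    family = _LABEL_FAMILY.get(m.group("famlabel"))
    if family is None:
        raise ProtocolError(f"unknown family label in {text!r}")
    qualifier: str | None
    if family == "mfaf":
        qualifier = _PHRASE_METHOD[m.group("method")]
        statistic = ""
    else:
        qualifier = m.group("direction")
        statistic = m.group("stat") or ""
    return FeatureName(
        level=m.group("level"),
        side=m.group("side"),
        muscle=m.group("muscle"),
        position=m.group("position"),
        family=family,
        statistic=statistic,
        qualifier=qualifier,
    )


@lru_cache(maxsize=32)
def roi_feature_names(key: ROIKey) -> tuple[FeatureName, ...]:
    """The 57 feature identities of one ROI, in family order."""
    common = dict(level=key.level, side=key.side, muscle=key.muscle, position=key.position)
    names: list[FeatureName] = []
    for method in MFAF_METHODS:
        names.append(FeatureName(**common, family="mfaf", statistic="", qualifier=method))
    for stat in FOS_STATS:
        names.append(FeatureName(**common, family="fos", statistic=stat))
    for stat in HARALICK_STATS:
        for direction in DIRECTIONS:
            names.append(FeatureName(**common, family="haralick", statistic=stat, qualifier=direction))
    for stat in GALLOWAY_STATS:
        for direction in DIRECTIONS:
            names.append(FeatureName(**common, family="galloway", statistic=stat, qualifier=direction))
    for stat in LBP_STATS:
        names.append(FeatureName(**common, family="lbp", statistic=stat))
    for stat in SWE_STATS:
        names.append(FeatureName(**common, family="swe", statistic=stat))
    return tuple(names)


def thickness_feature_names() -> tuple[FeatureName, ...]:
    """The two side-averaged thickness features (TLF, TrA)."""
    return tuple(
        FeatureName(
            level="L2-L3", side="LR", muscle=muscle, position="prone",
            family="morphological", statistic="Thickness",
        )
        for muscle in ("TLF", "TrA")
    )


@lru_cache(maxsize=1)
def feature_universe() -> tuple[FeatureName, ...]:
    """All 800 feature identities in canonical order
    (level, side, muscle, position, family, statistic, qualifier)."""
    names: list[FeatureName] = []
    for key in PROTOCOL_KEYS:
        names.extend(roi_feature_names(key))
    names.extend(thickness_feature_names())
    names.sort(key=FeatureName.sort_key)
    return tuple(names)


@lru_cache(maxsize=1)
def feature_universe_serialized() -> tuple[str, ...]:
    return tuple(n.serialize() for n in feature_universe())
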