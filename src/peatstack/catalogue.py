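"""Land-cover classification scheme for coastal tropical peatland landscapes.

Twelve thematic classes grouped into six general classes. The four swamp /
bog classes constitute the peatland group; plantation crops (coconut,
rubber, oil palm) are kept separate from natural forest because their
conversion pressure on peat is the management question the map serves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical class order used everywhere (maps, confusion matrices, reports).
CLASS_NAMES: tuple[str, ...] = (
    "mangrove swamp",
    "mixed swamp",
    "palm swamp",
    "bog plain",
    "natural forest",
    "sparse vegetation",
    "coconut",
    "rubber",
    "oil palm",
    "built-up",
    "bare surface",
    "water",
)

GENERAL_CLASS_MAP: dict[str, str] = {
    "mangrove swamp": "Peatland",
    "mixed swamp": "Peatland",
    "palm swamp": "Peatland",
    "bog plain": "Peatland",
    "natural forest": "Forest",
    "sparse vegetation": "Sparse",
    "coconut": "Plantation",
    "rubber": "Plantation",
    "oil palm": "Plantation",
    "built-up": "Artificial and bare areas",
    "bare surface": "Artificial and bare areas",
    "water": "Hydrology",
}

PEATLAND_CLASSES: tuple[str, ...] = CLASS_NAMES[:4]


@dataclass(frozen=True)
class ClassCatalogue:
    """Ordered land-cover classes plus their general-class grouping.

    Invariants enforced at construction: exactly 12 classes, every class
    mapped to exactly one general class, and the four peatland classes
    mapped to ``Peatland``.
    """

    classes: tuple[str, ...] = CLASS_NAMES
    general_class_map: dict[str, str] = field(
        default_factory=lambda: dict(GENERAL_CLASS_MAP)
    )

    def __post_init__(self) -> None:
        if len(self.classes) != 12:
            raise ValueError(f"catalogue must hold 12 classes, got {len(self.classes)}")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names in catalogue")
        missing = [c for c in self.classes if c not in self.general_class_map]
        if missing:
            raise ValueError(f"classes without a general class: {missing}")
        for c in PEATLAND_CLASSES:
            if c in self.classes and self.general_class_map[c] != "Peatland":
                raise ValueError(f"{c!r} must map to the Peatland general class")

    def index(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise KeyError(f"unknown land-cover class {name!r}") from None

    def general_classes(self) -> list[str]:
        """General classes in first-appearance order."""
        seen: list[str] = []
        for c in self.classes:
            g = self.general_class_map[c]
            if g not in seen:
                seen.append(g)
        return seen

    def members(self, general: str) -> list[str]:
        return [c for c in self.classes if self.general_class_map[c] == general]

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)


def default_catalogue() -> ClassCatalogue:
    return ClassCatalogue()
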