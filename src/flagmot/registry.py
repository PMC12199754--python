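"""Default query-protein registry: 54 flagellar proteins with functional classes.

This registry is synthetic: it enumerates a standard 54-member flagellar
regulon (C-ring rotor, MS/P/L rings, rod and hook, H and T rings, filament,
stator, type-III export apparatus, and regulators) with amino-acid length
ranges typical of each protein family. Real screens should supply their own
query specifications derived from the representative sequences actually used
for the homology search; this table exists so the pipeline and its simulators
run end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

FUNCTIONAL_CLASSES = (
    "C-ring",
    "MSP & L rings",
    "rod & hook",
    "H & T rings",
    "filament",
    "stator",
    "T3SS",
    "regulator",
    "other",
)


@dataclass(frozen=True)
class QueryProteinSpec:
    """One query protein: name, flagellar substructure, accepted subject-length range."""

    name: str
    functional_class: str
    length_min: int
    length_max: int
    n_representatives: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.length_min <= self.length_max):
            raise ValueError(
                f"{self.name}: need 0 < length_min <= length_max, "
                f"got ({self.length_min}, {self.length_max})"
            )
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"{self.name}: unknown functional class {self.functional_class!r}"
            )


# name, class, length_min, length_max (aa). Ranges are family-typical spans.
_DEFAULT_TABLE = [
    # C-ring (rotor)
    ("FliG", "C-ring", 280, 370),
    ("FliM", "C-ring", 280, 400),
    ("FliN", "C-ring", 90, 180),
    ("FliY", "C-ring", 250, 420),
    # MS ring and P/L rings
    ("FliF", "MSP & L rings", 450, 620),
    ("FliL", "MSP & L rings", 130, 250),
    ("FlgA", "MSP & L rings", 180, 280),
    ("FlgH", "MSP & L rings", 200, 260),
    ("FlgI", "MSP & L rings", 320, 400),
    # rod and hook
    ("FliE", "rod & hook", 90, 140),
    ("FliK", "rod & hook", 300, 480),
    ("FlgB", "rod & hook", 110, 180),
    ("FlgC", "rod & hook", 120, 180),
    ("FlgD", "rod & hook", 200, 320),
    ("FlgE", "rod & hook", 380, 480),
    ("FlgF", "rod & hook", 220, 280),
    ("FlgG", "rod & hook", 240, 290),
    ("FlgJ", "rod & hook", 290, 400),
    ("FlgK", "rod & hook", 500, 690),
    ("FlgL", "rod & hook", 290, 430),
    ("FlgN", "rod & hook", 120, 180),
    # H ring and T ring (sodium-driven motor accessories)
    ("FlgO", "H & T rings", 200, 300),
    ("FlgP", "H & T rings", 150, 230),
    ("FlgQ", "H & T rings", 120, 200),
    ("FlgT", "H & T rings", 320, 400),
    ("MotX", "H & T rings", 190, 230),
    ("MotY", "H & T rings", 270, 320),
    # filament
    ("FliC", "filament", 250, 610),
    ("FliD", "filament", 400, 670),
    ("FliS", "filament", 110, 160),
    ("FliT", "filament", 90, 140),
    # stator
    ("MotA", "stator", 230, 300),
    ("MotB", "stator", 250, 350),
    ("MotC", "stator", 380, 480),
    ("MotD", "stator", 240, 320),
    # type-III export apparatus
    ("FlhA", "T3SS", 650, 720),
    ("FlhB", "T3SS", 330, 400),
    ("FlhE", "T3SS", 120, 160),
    ("FliH", "T3SS", 200, 280),
    ("FliI", "T3SS", 400, 480),
    ("FliJ", "T3SS", 130, 170),
    ("FliO", "T3SS", 90, 160),
    ("FliP", "T3SS", 220, 280),
    ("FliQ", "T3SS", 80, 110),
    ("FliR", "T3SS", 240, 280),
    # regulators
    ("FliA", "regulator", 220, 260),
    ("FlhC", "regulator", 170, 220),
    ("FlhD", "regulator", 100, 140),
    ("FlhF", "regulator", 380, 490),
    ("FlgM", "regulator", 80, 120),
    ("FlrA", "regulator", 440, 500),
    ("FlrC", "regulator", 440, 490),
    # transporters and sigma factors
    ("RpoN", "other", 440, 520),
    ("RpoD", "other", 550, 680),
]


def default_query_specs() -> dict[str, QueryProteinSpec]:
    """The built-in 54-protein query set keyed by protein name."""
    specs = {
        name: QueryProteinSpec(name, cls, lo, hi) for name, cls, lo, hi in _DEFAULT_TABLE
    }
    assert len(specs) == 54
    return specs


def default_protein_names() -> list[str]:
    return [row[0] for row in _DEFAULT_TABLE]


def default_class_map() -> dict[str, str]:
    """protein name -> functional class for the built-in query set."""
    return {row[0]: row[1] for row in _DEFAULT_TABLE}
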