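"""Fixed cell-type vocabulary for analyzer-style white-blood-cell labels."""

from __future__ import annotations

CELL_TYPES: tuple[str, ...] = (
    "segmented neutrophil",
    "band neutrophil",
    "lymphocyte",
    "monocyte",
    "eosinophil",
    "basophil",
    "blast",
    "promyelocyte",
    "promonocyte",
    "myelocyte",
    "metamyelocyte",
    "erythroblast",
    "platelet",
    "smudge",
    "artefact",
    "unidentified",
)

#: the immature myeloid compartment ("Blasts" training scope)
IMMATURE_MYELOID: frozenset[str] = frozenset(
    {"blast", "promonocyte", "promyelocyte", "myelocyte", "metamyelocyte"}
)


class CellTypeError(ValueError):
    """Raised for a cell-type string outside the fixed vocabulary."""

    def __init__(self, cell_type: str):
        super().__init__(
            f"unknown cell type {cell_type!r}; expected one of {', '.join(CELL_TYPES)}"
        )
        self.cell_type = cell_type
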