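"""Class taxonomy for single-cell white-blood-cell (WBC) images.

The taxonomy distinguishes *atypical* WBCs — immature precursors and reactive
lymphocytes seen in acute myeloid leukemia (AML) blood smears — from *typical*
mature leukocytes. The eight atypical subtypes are fixed; the typical side of
the taxonomy is configurable because mature-cell panels vary between datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Canonical (alphabetical) ordering of the eight atypical subtypes. This order
#: defines the index layout of Stage-II prediction vectors and of every
#: atypical confusion matrix; it is defined here and nowhere else.
ATYPICAL_CLASSES: tuple[str, ...] = (
    "erythroblast",
    "lymphocyte_atypical",
    "metamyelocyte",
    "monoblast",
    "myeloblast",
    "myelocyte",
    "promyelocyte",
    "promyelocyte_bilobed",
)

#: Default mature/typical panel (7 classes), completing the 15-class taxonomy.
DEFAULT_TYPICAL_CLASSES: tuple[str, ...] = (
    "basophil",
    "eosinophil",
    "lymphocyte_typical",
    "monocyte",
    "neutrophil_band",
    "neutrophil_segmented",
    "smudge",
)

TYPICAL = "typical"
ATYPICAL = "atypical"


class TaxonomyError(ValueError):
    """A label is not part of the class taxonomy."""


@dataclass(frozen=True)
class Taxonomy:
    """The full WBC label set and its typical/atypical grouping.

    Parameters
    ----------
    typical_classes
        Names of the typical (mature) classes. The atypical side is fixed.
    """

    typical_classes: tuple[str, ...] = DEFAULT_TYPICAL_CLASSES
    atypical_classes: tuple[str, ...] = field(default=ATYPICAL_CLASSES, init=False)

    def __post_init__(self) -> None:
        overlap = set(self.typical_classes) & set(self.atypical_classes)
        if overlap:
            raise TaxonomyError(f"labels cannot be both typical and atypical: {sorted(overlap)}")
        if len(set(self.typical_classes)) != len(self.typical_classes):
            raise TaxonomyError("duplicate typical class names")

    @property
    def labels(self) -> tuple[str, ...]:
        """All labels, atypical first in canonical order, then typical sorted."""
        return self.atypical_classes + tuple(sorted(self.typical_classes))

    def __contains__(self, label: str) -> bool:
        return label in self.atypical_classes or label in self.typical_classes

    def group(self, label: str) -> str:
        """Return ``"typical"`` or ``"atypical"`` for a label."""
        if label in self.atypical_classes:
            return ATYPICAL
        if label in self.typical_classes:
            return TYPICAL
        raise TaxonomyError(f"unknown class label: {label!r}")

    def is_atypical(self, label: str) -> bool:
        return self.group(label) == ATYPICAL

    def atypical_index(self, label: str) -> int:
        """Canonical index of an atypical label (0..7)."""
        try:
            return self.atypical_classes.index(label)
        except ValueError:
            raise TaxonomyError(f"not an atypical class label: {label!r}") from None

    def atypical_label(self, index: int) -> str:
        """Inverse of :meth:`atypical_index`."""
        return self.atypical_classes[index]

    def validate(self, labels: Iterable[str]) -> None:
        """Raise :class:`TaxonomyError` naming the first unknown label."""
        for i, lab in enumerate(labels):
            if lab not in self:
                raise TaxonomyError(f"unknown class label {lab!r} (record {i})")


def default_taxonomy() -> Taxonomy:
    """The 15-class taxonomy used throughout: 8 atypical + 7 default typical."""
    return Taxonomy()
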