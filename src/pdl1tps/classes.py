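"""Tissue class scheme for PD-L1 IHC region classification.

The scoring workflow distinguishes eight region types on an SP263-stained
slide: PD-L1 positive and negative tumor cells (the only two classes that
enter the tumor proportion score), positive and negative lymphocytes,
macrophages, necrosis, stroma and non-tissue background.  Label rasters use
the integer IDs below, with ``0`` reserved for unannotated / ignore pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

IGNORE_ID = 0

DEFAULT_CLASS_NAMES = (
    "tc_pos",
    "tc_neg",
    "lymph_pos",
    "lymph_neg",
    "macrophage",
    "necrosis",
    "stroma",
    "non_tissue",
)


@dataclass(frozen=True)
class ClassScheme:
    """Ordered mapping between class names and integer label-raster IDs.

    Parameters
    ----------
    names
        Ordered class names.  The default scheme has exactly eight classes,
        one of which (``non_tissue``) is the distinguished background class.
    class_ids
        Integer IDs, one per name, all distinct and never ``0`` (the ignore
        value in label rasters).
    """

    names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    class_ids: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.class_ids is None:
            object.__setattr__(self, "class_ids", tuple(range(1, len(self.names) + 1)))
        if len(self.names) != len(self.class_ids):
            raise ValueError("names and class_ids must have equal length")
        if len(set(self.class_ids)) != len(self.class_ids):
            raise ValueError("class IDs must be unique")
        if IGNORE_ID in self.class_ids:
            raise ValueError(f"class ID {IGNORE_ID} is reserved for ignore/unannotated")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def id_of(self, name: str) -> int:
        try:
            return self.class_ids[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown class name: {name!r}") from None

    def name_of(self, class_id: int) -> str:
        try:
            return self.names[self.class_ids.index(class_id)]
        except ValueError:
            raise KeyError(f"unknown class ID: {class_id}") from None

    def index_of_id(self, class_id: int) -> int:
        """Position of a class ID in the ordered scheme (softmax column)."""
        try:
            return self.class_ids.index(class_id)
        except ValueError:
            raise KeyError(f"unknown class ID: {class_id}") from None

    def __contains__(self, class_id: int) -> bool:
        return class_id in self.class_ids

    @property
    def tc_pos(self) -> int:
        return self.id_of("tc_pos")

    @property
    def tc_neg(self) -> int:
        return self.id_of("tc_neg")

    @property
    def non_tissue(self) -> int:
        return self.id_of("non_tissue")


def default_scheme() -> ClassScheme:
    """The full 8-class scheme used for slide annotation and scoring."""
    return ClassScheme()


def reduced_scheme() -> ClassScheme:
    """Collapsed 3-class scheme {tc_pos, tc_neg, other} for desk-scale training.

    Tumor classes keep their IDs; every other tissue class maps to ``other``.
    """
    return ClassScheme(names=("tc_pos", "tc_neg", "other"), class_ids=(1, 2, 3))


def collapse_to_reduced(labels, full: ClassScheme | None = None):
    """Map an array of full-scheme labels onto the reduced 3-class scheme.

    ``0`` (ignore) is preserved; tumor classes keep IDs 1 and 2; all other
    classes become ID 3.
    """
    import numpy as np

    full = full or default_scheme()
    labels = np.asarray(labels)
    out = np.full_like(labels, 3)
    out[labels == IGNORE_ID] = IGNORE_ID
    out[labels == full.tc_pos] = 1
    out[labels == full.tc_neg] = 2
    return out
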