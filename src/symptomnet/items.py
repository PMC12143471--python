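"""The 14-item HADS catalog.

The Hospital Anxiety and Depression Scale has seven anxiety items (HA1-HA7)
and seven depression items (HD1-HD7), each self-rated 0-3 (0 = not at all,
3 = most of the time). All analyses in this package index nodes in the
canonical order HA1..HA7, HD1..HD7.
"""

from __future__ import annotations

from dataclasses import dataclass

ANXIETY = "anxiety"
DEPRESSION = "depression"

N_ITEMS = 14
N_LEVELS = 4  # ordinal categories 0..3


@dataclass(frozen=True)
class Item:
    item_id: str
    label: str
    subscale: str


HADS_ITEMS: tuple[Item, ...] = (
    Item("HA1", "Feeling of tension", ANXIETY),
    Item("HA2", "Frightened feeling", ANXIETY),
    Item("HA3", "Worrying thoughts", ANXIETY),
    Item("HA4", "Relaxed feeling", ANXIETY),
    Item("HA5", "Butterflies in stomach", ANXIETY),
    Item("HA6", "Restless feeling", ANXIETY),
    Item("HA7", "Feeling of panic", ANXIETY),
    Item("HD1", "Enjoyment", DEPRESSION),
    Item("HD2", "Laughter", DEPRESSION),
    Item("HD3", "Cheerful feeling", DEPRESSION),
    Item("HD4", "Slowed down", DEPRESSION),
    Item("HD5", "Loss of interest in appearance", DEPRESSION),
    Item("HD6", "Look forward to things", DEPRESSION),
    Item("HD7", "Enjoyment of book/media", DEPRESSION),
)

ITEM_IDS: tuple[str, ...] = tuple(item.item_id for item in HADS_ITEMS)
ANXIETY_ITEMS: tuple[str, ...] = tuple(
    i.item_id for i in HADS_ITEMS if i.subscale == ANXIETY
)
DEPRESSION_ITEMS: tuple[str, ...] = tuple(
    i.item_id for i in HADS_ITEMS if i.subscale == DEPRESSION
)
ITEM_LABELS: dict[str, str] = {i.item_id: i.label for i in HADS_ITEMS}
_SUBSCALE: dict[str, str] = {i.item_id: i.subscale for i in HADS_ITEMS}


def subscale_of(item_id: str) -> str:
    """Return ``"anxiety"`` or ``"depression"`` for a HADS item id."""
    try:
        return _SUBSCALE[item_id]
    except KeyError:
        raise KeyError(f"unknown HADS item id: {item_id!r}") from None
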