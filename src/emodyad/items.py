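"""Canonical daily-diary emotion items.

Sixteen emotion adjectives rated each evening on a 0-4 frequency scale
(0 = none of the time ... 4 = all of the time): seven negatively valenced
and nine positively valenced.  All modules key ratings by the short
``name`` below; ``label`` carries the questionnaire phrasing.
"""

from __future__ import annotations

from dataclasses import dataclass

NEGATIVE = "negative"
POSITIVE = "positive"

RATING_MIN = 0
RATING_MAX = 4


@dataclass(frozen=True)
class EmotionItem:
    name: str
    label: str
    valence: str


EMOTION_ITEMS: tuple[EmotionItem, ...] = (
    EmotionItem("anxious", "anxious", NEGATIVE),
    EmotionItem("sad", "sad", NEGATIVE),
    EmotionItem("angry", "angry", NEGATIVE),
    EmotionItem("frustrated", "frustrated", NEGATIVE),
    EmotionItem("disgusted", "disgusted", NEGATIVE),
    EmotionItem("lonely", "lonely", NEGATIVE),
    EmotionItem("ashamed", "ashamed", NEGATIVE),
    EmotionItem("enthusiastic", "enthusiastic", POSITIVE),
    EmotionItem("happy", "happy", POSITIVE),
    EmotionItem("satisfied", "satisfied", POSITIVE),
    EmotionItem("confident", "confident", POSITIVE),
    EmotionItem("calm", "calm", POSITIVE),
    EmotionItem("belong", "like you belong", POSITIVE),
    EmotionItem("close_to_others", "close to others", POSITIVE),
    EmotionItem("proud", "proud", POSITIVE),
    EmotionItem("full_of_life", "full of life", POSITIVE),
)

ITEM_NAMES: tuple[str, ...] = tuple(it.name for it in EMOTION_ITEMS)
NEGATIVE_ITEMS: tuple[str, ...] = tuple(
    it.name for it in EMOTION_ITEMS if it.valence == NEGATIVE
)
POSITIVE_ITEMS: tuple[str, ...] = tuple(
    it.name for it in EMOTION_ITEMS if it.valence == POSITIVE
)

assert len(EMOTION_ITEMS) == 16
assert len(NEGATIVE_ITEMS) == 7 and len(POSITIVE_ITEMS) == 9


def items_for(valence: str) -> tuple[str, ...]:
    """Item names of one valence; raises on an unknown valence string."""
    if valence == NEGATIVE:
        return NEGATIVE_ITEMS
    if valence == POSITIVE:
        return POSITIVE_ITEMS
    raise ValueError(f"unknown valence {valence!r}; expected 'negative' or 'positive'")
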