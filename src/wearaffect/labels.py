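"""Classification targets derived from ESM questionnaires.

Three label families come out of one response:

* **PANAS binary** — the four positive-affect items (inspired, active,
  determined, attentive) are summed against the six negative-affect items
  (upset, hostile, alert, ashamed, nervous, afraid); the larger sum decides
  the class (1 positive, 0 negative).  Equal sums are undefined under that
  rule, so tied responses are *excluded* from the binary task and counted in
  a report rather than force-assigned, which would bias the class balance.
* **5-class valence / arousal** — the raw 1–5 self-rating is the class.
* **Binary valence / arousal** — ratings 1–3 versus 4–5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .io import EsmResponse

__all__ = [
    "POSITIVE_ITEMS",
    "NEGATIVE_ITEMS",
    "LabelSet",
    "panas_scores",
    "panas_class",
    "scale_class",
    "binarize_scale",
    "label_set",
    "class_distribution",
    "format_distribution",
]

POSITIVE_ITEMS = ("inspired", "active", "determined", "attentive")
NEGATIVE_ITEMS = ("upset", "hostile", "alert", "ashamed", "nervous", "afraid")


@dataclass
class LabelSet:
    """All derived targets for one ESM response.

    ``panas_class`` is ``None`` for a positive/negative tie (excluded from
    the binary task).
    """

    panas_positive_sum: int
    panas_negative_sum: int
    panas_class: int | None
    valence_class: int
    arousal_class: int
    valence_binary: int
    arousal_binary: int

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LabelSet":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__})


def panas_scores(esm: EsmResponse) -> tuple[int, int]:
    """Sum the positive-affect and negative-affect item scores."""
    positive = sum(int(esm.panas_items[name]) for name in POSITIVE_ITEMS)
    negative = sum(int(esm.panas_items[name]) for name in NEGATIVE_ITEMS)
    return positive, negative


def panas_class(positive_sum: int, negative_sum: int) -> int | None:
    """Binary PANAS category: 1 if the positive sum dominates, 0 if the
    negative sum dominates, ``None`` (excluded) on a tie."""
    if positive_sum > negative_sum:
        return 1
    if negative_sum > positive_sum:
        return 0
    return None


def scale_class(score: int) -> int:
    """A 1–5 self-rating maps identically onto classes 1–5."""
    score = int(score)
    if not 1 <= score <= 5:
        raise ValueError(f"rating {score} outside [1, 5]")
    return score


def binarize_scale(cls: int) -> int:
    """Collapse classes 1–3 to 0 and classes 4–5 to 1."""
    cls = scale_class(cls)
    return 1 if cls >= 4 else 0


def label_set(esm: EsmResponse) -> LabelSet:
    """Derive every target for one response."""
    pos, neg = panas_scores(esm)
    v = scale_class(esm.valence)
    a = scale_class(esm.arousal)
    return LabelSet(
        panas_positive_sum=pos,
        panas_negative_sum=neg,
        panas_class=panas_class(pos, neg),
        valence_class=v,
        arousal_class=a,
        valence_binary=binarize_scale(v),
        arousal_binary=binarize_scale(a),
    )


def class_distribution(values, classes=None) -> dict:
    """Per-class counts and whole-percent proportions.

    ``values`` is an iterable of class labels (``None`` entries — excluded
    ties — are counted separately under ``"excluded"``).
    """
    values = list(values)
    if not values:
        raise ValueError("class_distribution needs a nonempty label list")
    present = [v for v in values if v is not None]
    n_excluded = len(values) - len(present)
    if classes is None:
        classes = sorted(set(present))
    counts = {c: 0 for c in classes}
    for v in present:
        counts[v] = counts.get(v, 0) + 1
    n = len(present)
    dist = {
        c: {"count": counts[c], "percent": int(round(100.0 * counts[c] / n)) if n else 0}
        for c in counts
    }
    return {"n": n, "n_excluded": n_excluded, "classes": dist}


def format_distribution(dist: dict) -> str:
    """Render a distribution as ``count (pct%)`` cells, one per class."""
    cells = [f"{v['count']} ({v['percent']}%)" for _, v in sorted(dist["classes"].items())]
    return "\t".join(cells)
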