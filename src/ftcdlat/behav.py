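"""Handedness scoring, dominance-consistency coding, and DLD/TD classification.

Two handedness instruments are scored:

* an adapted 10-item Edinburgh Handedness Inventory (EHI): one point per
  exclusively right-handed action, half a point for both hands, zero for
  left; the 0-10 score maps linearly onto a -100..100 laterality index, and a
  child is right-handed iff the index is strictly above 0;
* the Quantification of Hand Preference (QHP): 21 reaches (3 cards at each of
  7 positions, 30 degrees apart, position 4 at the midline); one point per
  right-handed reach, right-handed iff the score is strictly above 10.

A child is consistently left-hemisphere dominant iff left-lateralised for
language on fTCD AND right-handed on both instruments (code 1,1,1).

Developmental language disorder (DLD) is assigned when a child scores more
than 1 SD below the population norm on at least 2 of 13 language/literacy
measures; typically developing (TD) with at most one sub-threshold measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

EHI_ITEMS = (
    "writing", "drawing", "throwing", "scissors", "toothbrush",
    "knife", "spoon", "broom", "box_lid", "dealing_cards",
)

_EHI_POINTS = {"right": 1.0, "both": 0.5, "left": 0.0}

LANGUAGE_MEASURES = (
    "vocabulary", "verbal_comprehension", "sentence_repetition",
    "nonword_repetition", "oromotor_sequences", "picture_naming",
    "digit_naming", "sight_word_efficiency", "phonetic_decoding",
    "reading_accuracy", "reading_comprehension", "reading_rate",
    "communication_composite",
)

# Conventional norm scale per instrument family (IQ-type 100/15, scaled
# subtest 10/3, t-type 50/10). Configurable wherever norms are consumed.
DEFAULT_NORMS = {
    "vocabulary": (50.0, 10.0),
    "verbal_comprehension": (100.0, 15.0),
    "sentence_repetition": (10.0, 3.0),
    "nonword_repetition": (10.0, 3.0),
    "oromotor_sequences": (10.0, 3.0),
    "picture_naming": (100.0, 15.0),
    "digit_naming": (100.0, 15.0),
    "sight_word_efficiency": (100.0, 15.0),
    "phonetic_decoding": (100.0, 15.0),
    "reading_accuracy": (100.0, 15.0),
    "reading_comprehension": (100.0, 15.0),
    "reading_rate": (100.0, 15.0),
    "communication_composite": (100.0, 15.0),
    "performance_iq": (100.0, 15.0),
}


@dataclass
class DominanceCode:
    """(fTCD, EHI, QHP) bits; 1 codes left-hemisphere dominance on that measure."""

    ftcd: int
    ehi: int
    qhp: int

    @property
    def consistent(self) -> bool:
        return (self.ftcd, self.ehi, self.qhp) == (1, 1, 1)


def score_ehi(items) -> tuple[float, float, bool]:
    """Score 10 EHI item responses -> (score 0-10, laterality index -100..100, right flag).

    The index is the linear map (2*score - 10) * 10; right-handed iff index > 0.
    """
    items = list(items)
    if len(items) != 10:
        raise ValidationError(f"EHI requires exactly 10 items, got {len(items)}")
    bad = [v for v in items if v not in _EHI_POINTS]
    if bad:
        raise ValidationError(f"invalid EHI response(s): {bad}")
    score = sum(_EHI_POINTS[v] for v in items)
    li = (2.0 * score - 10.0) * 10.0
    return score, li, li > 0


def score_qhp(reaches) -> tuple[int, bool, tuple[float, ...]]:
    """Score a QHP reach log -> (score 0-21, right flag, per-position right proportions).

    ``reaches`` is an iterable of (position 1-7, hand) records, exactly 3 per
    position; right-handed iff the score is strictly over 10.
    """
    recs = [(int(p), h) for p, h in reaches]
    if len(recs) != 21:
        raise ValidationError(f"QHP requires exactly 21 reaches, got {len(recs)}")
    per_pos: dict[int, list[str]] = {p: [] for p in range(1, 8)}
    for p, h in recs:
        if p not in per_pos:
            raise ValidationError(f"invalid QHP position: {p}")
        if h not in ("right", "left"):
            raise ValidationError(f"invalid QHP hand: {h}")
        per_pos[p].append(h)
    if any(len(v) != 3 for v in per_pos.values()):
        raise ValidationError("QHP requires exactly 3 reaches per position 1-7")
    score = sum(h == "right" for _, h in recs)
    profile = tuple(sum(h == "right" for h in per_pos[p]) / 3.0 for p in range(1, 8))
    return score, score > 10, profile


def score_ehi_table(items: pd.DataFrame) -> pd.DataFrame:
    """Score a long-format EHI item table (child_id, item, response) per child."""
    rows = []
    for cid, grp in items.groupby("child_id", sort=False):
        score, li, right = score_ehi(grp["response"].tolist())
        rows.append({"child_id": cid, "ehi_score": score, "ehi_li": li, "ehi_right": right})
    return pd.DataFrame(rows)


def score_qhp_table(reaches: pd.DataFrame) -> pd.DataFrame:
    """Score a long-format QHP reach table (child_id, position, hand) per child."""
    rows = []
    for cid, grp in reaches.groupby("child_id", sort=False):
        score, right, profile = score_qhp(zip(grp["position"], grp["hand"]))
        row = {"child_id": cid, "qhp_score": score, "qhp_right": right}
        row.update({f"qhp_pos{p}": profile[p - 1] for p in range(1, 8)})
        rows.append(row)
    return pd.DataFrame(rows)


def code_dominance(laterality_category: str, ehi_right: bool, qhp_right: bool) -> DominanceCode:
    """Combine fTCD category and the two handedness flags into a Table-5-style code."""
    if laterality_category not in ("left", "bilateral", "right"):
        raise ValidationError(f"invalid or missing laterality category: {laterality_category!r}")
    return DominanceCode(
        ftcd=int(laterality_category == "left"),
        ehi=int(bool(ehi_right)),
        qhp=int(bool(qhp_right)),
    )


def classify_dld(scores: dict, norms: dict | None = None, *, allow_missing: bool = False) -> tuple[int, str]:
    """Count sub-threshold measures and classify DLD/TD.

    A measure is flagged iff its value is strictly below mean - SD on its norm
    scale; DLD iff at least two of the 13 measures are flagged. With
    ``allow_missing`` (real-data leniency), absent measures are skipped instead
    of raising.
    """
    norms = norms or DEFAULT_NORMS
    n_flags = 0
    missing = []
    for m in LANGUAGE_MEASURES:
        if m not in scores or scores[m] is None or pd.isna(scores[m]):
            missing.append(m)
            continue
        mean, sd = norms[m]
        if scores[m] < mean - sd:
            n_flags += 1
    if missing and not allow_missing:
        raise ValidationError(f"missing language measure(s): {', '.join(missing)}")
    return n_flags, ("DLD" if n_flags >= 2 else "TD")


def exclusion_screen(
    performance_iq: float,
    asd_flag: bool = False,
    cotwin_asd_flag: bool = False,
    hearing_fail: bool = False,
    medical_flag: bool = False,
    iq_floor: float = 70.0,
) -> tuple[bool, str | None]:
    """Apply recruitment exclusions -> (include flag, reason if excluded).

    Excluded below an IQ of 70 (2 SD under the population mean; the boundary
    itself is included), for an ASD diagnosis in the child OR the co-twin, for
    hearing failure, or for a serious medical condition.
    """
    if performance_iq < iq_floor:
        return False, "low IQ"
    if asd_flag or cotwin_asd_flag:
        return False, "ASD in pair"
    if hearing_fail:
        return False, "hearing"
    if medical_flag:
        return False, "medical"
    return True, None
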