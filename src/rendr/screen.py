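"""Bulk-fluorescence screen analytics.

Plate-reader wells carry raw fluorescence (FL) and optical density (OD600)
plus condition labels.  Media blanks are subtracted from both channels
before forming FL/OD, the per-cell expression proxy.  The colony screen
scores each variant by its on/off separation — the signed distance of the
point (FL/OD on, FL/OD off) from the x = y line — splits variants into
rank-based tertiles per replicate, and calls a variant functional when it
lands in the top two tertiles in both replicates.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "blank_correct_flod",
    "process_plate",
    "distance_score",
    "tertile_classify",
    "functional_call",
    "fold_activation",
]

SQRT2 = math.sqrt(2.0)


def blank_correct_flod(fl: float, od: float, blank_fl: float, blank_od: float) -> float:
    """Blank-corrected FL/OD for a single well: (FL-blankFL)/(OD-blankOD).

    The blanks are the media-blank means for the well's plate (and
    condition, when per-condition blanks exist).  Corrected OD must be
    positive — otherwise the well shows no growth and the ratio is
    meaningless.
    """
    od_corr = od - blank_od
    if od_corr <= 0:
        raise ValueError(f"corrected OD {od_corr:g} <= 0: no growth in well")
    return (fl - blank_fl) / od_corr


def process_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Blank-correct a plate table and add an ``fl_od`` column.

    Expects columns ``FL``, ``OD``, ``is_media_blank`` (bool) and
    optionally ``condition``.  Media-blank means are taken per condition
    when blanks exist for that condition, falling back to the plate-wide
    blank mean; blank wells themselves get ``fl_od = NaN``.  Blank-cell
    (autofluorescence) wells are processed like experimental wells — they
    are reported, not subtracted.
    """
    if not plate["is_media_blank"].any():
        raise ValueError("plate contains no media blank wells")
    out = plate.copy()
    blanks = plate[plate["is_media_blank"]]
    plate_fl, plate_od = blanks["FL"].mean(), blanks["OD"].mean()

    def blank_means(cond) -> tuple[float, float]:
        if "condition" in plate.columns:
            sub = blanks[blanks["condition"] == cond]
            if len(sub):
                return sub["FL"].mean(), sub["OD"].mean()
        return plate_fl, plate_od

    fl_od = np.full(len(plate), np.nan)
    for pos, (_, row) in enumerate(plate.iterrows()):
        if row["is_media_blank"]:
            continue
        bfl, bod = blank_means(row.get("condition"))
        fl_od[pos] = blank_correct_flod(row["FL"], row["OD"], bfl, bod)
    out["fl_od"] = fl_od
    return out


def distance_score(fl_od_off: float, fl_od_on: float) -> float:
    """Signed on/off separation: (FL/OD_on - FL/OD_off) / sqrt(2).

    This is the distance of the point (on, off) from the x = y line of an
    on-vs-off scatter.  In the inhibitor screen the on state is the
    inhibitor-absent condition (-AHL) and the off state the
    inhibitor-present one (+AHL), so the score is
    ``(FL/OD(-AHL) - FL/OD(+AHL)) / sqrt(2)``; swapping the two states
    negates it.
    """
    return (fl_od_on - fl_od_off) / SQRT2


def tertile_classify(scores: pd.Series | Sequence[float]) -> pd.Series:
    """Split variants into rank-based tertiles of their distance score.

    Labels are 1 (bottom) to 3 (top); tertile sizes differ by at most one.
    Ties are broken by stable variant-id order, so the labelling does not
    depend on input order.  Requires >= 3 variants.
    """
    s = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
    n = len(s)
    if n < 3:
        raise ValueError(f"need >= 3 variants to form tertiles, got {n}")
    # rank ascending by (score, variant id) for a deterministic tie-break
    idx = sorted(s.index, key=lambda v: (s[v], str(v)))
    labels = pd.Series(0, index=s.index, dtype=int, name="tertile")
    for rank, v in enumerate(idx):
        labels[v] = 1 + (rank * 3) // n
    return labels


def functional_call(tertiles: pd.DataFrame | Sequence[tuple[int, int]]) -> pd.Series:
    """Call variants functional from two replicate tertile classifications.

    A variant is functional iff it falls in the top two tertiles (label
    >= 2) in *both* replicates.  ``tertiles`` is a two-column frame (one
    column per replicate) or a sequence of (rep1, rep2) label pairs;
    missing replicates are an error.
    """
    df = pd.DataFrame(tertiles)
    if df.shape[1] != 2:
        raise ValueError(f"expected exactly 2 replicate classifications, got {df.shape[1]}")
    if df.isna().any().any():
        raise ValueError("missing replicate tertile for some variant")
    return ((df.iloc[:, 0] >= 2) & (df.iloc[:, 1] >= 2)).rename("functional")


def fold_activation(fl_od_plus_input: float, fl_od_minus_input: float) -> float:
    """On/off ratio of expression with vs without the RNA input."""
    if fl_od_minus_input <= 0:
        raise ValueError("off-state FL/OD must be positive for a fold ratio")
    return fl_od_plus_input / fl_od_minus_input
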