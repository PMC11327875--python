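"""Temporal profile categories and lncRNA–PCG concordance.

A three-point profile (e.g. L3 → EP → LP averaged TPM) falls into one of four
categories: *increasing* (minimum at the first stage, maximum at the last),
*decreasing* (the reverse), *peak* (maximum at the middle stage) or *valley*
(minimum at the middle stage).  With distinct values exactly one category
applies; any tie for the deciding extremum yields *ambiguous*.

A lncRNA–PCG pair is *concordant* when both members share the category,
*discordant* when the categories are opposite (increasing/decreasing or
peak/valley), and *unrelated* otherwise — including whenever the PCG is not
expressed.  A per-pair Pearson correlation on log10(TPM + 0.1) accompanies
the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import LncRNAPair
from .expression import ConditionExpression, ExpressionMatrix, EXPRESSED_TPM

PCC_PSEUDOCOUNT = 0.1


class ProfileCategory(str, Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    PEAK = "peak"
    VALLEY = "valley"
    AMBIGUOUS = "ambiguous"


class PairRelation(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    UNRELATED = "unrelated"


_OPPOSITES = {
    frozenset({ProfileCategory.INCREASING, ProfileCategory.DECREASING}),
    frozenset({ProfileCategory.PEAK, ProfileCategory.VALLEY}),
}


def categorize_profile(values: Sequence[float]) -> ProfileCategory:
    """Category of a three-point temporal profile.

    ``values`` must be the three stage means in temporal order.  Increasing
    requires the unique minimum first and the unique maximum last; peak the
    unique maximum in the middle; valley the unique minimum in the middle;
    decreasing mirrors increasing.  Ties on the deciding extremum give
    ``ambiguous``.
    """
    if len(values) != 3:
        raise ValueError(f"profile needs exactly 3 values, got {len(values)}")
    v = [float(x) for x in values]
    vmax, vmin = max(v), min(v)
    if vmax == vmin:
        return ProfileCategory.AMBIGUOUS
    argmaxs = {i for i, x in enumerate(v) if x == vmax}
    argmins = {i for i, x in enumerate(v) if x == vmin}
    if 1 in argmaxs:
        return ProfileCategory.PEAK if argmaxs == {1} else ProfileCategory.AMBIGUOUS
    if 1 in argmins:
        return ProfileCategory.VALLEY if argmins == {1} else ProfileCategory.AMBIGUOUS
    # both extrema at the ends
    if argmaxs == {2} and argmins == {0}:
        return ProfileCategory.INCREASING
    if argmaxs == {0} and argmins == {2}:
        return ProfileCategory.DECREASING
    return ProfileCategory.AMBIGUOUS


def relate_pair(
    lnc_cat: ProfileCategory,
    pcg_cat: ProfileCategory | None,
    pcg_expressed: bool,
) -> PairRelation:
    """Concordant / discordant / unrelated verdict for a category pair.

    A not-expressed PCG forces *unrelated* regardless of categories, as does
    an ambiguous category on either side.  The relation is symmetric in the
    two category arguments.
    """
    if not pcg_expressed or pcg_cat is None:
        return PairRelation.UNRELATED
    if lnc_cat is ProfileCategory.AMBIGUOUS or pcg_cat is ProfileCategory.AMBIGUOUS:
        return PairRelation.UNRELATED
    if lnc_cat == pcg_cat:
        return PairRelation.CONCORDANT
    if frozenset({lnc_cat, pcg_cat}) in _OPPOSITES:
        return PairRelation.DISCORDANT
    return PairRelation.UNRELATED


def pair_pcc(
    lnc: Sequence[float],
    pcg: Sequence[float],
    pseudocount: float = PCC_PSEUDOCOUNT,
) -> float:
    """Pearson correlation of two TPM vectors on the log10(x + pseudocount) scale.

    Returns NaN when either transformed vector has zero variance.
    """
    x = np.asarray(lnc, dtype=float)
    y = np.asarray(pcg, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    lx = np.log10(x + pseudocount)
    ly = np.log10(y + pseudocount)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        return float("nan")
    return float(stats.pearsonr(lx, ly).statistic)


@dataclass
class PairProfile:
    lncrna_id: str
    pcg_id: str | None
    lnc_category: ProfileCategory | None
    pcg_category: ProfileCategory | None
    relation: PairRelation
    pcc: float


def profile_pairs(
    pairs: Sequence[LncRNAPair] | pd.DataFrame,
    ce: ConditionExpression,
    em: ExpressionMatrix | None = None,
    stage_order: Sequence[str] = ("L3", "EP", "LP"),
    tissue: str | None = None,
    expressed_threshold: float = EXPRESSED_TPM,
    pseudocount: float = PCC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Categorize both members of each pair and call the relation.

    ``ce`` supplies replicate-averaged stage profiles (its columns must carry
    a ``stage``-like last factor ordered via ``stage_order``; with a
    ``tissue`` factor, pass ``tissue`` to select one).  When ``em`` is given,
    the Pearson correlation uses its replicate-level columns (restricted to
    the chosen tissue); otherwise the averaged stage values are used.

    Returns a table with one row per pair: lncrna_id, pcg_id, lnc_category,
    pcg_category, relation, pcc.
    """
    if isinstance(pairs, pd.DataFrame):
        rows = list(pairs[["lncrna_id", "pcg_id"]].itertuples(index=False))
    else:
        rows = [(p.lncrna_id, p.pcg_id) for p in pairs]

    vals = ce.values
    if tissue is not None:
        if "tissue" not in ce.factors:
            raise ValueError("condition expression has no tissue factor")
        vals = vals.xs(tissue, axis=1, level="tissue")
    # one column per stage, in temporal order
    if isinstance(vals.columns, pd.MultiIndex):
        vals = vals.copy()
        vals.columns = vals.columns.get_level_values(-1)
    missing = [s for s in stage_order if s not in vals.columns]
    if missing:
        raise ValueError(f"stages missing from conditions: {missing}")
    vals = vals[list(stage_order)]

    if em is not None:
        sample_meta = em.meta
        if tissue is not None:
            sample_meta = sample_meta[sample_meta["tissue"] == tissue]
        pcc_mat = em.values[list(sample_meta.index)]
    else:
        pcc_mat = vals

    out = []
    for lnc_id, pcg_id in rows:
        lnc_prof = vals.loc[lnc_id] if lnc_id in vals.index else None
        lnc_cat = categorize_profile(lnc_prof) if lnc_prof is not None else None
        pcg_prof = (
            vals.loc[pcg_id] if (pcg_id is not None and pcg_id in vals.index) else None
        )
        pcg_expressed = bool(
            pcg_prof is not None and (pcg_prof >= expressed_threshold).any()
        )
        pcg_cat = categorize_profile(pcg_prof) if pcg_prof is not None else None
        if lnc_cat is None:
            relation = PairRelation.UNRELATED
        else:
            relation = relate_pair(lnc_cat, pcg_cat, pcg_expressed)
        if lnc_id in pcc_mat.index and pcg_id is not None and pcg_id in pcc_mat.index:
            pcc = pair_pcc(pcc_mat.loc[lnc_id], pcc_mat.loc[pcg_id], pseudocount)
        else:
            pcc = float("nan")
        out.append(
            {
                "lncrna_id": lnc_id,
                "pcg_id": pcg_id,
                "lnc_category": lnc_cat.value if lnc_cat else None,
                "pcg_category": pcg_cat.value if pcg_cat else None,
                "relation": relation.value,
                "pcc": pcc,
            }
        )
    return pd.DataFrame(out)


def relation_summary(profiled: pd.DataFrame) -> pd.Series:
    """Fractions of concordant/discordant/unrelated pairs."""
    counts = profiled["relation"].value_counts()
    frac = counts / counts.sum()
    return frac.reindex(
        [r.value for r in PairRelation], fill_value=0.0
    ).rename("fraction")
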