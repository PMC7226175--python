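"""Per-gene trajectory-correlation scores and intervention shift tests.

The trajectory gene score is the signed R^2: sign(r) * r^2 for the Pearson
correlation r between a gene's (median-of-ratios normalized, log scale)
expression and the oriented axis-1 coordinate over a stated sample subset.
Genes constant on the subset are flagged undefined rather than scored 0, so
they never fabricate ties at the center of a ranking.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Embedding, NormalizedMatrix

log = logging.getLogger("ewstraj")


class TrajScoreError(ValueError):
    pass


def gene_axis_correlation(
    norm: NormalizedMatrix,
    emb: Embedding,
    subset: list[str] | None = None,
    subset_tag: str = "all",
) -> pd.DataFrame:
    """Signed-R^2 of every gene's expression against the axis-1 coordinate.

    Returns a table indexed by gene with columns ``signed_r2`` (NaN when
    undefined), ``defined``, ``n_used`` and ``subset_tag``.
    """
    subset = list(subset) if subset is not None else list(emb.sample_ids)
    missing = set(subset) - set(emb.sample_ids)
    if missing:
        raise TrajScoreError(f"subset samples absent from embedding: {sorted(missing)[:5]}")
    if len(subset) < 3:
        raise TrajScoreError("subset must contain >= 3 samples")
    axis1 = emb.axis1.loc[subset].to_numpy()
    X = norm.subset_samples(subset).values  # genes x subset

    xc = X - X.mean(axis=1, keepdims=True)
    yc = axis1 - axis1.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    defined = (sx > 0) & (sy > 0)
    r = np.full(X.shape[0], np.nan)
    if sy > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            r[defined] = (xc @ yc)[defined] / (sx[defined] * sy)
    signed_r2 = np.sign(r) * r**2
    return pd.DataFrame(
        {
            "signed_r2": signed_r2,
            "defined": defined,
            "n_used": len(subset),
            "subset_tag": subset_tag,
        },
        index=pd.Index(norm.gene_ids, name="gene_id"),
    )


def threshold_markers(scores: pd.DataFrame, cutoff: float, direction: str = "below") -> set[str]:
    """Genes strictly beyond ``cutoff`` in the stated direction.

    A gene scoring exactly at the cutoff is excluded; undefined genes are
    excluded. An empty result is returned with a warning, not an error.
    """
    if not (-1.0 <= cutoff <= 1.0):
        raise TrajScoreError("cutoff must lie in [-1, 1]")
    s = scores.loc[scores["defined"], "signed_r2"]
    if direction == "below":
        picked = set(s.index[s < cutoff])
    elif direction == "above":
        picked = set(s.index[s > cutoff])
    else:
        raise TrajScoreError("direction must be 'below' or 'above'")
    if not picked:
        log.warning("threshold_markers: no gene beyond cutoff %.3g (%s)", cutoff, direction)
    return picked


def intervention_shift_test(
    emb: Embedding,
    meta: pd.DataFrame,
    tail: str = "greater",
    intervention_col: str = "intervention",
    treatment: str = "knockdown",
    control: str = "control",
) -> dict:
    """Welch t-test of axis-1 position, treatment arm vs control arm.

    ``tail="greater"`` tests whether the treatment arm sits higher on axis 1
    (the expected direction for fusion knockdown); ``tail="two-sided"`` is
    for other interventions.
    """
    axis1 = emb.axis1
    arm = meta.loc[meta.index.intersection(axis1.index), intervention_col]
    x = axis1[arm.index[arm == treatment]].to_numpy()
    y = axis1[arm.index[arm == control]].to_numpy()
    if len(x) < 3 or len(y) < 3:
        raise TrajScoreError("each arm needs >= 3 embedded samples")
    if tail not in ("greater", "two-sided"):
        raise TrajScoreError("tail must be 'greater' or 'two-sided'")
    res = stats.ttest_ind(x, y, equal_var=False, alternative=tail)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "tail": tail,
        "mean_treatment": float(x.mean()),
        "mean_control": float(y.mean()),
        "direction": "treatment_higher" if x.mean() > y.mean() else "control_higher",
        "n_treatment": len(x),
        "n_control": len(y),
    }
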