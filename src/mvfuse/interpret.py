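"""Leave-one-out zero-fill feature importance.

For every feature in every view, the feature's (scaled) value is replaced by
zero for all test subjects, latents are re-extracted, the phenotype is
re-predicted, and the test-set MAE is recomputed.  The importance of a
feature is the MAE increase over the intact baseline; a feature is important
when zeroing it degrades prediction.  Zero-filling happens in the scaled
[0, 1] space, where 0 corresponds to the training minimum of that feature —
the model only ever sees scaled inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mvae import MVAEParams
from .train import LinearHead, Scaler, apply_scaler, evaluate, extract_latents, predict

__all__ = ["loo_importance"]


def loo_importance(
    params: MVAEParams,
    head: LinearHead,
    scaler: Scaler,
    test_views,
    y_test,
    view_names=None,
    feature_names=None,
    top_k: int = 15,
) -> pd.DataFrame:
    """Zero-fill importance ranking over all features of all views.

    ``test_views`` are raw (unscaled) test-subject matrices; scaling uses
    the training-set scaler.  Returns a DataFrame with columns view,
    feature, baseline_mae, zeroed_mae, delta, sorted by delta descending;
    ``.attrs['top']`` holds the top-``top_k`` slice (the headline summary).
    """
    y_test = np.asarray(y_test, dtype=float)
    if y_test.size == 0:
        raise ValueError("empty test set")
    names = view_names or params.views()
    scaled = apply_scaler(scaler, [np.asarray(v, dtype=float) for v in test_views])
    if any(v.shape[0] != y_test.size for v in scaled):
        raise ValueError("test views and y_test row counts differ")

    baseline = evaluate(y_test, predict(head, extract_latents(params, scaled, names))).mae
    rows = []
    for vi, (vname, view) in enumerate(zip(names, scaled)):
        fnames = (
            feature_names[vi]
            if feature_names is not None
            else [f"{vname}_f{j}" for j in range(view.shape[1])]
        )
        for j in range(view.shape[1]):
            perturbed = list(scaled)
            mod = view.copy()
            mod[:, j] = 0.0
            perturbed[vi] = mod
            mae = evaluate(
                y_test, predict(head, extract_latents(params, perturbed, names))
            ).mae
            rows.append(
                {
                    "view": vname,
                    "feature": fnames[j],
                    "baseline_mae": baseline,
                    "zeroed_mae": mae,
                    "delta": mae - baseline,
                }
            )
    ranking = (
        pd.DataFrame(rows)
        .sort_values("delta", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    ranking.attrs["top"] = ranking.head(top_k)
    return ranking
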