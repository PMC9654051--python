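"""Sum-of-weights ranking and the tissue-independence diagnostic.

The per-feature sum of the seven min-max-normalised model weights is the
ranking statistic; the top-k features (default 20) form the transcriptomic
signature. A successful tissue-independent signature leaves the categorical
tissue attribute near the bottom of the ranking — the diagnostic reports the
tissue attribute's rank, sum, and whether it falls in the bottom decile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import TISSUE_FEATURE
from .weighting import MODELS, WeightMatrix


def sum_weights(wm: WeightMatrix) -> pd.Series:
    """Per-feature arithmetic sum of the seven normalised weights."""
    missing = set(MODELS) - set(wm.norm.columns)
    if missing:
        raise ValueError(f"missing model column(s): {sorted(missing)}")
    return wm.norm[list(MODELS)].sum(axis=1).rename("sum_of_weights")


def rank_features(sums: pd.Series, wm: WeightMatrix | None = None) -> pd.DataFrame:
    """Full descending ranking; ties broken lexicographically by feature id."""
    df = sums.rename("sum_of_weights").to_frame()
    df["feature"] = df.index
    df = df.sort_values(["sum_of_weights", "feature"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df["sum_of_weights"].duplicated(keep=False)
    cols = ["rank", "feature", "sum_of_weights", "tied"]
    if wm is not None:
        for m in MODELS:
            df[m] = wm.norm.loc[df.index, m]
        cols = ["rank", "feature", *MODELS, "sum_of_weights", "tied"]
    return df[cols].reset_index(drop=True)


def rank_and_top_k(
    sums: pd.Series, k: int = 20, wm: WeightMatrix | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (top-k entries, full ranking)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(sums):
        raise ValueError(f"k={k} exceeds the {len(sums)} available features")
    full = rank_features(sums, wm)
    return full.head(k).copy(), full


def tissue_independence_check(
    ranking: pd.DataFrame, tissue_feature: str = TISSUE_FEATURE
) -> dict:
    """Locate the tissue attribute in the full ranking.

    Returns rank, sum_of_weights, n_features, and whether the attribute sits
    in the bottom decile of ranks (the expected position when the signature
    is genuinely tissue-independent).
    """
    hit = ranking.loc[ranking["feature"] == tissue_feature]
    if hit.empty:
        raise ValueError(f"tissue feature {tissue_feature!r} absent from ranking")
    rank = int(hit["rank"].iloc[0])
    n = len(ranking)
    return {
        "feature": tissue_feature,
        "rank": rank,
        "sum_of_weights": float(hit["sum_of_weights"].iloc[0]),
        "n_features": n,
        "tissue_in_bottom_decile": rank > 0.9 * n,
    }


def format_signature_table(top: pd.DataFrame, gene_names: dict[str, str] | None = None) -> pd.DataFrame:
    """Report layout: rank, attribute, gene name, 1-decimal weights, unrounded sum.

    Printed weights are rounded to one decimal for display while the sum is
    computed from unrounded values, so a printed row's digits may disagree
    with its sum by up to 0.1 — a deliberate mirror of how such tables are
    customarily typeset.
    """
    out = top.copy()
    out["gene_name"] = [gene_names.get(f, "") if gene_names else "" for f in out["feature"]]
    for m in MODELS:
        if m in out.columns:
            out[m] = out[m].round(1)
    out["sum_of_weights"] = out["sum_of_weights"].round(1)
    cols = ["rank", "feature", "gene_name", *[m for m in MODELS if m in out.columns], "sum_of_weights"]
    return out[cols]
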