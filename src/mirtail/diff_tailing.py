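"""Between-condition comparison of mono-uridylation.

Change is measured in percentage points (mutant minus wild type); a
relative change is emitted alongside for transparency. miRNAs with at
least ``min_tags`` denominator tags in both conditions are analysed,
ranked ascending by percentage-point change (most decreased first),
and the top quartile of decreased uridylation is the first
ceil(n_analysed / 4) ranks. Ties are broken deterministically by
greater total tag count, then name.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .tailing import TailingProfile

DEFAULT_MIN_TAGS = 10


@dataclass
class UridylationChange:
    mirna_name: str
    pct_wt: float
    pct_mut: float
    delta_points: float
    rel_change: float
    tags_wt: int
    tags_mut: int
    analysed: bool
    rank: Optional[int] = None
    in_top_quartile_decrease: bool = False


def uridylation_change(
    profile_wt: TailingProfile, profile_mut: TailingProfile
) -> UridylationChange:
    if profile_wt.mirna_name != profile_mut.mirna_name:
        raise ValueError("profiles are for different miRNAs")
    pct_wt, pct_mut = profile_wt.mono_u_pct, profile_mut.mono_u_pct
    ok = profile_wt.defined and profile_mut.defined and not (
        math.isnan(pct_wt) or math.isnan(pct_mut)
    )
    delta = pct_mut - pct_wt if ok else math.nan
    rel = (pct_mut - pct_wt) / pct_wt if ok and pct_wt > 0 else math.nan
    return UridylationChange(
        mirna_name=profile_wt.mirna_name,
        pct_wt=pct_wt, pct_mut=pct_mut,
        delta_points=delta, rel_change=rel,
        tags_wt=profile_wt.denominator, tags_mut=profile_mut.denominator,
        analysed=ok,
    )


def change_table(
    profiles_wt: Iterable[TailingProfile], profiles_mut: Iterable[TailingProfile]
) -> pd.DataFrame:
    """Pair profiles by miRNA name and compute changes."""
    wt = {p.mirna_name: p for p in profiles_wt}
    mut = {p.mirna_name: p for p in profiles_mut}
    shared = sorted(set(wt) & set(mut))
    rows = [uridylation_change(wt[n], mut[n]).__dict__ for n in shared]
    columns = [f.name for f in dataclasses.fields(UridylationChange)]
    return pd.DataFrame(rows, columns=columns)


def rank_and_quartile(changes: pd.DataFrame, min_tags: int = DEFAULT_MIN_TAGS) -> pd.DataFrame:
    """Rank analysed miRNAs by uridylation change and call top-quartile
    membership.

    Rank 1 is the most decreased; top quartile = ranks up to
    ceil(n_analysed / 4).
    """
    df = changes.copy()
    df["analysed"] = (
        df["analysed"]
        & (df["tags_wt"] >= min_tags)
        & (df["tags_mut"] >= min_tags)
    )
    df["rank"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df["in_top_quartile_decrease"] = False
    analysed = df[df["analysed"]].copy()
    n = len(analysed)
    if n == 0:
        return df
    analysed["total_tags"] = analysed["tags_wt"] + analysed["tags_mut"]
    order = analysed.sort_values(
        by=["delta_points", "total_tags", "mirna_name"],
        ascending=[True, False, True],
        kind="mergesort",
    ).index
    q = math.ceil(n / 4)
    for r, idx in enumerate(order, start=1):
        df.loc[idx, "rank"] = r
        df.loc[idx, "in_top_quartile_decrease"] = r <= q
    return df


def intersect_with_expression(
    ranked: pd.DataFrame, expression: pd.DataFrame, fold_threshold: float = 2.0
) -> pd.DataFrame:
    """Flag miRNAs that are both in the top quartile of decreased
    uridylation and accumulate above the expression fold threshold."""
    expr = expression.set_index("mirna_name")["ratio"]
    out = ranked.copy()
    out["cpm_ratio"] = out["mirna_name"].map(expr)
    out["decreased_and_accumulating"] = (
        out["in_top_quartile_decrease"].fillna(False)
        & (out["cpm_ratio"] >= fold_threshold)
    )
    return out
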