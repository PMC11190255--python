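"""Weighted-rank aggregation for multi-criteria strain selection.

Strains are ranked per variable (larger fitness and lipid signal are
better, smaller t_max is better) with rank n = best and rank 1 = worst.
Each fitness/t_max rank is multiplied by ``k_growth`` (default 1.2) and the
lipid rank by ``k_lipid`` (default 1.6), the weighted ranks are summed, and
strains are re-ranked on the summed score; the top-N (default 11) strains
are selected.

Two weight semantics are provided. ``literal`` applies the k multipliers to
every column as stated above. ``grouped`` normalises so the growth columns
jointly carry 40% of the score and lipid 60% regardless of how many media
were screened; with several media the literal multipliers give lipid far
less than 60% of the total, so neither semantics is privileged — the mode
is explicit in the API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WeightConfig", "weighted_rank", "select_top", "VariableKind"]

#: Recognised variable kinds and their sort direction (True = larger is better).
VariableKind = {"fitness": True, "t_max": False, "lipid": True}


@dataclass(frozen=True)
class WeightConfig:
    """Importance multipliers for the two trait groups."""

    k_growth: float = 1.2
    k_lipid: float = 1.6
    mode: str = "literal"  # or "grouped"

    def __post_init__(self) -> None:
        if self.k_growth <= 0 or self.k_lipid <= 0:
            raise ValueError("weights must be > 0")
        if self.mode not in ("literal", "grouped"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _variable_ranks(values: pd.Series, larger_is_better: bool) -> pd.Series:
    """Rank with n = best, 1 = worst; average ranks on ties; missing -> worst.

    A strain with no value for a variable (e.g. it never grew on that
    medium) cannot be ordered and is pinned to the worst rank, 1.
    """
    ranks = values.rank(method="average", ascending=larger_is_better)
    return ranks.fillna(1.0)


def weighted_rank(
    variables: pd.DataFrame,
    kinds: dict[str, str],
    weights: WeightConfig | None = None,
) -> pd.DataFrame:
    """Rank strains over phenotype columns and aggregate with importance weights.

    ``variables`` is a strains x variables table (index: strain id);
    ``kinds`` maps each column to 'fitness', 't_max' or 'lipid'. Returns a
    table with one ``rank_<col>`` column per variable, the weighted
    ``score``, the ``final_rank`` (n = best, deterministic tie-break by
    strain id), a ``n_missing`` count of worst-pinned missing variables, and
    a ``selected`` placeholder column (filled by :func:`select_top`).
    """
    weights = weights or WeightConfig()
    if len(variables) < 1:
        raise ValueError("need at least one strain")
    unknown = set(kinds.values()) - set(VariableKind)
    if unknown:
        raise ValueError(f"unknown variable kinds: {sorted(unknown)}")
    missing_cols = set(variables.columns) - set(kinds)
    if missing_cols:
        raise ValueError(f"no kind declared for columns: {sorted(missing_cols)}")
    if "lipid" not in kinds.values():
        raise ValueError("a lipid variable is required")
    for col in variables.columns:
        if variables[col].isna().all():
            raise ValueError(f"variable {col!r} has no values at all")

    growth_cols = [c for c in variables.columns if kinds[c] in ("fitness", "t_max")]
    lipid_cols = [c for c in variables.columns if kinds[c] == "lipid"]
    if weights.mode == "literal":
        col_weight = {
            c: (weights.k_growth if c in growth_cols else weights.k_lipid)
            for c in variables.columns
        }
    else:  # grouped: growth columns jointly 40%, lipid columns jointly 60%,
        # the stated importance split, independent of how many media were screened
        g_share, l_share = 0.4, 0.6
        col_weight = {c: g_share / len(growth_cols) for c in growth_cols}
        col_weight.update({c: l_share / len(lipid_cols) for c in lipid_cols})

    out = pd.DataFrame(index=variables.index)
    score = pd.Series(0.0, index=variables.index)
    for col in variables.columns:
        ranks = _variable_ranks(variables[col], VariableKind[kinds[col]])
        out[f"rank_{col}"] = ranks
        score = score + col_weight[col] * ranks
    out["n_missing"] = variables.isna().sum(axis=1).astype(int)
    out["score"] = score

    # Final rank: n = best. Sort by (score desc, strain id asc) so ties are
    # broken deterministically and input order never matters.
    order = out.assign(_sid=out.index.astype(str)).sort_values(
        ["score", "_sid"], ascending=[False, True], kind="mergesort"
    )
    n = len(out)
    final = pd.Series(np.arange(n, 0, -1), index=order.index)
    out["final_rank"] = final
    out["selected"] = False
    return out.sort_values("final_rank", ascending=False)


def select_top(rank_table: pd.DataFrame, n_select: int = 11) -> list[str]:
    """Strain ids with the ``n_select`` largest final ranks, best first.

    Also flips the ``selected`` flag in ``rank_table`` (in place).
    """
    n = len(rank_table)
    if not (1 <= n_select <= n):
        raise ValueError(f"n_select must be in [1, {n}], got {n_select}")
    best_first = rank_table.sort_values("final_rank", ascending=False)
    chosen = list(best_first.index[:n_select])
    rank_table.loc[chosen, "selected"] = True
    return chosen
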