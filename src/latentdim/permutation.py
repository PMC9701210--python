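"""Family-restricted permutation inference for latent dimensions.

Participants belonging to one family are statistically dependent (twins,
siblings), so behavioural rows may not be shuffled freely.  Families act as
exchangeability blocks: whole blocks may swap positions only with blocks of
identical composition (the multiset of member types MZ / DZ / non-twin),
and within a block members permute only among members of the same type.
For an all-singleton sample this reduces to a uniform random permutation.

Per outer split, each permutation shuffles the behavioural rows within the
optimisation set and, independently, within the holdout set; the RCCA model
is refitted on the permuted optimisation set with the hyperparameters
frozen at their selected values, the permuted holdout set is projected, and
the holdout canonical correlation enters the null distribution.  The
p-value is the exceedance fraction (strictly greater, by default), floored
at 1/n_perm, and Bonferroni-corrected over the outer splits; the omnibus
null of no effect in any split is rejected when any corrected p falls
below alpha (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rcca import DegenerateDataError, fit_rcca, project

__all__ = [
    "ExchangeabilityBlocks",
    "PermutationResult",
    "blocks_from_metadata",
    "permute_within_blocks",
    "permutation_pvalue",
    "permutation_null",
    "run_permutation_test",
    "omnibus_decision",
]


@dataclass
class ExchangeabilityBlocks:
    """Families as exchangeability blocks over positional indices 0..n-1.

    ``blocks`` maps each block to ``{member_type: positions}``;
    ``signatures`` gives each block's composition signature.
    """

    blocks: list[dict[str, np.ndarray]]
    signatures: list[tuple]
    n: int


def blocks_from_metadata(metadata: pd.DataFrame) -> ExchangeabilityBlocks:
    """Build exchangeability blocks from family_id and zygosity columns."""
    meta = metadata.reset_index(drop=True)
    blocks, sigs = [], []
    for _, idx in meta.groupby("family_id", sort=False).indices.items():
        sub = meta.iloc[idx]
        by_type: dict[str, np.ndarray] = {}
        for t in ("MZ", "DZ", "NT"):
            pos = np.asarray(idx)[(sub["zygosity"] == t).to_numpy()]
            if len(pos):
                by_type[t] = pos
        blocks.append(by_type)
        sigs.append(tuple(sorted((t, len(p)) for t, p in by_type.items())))
    return ExchangeabilityBlocks(blocks=blocks, signatures=sigs, n=len(meta))


def permute_within_blocks(
    blocks: ExchangeabilityBlocks, rng: np.random.Generator
) -> np.ndarray:
    """Draw one valid restricted permutation.

    Returns ``perm`` such that ``Y[perm]`` relabels the rows: whole blocks
    move only onto blocks with an identical composition signature, and
    within a block each member type's slots are filled by members of the
    same type, in random order.
    """
    perm = np.empty(blocks.n, dtype=int)
    groups: dict[tuple, list[int]] = {}
    for bi, sig in enumerate(blocks.signatures):
        groups.setdefault(sig, []).append(bi)
    for members in groups.values():
        order = rng.permutation(len(members))
        for tgt_pos, src_pos in enumerate(order):
            tgt = blocks.blocks[members[tgt_pos]]
            src = blocks.blocks[members[src_pos]]
            for t, tgt_slots in tgt.items():
                perm[tgt_slots] = rng.permutation(src[t])
    return perm


def permutation_pvalue(
    observed: float,
    nulls: np.ndarray,
    n_comparisons: int = 5,
    estimator: str = "floor",
    tie_rule: str = "greater",
) -> tuple[float, float]:
    """Exceedance p-value with its Bonferroni correction over outer splits.

    ``floor``: p = count / n_perm, floored at 1/n_perm (the minimum
    reportable uncorrected p at 1000 permutations is 0.001).
    ``add_one``: p = (count + 1) / (n_perm + 1).
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    if tie_rule == "greater":
        count = int(np.sum(nulls > observed))
    elif tie_rule == "geq":
        count = int(np.sum(nulls >= observed))
    else:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    n = nulls.size
    if estimator == "floor":
        p = max(count, 1) / n
    elif estimator == "add_one":
        p = (count + 1) / (n + 1)
    else:
        raise ValueError(f"unknown p estimator {estimator!r}")
    p = min(p, 1.0)
    return p, min(1.0, n_comparisons * p)


def permutation_null(
    X_opt: np.ndarray,
    Y_opt: np.ndarray,
    X_hold: np.ndarray,
    Y_hold: np.ndarray,
    blocks_opt: ExchangeabilityBlocks,
    blocks_hold: ExchangeabilityBlocks,
    c_x: float,
    c_y: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null holdout correlations under family-restricted Y-row shuffling.

    Hyperparameters stay frozen at the values selected on the original
    data; they are never re-selected under permutation.  A failed fit is
    retried once with a fresh permutation; persistent failures propagate.
    """
    nulls = np.empty(n_perm)
    for it in range(n_perm):
        for attempt in (0, 1):
            try:
                po = permute_within_blocks(blocks_opt, rng)
                ph = permute_within_blocks(blocks_hold, rng)
                m = fit_rcca(X_opt, Y_opt[po], c_x, c_y)
                nulls[it] = project(m, X_hold, Y_hold[ph]).corr()
                break
            except DegenerateDataError:
                if attempt:
                    raise
    return nulls


@dataclass
class PermutationResult:
    observed: float
    nulls: np.ndarray
    p: float
    p_corrected: float


def run_permutation_test(
    X_opt: np.ndarray,
    Y_opt: np.ndarray,
    X_hold: np.ndarray,
    Y_hold: np.ndarray,
    metadata_opt: pd.DataFrame,
    metadata_hold: pd.DataFrame,
    c_x: float,
    c_y: float,
    n_perm: int,
    rng: np.random.Generator,
    n_comparisons: int = 5,
    estimator: str = "floor",
    tie_rule: str = "greater",
) -> PermutationResult:
    """Observed holdout correlation plus its restricted-permutation test."""
    model = fit_rcca(X_opt, Y_opt, c_x, c_y)
    observed = project(model, X_hold, Y_hold).corr()
    nulls = permutation_null(
        X_opt, Y_opt, X_hold, Y_hold,
        blocks_from_metadata(metadata_opt), blocks_from_metadata(metadata_hold),
        c_x, c_y, n_perm, rng,
    )
    p, p_corr = permutation_pvalue(observed, nulls, n_comparisons, estimator, tie_rule)
    return PermutationResult(observed=observed, nulls=nulls, p=p, p_corrected=p_corr)


def omnibus_decision(corrected_p: np.ndarray, alpha: float = 0.05) -> bool:
    """Reject the no-effect-in-any-split null iff any corrected p < alpha
    (strict inequality: p exactly equal to alpha does not reject)."""
    corrected_p = np.asarray(corrected_p, dtype=float)
    if corrected_p.size == 0:
        raise ValueError("need one corrected p per outer split")
    return bool(np.min(corrected_p) < alpha)
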