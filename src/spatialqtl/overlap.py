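"""Cross-phenotype set-overlap statistics: k-way intersections, a bootstrap
null over a background universe, and an analytic hypergeometric tail for
pairwise overlaps.

The bootstrap null draws, independently for each phenotype, a uniform random
subset of the background of the same size as that phenotype's observed set,
and records the intersection size of the combination; the empirical p-value
uses the add-one estimator (1 + #{null >= observed}) / (1 + n_boot), so it is
never zero and the smallest reportable value at 10,000 draws is just under
1e-4.  Each combination gets its own RNG stream derived by stable hashing of
the combination label, making results invariant to evaluation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import combo_label

_CHUNK_ELEMENTS = 20_000_000


@dataclass
class OverlapResult:
    combination: tuple[str, ...]
    observed: int
    background_label: str
    background_size: int
    n_boot: int
    null_counts: np.ndarray
    empirical_p: float
    seed: int


def compute_intersections(
    sets: Mapping[str, Collection[str]], exclusive: bool = False
) -> pd.DataFrame:
    """Intersection size for every combination of >=2 phenotypes.

    Inclusive semantics by default: the count for combination C is
    ``|intersection of the members' sets|`` regardless of other phenotypes.
    ``exclusive=True`` reports UpSet-style counts (elements in exactly the
    member sets and no others); no significance test is attached to those.
    """
    if len(sets) < 2:
        raise ValueError("need >=2 phenotypes to intersect")
    names = sorted(sets)
    as_sets = {k: set(v) for k, v in sets.items()}
    rows = []
    for k in range(2, len(names) + 1):
        for combo in _combinations(names, k):
            inter = set.intersection(*(as_sets[p] for p in combo))
            if exclusive:
                others = set(names) - set(combo)
                for o in others:
                    inter = inter - as_sets[o]
            rows.append({
                "combination": combo_label(combo),
                "k": k,
                "observed": len(inter),
                "members": ";".join(sorted(inter)),
            })
    return pd.DataFrame(rows)


def _combination_rng(seed: int, combination: Sequence[str]) -> np.random.Generator:
    """One independent, order-invariant stream per combination label."""
    label = combo_label(combination)
    digest = hashlib.blake2b(label.encode(), digest_size=8).digest()
    stream = int.from_bytes(digest, "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _sample_membership(rng: np.random.Generator, n_boot: int, n_bg: int, size: int) -> np.ndarray:
    """Boolean (n_boot, n_bg) matrix: uniform size-``size`` subsets w/o replacement."""
    member = np.zeros((n_boot, n_bg), dtype=bool)
    if size == 0:
        return member
    if size == n_bg:
        member[:] = True
        return member
    rows_per_chunk = max(1, _CHUNK_ELEMENTS // n_bg)
    for lo in range(0, n_boot, rows_per_chunk):
        hi = min(lo + rows_per_chunk, n_boot)
        keys = rng.random((hi - lo, n_bg))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        np.put_along_axis(member[lo:hi], idx, True, axis=1)
    return member


def bootstrap_overlap(
    set_sizes: Mapping[str, int],
    background: Collection[str],
    observed: int,
    n_boot: int = 10_000,
    seed: int = 0,
    background_label: str = "all_egenes",
) -> OverlapResult:
    """Bootstrap null for a k-way overlap of random subsets of ``background``."""
    if n_boot < 1:
        raise ValueError(f"n_boot must be >=1, got {n_boot}")
    combo = tuple(sorted(set_sizes))
    n_bg = len(set(background))
    for phen, size in set_sizes.items():
        if size > n_bg:
            raise ValueError(
                f"set size {size} for {phen!r} exceeds background size {n_bg}"
            )
    rng = _combination_rng(seed, combo)
    acc = np.ones((n_boot, n_bg), dtype=bool)
    for phen in combo:
        acc &= _sample_membership(rng, n_boot, n_bg, set_sizes[phen])
    null_counts = acc.sum(axis=1).astype(np.int64)
    empirical_p = (1 + int((null_counts >= observed).sum())) / (1 + n_boot)
    return OverlapResult(
        combination=combo,
        observed=int(observed),
        background_label=background_label,
        background_size=n_bg,
        n_boot=n_boot,
        null_counts=null_counts,
        empirical_p=empirical_p,
        seed=int(seed),
    )


def hypergeom_overlap_p(n1: int, n2: int, N: int, observed: int) -> float:
    """Exact upper tail P(X >= observed), X ~ Hypergeometric(N, n1, n2)."""
    if n1 > N or n2 > N:
        raise ValueError(f"set sizes ({n1}, {n2}) exceed background size {N}")
    lo = max(0, n1 + n2 - N)
    hi = min(n1, n2)
    if not lo <= observed <= hi:
        raise ValueError(
            f"observed overlap {observed} impossible for sizes ({n1}, {n2}) in {N} "
            f"(feasible range [{lo}, {hi}])"
        )
    return float(hypergeom.sf(observed - 1, N, n1, n2))


def run_both_backgrounds(
    egene_sets: Mapping[str, Collection[str]],
    backgrounds: Mapping[str, Collection[str]],
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Evaluate every combination under every background.

    Each phenotype set must be contained in each background.  The output
    flags combinations whose empirical significance (at ``alpha``) differs
    between backgrounds; pairwise combinations also carry the analytic
    hypergeometric tail probability.
    """
    inter = compute_intersections(egene_sets)
    sizes_all = {p: len(set(v)) for p, v in egene_sets.items()}
    rows = []
    for bg_label, bg in backgrounds.items():
        bg_set = set(bg)
        for phen, members in egene_sets.items():
            stray = set(members) - bg_set
            if stray:
                raise ValueError(
                    f"background {bg_label!r} is missing {len(stray)} genes from "
                    f"{phen!r}'s eGene set (e.g. {sorted(stray)[:3]})"
                )
        for rec in inter.itertuples():
            combo = tuple(rec.combination.split("+"))
            sizes = {p: sizes_all[p] for p in combo}
            res = bootstrap_overlap(
                sizes, bg_set, rec.observed, n_boot=n_boot, seed=seed,
                background_label=bg_label,
            )
            row = {
                "combination": rec.combination,
                "k": rec.k,
                "background": bg_label,
                "background_size": res.background_size,
                "observed": rec.observed,
                "empirical_p": res.empirical_p,
                "null_mean": float(res.null_counts.mean()),
                "analytic_p": np.nan,
            }
            if rec.k == 2:
                p1, p2 = combo
                row["analytic_p"] = hypergeom_overlap_p(
                    sizes[p1], sizes[p2], res.background_size, rec.observed
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    sig = out.assign(significant=out["empirical_p"] < alpha)
    differs = sig.groupby("combination")["significant"].nunique() > 1
    out["significance_differs_between_backgrounds"] = out["combination"].map(differs)
    return out
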