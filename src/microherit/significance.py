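"""Permutation-based heritability thresholds and genus enrichment.

A heritability estimate for a single OTU has no tractable null
distribution at the boundary h2 = 0, so significance is assessed
empirically: the OTU's abundances are shuffled across animals (design
columns and the selection traits untouched), the multi-trait model is
refitted, and the threshold is the lower bound of the upper
``error_rate`` tail of the permuted estimates.

Over- or under-representation of bacterial genera among the
significantly heritable OTU is tested per genus with a two-sided
Fisher's exact test on the 2x2 table (significant vs not) x (genus vs
other genera).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .animal_model import AnimalModel, ModelFrame

__all__ = [
    "PermutationResult",
    "permute_and_refit",
    "empirical_threshold",
    "genus_enrichment",
]


@dataclass
class PermutationResult:
    h2_estimates: np.ndarray
    threshold: float
    n_perm: int
    error_rate: float
    seed: int
    n_nonconverged: int = 0
    notes: list[str] = field(default_factory=list)


def permute_and_refit(
    otu_values: np.ndarray,
    frame_template: ModelFrame,
    A,
    n_perm: int,
    seed: int,
    trait: int | str | None = None,
    error_rate: float = 0.05,
    em_rounds: int = 20,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> PermutationResult:
    """Shuffle one OTU's values across animals and refit the model.

    ``frame_template`` is the multi-trait frame whose ``trait`` column
    (default: the last trait) receives the shuffled values.  The
    relationship eigendecomposition is shared across all refits, so a
    permutation run costs one decomposition plus ``n_perm`` cheap
    REML fits.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    otu_values = np.asarray(otu_values, dtype=float)
    if otu_values.shape != (frame_template.n,):
        raise ValueError("otu_values must match the frame's records")
    t = frame_template.n_traits - 1 if trait is None else (
        trait if isinstance(trait, int) else frame_template.traits.index(trait)
    )
    model = AnimalModel(frame_template.with_trait_values(t, otu_values), A)
    engine = model.engine
    P0, R0 = model.default_start()
    rng = np.random.default_rng(seed)
    h2s = np.empty(n_perm)
    n_bad = 0
    for k in range(n_perm):
        perm = rng.permutation(frame_template.n)
        engine.set_trait(t, otu_values[perm])
        vc = engine.fit(P0, R0, em_rounds=em_rounds, tol=tol, max_iter=max_iter)
        tot = vc.P[t, t] + vc.R[t, t]
        h2s[k] = vc.P[t, t] / tot if tot > 0 else 0.0
        if not vc.converged:
            n_bad += 1
    notes = []
    if n_bad > 0.05 * n_perm:
        msg = f"{n_bad}/{n_perm} permutation refits did not converge"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    thr = empirical_threshold(h2s, error_rate)
    return PermutationResult(
        h2_estimates=h2s,
        threshold=thr,
        n_perm=n_perm,
        error_rate=error_rate,
        seed=seed,
        n_nonconverged=n_bad,
        notes=notes,
    )


def empirical_threshold(h2_estimates, error_rate: float = 0.05) -> float:
    """Lower value of the upper ``error_rate`` tail.

    Estimates are sorted ascending; with k = floor(error_rate * n) the
    threshold is the element of (1-based) rank n - k + 1, i.e. the
    smallest member of the top k.  Ties resolve to the first qualifying
    sorted element by construction.
    """
    x = np.sort(np.asarray(h2_estimates, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("no heritability estimates")
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    k = math.floor(error_rate * n)
    if k < 1:
        raise ValueError(
            f"error_rate {error_rate} selects no estimates out of {n}; "
            "increase the number of permutations"
        )
    return float(x[n - k])


def genus_enrichment(
    taxonomy: pd.DataFrame,
    significant_otu_ids,
    all_otu_ids,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact test of genus representation among significant OTU.

    For each genus the 2x2 table is
    [[significant & genus, significant & other],
     [non-significant & genus, non-significant & other]].
    Returns one row per genus with counts, the genus percentage in the
    significant group (g1_pct) and over all OTU (g2_pct), the odds
    ratio, the two-sided p-value (sum of hypergeometric probabilities
    of tables at most as probable as the observed one), and the flag at
    ``alpha``.
    """
    all_ids = [str(o) for o in all_otu_ids]
    sig = {str(o) for o in significant_otu_ids}
    unknown = sig - set(all_ids)
    if unknown:
        raise ValueError(f"significant OTU not in the full set: {sorted(unknown)[:5]}")
    genus_of = taxonomy["genus"].astype(str)
    missing = set(all_ids) - set(taxonomy.index.astype(str))
    if missing:
        raise ValueError(f"taxonomy missing OTU: {sorted(missing)[:5]}")
    genus = pd.Series({o: genus_of.loc[o] for o in all_ids})
    n_sig, n_all = len(sig), len(all_ids)
    rows = []
    for g, members in genus.groupby(genus).groups.items():
        ids = set(members)
        a = len(ids & sig)
        b = n_sig - a
        c = len(ids) - a
        d = (n_all - n_sig) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "genus": g,
                "n_significant": a,
                "n_other_significant": b,
                "n_nonsignificant": c,
                "n_other_nonsignificant": d,
                "g1_pct": 100.0 * a / n_sig if n_sig else np.nan,
                "g2_pct": 100.0 * (a + c) / n_all,
                "odds_ratio": odds,
                "p_value": float(p),
                "significant": bool(p < alpha),
            }
        )
    out = pd.DataFrame(rows).sort_values("p_value").reset_index(drop=True)
    return out
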