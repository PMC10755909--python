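"""All-pairwise Wald comparisons and compact letter displays.

Levels sharing a letter are not significantly different at the chosen
alpha under the chosen multiplicity adjustment. The default adjustment is
the Tukey-style studentized-range approximation (the convention of
estimated-marginal-means software); "bonferroni" and "none" are
alternatives. Tests use the normal (z) reference by default.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LetterGrouping:
    """Letters per level, plus the pairwise tests they summarize."""

    levels: List         # ordered by estimate (ascending)
    letters: Dict        # level -> letter string, e.g. "ab"
    alpha: float
    adjustment: str
    pairwise: pd.DataFrame  # level_1, level_2, estimate_diff, se, z, p_adj


def pairwise_letters(
    levels: Sequence,
    estimates: np.ndarray,
    vcov: np.ndarray,
    alpha: float = 0.05,
    adjustment: str = "tukey",
    df: float = np.inf,
) -> LetterGrouping:
    """Pairwise Wald tests over levels and the resulting letter display.

    ``vcov`` is the covariance of the estimates (aligned with ``levels``).
    ``df`` switches the reference distribution from z (the default,
    df=inf) to a t/studentized-range with that many degrees of freedom.
    Letters run alphabetically from the smallest estimate; ties keep the
    input level order.
    """
    levels = list(levels)
    est = np.asarray(estimates, float)
    V = np.asarray(vcov, float)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two levels to compare")
    if V.shape != (k, k):
        raise ValueError(f"vcov shape {V.shape} does not match {k} levels")
    if adjustment not in ("tukey", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")

    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            var = V[i, i] + V[j, j] - 2.0 * V[i, j]
            diff = est[i] - est[j]
            if var <= 0:
                if abs(diff) < 1e-12:
                    rows.append((levels[i], levels[j], diff, 0.0, 0.0, 1.0))
                    continue
                raise ValueError(
                    f"singular vcov slice: non-positive contrast variance for "
                    f"({levels[i]}, {levels[j]})"
                )
            se = float(np.sqrt(var))
            z = diff / se
            rows.append((levels[i], levels[j], diff, se, z, _p_adj(z, k, m, adjustment, df)))
    pairwise = pd.DataFrame(
        rows, columns=["level_1", "level_2", "estimate_diff", "se", "z", "p_adj"]
    )

    order = sorted(range(k), key=lambda i: (est[i], i))
    ordered = [levels[i] for i in order]
    sig = {
        frozenset((r.level_1, r.level_2))
        for r in pairwise.itertuples()
        if r.p_adj < alpha
    }
    letters = _insert_absorb(ordered, sig)
    return LetterGrouping(
        levels=ordered, letters=letters, alpha=alpha,
        adjustment=adjustment, pairwise=pairwise,
    )


def _p_adj(z: float, k: int, m: int, adjustment: str, df: float) -> float:
    if np.isinf(df):
        p_raw = 2.0 * stats.norm.sf(abs(z))
    else:
        p_raw = 2.0 * stats.t.sf(abs(z), df)
    if adjustment == "none":
        return float(p_raw)
    if adjustment == "bonferroni":
        return float(min(1.0, m * p_raw))
    # Tukey: |z| * sqrt(2) referred to the studentized range of k means
    return float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, df))


def _insert_absorb(ordered: List, sig: set) -> Dict:
    """Insert-and-absorb letter assignment.

    Start from one group holding every level; for each significant pair
    split every group containing both; absorb groups that became subsets.
    """
    groups: List[set] = [set(ordered)]
    for pair in sig:
        a, b = tuple(pair)
        new_groups: List[set] = []
        for grp in groups:
            if a in grp and b in grp:
                new_groups.append(grp - {a})
                new_groups.append(grp - {b})
            else:
                new_groups.append(grp)
        # absorb subsets
        groups = []
        for grp in sorted(new_groups, key=len, reverse=True):
            if grp and not any(grp <= kept for kept in groups):
                groups.append(grp)
    pos = {lvl: i for i, lvl in enumerate(ordered)}
    groups.sort(key=lambda grp: min(pos[x] for x in grp))
    alphabet = string.ascii_lowercase
    letters = {lvl: "" for lvl in ordered}
    for gi, grp in enumerate(groups):
        lab = alphabet[gi] if gi < 26 else f"({gi})"
        for lvl in grp:
            letters[lvl] += lab
    return {lvl: "".join(sorted(letters[lvl])) for lvl in ordered}
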