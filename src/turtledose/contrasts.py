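"""Pairwise Wald contrasts with Holm correction and compact letter displays.

Shared by the debris-count model (cause-of-death coefficient ordering) and
the stranding presence/absence model.  A compact letter display labels the
factor levels so that two levels share a letter if and only if they belong
to a common group of mutually non-significant levels after correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from string import ascii_lowercase

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise difference between factor-level effects (log scale)."""

    pair: tuple[str, str]
    estimate: float
    std_error: float
    z: float
    p_raw: float
    p_adjusted: float


def pairwise_wald(effects: pd.Series, cov: pd.DataFrame,
                  alpha: float = 0.05) -> list[ContrastResult]:
    """All pairwise Wald z contrasts among the given level effects.

    ``effects`` maps level name -> effect estimate; ``cov`` is the covariance
    of those effects (a reference level enters with effect 0 and zero
    variance/covariance rows).  p-values are Holm-adjusted; with a single
    pair the adjusted p equals the raw p.
    """
    levels = list(effects.index)
    if len(levels) < 2:
        raise ValueError("need at least two levels to contrast")
    pairs = list(combinations(levels, 2))
    est, se = [], []
    for a, b in pairs:
        d = float(effects[a] - effects[b])
        v = float(cov.loc[a, a] + cov.loc[b, b] - 2 * cov.loc[a, b])
        est.append(d)
        se.append(np.sqrt(max(v, 0.0)))
    est = np.asarray(est)
    se = np.asarray(se)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.inf * np.sign(est))
        z = np.where(est == 0, 0.0, z)
    p_raw = 2 * stats.norm.sf(np.abs(z))
    p_adj = multipletests(p_raw, alpha=alpha, method="holm")[1]
    return [ContrastResult(pair=(a, b), estimate=float(e), std_error=float(s),
                           z=float(zz), p_raw=float(pr), p_adjusted=float(pa))
            for (a, b), e, s, zz, pr, pa in zip(pairs, est, se, z, p_raw,
                                                p_adj)]


def compact_letters(effects: pd.Series, contrasts: list[ContrastResult],
                    alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from the adjusted-significance graph.

    Levels are vertices; an edge joins each pair NOT significantly different
    at ``alpha`` (after correction).  Every maximal clique receives one
    letter, cliques ordered by the mean effect of their members, so letters
    run roughly from the lowest group upward.  A level's display is the
    sorted concatenation of the letters of the cliques containing it.
    """
    g = nx.Graph()
    g.add_nodes_from(effects.index)
    for c in contrasts:
        if c.p_adjusted >= alpha:
            g.add_edge(*c.pair)
    cliques = sorted(nx.find_cliques(g),
                     key=lambda c: (float(np.mean([effects[m] for m in c])),
                                    sorted(c)))
    letters: dict[str, list[str]] = {lvl: [] for lvl in effects.index}
    for letter, clique in zip(_letter_stream(), cliques):
        for member in clique:
            letters[member].append(letter)
    return {lvl: "".join(sorted(ls)) for lvl, ls in letters.items()}


def _letter_stream():
    for ch in ascii_lowercase:
        yield ch
    i = 2
    while True:  # a2, b2, ... beyond 26 groups (never needed in practice)
        for ch in ascii_lowercase:
            yield f"{ch}{i}"
        i += 1


def contrasts_frame(contrasts: list[ContrastResult],
                    letters: dict[str, str]) -> pd.DataFrame:
    """Flatten contrasts + letter display into one emission-ready table."""
    df = pd.DataFrame([{
        "level_a": c.pair[0], "level_b": c.pair[1], "estimate": c.estimate,
        "std_error": c.std_error, "z": c.z, "p_raw": c.p_raw,
        "p_adjusted": c.p_adjusted} for c in contrasts])
    df["letters_a"] = df["level_a"].map(letters)
    df["letters_b"] = df["level_b"].map(letters)
    return df
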