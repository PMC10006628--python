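"""Overrepresentation of the selected protein set in user-supplied term sets.

One-sided Fisher exact (hypergeometric upper tail) per term: with a
universe of N proteins, a term of size K and n selected proteins, the
p-value for an observed overlap x is P(X >= x), X ~ Hypergeom(N, K, n).
Raw p-values are reported; an optional Bonferroni flag adjusts over terms.
Term sets come from a two-column TSV (term id, protein symbol); no ontology
graph is modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["EnrichmentResult", "fisher_overrepresentation", "read_term_sets"]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # term_id -> term_size, overlap, p [, p_bonferroni]

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.Index:
        col = "p_bonferroni" if adjusted else "p"
        return self.table.index[self.table[col] < alpha]


def fisher_overrepresentation(selected, universe, terms: dict,
                              bonferroni: bool = False) -> EnrichmentResult:
    """Upper-tail hypergeometric test of each term against the selection.

    ``selected`` must be a subset of ``universe``; each term set is first
    intersected with the universe, and terms disjoint from it are skipped
    with a warning.
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValueError("empty universe")
    stray = selected - universe
    if stray:
        raise ValueError(f"selected proteins outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(selected)
    rows = []
    for term_id, members in terms.items():
        members = set(members) & universe
        if not members:
            warnings.warn(f"term {term_id!r} is disjoint from the universe; skipped")
            continue
        K = len(members)
        x = len(members & selected)
        p = float(hypergeom.sf(x - 1, N, K, n))
        rows.append((term_id, K, x, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term_id", "term_size", "overlap", "p"])
    table = table.set_index("term_id")
    if bonferroni:
        table["p_bonferroni"] = (table["p"] * len(table)).clip(upper=1.0)
    return EnrichmentResult(table)


def read_term_sets(path) -> dict:
    """Load term sets from a two-column TSV (term id, protein symbol)."""
    df = pd.read_csv(path, sep="\t", header=0)
    term_col, sym_col = df.columns[:2]
    return {t: set(g[sym_col]) for t, g in df.groupby(term_col, sort=False)}
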