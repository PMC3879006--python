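"""Gene-set over-representation of the significant-locus genes.

Each category is tested with the standard hypergeometric upper tail
against the universe of annotated genes on the panel, and summarized by
the sample odds ratio of the 2x2 table

    =============  ==========  ==============
                   in subset   not in subset
    in term        a           b = K - a
    not in term    c = m - a   d = N - K - m + a
    =============  ==========  ==============

Note: a DAG-conditional variant of this test (conditioning each parent
term on its significant children) requires the full ontology graph and
is deliberately not implemented; the plain hypergeometric is reported
and flagged in output headers.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy import stats

__all__ = ["enrich", "nearest_gene_assignment"]

TEST_LABEL = "hypergeometric (unconditional)"


def nearest_gene_assignment(significant_probes, annotations: pd.DataFrame,
                            ) -> list[str]:
    """Map significant probes to their closest annotated genes.

    Takes the first listed gene symbol for each probe (annotation lists
    are ordered by proximity), skipping probes with no annotated gene
    (with a warning), and collapses duplicates while preserving first-
    occurrence order.
    """
    import warnings

    ann = annotations.set_index("probe_id")
    genes: list[str] = []
    n_skipped = 0
    for pid in significant_probes:
        raw = ann.at[pid, "gene_symbols"]
        if isinstance(raw, str):
            symbols = [g.strip() for g in raw.split(";") if g.strip()]
        else:
            symbols = list(raw)
        if not symbols:
            n_skipped += 1
            continue
        if symbols[0] not in genes:
            genes.append(symbols[0])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} probe(s) without gene "
                      "annotation", stacklevel=2)
    return genes


def enrich(subset_genes, gene2term: pd.DataFrame,
           universe_genes=None) -> pd.DataFrame:
    """Per-term over-representation of ``subset_genes``.

    ``gene2term`` is a flat two-column map (term, gene). The universe
    defaults to all genes carrying at least one annotation; an explicit
    universe is used as given (restricting the map to its members), so
    genes without any category still count toward N. Every subset gene
    must be in the universe. Terms with no subset hit (a = 0) are
    omitted. Rows are sorted by p ascending, then odds ratio
    descending, then term name; infinite odds ratios (b*c = 0) are
    reported as ``inf``.

    Output columns: term, a, K, m, N, odds_ratio, p.
    """
    g2t = gene2term.rename(columns=dict(
        zip(gene2term.columns[:2], ["term", "gene"])))[["term", "gene"]]
    g2t = g2t.drop_duplicates()

    if universe_genes is not None:
        universe = set(universe_genes)
        g2t = g2t[g2t["gene"].isin(universe)]
    else:
        universe = set(g2t["gene"])
    if not universe:
        raise ValueError("annotation universe is empty")

    subset = list(dict.fromkeys(subset_genes))
    missing = [g for g in subset if g not in universe]
    if missing:
        raise ValueError(
            f"subset gene(s) absent from the annotated universe: {missing}")

    N = len(universe)
    m = len(subset)
    subset_set = set(subset)

    rows = []
    for term, members in g2t.groupby("term")["gene"]:
        member_set = set(members)
        K = len(member_set)
        a = len(member_set & subset_set)
        if a == 0:
            continue
        b = K - a
        c = m - a
        d = N - K - m + a
        if b * c == 0:
            odds = math.inf if a * d > 0 else math.nan
        else:
            odds = (a * d) / (b * c)
        p = float(stats.hypergeom.sf(a - 1, N, K, m))
        rows.append({"term": term, "a": a, "K": K, "m": m, "N": N,
                     "odds_ratio": odds, "p": p})

    out = pd.DataFrame(rows,
                       columns=["term", "a", "K", "m", "N", "odds_ratio", "p"])
    if len(out):
        out = out.sort_values(
            ["p", "odds_ratio", "term"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return out
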