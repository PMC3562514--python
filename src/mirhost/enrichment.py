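"""Gene-set over-representation testing for predicted miRNA targets.

GO / KEGG / disease-ontology / user term collections are consumed as plain
GMT files; each term is scored with the hypergeometric upper tail (the
probability of at least the observed overlap between the query gene list and
the term under random draws from the universe).  A one-sided Fisher exact
test on a 2x2 overlap table is provided for comparing two prediction sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

AdjustMethod = Literal["bh", "bonferroni", "none"]


@dataclass
class GeneSetCollection:
    label: str
    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"gene set {tid!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path: str | Path, label: str = "user") -> GeneSetCollection:
    """Read a GMT file: tab-separated lines of term id, description, then
    one or more member gene ids (de-duplicated)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has <3 fields")
            tid, desc, *members = fields
            if tid in terms:
                raise ValueError(f"{path}: duplicate term id {tid!r} at line {lineno}")
            terms[tid] = (desc, frozenset(m for m in members if m))
    return GeneSetCollection(label=label, terms=terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (desc, members) in collection.terms.items():
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of the query in every
    term, sets intersected with the universe first; sorted by raw p.

    For overlap k, term size K, query size n, universe size N:
    p = P(X >= k), X ~ Hypergeometric(N, K, n).
    """
    universe_set = set(universe)
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene list")
    if not query_set <= universe_set:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe_set), len(query_set)
    rows = []
    for tid, (desc, members) in collection.terms.items():
        K = len(members & universe_set)
        if K == 0:
            continue
        k = len(members & query_set)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": tid, "description": desc, "k": k, "K": K, "n": n,
             "N": N, "pval": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = adjust_pvalues(out["pval"].to_numpy(), method="bh")
        out = out.sort_values(["pval", "term_id"], kind="stable").reset_index(drop=True)
    return out


def adjust_pvalues(
    pvals: np.ndarray, method: AdjustMethod = "bh"
) -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up (default),
    Bonferroni, or identity."""
    pvals = np.asarray(pvals, dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none" or len(pvals) == 0:
        return pvals.copy()
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(pvals, method=sm_method)[1]


def fisher_overlap_test(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact test on the 2x2 table
    [[a, b], [c, d]], where ``a`` is the overlap between two prediction
    sets.  Returns the exact hypergeometric upper-tail p-value."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
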