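"""GO-slim term enrichment among called strains.

Over-representation of each flattened GO-slim term among the hit genes
is tested against the screenable reference set (all strains with a
comparable day-0 density) with the hypergeometric upper tail, followed
by Benjamini-Hochberg FDR control.  Dubious ORFs are excluded from hits
and reference alike, and terms annotating fewer than 25 reference genes
are not evaluated.  No ontology-graph propagation is performed: GO slim
is already a flattened term set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_TERM_SIZE = 25
DEFAULT_Q_THRESHOLD = 0.06


@dataclass
class GeneSetAnnotation:
    """Flat gene -> term annotation with a dubious-ORF flag per gene."""

    term_genes: dict[str, set[str]]
    dubious: set[str] = field(default_factory=set)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GeneSetAnnotation":
        """Build from a two-column (gene, term) table, plus optional ``dubious`` column."""
        terms: dict[str, set[str]] = {}
        for _, row in table.iterrows():
            terms.setdefault(str(row["term"]), set()).add(str(row["gene"]))
        dubious = set()
        if "dubious" in table.columns:
            dubious = set(table.loc[table["dubious"].astype(bool), "gene"].astype(str))
        return cls(term_genes=terms, dubious=dubious)


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a draw of ``n`` from a universe of ``N``
    genes of which ``K`` carry the term.  ``k = 0`` gives p = 1 exactly.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    hit_genes: set[str],
    reference_genes: set[str],
    annotation: GeneSetAnnotation,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    tail: str = "upper",
) -> pd.DataFrame:
    """Term-level enrichment of ``hit_genes`` within ``reference_genes``.

    Term sizes are counted within the reference set, not the genome.
    ``tail='lower'`` tests depletion instead (P(X <= k)); the default is
    the over-representation test.  Returns a table sorted by q with
    columns ``term, k, K, n, N, p, q, enriched``; empty hits yield an
    empty table with a logged warning.
    """
    hit_genes = set(hit_genes)
    reference_genes = set(reference_genes)
    if not hit_genes <= reference_genes:
        extra = sorted(hit_genes - reference_genes)[:3]
        raise ValueError(f"hit genes not in reference, e.g. {extra}")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")

    hits = hit_genes - annotation.dubious
    reference = reference_genes - annotation.dubious
    if not hits:
        logger.warning("empty hit set after dubious-ORF exclusion; nothing to test")
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q", "enriched"])

    n, N = len(hits), len(reference)
    rows = []
    for term, genes in sorted(annotation.term_genes.items()):
        in_ref = genes & reference
        K = len(in_ref)
        if K < min_term_size:
            continue
        k = len(in_ref & hits)
        if tail == "upper":
            p = hypergeom_p(k, n, K, N)
        else:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    if not rows:
        logger.warning("no term reaches min_term_size=%d in the reference", min_term_size)
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q", "enriched"])

    result = pd.DataFrame.from_records(rows)
    _, q, _, _ = multipletests(result["p"], method="fdr_bh")
    result["q"] = q
    result["enriched"] = result["q"] < q_threshold
    return result.sort_values(["q", "p", "term"], kind="stable").reset_index(drop=True)
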