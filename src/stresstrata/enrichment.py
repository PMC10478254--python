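"""Differential expression ranking and gene-set overrepresentation.

Genes are ranked by a pooled-variance two-sample t-test on log2(CPM + 1)
(the log transform stabilises the strong mean–variance coupling of CPM
values); the top-N list by ascending p enters a right-tailed hypergeometric
overrepresentation test against a gene-set collection, with
Benjamini–Hochberg adjustment across sets. This is a transparent surrogate
for commercial canonical-pathway tools, which reduce to the same
Fisher/hypergeometric computation for set overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class DEGRecord:
    gene: str
    t_statistic: float
    p: float
    log2fc: float  # group1 − group2 on the log2(CPM+1) scale


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p_right_tail: float
    q_bh: float
    overlap_genes: list[str]
    #: sign of log2fc per overlap gene (+1 up in group1, −1 down), when
    #: DEG records were supplied
    directions: dict[str, int] | None = None


def differential_expression(
    matrix: ExpressionMatrix, groups: Mapping[str, int]
) -> list[DEGRecord]:
    """Per-gene pooled t-test on log2(CPM + 1) between groups 1 and 2.

    ``groups`` maps sample id → 1 or 2; samples absent from the map are
    ignored. Genes with zero within-group variance in both groups cannot be
    tested and are excluded (the count is logged).
    """
    g1 = [s for s, g in groups.items() if g == 1]
    g2 = [s for s, g in groups.items() if g == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    bad = set(groups.values()) - {1, 2}
    if bad:
        raise ValueError(f"group labels must be 1 or 2, got {sorted(bad)}")

    x = np.log2(matrix.values.loc[:, g1].to_numpy(dtype=float) + 1.0)
    y = np.log2(matrix.values.loc[:, g2].to_numpy(dtype=float) + 1.0)
    nx, ny = x.shape[1], y.shape[1]
    df = nx + ny - 2
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
    diff = x.mean(axis=1) - y.mean(axis=1)

    testable = sp2 > 0
    n_excluded = int((~testable).sum())
    if n_excluded:
        logger.info("excluded %d zero-variance gene(s) from DEG ranking", n_excluded)

    t = np.zeros(len(diff))
    p = np.ones(len(diff))
    se = np.sqrt(sp2[testable] * (1.0 / nx + 1.0 / ny))
    t[testable] = diff[testable] / se
    p[testable] = 2.0 * sps.t.sf(np.abs(t[testable]), df)

    genes = matrix.gene_ids
    return [
        DEGRecord(gene=genes[i], t_statistic=float(t[i]), p=float(min(p[i], 1.0)),
                  log2fc=float(diff[i]))
        for i in range(len(genes))
        if testable[i]
    ]


def top_n(records: Sequence[DEGRecord], n: int = 8000) -> list[str]:
    """The first min(n, len) genes sorted by ascending p.

    Ties break by descending |t| and then gene id, so the cut is
    deterministic and independent of input order.
    """
    if not records:
        raise ValueError("no DEG records to rank")
    ordered = sorted(records, key=lambda r: (r.p, -abs(r.t_statistic), r.gene))
    return [r.gene for r in ordered[: min(n, len(ordered))]]


def overrepresentation(
    gene_list: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
    deg_records: Sequence[DEGRecord] | None = None,
) -> list[EnrichmentRecord]:
    """Right-tailed hypergeometric overrepresentation of each gene set.

    Set members are intersected with the universe before testing; the gene
    list must be contained in the universe. For a set with K universe
    members, a list of size n and a universe of size M with overlap k,
    p = P[X ≥ k], X ~ Hypergeometric(M, K, n). Output is sorted by
    ascending p (ties by set name) and carries BH q-values across sets.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    listed = set(gene_list)
    outside = listed - universe_set
    if outside:
        raise ValueError(f"gene list not contained in universe: {sorted(outside)[:5]}")
    m = len(universe_set)
    n_list = len(listed)
    lfc = {r.gene: r.log2fc for r in deg_records} if deg_records is not None else None

    records: list[EnrichmentRecord] = []
    for name, members in sets.items():
        in_universe = members & universe_set
        overlap_genes = sorted(in_universe & listed)
        k = len(overlap_genes)
        kk = len(in_universe)
        p = float(sps.hypergeom.sf(k - 1, m, kk, n_list)) if kk else 1.0
        directions = None
        if lfc is not None:
            directions = {
                g: (1 if lfc[g] >= 0 else -1) for g in overlap_genes if g in lfc
            }
        records.append(
            EnrichmentRecord(
                set_name=name,
                overlap=k,
                set_size=kk,
                list_size=n_list,
                universe_size=m,
                p_right_tail=min(1.0, p),
                q_bh=np.nan,
                overlap_genes=overlap_genes,
                directions=directions,
            )
        )
    if records:
        qs = bh_adjust([r.p_right_tail for r in records])
        for r, q in zip(records, qs):
            r.q_bh = float(q)
    records.sort(key=lambda r: (r.p_right_tail, r.set_name))
    return records
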