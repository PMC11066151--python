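"""Gene-level summarization and platform intersection.

Probe-level arrays are collapsed to one row per gene by keeping the most
variable probeset per gene; probesets without a gene annotation are
discarded.  Cross-platform analyses restrict a matrix to the genes shared
with a second platform while preserving row order.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import pandas as pd


def collapse_probesets(probe_matrix: pd.DataFrame,
                       probe_gene_map: Mapping[str, Optional[str]]) -> pd.DataFrame:
    """Collapse a probesets x samples matrix to genes x samples.

    For every gene the probeset with the largest sample variance
    (denominator n-1) is kept; ties go to the lexicographically smallest
    probeset identifier.  Probesets mapping to ``None``/empty are dropped.
    Gene rows appear in order of first occurrence in the probe matrix.
    """
    variances = probe_matrix.var(axis=1, ddof=1)
    best: dict[str, str] = {}
    order: list[str] = []
    for probeset in probe_matrix.index:
        gene = probe_gene_map.get(probeset)
        if gene is None or gene == "":
            continue
        if gene not in best:
            best[gene] = probeset
            order.append(gene)
        else:
            incumbent = best[gene]
            v_new, v_old = variances[probeset], variances[incumbent]
            if v_new > v_old or (v_new == v_old and probeset < incumbent):
                best[gene] = probeset
    if not best:
        raise ValueError("no probeset maps to any gene")
    collapsed = probe_matrix.loc[[best[g] for g in order]].copy()
    collapsed.index = pd.Index(order, name=probe_matrix.index.name)
    return collapsed


def intersect_genes(expr: pd.DataFrame, other_gene_ids: Iterable[str]) -> pd.DataFrame:
    """Restrict ``expr`` to genes present in ``other_gene_ids``, keeping order."""
    other = set(other_gene_ids)
    keep = [g for g in expr.index if g in other]
    if not keep:
        raise ValueError("gene intersection between the two platforms is empty")
    return expr.loc[keep]


def read_probe_gene_map(path) -> dict[str, Optional[str]]:
    """Read a 2-column TSV (probeset_id, gene_id; empty gene = unmapped)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    probes = df.iloc[:, 0]
    if probes.duplicated().any():
        dups = sorted(probes[probes.duplicated()].unique())
        raise ValueError(f"duplicate probeset identifiers: {dups}")
    return {p: (g if g else None) for p, g in zip(probes, df.iloc[:, 1])}
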