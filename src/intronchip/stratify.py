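"""Expression filtering and decile stratification of genes.

Linear-scale array expression values below 1 are treated as
undetectable and excluded.  Detected genes are partitioned into spliced
and unspliced sets, ranked in descending expression within each
partition, and split into ``n_groups`` contiguous rank groups (decile 1
holds the most highly expressed genes; when the partition size is not
divisible, the extra genes go to the highest-expression groups, as a
plain slice of the sorted list gives).  Ties are broken by gene id so
the assignment is deterministic and seed-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import BinScheme
from .genome_model import GenomeAnnotation
from .metagene import (
    LAYOUT_SPLICED,
    LAYOUT_UNSPLICED,
    MetageneProfile,
    build_spliced_profile,
    build_unspliced_profile,
)
from .normalize import EnrichmentTrack

logger = logging.getLogger(__name__)

EXPRESSION_DETECTION_THRESHOLD = 1.0


@dataclass
class ExpressionBinTable:
    """Per-gene expression, splice status and decile assignment.

    ``table`` columns: gene_id, expression (linear scale, replicate
    mean), spliced (bool), excluded (bool), decile (1..n_groups;
    <NA> for excluded genes).
    """

    table: pd.DataFrame
    n_groups: int

    def decile_gene_ids(self, decile: int, spliced: bool) -> list[str]:
        t = self.table
        sel = (t["decile"] == decile) & (t["spliced"] == spliced) & ~t["excluded"]
        return t.loc[sel, "gene_id"].tolist()

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    def counts(self) -> dict[str, int]:
        t = self.table
        kept = t[~t["excluded"]]
        return {
            "n_genes": len(t),
            "n_excluded": self.n_excluded,
            "n_spliced": int(kept["spliced"].sum()),
            "n_unspliced": int((~kept["spliced"]).sum()),
        }


def _group_sizes(n: int, k: int) -> list[int]:
    """Slice n sorted items into k groups, extras to the earliest groups."""
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def filter_and_rank(expr: pd.DataFrame, annotation: GenomeAnnotation,
                    n_groups: int = 10) -> ExpressionBinTable:
    """Build the decile table from a gene-by-replicate expression frame.

    ``expr`` needs a ``gene_id`` column; every further column is one
    replicate of linear-scale expression, averaged before filtering.
    Genes absent from the annotation are dropped (count logged).
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    expr = expr.copy()
    rep_cols = [c for c in expr.columns if c != "gene_id"]
    if not rep_cols:
        raise ValueError("expression table has no value columns")
    expr["expression"] = expr[rep_cols].astype(float).mean(axis=1)

    known = expr["gene_id"].isin(annotation.genes.keys())
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropping %d expression gene(s) absent from annotation", n_dropped)
    expr = expr[known]

    rows = []
    for r in expr.itertuples():
        gene = annotation.genes[r.gene_id]
        rows.append((r.gene_id, r.expression, gene.spliced,
                     r.expression < EXPRESSION_DETECTION_THRESHOLD))
    table = pd.DataFrame(rows, columns=["gene_id", "expression", "spliced", "excluded"])
    table["decile"] = pd.array([pd.NA] * len(table), dtype="Int64")

    for spliced in (True, False):
        part = table[(table["spliced"] == spliced) & ~table["excluded"]]
        if part.empty:
            continue
        if len(part) < n_groups:
            raise ValueError(
                f"{'spliced' if spliced else 'unspliced'} partition has "
                f"{len(part)} genes, fewer than {n_groups} groups"
            )
        order = part.sort_values(
            ["expression", "gene_id"], ascending=[False, True], kind="mergesort"
        ).index
        sizes = _group_sizes(len(order), n_groups)
        pos = 0
        for d, size in enumerate(sizes, start=1):
            table.loc[order[pos : pos + size], "decile"] = d
            pos += size
    return ExpressionBinTable(table=table, n_groups=n_groups)


def read_expression_tsv(path) -> pd.DataFrame:
    """Read ``gene_id  value[ value2 ...]`` expression TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if df.columns[0] != "gene_id":
        raise ValueError("expression TSV must start with a gene_id column")
    return df


def write_decile_tsv(bins: ExpressionBinTable, path) -> None:
    bins.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def profiles_by_decile(bins: ExpressionBinTable, track: EnrichmentTrack,
                       annotation: GenomeAnnotation, probes, scheme: BinScheme,
                       ) -> dict[str, list[MetageneProfile]]:
    """One spliced (70-bin) and one unspliced (40-bin) profile per decile.

    Returns ``{layout: [profile for decile 1..n]}``; each profile is
    labelled ``decile_<d>``.  An empty decile raises.
    """
    probes = list(probes)
    out: dict[str, list[MetageneProfile]] = {LAYOUT_SPLICED: [], LAYOUT_UNSPLICED: []}
    for d in range(1, bins.n_groups + 1):
        for spliced, layout, builder in (
            (True, LAYOUT_SPLICED, build_spliced_profile),
            (False, LAYOUT_UNSPLICED, build_unspliced_profile),
        ):
            gids = bins.decile_gene_ids(d, spliced)
            if not gids:
                raise ValueError(f"decile {d} ({layout}) is empty")
            genes = [annotation.genes[g] for g in gids]
            out[layout].append(builder(genes, track, probes, scheme,
                                       gene_set_label=f"decile_{d}"))
    return out
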