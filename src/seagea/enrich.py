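"""SNP genomic-context classification and GO-term enrichment.

Context classes (precedence exonic > intronic > promoter > intergenic) are
derived from GFF3 gene/exon features; the promoter is a strand-aware window
upstream of the transcription start.  Enrichment compares candidate loci
against the full filtered background with two-sided Fisher's exact tests
and Benjamini-Hochberg control.

Coordinates: GFF3 intervals are 1-based inclusive; internal arithmetic uses
half-open 0-based intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .popstruct import fdr_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "classify_context",
    "load_go_map",
    "fisher_enrichment",
    "CONTEXT_CLASSES",
]

CONTEXT_CLASSES = ("exonic", "intronic", "promoter", "intergenic")


@dataclass
class AnnotationMap:
    """locus_id -> (gene or none, context class, GO term ids)."""

    table: pd.DataFrame  # columns: locus_id, gene, context, go_terms (list)

    def __post_init__(self) -> None:
        bad = set(self.table["context"]) - set(CONTEXT_CLASSES)
        if bad:
            raise ValueError(f"unknown context classes: {sorted(bad)}")

    def terms_of(self, locus_id: str) -> list[str]:
        row = self.table.loc[self.table["locus_id"] == locus_id]
        return list(row["go_terms"].iloc[0]) if len(row) else []


def _gene_features(gff_path: str):
    """(gene span, strand) and exon intervals per contig, via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, list] = {}
    exons: dict[str, list] = {}
    for g in db.features_of_type("gene"):
        genes.setdefault(g.seqid, []).append((g.start, g.end, g.strand, g.id))
    for e in db.features_of_type("exon"):
        exons.setdefault(e.seqid, []).append((e.start, e.end))
    return genes, exons


def classify_context(
    locus_ids, contigs, positions, gff_path: str, promoter_bp: int = 2000
) -> pd.DataFrame:
    """Classify each 1-based SNP position as exonic / intronic / promoter /
    intergenic.  Contigs absent from the GFF fall back to intergenic with a
    warning."""
    genes, exons = _gene_features(gff_path)
    gene_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    prom_trees: dict[str, IntervalTree] = {}
    for contig, feats in genes.items():
        gt, pt = IntervalTree(), IntervalTree()
        for start, end, strand, gid in feats:
            gt.addi(start - 1, end, gid)  # half-open 0-based
            if strand == "-":
                pt.addi(end, end + promoter_bp, gid)
            else:
                pt.addi(max(0, start - 1 - promoter_bp), start - 1, gid)
        gene_trees[contig] = gt
        prom_trees[contig] = pt
    for contig, feats in exons.items():
        et = IntervalTree()
        for start, end in feats:
            et.addi(start - 1, end)
        exon_trees[contig] = et

    warned: set[str] = set()
    rows = []
    for lid, contig, pos in zip(locus_ids, contigs, positions):
        pos0 = int(pos) - 1
        if contig not in gene_trees:
            if contig not in warned:
                logger.warning("classify_context: contig %r absent from GFF", contig)
                warned.add(contig)
            rows.append({"locus_id": lid, "gene": "none", "context": "intergenic"})
            continue
        gene_hits = gene_trees[contig][pos0]
        if gene_hits:
            gid = sorted(h.data for h in gene_hits)[0]
            in_exon = contig in exon_trees and bool(exon_trees[contig][pos0])
            context = "exonic" if in_exon else "intronic"
        else:
            prom_hits = prom_trees[contig][pos0]
            if prom_hits:
                gid = sorted(h.data for h in prom_hits)[0]
                context = "promoter"
            else:
                gid, context = "none", "intergenic"
        rows.append({"locus_id": lid, "gene": gid, "context": context})
    return pd.DataFrame(rows)


def load_go_map(path) -> dict[str, list[str]]:
    """Read a locus_id,gene,go_terms CSV (";"-separated term lists)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        terms = [t for t in str(row["go_terms"]).split(";") if t]
        for t in terms:
            if not (t.startswith("GO:") and t[3:].isdigit() and len(t) == 10):
                raise ValueError(f"invalid GO id {t!r} for locus {row['locus_id']}")
        out[row["locus_id"]] = terms
    return out


def fisher_enrichment(
    candidate_ids, background_ids, go_map: dict[str, list[str]], q: float = 0.05
) -> pd.DataFrame:
    """Per-term two-sided Fisher's exact test of candidates vs background.

    The 2x2 table per term is candidate/non-candidate x has-term/lacks-term
    over the background locus set; BH step-up flags at adjusted p <= q.
    """
    cand = set(candidate_ids)
    bg = list(dict.fromkeys(background_ids))
    if not cand <= set(bg):
        raise ValueError("candidates must be a subset of the background")
    terms: dict[str, set[str]] = {}
    for lid in bg:
        for t in go_map.get(lid, []):
            terms.setdefault(t, set()).add(lid)
    rows = []
    n_cand = len(cand)
    n_other = len(bg) - n_cand
    for term in sorted(terms):
        with_term = terms[term]
        a = len(with_term & cand)
        b = n_cand - a
        c = len(with_term) - a
        d = n_other - c
        if a + c == 0:
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "term": term,
                "cand_with": a,
                "cand_without": b,
                "bg_with": c,
                "bg_without": d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term", "cand_with", "cand_without", "bg_with", "bg_without", "odds_ratio", "p"],
    )
    if len(table):
        adjusted, flags = fdr_adjust(table["p"].to_numpy(), method="BH", q=q)
        table["p_adjusted"] = adjusted
        table["significant"] = flags
    else:
        table["p_adjusted"] = []
        table["significant"] = []
    return table
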