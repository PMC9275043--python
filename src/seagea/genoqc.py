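"""Genotype input and quality control.

Reads diploid biallelic SNP genotypes from VCF into a minor-allele dosage
matrix and applies the locus- and individual-level filters used throughout
the pipeline: per-locus missingness, minor allele count (MAC), and pruning
of duplicate / closely related individuals by a thresholded pairwise
relatedness screen.

Dosage convention: each genotype is the number of copies of the *globally
minor* allele (0, 1, 2), with missing genotypes stored as NaN.  The minor
allele is defined across all retained individuals and is re-evaluated after
individuals are removed, before MAC filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "RelatednessMatrix",
    "load_genotypes",
    "write_vcf",
    "filter_loci",
    "filter_individuals",
    "pairwise_relatedness",
    "prune_related",
    "minor_allele_counts",
]


@dataclass
class GenotypeMatrix:
    """Individuals x loci minor-allele dosages with locus metadata.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for
    missing genotypes.
    """

    dosage: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    contigs: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, L = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match dosage columns")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus_ids must be unique")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosage=self.dosage[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosage=self.dosage[:, idx],
            locus_ids=[self.locus_ids[i] for i in idx],
            contigs=self.contigs[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            dosage=self.dosage.copy(),
            sample_ids=list(self.sample_ids),
            locus_ids=list(self.locus_ids),
            contigs=self.contigs.copy(),
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            planted_pairs=list(self.planted_pairs),
        )


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise relatedness estimates; NaN where a pair had fewer
    overlapping genotyped loci than the configured floor."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relatedness matrix must be square")
        self.values = v


def _orient_to_minor(dosage: np.ndarray, ref: np.ndarray, alt: np.ndarray):
    """Flip loci so dosage counts the globally minor allele.

    A locus is flipped when the counted-allele frequency exceeds 0.5
    (strictly; ties are left as-is so the orientation is reproducible).
    """
    dosage = dosage.copy()
    ref = ref.copy()
    alt = alt.copy()
    with np.errstate(invalid="ignore"):
        n_obs = np.sum(~np.isnan(dosage), axis=0)
        tot = np.nansum(dosage, axis=0)
    freq = np.divide(tot, 2.0 * n_obs, out=np.zeros_like(tot), where=n_obs > 0)
    flip = freq > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]
    ref[flip], alt[flip] = alt[flip].copy(), ref[flip].copy()
    return dosage, ref, alt, int(flip.sum())


def load_genotypes(vcf_path: str) -> GenotypeMatrix:
    """Read a VCF into a minor-allele dosage :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (count logged).  Loci whose
    ALT allele is the major allele are flipped so dosage counts the minor
    allele.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths
        raise ValueError(f"cannot open VCF {vcf_path}: {exc}") from exc
    samples = list(vcf.samples)
    rows = []
    contigs, positions, refs, alts, ids = [], [], [], [], []
    n_skipped = 0
    for i, v in enumerate(vcf):
        try:
            if len(v.ALT) != 1 or not v.is_snp:
                n_skipped += 1
                continue
            gt = np.asarray(v.gt_types, dtype=float)
        except Exception as exc:
            raise ValueError(
                f"malformed VCF record #{i + 1} at "
                f"{getattr(v, 'CHROM', '?')}:{getattr(v, 'POS', '?')}: {exc}"
            ) from exc
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        contigs.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    if n_skipped:
        logger.info("load_genotypes: skipped %d multi-allelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {vcf_path}")
    dosage = np.vstack(rows).T  # individuals x loci
    ref = np.asarray(refs, dtype=object)
    alt = np.asarray(alts, dtype=object)
    dosage, ref, alt, n_flip = _orient_to_minor(dosage, ref, alt)
    if n_flip:
        logger.info("load_genotypes: flipped %d loci to minor-allele coding", n_flip)
    return GenotypeMatrix(
        dosage=dosage,
        sample_ids=samples,
        locus_ids=ids,
        contigs=np.asarray(contigs, dtype=object),
        positions=np.asarray(positions, dtype=int),
        ref=ref,
        alt=alt,
    )


_GT_STR = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a GT-only VCFv4.2 file (dosage = number of ALT copies)."""
    contig_order = list(dict.fromkeys(G.contigs.tolist()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=seagea\n")
        for c in contig_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        order = np.lexsort((G.positions, np.asarray([contig_order.index(c) for c in G.contigs])))
        for j in order:
            gts = [
                "./." if np.isnan(d) else _GT_STR[d] for d in G.dosage[:, j]
            ]
            fh.write(
                f"{G.contigs[j]}\t{G.positions[j]}\t{G.locus_ids[j]}\t"
                f"{G.ref[j]}\t{G.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def minor_allele_counts(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus MAC = min(counted-allele copies, other-allele copies),
    over non-missing genotypes.  Invariant under ref/alt relabeling."""
    n_obs = np.sum(~np.isnan(G.dosage), axis=0)
    tot = np.nansum(G.dosage, axis=0)
    return np.minimum(tot, 2.0 * n_obs - tot)


def filter_loci(
    G: GenotypeMatrix, max_locus_missing: float = 0.2, min_mac: int = 3
) -> GenotypeMatrix:
    """Keep loci with missing fraction <= ``max_locus_missing`` and minor
    allele count >= ``min_mac``; locus order preserved."""
    if not 0 <= max_locus_missing <= 1:
        raise ValueError("max_locus_missing must be in [0, 1]")
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")
    miss = np.mean(np.isnan(G.dosage), axis=0)
    mac = minor_allele_counts(G)
    keep = (miss <= max_locus_missing) & (mac >= min_mac)
    if not keep.any():
        raise ValueError("filter_loci removed every locus")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_loci: removed %d of %d loci", n_drop, G.n_loci)
    return G.take_loci(np.flatnonzero(keep))


def filter_individuals(G: GenotypeMatrix, max_indiv_missing: float = 0.5) -> GenotypeMatrix:
    """Generic per-individual missingness cap."""
    miss = np.mean(np.isnan(G.dosage), axis=1)
    keep = miss <= max_indiv_missing
    if not keep.any():
        raise ValueError("filter_individuals removed every individual")
    return G.take_individuals(np.flatnonzero(keep))


def pairwise_relatedness(
    G: GenotypeMatrix, min_overlap: int = 50, estimator: str = "grm"
) -> RelatednessMatrix:
    """Moment-based pairwise relatedness from sample allele frequencies.

    The default ``"grm"`` estimator is the genomic-relationship form
    r_xy = sum_l (x_l - 2 p_l)(y_l - 2 p_l) / sum_l 2 p_l (1 - p_l)
    over pairwise-complete loci, clipped to [-1, 1].  Expectations:
    duplicates ~1, parent-offspring ~0.5, unrelated ~0.  Pairs with fewer
    than ``min_overlap`` shared genotyped loci get NaN.
    """
    if estimator != "grm":
        raise ValueError(f"unknown relatedness estimator: {estimator!r}")
    X = G.dosage
    n, L = X.shape
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * n_obs)
    p = np.where(n_obs > 0, p, np.nan)
    denom_l = 2.0 * p * (1.0 - p)
    informative = np.nan_to_num(denom_l) > 0
    C = np.where(obs, X - 2.0 * p, 0.0)  # centered, 0 where missing
    C[:, ~informative] = 0.0
    O = obs.astype(float)
    O[:, ~informative] = 0.0
    num = C @ C.T
    den = O @ (O * denom_l).T  # sum of 2p(1-p) over pairwise-complete informative loci
    overlap = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        R = num / den
    R = np.clip(R, -1.0, 1.0)
    low = overlap < min_overlap
    if low.any():
        logger.info(
            "pairwise_relatedness: %d pairs below overlap floor %d",
            int(np.triu(low, 1).sum()),
            min_overlap,
        )
    R[low] = np.nan
    R = (R + R.T) / 2.0
    return RelatednessMatrix(values=R, sample_ids=list(G.sample_ids))


def prune_related(
    G: GenotypeMatrix, R: RelatednessMatrix, threshold: float = 0.5
) -> tuple[GenotypeMatrix, list[str]]:
    """Greedy pruning of related pairs at |R| >= ``threshold``.

    While any pair remains at or above the threshold, remove the individual
    involved in the most such pairs; ties broken by more missing data, then
    by lexicographically last sample id.  Returns the pruned matrix and the
    removed ids.
    """
    if R.sample_ids != G.sample_ids:
        raise ValueError("relatedness matrix not aligned to genotype matrix")
    A = np.abs(R.values.copy())
    np.fill_diagonal(A, 0.0)
    A = np.nan_to_num(A, nan=0.0)
    hot = A >= threshold
    miss = np.mean(np.isnan(G.dosage), axis=1)
    active = np.ones(G.n_individuals, dtype=bool)
    removed: list[int] = []
    while True:
        deg = (hot & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        top = deg == deg.max()
        cand = np.flatnonzero(top)
        cand = cand[miss[cand] == miss[cand].max()]
        ids = [G.sample_ids[i] for i in cand]
        pick = cand[int(np.argmax(ids))]
        active[pick] = False
        removed.append(pick)
    removed_ids = [G.sample_ids[i] for i in removed]
    if removed_ids:
        logger.info("prune_related: removed %d individuals: %s", len(removed_ids), removed_ids)
    return G.take_individuals(np.flatnonzero(active)), removed_ids
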