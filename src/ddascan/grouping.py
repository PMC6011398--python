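"""SNP-group construction: gene proximity assignment, pathway unions, LD pruning.

SNPs are assigned to a gene when they fall within a fixed window (default
50 kb) of its coding region; pathway groups are unions of their member
genes' SNP sets.  Groups smaller than a minimum SNP count (default 20 for
pathways) are dropped, and groups with identical SNP content can be
collapsed to a single record.  A greedy full-group LD pruning pass removes
SNPs whose squared allele-count correlation with a retained SNP exceeds a
cap (default r^2 = 0.9).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import GeneSetCollection, GeneTable, GenotypeData, SnpInfo, MISSING

logger = logging.getLogger("ddascan")


@dataclass
class SnpGroup:
    """A named, deduplicated set of SNP column indices."""

    name: str
    source: str  # {gene, pathway, custom}
    snp_indices: np.ndarray
    aliases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = np.asarray(self.snp_indices, dtype=np.int64)
        uniq = np.unique(idx)
        if uniq.size != idx.size:
            raise ValueError(f"group {self.name}: SNP indices must be unique")
        self.snp_indices = uniq  # sorted, unique
        if self.source not in ("gene", "pathway", "custom"):
            raise ValueError(f"group {self.name}: unknown source {self.source!r}")
        if uniq.size and uniq[0] < 0:
            raise ValueError(f"group {self.name}: negative SNP index")

    def __len__(self) -> int:
        return int(self.snp_indices.size)


def assign_snps_to_genes(
    snps: list[SnpInfo],
    genes: GeneTable,
    window_bp: int = 50_000,
) -> dict[str, set[int]]:
    """Map gene_id -> set of SNP indices within ``window_bp`` of the gene.

    A SNP at 0-based position ``p0 = pos - 1`` belongs to gene (start, end)
    iff ``max(start - window_bp, 0) <= p0 < end + window_bp`` on the same
    chromosome.  A SNP may belong to several genes; genes with no SNPs are
    absent from the mapping.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(snps):
        by_chrom.setdefault(s.chrom, []).append((s.pos - 1, i))
    for lst in by_chrom.values():
        lst.sort()
    mapping: dict[str, set[int]] = {}
    for gene in genes:
        positions = by_chrom.get(gene.chrom)
        if not positions:
            continue
        lo = max(gene.start - window_bp, 0)
        hi = gene.end + window_bp  # exclusive
        pos_arr = np.array([p for p, _ in positions])
        left = int(np.searchsorted(pos_arr, lo, side="left"))
        right = int(np.searchsorted(pos_arr, hi, side="left"))
        if right > left:
            mapping[gene.gene_id] = {positions[k][1] for k in range(left, right)}
    return mapping


def build_snp_groups(
    gene_map: dict[str, set[int]],
    gene_sets: Optional[GeneSetCollection] = None,
    min_snps: int = 1,
    dedupe: bool = True,
) -> list[SnpGroup]:
    """Build gene-mode or pathway-mode SNP groups.

    With ``gene_sets`` given, each group is the union of its member genes'
    SNP sets (pathway mode); otherwise one group per gene.  Groups below
    ``min_snps`` are dropped.  With ``dedupe``, groups sharing identical SNP
    content collapse to one record whose primary name is the
    lexicographically smallest and whose other names become aliases.
    """
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    raw: list[tuple[str, str, frozenset[int]]] = []
    if gene_sets is not None:
        for name, members in gene_sets.sets.items():
            known = [g for g in members if g in gene_map]
            if not known:
                logger.warning("gene set %r references no known genes; dropped", name)
                continue
            union: set[int] = set()
            for g in known:
                union |= gene_map[g]
            raw.append((name, "pathway", frozenset(union)))
    else:
        for gene_id, snp_set in gene_map.items():
            raw.append((gene_id, "gene", frozenset(snp_set)))

    raw = [(n, src, s) for n, src, s in raw if len(s) >= min_snps]

    if dedupe:
        by_content: dict[frozenset[int], list[tuple[str, str]]] = {}
        for name, src, content in raw:
            by_content.setdefault(content, []).append((name, src))
        groups = []
        for content, names in by_content.items():
            names.sort()
            primary, src = names[0]
            groups.append(
                SnpGroup(
                    name=primary,
                    source=src,
                    snp_indices=np.array(sorted(content)),
                    aliases=[n for n, _ in names[1:]],
                )
            )
    else:
        groups = [
            SnpGroup(name=n, source=src, snp_indices=np.array(sorted(content)))
            for n, src, content in raw
        ]
    groups.sort(key=lambda g: g.name)
    logger.info("built %d SNP groups (min_snps=%d, dedupe=%s)", len(groups), min_snps, dedupe)
    return groups


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of allele counts, missing pairs excluded."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune_group(G: GenotypeData, group: SnpGroup, r2_max: float = 0.9) -> SnpGroup:
    """Greedy LD pruning over the whole group in genomic position order.

    Monomorphic SNPs (zero variance among non-missing calls) are removed
    first.  Then each SNP, visited in (chrom, pos) order, is kept only if
    its r^2 with every already-retained SNP is <= ``r2_max``.  At least one
    SNP is always retained.  The full-group check means no retained pair
    exceeds the cap (stronger than windowed pruning).
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    idx = group.snp_indices
    polymorphic = []
    for i in idx:
        col = G.matrix[:, i]
        vals = col[col != MISSING]
        if vals.size and vals.std() > 0:
            polymorphic.append(int(i))
    if not polymorphic:
        # degenerate group: keep the first SNP so the group never empties
        polymorphic = [int(idx[0])]
    order = sorted(polymorphic, key=lambda i: (G.snps[i].chrom, G.snps[i].pos))
    retained: list[int] = []
    for i in order:
        if all(_pairwise_r2(G.matrix[:, i], G.matrix[:, j]) <= r2_max for j in retained):
            retained.append(i)
    pruned = SnpGroup(
        name=group.name,
        source=group.source,
        snp_indices=np.array(sorted(retained)),
        aliases=list(group.aliases),
    )
    if len(pruned) < len(group):
        logger.info(
            "LD pruning %s: %d -> %d SNPs (r2_max=%.2f)",
            group.name, len(group), len(pruned), r2_max,
        )
    return pruned


def write_group_manifest(groups: list[SnpGroup], G: GenotypeData, path: str | Path) -> None:
    """Write a TSV manifest: name, source, n_snps, SNP ids, aliases."""
    snp_ids = G.snp_ids()
    with open(path, "w") as fh:
        fh.write("name\tsource\tn_snps\tsnp_ids\taliases\n")
        for g in groups:
            ids = ",".join(snp_ids[i] for i in g.snp_indices)
            fh.write(f"{g.name}\t{g.source}\t{len(g)}\t{ids}\t{','.join(g.aliases)}\n")
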