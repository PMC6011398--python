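"""Genotype, phenotype and annotation file I/O.

Genotypes are held as an ``n_samples x n_snps`` integer matrix of
minor-allele counts in {0, 1, 2}, with :data:`MISSING` (-1) as the single
missing-data sentinel.  Supported on-disk formats are PLINK 1 binary
(BED/BIM/FAM, SNP-major) and a plain TSV dialect (header row
``sample_id<TAB>snp1<TAB>...``, one row per sample, numeric dosages, ``NA``
for missing).  Fractional TSV dosages are rounded half-away-from-zero and
clamped into [0, 2], mirroring the treatment of imputed dosages upstream.

Quantitative traits are dichotomized into case/control labels by a strict
threshold (e.g. blood glucose > 14.0 mmol/L defines diabetic cases in the
outbred-mouse design this package emulates).  Labels are coded 1 = case,
0 = control internally; the PLINK FAM 2/1 coding is translated on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("ddascan")

#: Sentinel for a missing genotype call, distinct from {0, 1, 2}.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1 binary, SNP-major


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending record."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpInfo:
    """Metadata for one biallelic SNP.

    ``pos`` is the 1-based physical position (BIM convention); ``alleles``
    is (A1, A2) with A1 the allele whose count the genotype stores (minor).
    """

    id: str
    chrom: str
    pos: int
    alleles: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValidationError(f"SNP {self.id}: position must be >= 1, got {self.pos}")


@dataclass
class GenotypeData:
    """Case-control genotype matrix with SNP metadata.

    ``matrix`` holds minor-allele counts, ``labels`` (optional) the binary
    phenotype (1 = case, 0 = control).
    """

    matrix: np.ndarray
    snps: list[SnpInfo]
    sample_ids: list[str]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValidationError("genotype matrix must be 2-dimensional")
        n, m = self.matrix.shape
        if len(self.snps) != m:
            raise ValidationError(f"{len(self.snps)} SnpInfo records for {m} matrix columns")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} matrix rows")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate SNP ids")
        valid = (self.matrix == MISSING) | ((self.matrix >= 0) & (self.matrix <= 2))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValidationError(
                f"genotype value {self.matrix[bad[0], bad[1]]} at sample {bad[0]}, "
                f"snp {bad[1]} outside {{0,1,2,missing}}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (n,):
                raise ValidationError("labels length must equal n_samples")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValidationError("labels must be 0 (control) or 1 (case)")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive


@dataclass
class GeneTable:
    """Gene coordinate table; 0-based half-open intervals as in BED."""

    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        if dupes:
            raise ValidationError(f"duplicate gene ids: {', '.join(dupes)}")
        for r in self.records:
            if r.start >= r.end:
                raise ValidationError(
                    f"gene {r.gene_id}: start ({r.start}) must be < end ({r.end})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, GeneRecord]:
        return {r.gene_id: r for r in self.records}


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways): mapping set name -> set of gene ids."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# Genotype readers / writers
# ---------------------------------------------------------------------------

def _round_dosage(value: float, where: str) -> int:
    # half-away-from-zero, clamped into [0,2]; >2 edge noise tolerated up to 3
    if not np.isfinite(value) or value < 0 or value >= 3:
        raise ValidationError(f"{where}: dosage {value} outside valid range [0, 3)")
    g = int(np.floor(value + 0.5))
    return min(g, 2)


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeData:
    """Read a genotype matrix from ``plink-bed`` or ``tsv`` format.

    For ``plink-bed``, ``path`` is the ``.bed`` file or the trio prefix; the
    BIM/FAM companions must sit alongside.  FAM phenotypes 2/1 are mapped to
    case/control 1/0 (0 or -9 leaves labels absent for that dataset if any
    sample is missing a phenotype).
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "plink-bed":
        return _read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_tsv(path: Path) -> GenotypeData:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[0] != "sample_id":
            raise ParseError(f"{path}: header must start with 'sample_id', got {cols[0]!r}")
        snp_ids = cols[1:]
        if not snp_ids:
            raise ParseError(f"{path}: no SNP columns in header")
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            sample_ids.append(fields[0])
            row = []
            for snp_id, tok in zip(snp_ids, fields[1:]):
                if tok == "NA":
                    row.append(MISSING)
                    continue
                try:
                    val = float(tok)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric dosage {tok!r} for {snp_id}")
                row.append(_round_dosage(val, f"{path}:{lineno} snp {snp_id}"))
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    # positions are synthetic for the TSV dialect (it carries no coordinates)
    snps = [SnpInfo(id=s, chrom="0", pos=i + 1) for i, s in enumerate(snp_ids)]
    return GenotypeData(np.array(rows, dtype=np.int8), snps, sample_ids)


def write_genotypes_tsv(G: GenotypeData, path: str | Path) -> None:
    """Write the TSV genotype dialect (integers, 'NA' for missing)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(G.snp_ids()) + "\n")
        for i, sid in enumerate(G.sample_ids):
            toks = ["NA" if g == MISSING else str(int(g)) for g in G.matrix[i]]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")


def _plink_prefix(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".bed" else path


def _read_plink(path: Path) -> GenotypeData:
    prefix = _plink_prefix(path)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)

    snps: list[SnpInfo] = []
    with open(bim) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(f"{bim}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom, snp_id, _cm, pos, a1, a2 = fields
            snps.append(SnpInfo(id=snp_id, chrom=chrom, pos=int(pos), alleles=(a1, a2)))

    sample_ids: list[str] = []
    phenos: list[int] = []
    with open(fam) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(f"{fam}:{lineno}: expected 6 columns, got {len(fields)}")
            sample_ids.append(fields[1])
            phenos.append(int(float(fields[5])))

    n, m = len(sample_ids), len(snps)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ParseError(f"{bed}: not a SNP-major PLINK 1 BED file (bad magic)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ParseError(
            f"{bed}: expected {bytes_per_snp * m} data bytes for {n} samples x {m} SNPs, "
            f"got {body.size}"
        )
    # unpack 2-bit codes, little-endian within each byte
    codes = body.reshape(m, bytes_per_snp)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    expanded = (codes[:, :, None] >> shifts[None, None, :]) & 0b11  # (m, bps, 4)
    expanded = expanded.reshape(m, bytes_per_snp * 4)[:, :n]
    # 2-bit code -> A1 (minor) allele count: 00->2, 10->1, 11->0, 01->missing
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    matrix = lut[expanded].T.copy()  # (n, m)

    labels: Optional[np.ndarray] = None
    ph = np.array(phenos)
    if np.isin(ph, (1, 2)).all():
        labels = (ph == 2).astype(np.int8)
    return GenotypeData(matrix, snps, sample_ids, labels)


def write_plink(G: GenotypeData, prefix: str | Path) -> None:
    """Write a PLINK 1 BED/BIM/FAM trio (SNP-major; A1 = counted allele)."""
    prefix = Path(prefix)
    n, m = G.matrix.shape
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in G.snps:
            fh.write(f"{s.chrom}\t{s.id}\t0\t{s.pos}\t{s.alleles[0]}\t{s.alleles[1]}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            if G.labels is None:
                pheno = -9
            else:
                pheno = 2 if G.labels[i] == 1 else 1
            fh.write(f"F{i} {sid} 0 0 0 {pheno}\n")
    # genotype count -> 2-bit code: 2->00, 1->10, 0->11, missing->01
    lut = np.zeros(4, dtype=np.uint8)
    lut[2], lut[1], lut[0] = 0b00, 0b10, 0b11
    codes = np.where(G.matrix == MISSING, 0b01, lut[np.clip(G.matrix, 0, 2)]).astype(np.uint8)
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Annotation readers
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> GeneTable:
    """Read gene coordinates from a BED3+ file (chrom, start, end, name)."""
    path = Path(path)
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: need >= 4 BED columns, got {len(fields)}")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: gene {name}: start ({start}) must be < end ({end})"
                )
            records.append(GeneRecord(gene_id=name, chrom=chrom, start=start, end=end))
    return GeneTable(records)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in table:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\n")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, member genes)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = {g for g in genes if g}
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write(name + "\t" + desc + "\t" + "\t".join(sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# Trait dichotomization
# ---------------------------------------------------------------------------

def dichotomize_trait(
    values: Sequence[float] | np.ndarray,
    threshold: float,
    direction: str = "greater",
) -> np.ndarray:
    """Turn a quantitative trait into binary case/control labels.

    A sample is a case iff its value is *strictly* beyond ``threshold`` in
    the stated direction (``greater`` or ``less``); e.g. blood glucose
    strictly above 14.0 mmol/L.  Raises if either class would be empty,
    since association is undefined on a single class.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("trait values must be finite")
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if direction == "greater":
        labels = (values > threshold).astype(np.int8)
    elif direction == "less":
        labels = (values < threshold).astype(np.int8)
    else:
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    n_case = int(labels.sum())
    n_ctrl = int(labels.size - n_case)
    if n_case == 0 or n_ctrl == 0:
        raise ValidationError(
            f"dichotomization produced a single class ({n_case} cases, {n_ctrl} controls)"
        )
    logger.info("dichotomize_trait: %d cases, %d controls", n_case, n_ctrl)
    return labels
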