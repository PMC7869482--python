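"""Gene-level mutation counting from per-sample VCF files.

Treats each patient as a "document" and each gene as a "term": variants from a
sample's VCF are assigned to genes by positional containment, yielding a
sample x gene count matrix whose row sums (document lengths) feed the BM25
term-frequency weighting downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_gene_version(gene_id: str) -> str:
    """Drop an Ensembl-style trailing version suffix (``ENSG...{.N}``)."""
    return _VERSION_SUFFIX.sub("", gene_id)


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome dialects by stripping a leading ``chr``."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in 1-based inclusive coordinates (VCF POS convention)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


def _check_unique_gene_ids(genes: list[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id in gene model: {g.gene_id}")
        seen.add(g.gene_id)


def read_gene_model(path: str | Path) -> list[GeneModel]:
    """Read a gene annotation from BED (0-based half-open) or GFF3/GTF
    (1-based inclusive), converting to the internal 1-based inclusive
    convention and stripping gene-ID version suffixes.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        genes = _read_bed(path)
    elif suffix in {".gff", ".gff3", ".gtf"}:
        genes = _read_gff(path, gtf=suffix == ".gtf")
    else:
        raise ValueError(f"unrecognized gene-model format: {path.name}")
    _check_unique_gene_ids(genes)
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(
                    f"{path.name}:{lineno}: BED gene line needs >= 4 fields"
                )
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: non-integer BED coordinates"
                ) from exc
            genes.append(
                GeneModel(
                    gene_id=strip_gene_version(fields[3]),
                    chrom=normalize_chrom(fields[0]),
                    start=start0 + 1,  # 0-based half-open -> 1-based inclusive
                    end=end0,
                )
            )
    return genes


_GFF3_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_GFF3_NAME = re.compile(r"(?:^|;)\s*Name=([^;]+)")
_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')
_GTF_GENE_NAME = re.compile(r'gene_name\s+"([^"]+)"')


def _read_gff(path: Path, gtf: bool) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path.name}:{lineno}: GFF/GTF line has {len(fields)} fields"
                )
            if fields[2] != "gene":
                continue
            attrs = fields[8]
            if gtf:
                m, mname = _GTF_GENE_ID.search(attrs), _GTF_GENE_NAME.search(attrs)
            else:
                m, mname = _GFF3_ID.search(attrs), _GFF3_NAME.search(attrs)
            if m is None:
                raise ValueError(
                    f"{path.name}:{lineno}: gene line without a gene identifier"
                )
            gene_id = m.group(1)
            if gene_id.startswith("gene:"):
                gene_id = gene_id[5:]
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            genes.append(
                GeneModel(
                    gene_id=strip_gene_version(gene_id),
                    chrom=normalize_chrom(fields[0]),
                    start=start,
                    end=end,
                    symbol=mname.group(1) if mname else None,
                )
            )
    return genes


def write_gene_model_bed(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# Mutation count matrix
# ---------------------------------------------------------------------------


@dataclass
class MutationCountMatrix:
    """Sample x gene nonnegative integer mutation counts.

    ``doc_lengths`` (per-sample total counts, the BM25 document length dl) and
    ``avg_doc_length`` (avgdl) are recomputed from ``counts`` on construction,
    so the row-sum invariant holds by definition.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray
    doc_lengths: np.ndarray = field(init=False)
    avg_doc_length: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.array_equal(self.counts, np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        self.doc_lengths = self.counts.sum(axis=1)
        self.avg_doc_length = float(self.doc_lengths.mean()) if len(
            self.sample_ids
        ) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.gene_ids
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_count_table(path: str | Path) -> MutationCountMatrix:
    """Read a precomputed sample x gene count TSV (samples as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{Path(path).name}: no samples")
    values = df.to_numpy()
    bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{Path(path).name}: cell at sample {df.index[i]!r}, "
            f"gene {df.columns[j]!r} is not a nonnegative integer"
        )
    return MutationCountMatrix(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[strip_gene_version(str(g)) for g in df.columns],
        counts=values.astype(np.int64),
    )


def count_mutations(
    vcf_paths: list[str | Path],
    gene_model: list[GeneModel],
    mode: str = "per_variant",
    pass_only: bool = False,
) -> MutationCountMatrix:
    """Assemble a mutation-count matrix from one VCF per sample.

    A record is assigned to every gene whose 1-based inclusive interval
    contains its POS; records outside all genes are dropped (and summarized in
    the log). ``mode='per_gene_binary'`` collapses counts to presence
    indicators; ``pass_only`` keeps only FILTER=PASS records.
    """
    from cyvcf2 import VCF

    if mode not in {"per_variant", "per_gene_binary"}:
        raise ValueError(f"unknown counting mode: {mode}")
    _check_unique_gene_ids(gene_model)
    gene_ids = [g.gene_id for g in gene_model]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    trees: dict[str, IntervalTree] = {}
    for g in gene_model:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start, g.end + 1, g.gene_id
        )

    sample_ids, rows = [], []
    n_dropped = n_multi = 0
    for vcf_path in vcf_paths:
        vcf_path = Path(vcf_path)
        if not vcf_path.exists():
            raise FileNotFoundError(f"VCF not found: {vcf_path}")
        sample_id = vcf_path.name
        for ext in (".gz", ".vcf", ".bcf"):
            if sample_id.endswith(ext):
                sample_id = sample_id[: -len(ext)]
        row = np.zeros(len(gene_ids), dtype=np.int64)
        for rec in VCF(str(vcf_path)):
            if pass_only and rec.FILTER is not None:  # cyvcf2: None == PASS
                continue
            tree = trees.get(normalize_chrom(rec.CHROM))
            hits = tree[rec.POS] if tree is not None else set()
            if not hits:
                n_dropped += 1
                continue
            if len(hits) > 1:
                n_multi += 1
            for iv in hits:
                row[gene_index[iv.data]] += 1
        sample_ids.append(sample_id)
        rows.append(row)

    counts = np.vstack(rows) if rows else np.zeros((0, len(gene_ids)), dtype=np.int64)
    if mode == "per_gene_binary":
        counts = (counts > 0).astype(np.int64)
    if n_dropped or n_multi:
        logger.info(
            "count_mutations: %d records outside all genes dropped, "
            "%d records assigned to multiple overlapping genes",
            n_dropped,
            n_multi,
        )
    return MutationCountMatrix(sample_ids=sample_ids, gene_ids=gene_ids, counts=counts)
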