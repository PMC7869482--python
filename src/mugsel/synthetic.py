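"""Synthetic paired mutation/expression cohorts with planted class genes.

Emulates the study's cohort structure — several cancer-type classes over one
shared gene universe, with both a per-sample VCF-derived mutation profile and
an FPKM-style expression profile — so the whole pipeline is exercisable
without external data. Each class has a disjoint set of planted genes that are
both preferentially mutated (elevated Poisson rate) and differentially
expressed (multiplicative FPKM shift) in that class, mirroring the premise
that mutation information transfers to expression data.

A *null* cohort (equal mutation rates, expression effect 1) is explicitly
constructible; it should make planted genes unrecoverable and is used as a
leakage guard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .expression_io import ExpressionMatrix
from .vcf_gene_counts import GeneModel, MutationCountMatrix

DEFAULT_CLASSES = ("breast", "lung", "kidney")


@dataclass
class CohortSpec:
    """Generator configuration.

    Defaults: 3 classes x 50 samples over 2,000 genes with 30 planted genes
    per class; background per-gene mutation rate 0.1 (Poisson mean count) vs
    0.5 for planted genes in their own class (rate ratio 5); log-normal
    expression baseline exp(N(2, 1)) with multiplicative effect 2 for planted
    genes in-class and log-scale noise SD 0.5.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {c: 50 for c in DEFAULT_CLASSES}
    )
    n_genes: int = 2000
    n_informative_per_class: int = 30
    background_mutation_rate: float = 0.1
    informative_mutation_rate: float = 0.5
    expression_baseline_loc: float = 2.0
    expression_baseline_scale: float = 1.0
    expression_effect: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_class:
            raise ValueError("n_per_class is empty")
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("each class needs >= 1 sample")
        if self.informative_mutation_rate < self.background_mutation_rate:
            raise ValueError(
                "informative_mutation_rate must be >= background_mutation_rate"
            )
        if self.background_mutation_rate < 0:
            raise ValueError("background_mutation_rate must be nonnegative")
        if self.expression_effect <= 0:
            raise ValueError("expression_effect must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        n_planted = self.n_informative_per_class * len(self.n_per_class)
        if n_planted > self.n_genes:
            raise ValueError(
                f"{n_planted} planted genes exceed the {self.n_genes}-gene universe"
            )


@dataclass
class GroundTruth:
    planted: dict[str, set[str]]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        sets = list(self.planted.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("planted gene sets must be pairwise disjoint")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "planted": {c: sorted(g) for c, g in self.planted.items()},
            "labels": self.labels,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def generate(
    spec: CohortSpec,
) -> tuple[MutationCountMatrix, ExpressionMatrix, GroundTruth]:
    """Sample a paired cohort; fully reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    gene_ids = [f"ENSG{j:011d}" for j in range(1, spec.n_genes + 1)]
    classes = list(spec.n_per_class)
    sample_ids, labels = [], {}
    for cls in classes:
        for i in range(spec.n_per_class[cls]):
            sid = f"{cls}_{i:03d}"
            sample_ids.append(sid)
            labels[sid] = cls

    # disjoint planted gene sets, drawn once from a seeded permutation
    perm = rng.permutation(spec.n_genes)
    planted: dict[str, set[str]] = {}
    planted_cols: dict[str, np.ndarray] = {}
    offset = 0
    for cls in classes:
        cols = perm[offset : offset + spec.n_informative_per_class]
        planted[cls] = {gene_ids[j] for j in cols}
        planted_cols[cls] = cols
        offset += spec.n_informative_per_class

    n = len(sample_ids)
    rates = np.full((n, spec.n_genes), spec.background_mutation_rate)
    class_rows = {
        cls: np.array([labels[s] == cls for s in sample_ids]) for cls in classes
    }
    for cls in classes:
        rates[np.ix_(class_rows[cls], planted_cols[cls])] = (
            spec.informative_mutation_rate
        )
    counts = rng.poisson(rates)

    mu = rng.normal(spec.expression_baseline_loc, spec.expression_baseline_scale,
                    size=spec.n_genes)
    log_expr = mu[None, :] + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes))
    effect = np.zeros((n, spec.n_genes))
    for cls in classes:
        effect[np.ix_(class_rows[cls], planted_cols[cls])] = np.log(
            spec.expression_effect
        )
    values = np.exp(log_expr + effect)

    return (
        MutationCountMatrix(sample_ids=sample_ids, gene_ids=gene_ids, counts=counts),
        ExpressionMatrix(sample_ids=sample_ids, gene_ids=gene_ids, values=values),
        GroundTruth(planted=planted, labels=labels),
    )


# ---------------------------------------------------------------------------
# VCF round-trip fixtures
# ---------------------------------------------------------------------------


def synthetic_gene_model(
    gene_ids: list[str], interval_length: int = 1000, gap: int = 1000,
    chrom: str = "1",
) -> list[GeneModel]:
    """Non-overlapping, evenly spaced gene intervals on one chromosome."""
    genes = []
    pos = 1
    for gid in gene_ids:
        genes.append(
            GeneModel(gene_id=gid, chrom=chrom, start=pos, end=pos + interval_length - 1)
        )
        pos += interval_length + gap
    return genes


def write_vcfs(
    counts: MutationCountMatrix,
    gene_model: list[GeneModel],
    out_dir: str | Path,
) -> list[Path]:
    """Write one minimal sites-only VCFv4.2 per sample, with counts[i][g]
    records at distinct positions inside gene g's interval, so that
    ``count_mutations`` on the output reproduces ``counts`` exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = {g.gene_id: g for g in gene_model}
    missing = [g for g in counts.gene_ids if g not in model]
    if missing:
        raise ValueError(f"genes absent from the gene model: {missing[:5]}")
    max_count = counts.counts.max(axis=0) if len(counts.sample_ids) else None
    for j, gid in enumerate(counts.gene_ids):
        g = model[gid]
        if max_count is not None and g.end - g.start + 1 < max_count[j]:
            raise ValueError(
                f"gene {gid} interval too short for its count {max_count[j]}"
            )
    contigs = sorted({model[g].chrom for g in counts.gene_ids})
    paths = []
    for i, sid in enumerate(counts.sample_ids):
        path = out_dir / f"{sid}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##source=mugsel-synthetic\n')
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            records = []
            for j, gid in enumerate(counts.gene_ids):
                g = model[gid]
                for r in range(int(counts.counts[i, j])):
                    records.append((g.chrom, g.start + r))
            for chrom, pos in sorted(records):
                fh.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\n")
        paths.append(path)
    return paths


def write_cohort(spec: CohortSpec, out_dir: str | Path,
                 with_vcfs: bool = True) -> dict[str, Path]:
    """Generate a cohort and write all artifacts (count/expression/label TSVs,
    ground-truth JSON, gene-model BED, optional per-sample VCFs)."""
    from .vcf_gene_counts import write_gene_model_bed

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts, expression, truth = generate(spec)
    artifacts: dict[str, Path] = {}

    artifacts["counts"] = out_dir / "mutation_counts.tsv"
    counts.write_tsv(artifacts["counts"])
    artifacts["expression"] = out_dir / "expression.tsv"
    expression.write_tsv(artifacts["expression"])
    artifacts["labels"] = out_dir / "labels.tsv"
    with open(artifacts["labels"], "w") as fh:
        fh.write("sample_id\tlabel\n")
        for s in counts.sample_ids:
            fh.write(f"{s}\t{truth.labels[s]}\n")
    artifacts["ground_truth"] = out_dir / "ground_truth.json"
    truth.write_json(artifacts["ground_truth"])

    model = synthetic_gene_model(counts.gene_ids)
    artifacts["gene_model"] = out_dir / "genes.bed"
    write_gene_model_bed(model, artifacts["gene_model"])
    if with_vcfs:
        vcf_dir = out_dir / "vcfs"
        write_vcfs(counts, model, vcf_dir)
        artifacts["vcf_dir"] = vcf_dir
    return artifacts


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            sid, lab = line.rstrip("\n").split("\t")[:2]
            labels[sid] = lab
    return labels
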