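"""Synthetic genomes with planted motif -> expression-class structure.

The generator emits the same three files the real pipeline consumes — a
genome FASTA, a gene GFF3 and a ``gene_id<TAB>maxTPM`` table — plus a truth
table.  Background sequence is i.i.d. uniform over {A,C,G,T}; each
chromosome's genes are assigned (low, medium, high) classes whose counts
match the class priors exactly, in random order; a class-specific 8-mer
is planted ``motifs_per_gene`` times at uniform non-overlapping positions in
the biological TSS-upstream kilobase (reverse-complemented on the reference
for minus-strand genes), and maxTPM is drawn so that log2(maxTPM+1) is
normal with a class-ordered location — disjoint across classes at the
default spread, so quantile labelling recovers the planted class.  With
``label_noise`` > 0 a gene's TPM is drawn from a wrong class's distribution
with that probability (recorded in the truth table).

Determinism: the same :class:`~mtmixg.config.SimConfig` (including seed)
yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .genome_io import CLASSES, GeneRecord, reverse_complement
from .predictor import MetricReport, compute_metrics

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulatedData:
    """In-memory view of one simulated cohort."""

    genome: Dict[str, str]
    genes: List[GeneRecord]
    expression: pd.DataFrame      # gene_id, maxTPM
    truth: pd.DataFrame           # gene_id, true_class, n_motifs, ...


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _plant(seq: np.ndarray, start: int, motif: str) -> None:
    seq[start:start + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def _upstream_offsets(rng: np.random.Generator, n: int, span: int,
                      mlen: int) -> List[int]:
    """n non-overlapping motif start offsets within [0, span - mlen]."""
    if n * mlen > span:
        raise ValueError("cannot plant motifs without overlap: window too small")
    offsets: List[int] = []
    for _ in range(n):
        for _attempt in range(1000):
            cand = int(rng.integers(0, span - mlen + 1))
            if all(abs(cand - o) >= mlen for o in offsets):
                offsets.append(cand)
                break
        else:  # pragma: no cover - essentially impossible at default density
            raise RuntimeError("failed to place non-overlapping motifs")
    return offsets


def _stratified_classes(n: int, priors) -> np.ndarray:
    """Class indices with counts matching the priors exactly (largest
    remainder for any rounding slack); the caller shuffles the order.

    Exact per-chromosome counts keep the cohort's class fractions at the
    priors, so the empirical logMaxTPM quantile cuts fall inside the gaps
    between the class-conditional TPM distributions and quantile labelling
    reproduces the planted classes.
    """
    raw = np.asarray(priors) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return np.repeat(np.arange(3), counts)


def simulate(config: SimConfig) -> SimulatedData:
    """Generate a cohort under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    fl = config.flank
    mlen = len(config.motifs[0])
    margin = max(fl.tss_up, fl.tss_down, fl.tts_up, fl.tts_down)
    min_len, max_len = config.gene_length_range
    if config.gene_spacing < 0:
        raise ValueError("gene_spacing must be non-negative (window collision)")
    slot = margin + max_len + margin + config.gene_spacing

    genome: Dict[str, str] = {}
    genes: List[GeneRecord] = []
    rows = []
    class_values = np.asarray(CLASSES)

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_genes = config.genes_per_chromosome
        length = slot * n_genes + margin
        seq = _random_sequence(rng, length)
        classes = rng.permutation(_stratified_classes(n_genes,
                                                      config.class_priors))
        for gi in range(n_genes):
            gene_id = f"g{ci + 1:02d}_{gi + 1:04d}"
            a = slot * gi + margin
            glen = int(rng.integers(min_len, max_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss, tts = a, a + glen - 1
            else:
                tss, tts = a + glen - 1, a
            k = int(classes[gi])
            motif = config.motifs[k]
            offsets = _upstream_offsets(rng, config.motifs_per_gene,
                                        fl.tss_up, mlen) if fl.tss_up else []
            for u in offsets:
                if strand == "+":
                    _plant(seq, tss - fl.tss_up + u, motif)
                else:
                    _plant(seq, tss + fl.tss_up + 1 - u - mlen,
                           reverse_complement(motif))
            # class-conditional expression, optionally noise-flipped
            flipped = bool(rng.random() < config.label_noise)
            k_draw = k
            if flipped:
                k_draw = int(rng.choice([j for j in range(3) if j != k]))
            log2tpm = rng.normal(config.tpm_log2_locations[k_draw],
                                 config.tpm_sigma)
            max_tpm = float(2.0 ** log2tpm)  # log-normal, strictly positive
            true_class = int(class_values[k])
            genes.append(GeneRecord(gene_id, chrom, strand, tss, tts,
                                    label=true_class))
            rows.append({
                "gene_id": gene_id, "chromosome": chrom, "strand": strand,
                "true_class": true_class, "n_motifs": len(offsets),
                "motif_offsets": ",".join(str(u) for u in sorted(offsets)),
                "noise_flag": int(flipped), "maxTPM": max_tpm,
            })
        genome[chrom] = seq.tobytes().decode("ascii")

    truth = pd.DataFrame(rows)
    expression = truth[["gene_id", "maxTPM"]].copy()
    return SimulatedData(genome=genome, genes=genes,
                         expression=expression, truth=truth)


def simulate_dataset(config: SimConfig, out_dir) -> Tuple[Path, Path, Path, Path]:
    """Simulate and write genome.fa, genes.gff3, expression.tsv, truth.tsv."""
    data = simulate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fa"
    gff = out / "genes.gff3"
    tpm = out / "expression.tsv"
    truth = out / "truth.tsv"
    write_fasta(fasta, data.genome)
    write_gff3(gff, data.genes)
    data.expression.to_csv(tpm, sep="\t", index=False, float_format="%.6f")
    data.truth.to_csv(truth, sep="\t", index=False, float_format="%.6f")
    return fasta, gff, tpm, truth


def write_fasta(path, genome: Dict[str, str]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")


def write_gff3(path, genes: List[GeneRecord]) -> None:
    """1-based inclusive gene rows with ID attributes (GFF3 pragma first)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start0, end0 = min(g.tss, g.tts), max(g.tss, g.tts)
            fh.write("\t".join([
                g.chromosome, "mtmixg_sim", "gene",
                str(start0 + 1), str(end0 + 1), ".", g.strand, ".",
                f"ID={g.gene_id}",
            ]) + "\n")


def truth_report(truth_path, predictions_path) -> MetricReport:
    """Score a prediction table against the planted classes."""
    from .predictor import read_predictions

    truth = pd.read_csv(truth_path, sep="\t")
    preds = read_predictions(predictions_path)
    missing = set(preds["gene_id"]) ^ set(truth["gene_id"])
    if missing:
        raise ValueError(f"gene-id mismatch between truth and predictions "
                         f"({len(missing)} ids differ)")
    merged = preds.merge(truth[["gene_id", "true_class"]], on="gene_id")
    probs = merged[["p_low", "p_med", "p_high"]].to_numpy()
    return compute_metrics(merged["predicted_label"].to_numpy(),
                           merged["true_class"].to_numpy(), probs)
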