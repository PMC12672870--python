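"""Genome, annotation and expression I/O plus dataset construction.

The model consumes, per gene, a fixed-length window of flanking DNA around
the transcription start site (TSS) and the transcription termination site
(TTS), one-hot encoded, together with a three-way expression class derived
from the empirical quantiles of log-transformed maxTPM.  This module reads
the three standard input files (genome FASTA, gene GFF3, expression TSV),
builds strand-aware windows, assigns labels and groups genes into
chromosome-matched cross-validation folds.

Coordinate conventions: everything is 0-based half-open internally; GFF3
(1-based inclusive) is converted at the boundary.  For a minus-strand gene
the TSS is the *end* coordinate on the reference and windows are extracted
on the reverse complement so that "upstream"/"downstream" are biological.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .config import FlankSpec

logger = logging.getLogger(__name__)

#: the three expression classes, in one-hot column order
CLASSES = (-1, 0, 1)
LABEL_TO_INDEX = {-1: 0, 0: 1, 1: 2}

#: one-hot column order of the four nucleotides
NUCLEOTIDE_ORDER = "ATCG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")
_IUPAC_TO_N = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVU"}
)

GenomeAssembly = Dict[str, str]


@dataclass
class GeneRecord:
    """One gene: anchors on the reference plus (optionally) its class label.

    ``tss``/``tts`` are 0-based reference positions; for a plus-strand gene
    tss <= tts, for a minus-strand gene tss >= tts.
    """

    gene_id: str
    chromosome: str
    strand: str
    tss: int
    tts: int
    label: Optional[int] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: tss > tts on '+' strand")
        if self.strand == "-" and self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: tss < tts on '-' strand")


@dataclass
class FoldPlan:
    """Chromosome-matched partition: all genes of a chromosome share a fold."""

    k: int
    assignment: Dict[str, int]
    chromosome_fold: Dict[str, int] = field(default_factory=dict)

    def test_genes(self, fold: int) -> List[str]:
        return [g for g, f in self.assignment.items() if f == fold]


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> GenomeAssembly:
    """Read a (possibly multi-line) FASTA into a name -> sequence map.

    Sequences are uppercased and any IUPAC ambiguity code outside {A,C,G,T}
    is mapped to N.  Duplicate or empty records raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: GenomeAssembly = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name:
            raise ValueError("FASTA record with empty name")
        if name in genome:
            raise ValueError(f"duplicate FASTA record {name!r}")
        seq = str(rec.seq).upper().translate(_IUPAC_TO_N)
        if not seq:
            raise ValueError(f"FASTA record {name!r} is empty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"record {name!r} has invalid characters {sorted(bad)}")
        genome[name] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def read_annotations(path, feature_type: str = "gene") -> List[GeneRecord]:
    """Read gene records from a GFF3 file (via gffutils).

    GFF3 coordinates (1-based inclusive) are converted to 0-based anchors:
    plus strand tss = start-1, tts = end-1; minus strand tss = end-1,
    tts = start-1.  Rows with strand '.' are skipped with a logged warning;
    any other strand value, or a missing ID attribute, is an error.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    records: List[GeneRecord] = []
    for feat in db.features_of_type(feature_type):
        ids = feat.attributes.get("ID")
        if not ids:
            raise ValueError(
                f"{feature_type} row at {feat.seqid}:{feat.start} lacks an ID attribute")
        gene_id = ids[0]
        if feat.strand == ".":
            logger.warning("skipping %s: strand '.' (unstranded)", gene_id)
            continue
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{gene_id}: invalid strand {feat.strand!r}")
        start0, end0 = feat.start - 1, feat.end - 1
        if feat.strand == "+":
            tss, tts = start0, end0
        else:
            tss, tts = end0, start0
        records.append(GeneRecord(gene_id, feat.seqid, feat.strand, tss, tts))
    return records


def read_expression(path, log_fn: Optional[Callable] = None) -> pd.DataFrame:
    """Read a ``gene_id<TAB>maxTPM`` table; adds the logMaxTPM column."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "maxTPM"}.issubset(df.columns):
        raise ValueError("expression table needs columns gene_id and maxTPM")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in expression table")
    if (df["maxTPM"] < 0).any():
        raise ValueError("maxTPM must be non-negative")
    log_fn = log_fn or default_log_transform
    df = df.copy()
    df["logMaxTPM"] = log_fn(df["maxTPM"].to_numpy(dtype=float))
    return df


def default_log_transform(tpm: np.ndarray) -> np.ndarray:
    """log2(maxTPM + 1): the pseudocount keeps zero-TPM genes finite."""
    return np.log2(np.asarray(tpm, dtype=float) + 1.0)


# ---------------------------------------------------------------------------
# windows and encoding


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _padded_slice(seq: str, start: int, end: int) -> str:
    """seq[start:end) with positions outside [0, len) filled with N."""
    if end < start:
        raise ValueError(f"negative-length window [{start}, {end})")
    n = len(seq)
    left = "N" * max(0, -start)
    right = "N" * max(0, end - n)
    return left + seq[max(0, start):min(n, end)] + right


def extract_gene_window(gene: GeneRecord, genome: Mapping[str, str],
                        spec: FlankSpec) -> str:
    """TSS flank ++ TTS flank in biological orientation, length spec.total.

    The two flanks are extracted independently (they may overlap for short
    genes).  For a minus-strand gene each flank equals the plus-strand flank
    taken on the reverse-complemented chromosome at the mirrored anchor,
    which reduces to reverse-complementing a mirrored reference slice.
    """
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} not in assembly")
    seq = genome[gene.chromosome]
    if gene.strand == "+":
        tss_win = _padded_slice(seq, gene.tss - spec.tss_up, gene.tss + spec.tss_down)
        tts_win = _padded_slice(seq, gene.tts - spec.tts_up, gene.tts + spec.tts_down)
    else:
        tss_win = reverse_complement(
            _padded_slice(seq, gene.tss - spec.tss_down + 1, gene.tss + spec.tss_up + 1))
        tts_win = reverse_complement(
            _padded_slice(seq, gene.tts - spec.tts_down + 1, gene.tts + spec.tts_up + 1))
    window = tss_win + tts_win
    assert len(window) == spec.total_length
    return window


_ONEHOT_LUT = np.zeros((256, 4), dtype=np.uint8)
for _i, _c in enumerate(NUCLEOTIDE_ORDER):
    _ONEHOT_LUT[ord(_c), _i] = 1
_KNOWN = np.zeros(256, dtype=bool)
for _c in NUCLEOTIDE_ORDER + "N":
    _KNOWN[ord(_c)] = True


def one_hot(seq: str) -> np.ndarray:
    """L x 4 one-hot matrix with column order (A, T, C, G); N rows are zero."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bad = ~_KNOWN[codes]
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(f"invalid character {seq[pos]!r} at position {pos}")
    return _ONEHOT_LUT[codes]


def assign_labels(table: pd.DataFrame, log_fn: Optional[Callable] = None,
                  q_low: float = 0.25, q_high: float = 0.75) -> Dict[str, int]:
    """Quantile-stratify genes into {-1, 0, +1} expression classes.

    Uses type-7 (linear interpolation) empirical quantiles of logMaxTPM:
    label -1 iff logMaxTPM <= Q_low, +1 iff logMaxTPM >= Q_high, else 0.
    The low-class test is applied first, so in the degenerate all-identical
    case every gene is labelled -1 (with a warning).
    """
    if len(table) == 0:
        raise ValueError("empty expression table")
    if "logMaxTPM" in table.columns and log_fn is None:
        vals = table["logMaxTPM"].to_numpy(dtype=float)
    else:
        log_fn = log_fn or default_log_transform
        vals = log_fn(table["maxTPM"].to_numpy(dtype=float))
    qlo, qhi = np.quantile(vals, [q_low, q_high])  # default = type-7 linear
    if qlo == qhi:
        warnings.warn("degenerate quantiles (Q_low == Q_high); "
                      "boundary genes all fall in the low class")
    labels = np.zeros(len(vals), dtype=int)
    labels[vals >= qhi] = 1
    labels[vals <= qlo] = -1  # applied last: low-class tie-break wins
    return dict(zip(table["gene_id"], (int(v) for v in labels)))


def make_chromosome_folds(genes: Sequence[GeneRecord]) -> FoldPlan:
    """One fold per chromosome (sorted lexicographically for determinism)."""
    chroms = sorted({g.chromosome for g in genes})
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes for chromosome-fold CV")
    chrom_fold = {c: i for i, c in enumerate(chroms)}
    assignment = {g.gene_id: chrom_fold[g.chromosome] for g in genes}
    if len(assignment) != len(genes):
        raise ValueError("duplicate gene ids in fold construction")
    return FoldPlan(k=len(chroms), assignment=assignment,
                    chromosome_fold=chrom_fold)


# ---------------------------------------------------------------------------
# encoded dataset


DATASET_FORMAT_VERSION = 1


@dataclass
class EncodedDataset:
    """One-hot windows plus labels for a cohort of genes.

    ``X`` is (N, L, 4) uint8; ``labels`` holds classes in {-1, 0, +1}.
    ``targets()`` yields the N x 3 one-hot class matrix in the fixed
    (low, medium, high) column order.
    """

    gene_ids: List[str]
    chromosomes: List[str]
    labels: np.ndarray
    X: np.ndarray
    flank: FlankSpec = field(default_factory=FlankSpec)

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def seq_len(self) -> int:
        return self.X.shape[1]

    def targets(self) -> np.ndarray:
        y = np.zeros((len(self), 3), dtype=np.float32)
        for i, lab in enumerate(self.labels):
            y[i, LABEL_TO_INDEX[int(lab)]] = 1.0
        return y

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(
            gene_ids=[self.gene_ids[i] for i in idx],
            chromosomes=[self.chromosomes[i] for i in idx],
            labels=self.labels[idx],
            X=self.X[idx],
            flank=self.flank,
        )


def encode_dataset(genome: Mapping[str, str], genes: Sequence[GeneRecord],
                   labels: Mapping[str, int],
                   spec: Optional[FlankSpec] = None) -> EncodedDataset:
    """Extract, one-hot encode and label the window of every annotated gene.

    Genes missing from ``labels`` are dropped with a logged warning.
    """
    spec = spec or FlankSpec()
    kept = [g for g in genes if g.gene_id in labels]
    dropped = len(genes) - len(kept)
    if dropped:
        logger.warning("dropping %d genes without expression labels", dropped)
    if not kept:
        raise ValueError("no genes with both annotation and expression label")
    X = np.empty((len(kept), spec.total_length, 4), dtype=np.uint8)
    labs = np.empty(len(kept), dtype=np.int8)
    for i, g in enumerate(kept):
        X[i] = one_hot(extract_gene_window(g, genome, spec))
        labs[i] = labels[g.gene_id]
    return EncodedDataset(
        gene_ids=[g.gene_id for g in kept],
        chromosomes=[g.chromosome for g in kept],
        labels=labs, X=X, flank=spec,
    )


def save_dataset(dataset: EncodedDataset, out_dir) -> None:
    """Write a dataset directory: manifest.tsv + X.npy + meta.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        fold = make_chromosome_folds(
            [GeneRecord(g, c, "+", 0, 0) for g, c in
             zip(dataset.gene_ids, dataset.chromosomes)]
        ).assignment
    except ValueError:
        fold = {g: 0 for g in dataset.gene_ids}
    manifest = pd.DataFrame({
        "gene_id": dataset.gene_ids,
        "chromosome": dataset.chromosomes,
        "fold": [fold[g] for g in dataset.gene_ids],
        "label": dataset.labels,
    })
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    np.save(out / "X.npy", dataset.X)
    meta = {
        "format_version": DATASET_FORMAT_VERSION,
        "n_genes": len(dataset),
        "seq_len": int(dataset.seq_len),
        "flank": dataclasses.asdict(dataset.flank),
        "onehot_order": NUCLEOTIDE_ORDER,
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_dataset(in_dir) -> EncodedDataset:
    out = Path(in_dir)
    meta = yaml.safe_load((out / "meta.yaml").read_text())
    if meta.get("format_version") != DATASET_FORMAT_VERSION:
        raise ValueError(f"unsupported dataset format {meta.get('format_version')}")
    manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
    X = np.load(out / "X.npy")
    return EncodedDataset(
        gene_ids=manifest["gene_id"].tolist(),
        chromosomes=manifest["chromosome"].astype(str).tolist(),
        labels=manifest["label"].to_numpy(dtype=np.int8),
        X=X,
        flank=FlankSpec(**meta["flank"]),
    )
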