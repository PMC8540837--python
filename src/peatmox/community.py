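"""pmoA amplicon post-processing.

Consumes merged, primer-trimmed reads (FASTQ) and OTU tables produced by
upstream clustering, and applies the marker-gene specific screens: a
sliding-window Phred quality filter, a reading-frame/stop-codon screen
(pmoA is protein coding, so a correct amplicon translates without stops),
length windows per primer set, taxonomy by best global alignment against a
trimmed reference database, relative-abundance normalization, per-sample
low-abundance denoising, and the log transform used before ordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from .gas_kinetics import ValidationError

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
IUPAC_DNA = set("ACGTRYSWKMBDHVN")
#: inclusive dominant-sequence length windows per primer set (nt)
LENGTH_WINDOWS = {"mb661R": (465, 474), "A682R": (492, 495)}


@dataclass
class AmpliconRead:
    """One primer-trimmed read with per-base Phred qualities."""

    id: str
    nucleotides: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=float)
        if len(self.nucleotides) != len(self.qualities):
            raise ValidationError(
                f"read {self.id}: sequence and quality lengths differ"
            )


def read_fastq(path) -> list[AmpliconRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            AmpliconRead(
                id=rec.id,
                nucleotides=str(rec.seq).upper(),
                qualities=np.array(rec.letter_annotations["phred_quality"], dtype=float),
            )
        )
    return reads


def write_fastq(reads: list[AmpliconRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.nucleotides}\n+\n{qual}\n")


@dataclass
class FilterReport:
    """Kept/rejected bookkeeping for one filtering pass."""

    kept: list = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def quality_window_filter(
    reads: list[AmpliconRead], window: int = 50, min_mean_phred: float = 20.0
) -> FilterReport:
    """Discard reads containing any length-`window` stretch of mean Phred
    below `min_mean_phred` (sliding window, step 1). Reads shorter than the
    window are judged on their full-length mean.
    """
    report = FilterReport()
    for read in reads:
        q = read.qualities
        if len(q) == 0:
            report.rejected.append((read.id, "empty read"))
            continue
        if len(q) < window:
            worst = q.mean()
        else:
            csum = np.concatenate([[0.0], np.cumsum(q)])
            worst = (csum[window:] - csum[:-window]).min() / window
        if worst < min_mean_phred:
            report.rejected.append(
                (read.id, f"window mean Phred {worst:.2f} < {min_mean_phred:g}")
            )
        else:
            report.kept.append(read)
    return report


def frame_stop_filter(sequence: str, frame_offset: int = 0) -> tuple[bool, str]:
    """Screen a putative coding sequence for framing and stop-codon errors.

    Fails when the length (from frame_offset) is not a multiple of three,
    or when any in-frame codon is a stop (TAA/TAG/TGA, bacterial code).
    Returns (passed, reason).
    """
    seq = sequence.upper()
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise ValidationError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    coding = seq[frame_offset:]
    if len(coding) % 3 != 0:
        return False, f"length {len(coding)} not divisible by 3"
    for i in range(0, len(coding), 3):
        codon = coding[i : i + 3]
        if codon in STOP_CODONS:
            return False, f"in-frame stop codon {codon} at position {i}"
    return True, "ok"


def length_window_filter(sequence: str, primer_set: str) -> bool:
    """Inclusive dominant-sequence length window per primer set."""
    if primer_set not in LENGTH_WINDOWS:
        raise ValidationError(
            f"unknown primer set {primer_set!r}; known: {sorted(LENGTH_WINDOWS)}"
        )
    lo, hi = LENGTH_WINDOWS[primer_set]
    return lo <= len(sequence) <= hi


@dataclass
class ReferenceDB:
    """Trimmed reference sequences with taxonomy paths for one primer set."""

    entries: list[tuple[str, str]]  # (taxonomy, sequence)
    primer_set: str = "mb661R"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("reference database is empty")

    @classmethod
    def from_fasta(cls, path, primer_set: str = "mb661R") -> "ReferenceDB":
        entries = [
            (rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(entries=entries, primer_set=primer_set)


@dataclass(frozen=True)
class TaxonomyAssignment:
    taxonomy: str
    percent_identity: float
    tie: bool


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def assign_taxonomy(sequence: str, db: ReferenceDB) -> TaxonomyAssignment:
    """Best global alignment of the OTU's dominant sequence against the db.

    The highest-scoring entry wins; identity is matches over alignment
    columns (x100). Exact score ties are broken by database order and
    flagged.
    """
    aligner = _aligner()
    query = sequence.upper()
    best_score, best_idx, tie = None, None, False
    for idx, (_, ref) in enumerate(db.entries):
        score = aligner.score(query, ref)
        if best_score is None or score > best_score:
            best_score, best_idx, tie = score, idx, False
        elif score == best_score:
            tie = True
    taxonomy, ref = db.entries[best_idx]
    alignment = aligner.align(query, ref)[0]
    counts = alignment.counts()
    identity = 100.0 * counts.identities / alignment.length
    if tie:
        logger.info("taxonomy tie for query (len %d); kept first db entry", len(query))
    return TaxonomyAssignment(taxonomy=taxonomy, percent_identity=identity, tie=tie)


@dataclass
class OTUTable:
    """Samples x OTUs count (or relative-abundance) matrix with metadata."""

    counts: pd.DataFrame                      # index: samples, columns: OTUs
    sample_metadata: pd.DataFrame | None = None
    representative_sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("OTU table entries must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValidationError("sample and OTU labels must be unique")
        if self.sample_metadata is not None and not self.sample_metadata.index.equals(
            self.counts.index
        ):
            self.sample_metadata = self.sample_metadata.reindex(self.counts.index)


def to_relative_abundance(table: OTUTable) -> tuple[OTUTable, list[str]]:
    """Row-normalize to relative abundances; all-zero samples stay zero
    and are returned as flags."""
    counts = table.counts
    row_sums = counts.sum(axis=1)
    empty = row_sums[row_sums == 0].index.tolist()
    if empty:
        logger.warning("samples with zero reads left as all-zero rows: %s", empty)
    rel = counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return (
        OTUTable(rel, table.sample_metadata, table.representative_sequences),
        empty,
    )


@dataclass
class DenoiseResult:
    table: OTUTable          # denoised counts
    relative: OTUTable       # relative abundances recomputed on survivors
    removed_read_fraction: float
    n_zeroed_entries: int


def denoise(table: OTUTable, threshold: float = 1e-3) -> DenoiseResult:
    """Per-sample low-abundance denoising of a count table.

    Any OTU whose within-sample relative abundance is strictly below
    `threshold` is treated as absent from that sample (count zeroed);
    relative abundances are recomputed on the surviving entries. Reports
    the fraction of original reads removed.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly between 0 and 1")
    counts = table.counts
    row_sums = counts.sum(axis=1)
    rel = counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    mask = (rel < threshold) & (counts > 0)
    total = counts.to_numpy().sum()
    removed = counts.where(mask, 0).to_numpy().sum()
    denoised = counts.mask(mask, 0)
    out = OTUTable(denoised, table.sample_metadata, table.representative_sequences)
    relative, _ = to_relative_abundance(out)
    frac = float(removed / total) if total > 0 else 0.0
    return DenoiseResult(
        table=out,
        relative=relative,
        removed_read_fraction=frac,
        n_zeroed_entries=int(mask.to_numpy().sum()),
    )


def log_normalize(matrix, base: float = 2.0):
    """Ordination-style log transform: x -> log_base(x) + 1 for x > 0, 0 -> 0.

    Monotone on the non-negative half-line; values in (0, 1/base) map below
    zero, which is reported with a warning (relevant when the transform is
    applied to relative abundances rather than counts).
    """
    arr = np.asarray(matrix, dtype=float) if not isinstance(matrix, pd.DataFrame) else matrix
    values = arr.to_numpy() if isinstance(arr, pd.DataFrame) else arr
    if (values < 0).any():
        raise ValidationError("log normalization requires a non-negative matrix")
    out = np.zeros_like(values, dtype=float)
    pos = values > 0
    out[pos] = np.log(values[pos]) / np.log(base) + 1.0
    if (out < 0).any():
        logger.warning(
            "log normalization produced negative values (inputs below 1/base)"
        )
    if isinstance(arr, pd.DataFrame):
        return pd.DataFrame(out, index=arr.index, columns=arr.columns)
    return out
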