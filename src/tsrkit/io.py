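"""Core data containers and readers/writers for genomic inputs.

All internal coordinates are 0-based, half-open, with strand recorded
explicitly.  Conversions to/from 1-based conventions happen only at the
I/O boundary (GTF and HOMER-style position files are 1-based inclusive).

Signal containers (:class:`EndProfile`, :class:`NormalizedProfile`,
:class:`CoverageTrack`) store sparse per-position values keyed by
``(chromosome, strand)``.  Normalization to "per 10^7 aligned reads" uses
the library-size metadata reported by the profile's producer (uniquely
aligned read count); it is carried, not recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

NORM_FACTOR = 1e7  # counts are expressed per 10^7 aligned reads

STRANDS = ("+", "-")

IUPAC_DNA = set("ACGTN")


class InvalidInputError(ValueError):
    """Raised when an input file or container violates its contract."""


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """Uppercase DNA sequences keyed by chromosome name."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise InvalidInputError(
                    f"sequence {name!r} contains non-DNA letters: {sorted(bad)}"
                )
            self.sequences[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence on [start, end); '-' strand returns reverse complement."""
        seq = self.sequences[chrom]
        start = max(0, start)
        end = min(len(seq), end)
        if start >= end:
            return ""
        sub = seq[start:end]
        if strand == "-":
            sub = str(Seq(sub).reverse_complement())
        return sub


def read_fasta(path) -> GenomeSequence:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InvalidInputError(f"duplicate sequence name {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.sequences):
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based, half-open span of the transcript
    end: int
    feature_type: str = "protein_coding"  # gene biotype, e.g. miRNA
    n_exons: int = 1

    @property
    def five_prime_end(self) -> int:
        """TSS position: interval start on '+', end-1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneAnnotation:
    """Transcript catalogue used for context classification."""

    transcripts: list[Transcript] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def tss_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
        """Per-chromosome sorted 5' ends.

        Returns chrom -> (positions, strand codes (+1/-1), transcript ids),
        sorted by position.
        """
        out: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        by_chrom: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            ts.sort(key=lambda t: (t.five_prime_end, t.transcript_id))
            pos = np.array([t.five_prime_end for t in ts], dtype=np.int64)
            sc = np.array([1 if t.strand == "+" else -1 for t in ts], dtype=np.int8)
            ids = [t.transcript_id for t in ts]
            out[chrom] = (pos, sc, ids)
        return out


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> GeneAnnotation:
    """Parse transcript features (with exon counts) from a GTF file.

    GTF coordinates are 1-based inclusive and are converted to the internal
    0-based half-open convention.  Malformed lines raise
    :class:`InvalidInputError` with the offending line number.
    """
    transcripts: dict[str, Transcript] = {}
    exon_counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise InvalidInputError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_gtf_attributes(attr_s)
            tid = attrs.get("transcript_id")
            if feature == "transcript":
                if tid is None:
                    raise InvalidInputError(f"{path}:{lineno}: transcript without transcript_id")
                transcripts[tid] = Transcript(
                    transcript_id=tid,
                    gene_id=attrs.get("gene_id", tid),
                    chrom=chrom,
                    strand=strand,
                    start=start1 - 1,
                    end=end1,
                    feature_type=attrs.get("gene_biotype", "protein_coding"),
                )
            elif feature == "exon" and tid is not None:
                exon_counts[tid] = exon_counts.get(tid, 0) + 1
    for tid, n in exon_counts.items():
        if tid in transcripts:
            transcripts[tid].n_exons = n
    ann = GeneAnnotation(sorted(transcripts.values(), key=lambda t: (t.chrom, t.start, t.transcript_id)))
    return ann


def write_gtf(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for t in sorted(annotation.transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{t.feature_type}";'
            )
            fh.write(
                "\t".join(
                    [t.chrom, "tsrkit", "transcript", str(t.start + 1), str(t.end), ".", t.strand, ".", attrs]
                )
                + "\n"
            )


def extract_tss(annotation: GeneAnnotation) -> pd.DataFrame:
    """One 5'-end record per transcript as a BED-like region table."""
    rows = [
        {
            "chrom": t.chrom,
            "start": t.five_prime_end,
            "end": t.five_prime_end + 1,
            "name": t.transcript_id,
            "score": 0,
            "strand": t.strand,
        }
        for t in annotation.transcripts
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return df.sort_values(["chrom", "start", "name"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# sparse position tracks
# ---------------------------------------------------------------------------


class PositionTrack:
    """Sparse per-position signal keyed by (chromosome, strand).

    Used for read 5'-end count profiles (integer raw counts), their
    per-10^7 normalized versions (float), and RNA-seq/GRO-seq tracks.
    """

    value_dtype = float

    def __init__(self, total_aligned_reads: float):
        if total_aligned_reads <= 0:
            raise InvalidInputError("total_aligned_reads must be positive")
        self.total_aligned_reads = total_aligned_reads
        self._data: dict[tuple[str, str], dict[int, float]] = {}
        self._cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    # -- construction -----------------------------------------------------
    def add(self, chrom: str, strand: str, position: int, value: float) -> None:
        if strand not in STRANDS:
            raise InvalidInputError(f"bad strand {strand!r}")
        if position < 0:
            raise InvalidInputError(f"negative position {position}")
        if value < 0:
            raise InvalidInputError("negative signal value")
        key = (chrom, strand)
        bucket = self._data.setdefault(key, {})
        bucket[position] = bucket.get(position, 0) + value
        self._cache.pop(key, None)

    def add_positions(self, chrom: str, strand: str, positions: Iterable[int], value: float = 1) -> None:
        key = (chrom, strand)
        bucket = self._data.setdefault(key, {})
        for p in positions:
            bucket[p] = bucket.get(p, 0) + value
        self._cache.pop(key, None)

    # -- access -----------------------------------------------------------
    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._data)

    def get(self, chrom: str, strand: str, position: int) -> float:
        return self._data.get((chrom, strand), {}).get(position, 0)

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted position and value arrays for one chromosome/strand."""
        key = (chrom, strand)
        if key not in self._cache:
            bucket = self._data.get(key, {})
            pos = np.fromiter(bucket.keys(), dtype=np.int64, count=len(bucket))
            order = np.argsort(pos, kind="mergesort")
            vals = np.fromiter(bucket.values(), dtype=float, count=len(bucket))
            self._cache[key] = (pos[order], vals[order])
        return self._cache[key]

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Total signal on [start, end)."""
        pos, vals = self.arrays(chrom, strand)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return float(vals[lo:hi].sum())

    def items(self) -> Iterator[tuple[str, str, int, float]]:
        for chrom, strand in self.keys():
            pos, vals = self.arrays(chrom, strand)
            for p, v in zip(pos.tolist(), vals.tolist()):
                yield chrom, strand, p, v

    def total_signal(self) -> float:
        return float(sum(v for _, _, _, v in self.items()))

    def n_positions(self) -> int:
        return sum(len(b) for b in self._data.values())


class EndProfile(PositionTrack):
    """Raw read 5'-end counts (non-negative integers)."""

    def normalize(self) -> "NormalizedProfile":
        return normalize_profile(self)


class NormalizedProfile(PositionTrack):
    """EndProfile scaled to counts per 10^7 aligned reads."""


class CoverageTrack(PositionTrack):
    """Strand-specific RNA-seq / GRO-seq signal (read starts or coverage)."""

    def normalize(self) -> "CoverageTrack":
        out = CoverageTrack(total_aligned_reads=self.total_aligned_reads)
        scale = NORM_FACTOR / self.total_aligned_reads
        for chrom, strand, p, v in self.items():
            out.add(chrom, strand, p, v * scale)
        return out


def normalize_profile(profile: EndProfile) -> NormalizedProfile:
    """Scale raw 5'-end counts to per-10^7-aligned-reads units."""
    if profile.total_aligned_reads <= 0:
        raise InvalidInputError("cannot normalize: non-positive total_aligned_reads")
    scale = NORM_FACTOR / profile.total_aligned_reads
    out = NormalizedProfile(total_aligned_reads=profile.total_aligned_reads)
    for chrom, strand, p, v in profile.items():
        out.add(chrom, strand, p, v * scale)
    return out


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path, strand: str, total_aligned_reads: float, kind: str = "ends"):
    """Read a single-strand 4-column bedGraph into a track.

    ``kind='ends'`` produces an :class:`EndProfile` (integer counts, one
    value per covered base); ``kind='coverage'`` a :class:`CoverageTrack`.
    Overlapping intervals on one strand are rejected as ambiguous.
    """
    if kind == "ends":
        track: PositionTrack = EndProfile(total_aligned_reads)
    elif kind == "coverage":
        track = CoverageTrack(total_aligned_reads)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise InvalidInputError(f"{path}:{lineno}: expected 4 columns")
            chrom, start_s, end_s, value_s = fields
            start, end = int(start_s), int(end_s)
            value = float(value_s)
            if start >= end:
                raise InvalidInputError(f"{path}:{lineno}: empty interval")
            if chrom in last_end and start < last_end[chrom]:
                raise InvalidInputError(
                    f"{path}:{lineno}: overlapping/unsorted interval on {chrom}"
                )
            last_end[chrom] = end
            for p in range(start, end):
                track.add(chrom, strand, p, value)
    return track


def write_bedgraph(track: PositionTrack, path, strand: str) -> None:
    """Write one strand of a track, one line per covered position.

    Single-base intervals mirror fragment-length-1 5'-end semantics;
    ordering is deterministic (chromosome lexicographic, then start).
    """
    with open(path, "w") as fh:
        for chrom, s in track.keys():
            if s != strand:
                continue
            pos, vals = track.arrays(chrom, strand)
            for p, v in zip(pos.tolist(), vals.tolist()):
                v_out = int(v) if float(v).is_integer() else v
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{v_out}\n")


# ---------------------------------------------------------------------------
# region tables
# ---------------------------------------------------------------------------

REGION_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _validate_regions(df: pd.DataFrame, where: str) -> pd.DataFrame:
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise InvalidInputError(f"{where}: start >= end at row {bad}")
    return df


def read_region_table(path, dialect: str = "bed6") -> pd.DataFrame:
    """Read a region table into 0-based half-open coordinates.

    Dialects: ``bed6`` (0-based half-open, headerless), ``homer_pos``
    (1-based inclusive: name chrom start end strand), ``tsv`` (header with
    at least chrom/start/end, 0-based half-open, extra columns preserved).
    """
    if dialect == "bed6":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=REGION_COLUMNS, dtype={0: str},
        )
    elif dialect == "homer_pos":
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["name", "chrom", "start", "end", "strand"], dtype={1: str},
        )
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "start": raw["start"].astype(int) - 1,  # 1-based inclusive -> 0-based half-open
                "end": raw["end"].astype(int),
                "name": raw["name"],
                "score": 0,
                "strand": raw["strand"],
            }
        )
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
        for col, default in (("name", ""), ("score", 0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[REGION_COLUMNS + [c for c in df.columns if c not in REGION_COLUMNS]]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return _validate_regions(df, str(path))


def write_region_table(df: pd.DataFrame, path, dialect: str = "tsv") -> None:
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if dialect == "bed6":
        df[REGION_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    elif dialect == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
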