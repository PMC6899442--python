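"""On-disk formats, coordinate conventions, and the shared domain types.

Every genomic coordinate in this package is BED-style: 0-based, half-open
``[start, end)``. 1-based coordinates appear only in human-readable report
strings. All record types used across the pipeline live here so that the
domain modules (interactions, footprints, motif_analysis, integration,
network) can share them without circular imports; each module re-exports
the types it owns.

Supported formats: BED3/BED6/narrowPeak (peaks, DHSs, footprints), BEDPE
with extra columns count/expected/p/q (interactions), JASPAR-style PWM
text, per-base cut-count TSV, expression TSV, FASTA, and YAML configs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

log = logging.getLogger("chicnet")


class FormatError(ValueError):
    """A malformed on-disk record (carries the offending line number)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Overlap length in bases; 0 if on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class RestrictionFragment:
    """One restriction fragment of the digested genome.

    Bait fragments are the promoter-containing fragments targeted by the
    capture probes; they carry the annotated gene symbol.
    """

    interval: GenomicInterval
    fragment_id: int
    is_bait: bool = False
    bait_gene: str = ""

    def __post_init__(self) -> None:
        if self.is_bait and not self.bait_gene:
            raise ValueError(f"bait fragment {self.fragment_id} lacks a gene")


@dataclass
class PeakRecord:
    """A peak or DHS with its summit (offset from interval start)."""

    interval: GenomicInterval
    summit_offset: int = -1
    tf_name: str = ""
    condition: str = ""
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.summit_offset < 0:
            self.summit_offset = len(self.interval) // 2
        if not (0 <= self.summit_offset < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")

    @property
    def summit(self) -> int:
        """Absolute summit position (0-based)."""
        return self.interval.start + self.summit_offset


@dataclass
class InteractionRecord:
    """One bait <-> other-end fragment pair with test results.

    ``distance`` is the separation of fragment midpoints in bases, or None
    for trans (inter-chromosomal) pairs.
    """

    bait_id: int
    other_id: int
    count: int
    distance: int | None = None
    expected: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    significant: bool = False
    bait_interval: GenomicInterval | None = None
    other_interval: GenomicInterval | None = None
    bait_gene: str = ""

    def __post_init__(self) -> None:
        if self.count < 0 or self.count != int(self.count):
            raise ValueError(f"count must be a nonnegative integer, got {self.count}")
        self.count = int(self.count)
        for v, name in ((self.p_value, "p_value"), (self.q_value, "q_value")):
            if not math.isnan(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.bait_id, self.other_id)


@dataclass
class CutProfile:
    """Per-base, per-strand DNaseI cut counts over a fixed window."""

    window: GenomicInterval
    cuts_plus: np.ndarray
    cuts_minus: np.ndarray

    def __post_init__(self) -> None:
        self.cuts_plus = np.asarray(self.cuts_plus, dtype=np.int64)
        self.cuts_minus = np.asarray(self.cuts_minus, dtype=np.int64)
        w = len(self.window)
        if self.cuts_plus.shape != (w,) or self.cuts_minus.shape != (w,):
            raise ValueError("cut arrays must match window length")
        if (self.cuts_plus < 0).any() or (self.cuts_minus < 0).any():
            raise ValueError("cut counts must be nonnegative")


@dataclass
class Footprint:
    """A called digital footprint: a protected gap in the cut profile."""

    interval: GenomicInterval
    score: float
    p_value: float
    q_value: float = float("nan")

    @property
    def footprint_length(self) -> int:
        return len(self.interval)


@dataclass
class MotifModel:
    """A column-stochastic PWM with a TF-family label."""

    motif_id: str
    family: str
    matrix: np.ndarray  # shape (4, L), rows A, C, G, T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x L")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))

    @property
    def score_matrix(self) -> np.ndarray:
        """Per-position log-likelihood ratios log(p_base / bg_base)."""
        return np.log(self.matrix / self.background[:, None])

    @property
    def max_llr(self) -> float:
        return float(self.score_matrix.max(axis=0).sum())


@dataclass
class MotifOccurrence:
    """A PWM match; ``occupied`` marks overlap with a called footprint."""

    interval: GenomicInterval
    motif_id: str
    strand: str
    llr_score: float
    occupied: bool = False

    @property
    def center(self) -> int:
        return self.interval.midpoint


@dataclass
class ExpressionRecord:
    """One gene's expression in two conditions with the differential test."""

    gene: str
    value_a: float
    value_b: float
    log2fc: float
    p_value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc must be finite for {self.gene}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1] for {self.gene}")


# ---------------------------------------------------------------------------
# Interval arithmetic helpers
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Symmetric overlap length: max(0, min(ends) - max(starts))."""
    return a.overlap_len(b)


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

_BED_DIALECTS = ("bed3", "bed6", "narrowPeak")


def read_bed(path: str | Path, dialect: str = "bed6") -> list[PeakRecord]:
    """Read a BED3/BED6/narrowPeak file into PeakRecords.

    narrowPeak column 10 (0-based offset from start) becomes the summit;
    bed3/bed6 summits default to the interval midpoint.
    """
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            minimum = 10 if dialect == "narrowPeak" else 3
            if len(cols) < minimum:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {minimum} columns, got {len(cols)}"
                )
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = cols[3] if len(cols) > 3 else ""
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            summit = -1
            if dialect == "narrowPeak":
                summit = int(cols[9])
                if summit == -1:
                    summit = (end - start) // 2
            records.append(
                PeakRecord(
                    interval=GenomicInterval(chrom, start, end, strand),
                    summit_offset=summit,
                    score=score,
                    name=name,
                )
            )
    return records


def write_bed(records: Iterable[PeakRecord], path: str | Path,
              dialect: str = "bed6") -> None:
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            iv = rec.interval
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if dialect != "bed3":
                cols += [rec.name or f"peak{i}", repr(float(rec.score)),
                         iv.strand if iv.strand in "+-" else "."]
            if dialect == "narrowPeak":
                cols += ["0", "-1", "-1", str(rec.summit_offset)]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BEDPE interactions
# ---------------------------------------------------------------------------

def write_interactions_bedpe(records: Iterable[InteractionRecord],
                             path: str | Path) -> None:
    """Write interactions as BEDPE.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name count expected p q.
    The name column encodes ``bait_id:other_id:bait_gene``.
    """
    with open(path, "w") as fh:
        for r in records:
            b = r.bait_interval or GenomicInterval("?", 0, 1)
            o = r.other_interval or GenomicInterval("?", 0, 1)
            name = f"{r.bait_id}:{r.other_id}:{r.bait_gene}"
            fh.write(
                "\t".join(
                    [b.chrom, str(b.start), str(b.end),
                     o.chrom, str(o.start), str(o.end),
                     name, str(r.count), repr(r.expected),
                     repr(r.p_value), repr(r.q_value)]
                ) + "\n"
            )


def read_interactions_bedpe(path: str | Path) -> list[InteractionRecord]:
    records: list[InteractionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise FormatError(f"{path}:{lineno}: expected >= 8 columns")
            try:
                c1, s1, e1 = cols[0], int(cols[1]), int(cols[2])
                c2, s2, e2 = cols[3], int(cols[4]), int(cols[5])
                count = int(cols[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            bait_id, other_id, bait_gene = -1, -1, ""
            parts = cols[6].split(":")
            if len(parts) == 3:
                bait_id, other_id, bait_gene = int(parts[0]), int(parts[1]), parts[2]
            expected = float(cols[8]) if len(cols) > 8 else float("nan")
            p = float(cols[9]) if len(cols) > 9 else float("nan")
            q = float(cols[10]) if len(cols) > 10 else float("nan")
            bait_iv = GenomicInterval(c1, s1, e1)
            other_iv = GenomicInterval(c2, s2, e2)
            dist = (abs(bait_iv.midpoint - other_iv.midpoint)
                    if c1 == c2 else None)
            records.append(
                InteractionRecord(
                    bait_id=bait_id, other_id=other_id, count=count,
                    distance=dist, expected=expected, p_value=p, q_value=q,
                    bait_interval=bait_iv, other_interval=other_iv,
                    bait_gene=bait_gene,
                )
            )
    return records


# ---------------------------------------------------------------------------
# JASPAR-style PWM text
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path, pseudocount: float = 1.0) -> list[MotifModel]:
    """Read a JASPAR-style PWM file.

    Format per motif: a header line ``>ID family`` followed by four rows
    (A, C, G, T) of L nonnegative counts. A Laplace pseudocount is added
    to every cell before column normalization so that scores are fully
    reproducible from the stored counts.
    """
    motifs: list[MotifModel] = []
    header: str | None = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(f"{path}:{lineno}: motif {header} needs 4 rows")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"{path}:{lineno}: rows of unequal length in {header}")
        counts = np.array(rows, dtype=float)
        if (counts < 0).any():
            raise FormatError(f"{path}:{lineno}: negative count in {header}")
        if (counts.sum(axis=0) == 0).any() and pseudocount == 0:
            raise FormatError(f"{path}:{lineno}: all-zero column in {header}")
        counts = counts + pseudocount
        matrix = counts / counts.sum(axis=0, keepdims=True)
        parts = header.split(None, 1)
        motif_id = parts[0]
        family = parts[1].strip() if len(parts) > 1 else motif_id
        motifs.append(MotifModel(motif_id=motif_id, family=family, matrix=matrix))
        header, rows = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: matrix row before header")
                # tolerate JASPAR "A [ 1 2 3 ]" decoration
                cleaned = line.lstrip("ACGTacgt").strip().strip("[]").strip()
                try:
                    rows.append([float(x) for x in cleaned.split()])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
        flush(lineno + 1)
    return motifs


def write_pwm_counts(motifs: Iterable[tuple[str, str, np.ndarray]],
                     path: str | Path) -> None:
    """Write (motif_id, family, 4xL count matrix) triples as JASPAR text."""
    with open(path, "w") as fh:
        for motif_id, family, counts in motifs:
            fh.write(f">{motif_id} {family}\n")
            for row in np.asarray(counts):
                fh.write(" ".join(f"{int(v)}" if float(v).is_integer()
                                  else repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Per-base cut tables
# ---------------------------------------------------------------------------

def write_cut_profiles(profiles: Iterable[CutProfile], path: str | Path) -> None:
    """TSV: chrom, window_start, window_end, offset, plus, minus."""
    with open(path, "w") as fh:
        fh.write("chrom\twindow_start\twindow_end\toffset\tplus\tminus\n")
        for prof in profiles:
            w = prof.window
            for off in range(len(w)):
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{off}"
                         f"\t{prof.cuts_plus[off]}\t{prof.cuts_minus[off]}\n")


def read_cut_profiles(path: str | Path) -> list[CutProfile]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (chrom, start, end), grp in df.groupby(
            ["chrom", "window_start", "window_end"], sort=False):
        grp = grp.sort_values("offset")
        width = int(end) - int(start)
        plus = np.zeros(width, dtype=np.int64)
        minus = np.zeros(width, dtype=np.int64)
        plus[grp["offset"].to_numpy()] = grp["plus"].to_numpy()
        minus[grp["offset"].to_numpy()] = grp["minus"].to_numpy()
        profiles.append(CutProfile(
            window=GenomicInterval(str(chrom), int(start), int(end)),
            cuts_plus=plus, cuts_minus=minus))
    return profiles


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> list[ExpressionRecord]:
    """TSV with header: gene, value_a, value_b, log2fc, pvalue."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 5:
            raise FormatError(f"{path}: expected 5-column expression table")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            try:
                records.append(ExpressionRecord(
                    gene=cols[0], value_a=float(cols[1]), value_b=float(cols[2]),
                    log2fc=float(cols[3]), p_value=float(cols[4])))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_expression_tsv(records: Iterable[ExpressionRecord],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tvalue_a\tvalue_b\tlog2fc\tpvalue\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.value_a!r}\t{r.value_b!r}"
                     f"\t{r.log2fc!r}\t{r.p_value!r}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before header")
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# Fragment maps and config
# ---------------------------------------------------------------------------

def write_fragments_bed(fragments: Iterable[RestrictionFragment],
                        path: str | Path) -> None:
    """BED6+: chrom start end fragment_id is_bait bait_gene."""
    with open(path, "w") as fh:
        for f in fragments:
            iv = f.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.fragment_id}"
                     f"\t{int(f.is_bait)}\t{f.bait_gene or '.'}\n")


def read_fragments_bed(path: str | Path) -> list[RestrictionFragment]:
    frags = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            try:
                frags.append(RestrictionFragment(
                    interval=GenomicInterval(cols[0], int(cols[1]), int(cols[2])),
                    fragment_id=int(cols[3]),
                    is_bait=bool(int(cols[4])),
                    bait_gene="" if cols[5] == "." else cols[5]))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return frags


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(obj, path: str | Path) -> None:
    data = asdict(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def setup_logging(level: int = logging.INFO) -> None:
    """Configure the package logger once, with library versions recorded."""
    if log.handlers:
        return
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(level)
    import scipy
    import pandas
    log.info("versions: numpy=%s scipy=%s pandas=%s",
             np.__version__, scipy.__version__, pandas.__version__)
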