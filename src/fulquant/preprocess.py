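"""Read-level quality filtering, adapter/polyA trimming and full-length classification.

Full-length cDNA libraries built with template-switching PCR carry the ISPCR
primer sequence at the 5' end of the molecule and a polyA (or, for reads
sequenced in the reverse orientation, a 5' polyT) tail at the other end.  A
read is called *full-length* when the adapter is found at one end and a polyA
tail at the other end, evidence that the underlying cDNA covers the whole
molecule from cap site to polyadenylation site.

Coordinates on reads are 0-based; all trimming keeps a contiguous substring
of the original sequence.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import edlib
import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: template-switch PCR primer used for full-length cDNA amplification
ISPCR_ADAPTER = "AAGCAGTGGTATCAACGCAGAGTAC"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """A basecalled read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


@dataclass(frozen=True)
class AdapterHit:
    end: str  # FIVE_PRIME or THREE_PRIME
    position: int  # start of the matched segment, read coordinates
    length: int  # span of the matched segment on the read
    identity: float  # matching fraction over the adapter length


@dataclass(frozen=True)
class PolyAHit:
    end: str
    start: int  # read coordinate of the first base of the run
    length: int


@dataclass
class ProcessedRead:
    read_id: str
    trimmed_sequence: str
    trimmed_qualities: tuple[int, ...]
    mean_qscore: float
    adapter_hits: list[AdapterHit] = field(default_factory=list)
    polya_hit: Optional[PolyAHit] = None
    is_full_length: bool = False
    trim_start: int = 0  # coordinates of trimmed_sequence on the raw read
    trim_end: int = 0


def mean_read_qscore(qualities) -> float:
    """Mean read quality on the Phred scale.

    This is the ONT ``mean_qscore`` convention: the per-base Phred values are
    converted to error probabilities, averaged, and converted back, i.e.
    ``-10*log10(mean(10**(-q/10)))``.  It is always <= the arithmetic mean of
    the Phred values.
    """
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("cannot compute mean qscore of an empty quality list")
    if np.any(q < 0):
        raise ValueError("Phred qualities must be non-negative")
    return float(-10.0 * np.log10(np.mean(np.power(10.0, -q / 10.0))))


def filter_by_qscore(
    reads: Iterable[RawRead], cutoff: float = 6.0, report: Optional[dict] = None
) -> Iterator[RawRead]:
    """Yield reads whose mean qscore is >= ``cutoff``.

    ``report`` (if given) accumulates ``qscore_kept`` / ``qscore_dropped``
    counts for the run manifest.
    """
    kept = dropped = 0
    for read in reads:
        if mean_read_qscore(read.qualities) >= cutoff:
            kept += 1
            yield read
        else:
            dropped += 1
    if report is not None:
        report["qscore_kept"] = report.get("qscore_kept", 0) + kept
        report["qscore_dropped"] = report.get("qscore_dropped", 0) + dropped


def _align_adapter(adapter: str, window_seq: str, offset: int, end: str,
                   min_identity: float) -> Optional[AdapterHit]:
    """Best semi-global (infix) alignment of ``adapter`` inside ``window_seq``."""
    if not window_seq:
        return None
    res = edlib.align(adapter, window_seq, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0:
        return None
    identity = (len(adapter) - dist) / len(adapter)
    if identity < min_identity:
        return None
    start, last = res["locations"][0]
    return AdapterHit(end=end, position=offset + start, length=last - start + 1,
                      identity=identity)


def find_adapter(
    sequence: str,
    window: int = 200,
    adapter: str = ISPCR_ADAPTER,
    min_identity: float = 0.7,
) -> list[AdapterHit]:
    """Search both read-end windows for the PCR adapter.

    The 5' window is searched with the adapter as given; the 3' window with
    its reverse complement (the orientation the adapter takes at the far end
    of a double-stranded cDNA read).  Alignment is semi-global, so indels are
    tolerated; a hit needs >= ``min_identity`` matching over the adapter
    length.
    """
    hits: list[AdapterHit] = []
    if len(sequence) < len(adapter):
        return hits
    head = sequence[:window]
    h5 = _align_adapter(adapter, head, 0, FIVE_PRIME, min_identity)
    if h5 is not None:
        hits.append(h5)
    tail_off = max(0, len(sequence) - window)
    tail = sequence[tail_off:]
    h3 = _align_adapter(reverse_complement(adapter), tail, tail_off,
                        THREE_PRIME, min_identity)
    if h3 is not None:
        hits.append(h3)
    return hits


def _best_run(seq: str, base: str, min_len: int = 10, max_mismatch: int = 1
              ) -> Optional[tuple[int, int]]:
    """Longest run of ``base`` in ``seq`` with at most ``max_mismatch``
    interior non-matching bases.  Returns (start, length) or None.

    Sliding window over positions allowing <= max_mismatch mismatches, with
    the run trimmed so that it starts and ends on a matching base (mismatches
    must be interior).  Ties go to the run closer to the end of ``seq``.
    """
    n = len(seq)
    best: Optional[tuple[int, int]] = None
    left = 0
    mism = 0
    for right in range(n):
        if seq[right] != base:
            mism += 1
        while mism > max_mismatch:
            if seq[left] != base:
                mism -= 1
            left += 1
        # trim edges to matching bases
        lo, hi = left, right
        while lo <= hi and seq[lo] != base:
            lo += 1
        while hi >= lo and seq[hi] != base:
            hi -= 1
        length = hi - lo + 1
        if length >= min_len:
            if best is None or length > best[1] or (length == best[1] and lo > best[0]):
                best = (lo, length)
    return best


def find_polya_tail(
    sequence: str,
    window: int = 200,
    min_len: int = 10,
    max_mismatch: int = 1,
    end_anchor: int = 50,
) -> list[PolyAHit]:
    """Find polyA/polyT tails in the two end windows.

    The 3' window is scanned for a run of >= ``min_len`` A with at most one
    interior mismatch; the 5' window for a T run (a reverse-orientation read
    carries the tail as polyT at its start).  A run only qualifies as a tail
    if its outer edge lies within ``end_anchor`` bases of the read end, so
    A-rich stretches in the middle of the window are not mistaken for tails.
    """
    hits: list[PolyAHit] = []
    head = sequence[:window]
    run5 = _best_run(head, "T", min_len, max_mismatch)
    if run5 is not None and run5[0] <= end_anchor:
        hits.append(PolyAHit(end=FIVE_PRIME, start=run5[0], length=run5[1]))
    off = max(0, len(sequence) - window)
    tail = sequence[off:]
    run3 = _best_run(tail, "A", min_len, max_mismatch)
    if run3 is not None:
        start = off + run3[0]
        if len(sequence) - (start + run3[1]) <= end_anchor:
            hits.append(PolyAHit(end=THREE_PRIME, start=start, length=run3[1]))
    return hits


def classify_and_trim(
    read: RawRead,
    window: int = 200,
    min_identity: float = 0.7,
    min_length: int = 50,
    adapter: str = ISPCR_ADAPTER,
) -> Optional[ProcessedRead]:
    """Trim adapters and polyA tails off the read ends and call full-length.

    A read is full-length iff an adapter was detected at one end and a polyA
    tail at the other.  Reads with neither feature are kept untrimmed but
    flagged not full-length.  Returns ``None`` when trimming would leave
    fewer than ``min_length`` bases (the caller logs the drop).
    """
    seq = read.sequence
    adapters = find_adapter(seq, window=window, adapter=adapter,
                            min_identity=min_identity)
    tails = find_polya_tail(seq, window=window)
    ad5 = next((h for h in adapters if h.end == FIVE_PRIME), None)
    ad3 = next((h for h in adapters if h.end == THREE_PRIME), None)
    pa5 = next((h for h in tails if h.end == FIVE_PRIME), None)
    pa3 = next((h for h in tails if h.end == THREE_PRIME), None)

    start = 0
    if ad5 is not None:
        start = max(start, ad5.position + ad5.length)
    if pa5 is not None:
        start = max(start, pa5.start + pa5.length)
    end = len(seq)
    if ad3 is not None:
        end = min(end, ad3.position)
    if pa3 is not None:
        end = min(end, pa3.start)
    if end - start < min_length:
        return None

    full_length = (ad5 is not None and pa3 is not None) or (
        ad3 is not None and pa5 is not None
    )
    polya = pa3 if pa3 is not None else pa5
    return ProcessedRead(
        read_id=read.read_id,
        trimmed_sequence=seq[start:end],
        trimmed_qualities=tuple(read.qualities[start:end]),
        mean_qscore=mean_read_qscore(read.qualities),
        adapter_hits=[h for h in (ad5, ad3) if h is not None],
        polya_hit=polya,
        is_full_length=full_length,
        trim_start=start,
        trim_end=end,
    )


# ---------------------------------------------------------------------------
# FASTQ I/O

def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[RawRead]:
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            read_id = title.split()[0]
            yield RawRead(read_id, seq.upper(),
                          tuple(ord(c) - 33 for c in qual))


def preprocess_fastq(
    fastq_path,
    out_fastq=None,
    out_tsv=None,
    qscore_cutoff: float = 6.0,
    window: int = 200,
    min_identity: float = 0.7,
    min_length: int = 50,
    report: Optional[dict] = None,
) -> list[ProcessedRead]:
    """Run the whole read-level stage on one FASTQ file.

    Writes the trimmed FASTQ and a per-read TSV when output paths are given,
    and returns the processed reads.
    """
    if report is None:
        report = {}
    processed: list[ProcessedRead] = []
    too_short = 0
    for read in filter_by_qscore(read_fastq(fastq_path), qscore_cutoff, report):
        pr = classify_and_trim(read, window=window, min_identity=min_identity,
                               min_length=min_length)
        if pr is None:
            too_short += 1
            continue
        processed.append(pr)
    report["too_short_after_trim"] = report.get("too_short_after_trim", 0) + too_short
    report["processed"] = report.get("processed", 0) + len(processed)
    report["full_length"] = report.get("full_length", 0) + sum(
        p.is_full_length for p in processed)

    if out_fastq is not None:
        with _open_text(out_fastq, "wt") as fh:
            for p in processed:
                qual = "".join(chr(q + 33) for q in p.trimmed_qualities)
                fh.write(f"@{p.read_id}\n{p.trimmed_sequence}\n+\n{qual}\n")
    if out_tsv is not None:
        with open(out_tsv, "w") as fh:
            fh.write("read_id\tmean_qscore\tfull_length\ttrim_start\ttrim_end\n")
            for p in processed:
                fh.write(
                    f"{p.read_id}\t{p.mean_qscore:.3f}\t{int(p.is_full_length)}"
                    f"\t{p.trim_start}\t{p.trim_end}\n")
    return processed


def qscore_pid_table(pairs: Iterable[tuple[float, float]], bins=None):
    """Diagnostic table of percent-identity versus mean qscore.

    ``pairs`` are (mean_qscore, percent_identity) per read.  Returns a list of
    (bin_low, n_reads, fraction with PID > 0.8) rows; used to audit the
    qscore cutoff, not to choose it automatically.
    """
    if bins is None:
        bins = list(range(0, 21))
    rows = []
    data = list(pairs)
    for lo, hi in zip(bins[:-1], bins[1:]):
        sub = [pid for q, pid in data if lo <= q < hi]
        if sub:
            rows.append((lo, len(sub), sum(p > 0.8 for p in sub) / len(sub)))
    return rows
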