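"""Barcode demultiplexing and global alignment of amplicon reads.

Implements the read-level half of the targeted bisulfite-sequencing
pipeline: exact-prefix barcode demultiplexing, end-trimming of the longer
sequence via an overlap alignment, Needleman-Wunsch global alignment under
a linear gap model, and the indel-rate read filters (default: a read is
removed when it reaches 15% insertions, 15% deletions, or 20% combined,
measured against alignment columns).

The dynamic-programming kernels are numba-jitted when numba is available
and fall back to pure Python otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

try:  # optional JIT; identical semantics without it
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=True)(func)

except ImportError:  # pragma: no cover - numba present in normal installs
    def _jit(func):
        return func


GAP = "-"
_NEG_SENTINEL = -1e308  # "no bisulfite-aware scoring" marker inside kernels

# base encoding used by the DP kernels
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


class FastqRecord(NamedTuple):
    """A minimal FASTQ record (id, sequence, per-base quality string)."""

    id: str
    seq: str
    qual: str


def encode_seq(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes for the DP kernels."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"sequence contains non-ACGTN character {bad!r}")
    return arr


@dataclass(frozen=True)
class ReferenceAmplicon:
    """Reference amplicon with indexed cytosines and one designated target.

    Parameters
    ----------
    id : str
        Sequence identifier.
    sequence : str
        Amplicon sequence (A/C/G/T/N; sense strand).
    target_position : int
        1-based position of the candidate m5C site; must hold a C.
    coordinate_offset : int
        Added to 1-based local positions when reporting absolute rRNA
        coordinates (e.g. so the yeast target prints as 2278).
    """

    id: str
    sequence: str
    target_position: int
    coordinate_offset: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        encode_seq(self.sequence)  # validates alphabet
        if not (1 <= self.target_position <= len(self.sequence)):
            raise ValueError(
                f"target_position {self.target_position} outside reference "
                f"of length {len(self.sequence)}"
            )
        if self.sequence[self.target_position - 1].upper() != "C":
            raise ValueError(
                f"target_position {self.target_position} holds "
                f"{self.sequence[self.target_position - 1]!r}, expected 'C'"
            )

    @property
    def c_positions(self) -> tuple[int, ...]:
        """Ordered 1-based positions where the reference base is C."""
        return tuple(
            i + 1 for i, b in enumerate(self.sequence.upper()) if b == "C"
        )

    def absolute(self, local_position: int) -> int:
        """Map a 1-based local position to absolute rRNA coordinates."""
        return local_position + self.coordinate_offset


@dataclass(frozen=True)
class ScoringScheme:
    """Linear-gap scoring for global alignment.

    ``c_t_match_as`` optionally rescores a read T aligned to a reference C
    (the bisulfite conversion signal); ``None`` scores it as a mismatch,
    which is the default because the counting stage interprets conversion.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    c_t_match_as: float | None = None

    def __post_init__(self):
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not self.gap < 0:
            raise ValueError("gap score must be negative")

    @property
    def _ct(self) -> float:
        return _NEG_SENTINEL if self.c_t_match_as is None else self.c_t_match_as


@dataclass(frozen=True)
class FilterThresholds:
    """Indel-fraction read filters.

    A read passes only if its insertion fraction, deletion fraction and
    combined indel fraction are each strictly below the corresponding
    threshold (``rule="all"``). ``rule="any"`` keeps a read that satisfies
    any single bound, the literal disjunctive reading, which is available
    but not the default because it removes almost nothing.
    ``denominator`` chooses between alignment columns and read length.
    """

    max_ins_fraction: float = 0.15
    max_del_fraction: float = 0.15
    max_indel_fraction: float = 0.20
    rule: str = "all"
    denominator: str = "columns"

    def __post_init__(self):
        for v in (self.max_ins_fraction, self.max_del_fraction, self.max_indel_fraction):
            if not 0 < v <= 1:
                raise ValueError("thresholds must lie in (0, 1]")
        if self.rule not in ("all", "any"):
            raise ValueError("rule must be 'all' or 'any'")
        if self.denominator not in ("columns", "read"):
            raise ValueError("denominator must be 'columns' or 'read'")


@dataclass
class AlignedRead:
    """A read's global alignment to the (possibly trimmed) reference.

    ``ref_start`` is the 0-based offset of the aligned reference slice
    within the full amplicon, so column positions can be mapped back after
    end-trimming. ``n_insertions`` counts read bases over reference gaps;
    ``n_deletions`` counts reference bases over read gaps.
    """

    read_id: str
    aligned_query: str
    aligned_reference: str
    score: float
    n_insertions: int
    n_deletions: int
    n_columns: int
    ref_start: int = 0
    passed_filter: bool | None = None

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_reference):
            raise ValueError("aligned strings differ in length")
        if len(self.aligned_query) != self.n_columns:
            raise ValueError("n_columns inconsistent with aligned strings")


class DemuxResult(NamedTuple):
    assigned: dict[str, list[FastqRecord]]
    unassigned: list[FastqRecord]


def demultiplex(
    reads: Iterable[FastqRecord], barcode_table: dict[str, str]
) -> DemuxResult:
    """Sort reads by exact full-barcode prefix and strip the barcode.

    A read is assigned to a sample iff its prefix equals that sample's
    complete barcode; reads with truncated or mismatching barcodes go to
    the unassigned bin untouched.
    """
    barcodes = list(barcode_table.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcode table")
    by_barcode = {bc: sample for sample, bc in barcode_table.items()}
    assigned: dict[str, list[FastqRecord]] = {s: [] for s in barcode_table}
    unassigned: list[FastqRecord] = []
    for read in reads:
        for bc, sample in by_barcode.items():
            if read.seq.startswith(bc):
                n = len(bc)
                assigned[sample].append(
                    FastqRecord(read.id, read.seq[n:], read.qual[n:])
                )
                break
        else:
            unassigned.append(read)
    return DemuxResult(assigned, unassigned)


# ---------------------------------------------------------------------------
# Needleman-Wunsch dynamic programming
# ---------------------------------------------------------------------------
#
# H[i, j] scores q[:i] against r[:j]. Traceback pointers: 1 = diagonal,
# 2 = reference base over query gap (deletion), 3 = query base over
# reference gap (insertion). Ties resolve diagonal > deletion > insertion,
# which makes the traceback deterministic.

def _fill_impl(q, r, match, mismatch, gap, ct, free_q_ends, free_r_ends):
    m = q.shape[0]
    n = r.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    P = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for i in range(1, m + 1):
        if not free_q_ends:
            H[i, 0] = H[i - 1, 0] + gap
        P[i, 0] = 3
    for j in range(1, n + 1):
        if not free_r_ends:
            H[0, j] = H[0, j - 1] + gap
        P[0, j] = 2
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            rj = r[j - 1]
            if qi == rj and qi != 4:  # N never matches
                s = match
            elif rj == 1 and qi == 3 and ct > -1e300:
                s = ct
            else:
                s = mismatch
            best = H[i - 1, j - 1] + s
            ptr = 1
            dele = H[i, j - 1] + gap
            if dele > best:
                best = dele
                ptr = 2
            ins = H[i - 1, j] + gap
            if ins > best:
                best = ins
                ptr = 3
            H[i, j] = best
            P[i, j] = ptr
    return H, P


_fill = _jit(_fill_impl)


def _traceback(P, q, r, i, j):
    """Walk pointers from (i, j) to (0, 0); return aligned strings."""
    aq: list[str] = []
    ar: list[str] = []
    while i > 0 or j > 0:
        ptr = P[i, j]
        if ptr == 1:
            aq.append(q[i - 1])
            ar.append(r[j - 1])
            i -= 1
            j -= 1
        elif ptr == 2:
            aq.append(GAP)
            ar.append(r[j - 1])
            j -= 1
        else:
            aq.append(q[i - 1])
            ar.append(GAP)
            i -= 1
    return "".join(reversed(aq)), "".join(reversed(ar))


def global_align(
    query: str,
    reference: str,
    scoring: ScoringScheme = ScoringScheme(),
    read_id: str = "",
    ref_start: int = 0,
) -> AlignedRead:
    """Optimal global (Needleman-Wunsch) alignment under linear gaps.

    The score is maximal over all global alignments; the traceback is
    deterministic (diagonal preferred over deletion over insertion).
    """
    if not query or not reference:
        raise ValueError("cannot align an empty sequence")
    q = encode_seq(query)
    r = encode_seq(reference)
    H, P = _fill(
        q, r, scoring.match, scoring.mismatch, scoring.gap, scoring._ct,
        False, False,
    )
    aq, ar = _traceback(P, query, reference, len(query), len(reference))
    n_ins = ar.count(GAP)
    n_del = aq.count(GAP)
    return AlignedRead(
        read_id=read_id,
        aligned_query=aq,
        aligned_reference=ar,
        score=float(H[len(query), len(reference)]),
        n_insertions=n_ins,
        n_deletions=n_del,
        n_columns=len(aq),
        ref_start=ref_start,
    )


class TrimResult(NamedTuple):
    query: str
    reference: str
    ref_start: int  # 0-based offset of trimmed reference in the original
    alignable: bool


def trim_for_alignment(
    query: str, reference: str, scoring: ScoringScheme = ScoringScheme()
) -> TrimResult:
    """Trim the longer sequence's overhangs before global alignment.

    An end-gap-free (overlap) pass locates the best placement of the
    shorter sequence within the longer one; bases of the longer sequence
    outside that span are removed. If no overlap scores above 0 the read
    is reported unalignable.
    """
    if not query or not reference:
        raise ValueError("cannot trim an empty sequence")
    if len(query) == len(reference):
        return TrimResult(query, reference, 0, True)
    q = encode_seq(query)
    r = encode_seq(reference)
    args = (scoring.match, scoring.mismatch, scoring.gap, scoring._ct)
    if len(reference) > len(query):
        H, P = _fill(q, r, *args, False, True)
        last = H[len(query), :]
        j_end = int(len(last) - 1 - np.argmax(last[::-1]))  # rightmost max
        if last[j_end] <= 0:
            return TrimResult(query, reference, 0, False)
        i, j = len(query), j_end
        while i > 0:
            ptr = P[i, j]
            if ptr == 1:
                i -= 1
                j -= 1
            elif ptr == 2:
                j -= 1
            else:
                i -= 1
        return TrimResult(query, reference[j:j_end], j, True)
    # query longer: trim query overhangs instead
    H, P = _fill(q, r, *args, True, False)
    last = H[:, len(reference)]
    i_end = int(len(last) - 1 - np.argmax(last[::-1]))
    if last[i_end] <= 0:
        return TrimResult(query, reference, 0, False)
    i, j = i_end, len(reference)
    while j > 0:
        ptr = P[i, j]
        if ptr == 1:
            i -= 1
            j -= 1
        elif ptr == 2:
            j -= 1
        else:
            i -= 1
    return TrimResult(query[i:i_end], reference, 0, True)


def filter_by_indels(
    aln: AlignedRead, thr: FilterThresholds = FilterThresholds()
) -> AlignedRead:
    """Set ``passed_filter`` from the indel-fraction thresholds.

    Comparisons are strict: a read at exactly 15% insertions is removed.
    """
    if aln.n_columns <= 0:
        raise ValueError("alignment has no columns")
    if thr.denominator == "columns":
        denom = aln.n_columns
    else:
        denom = len(aln.aligned_query.replace(GAP, ""))
    ins_frac = aln.n_insertions / denom
    del_frac = aln.n_deletions / denom
    both_frac = (aln.n_insertions + aln.n_deletions) / denom
    checks = (
        ins_frac < thr.max_ins_fraction,
        del_frac < thr.max_del_fraction,
        both_frac < thr.max_indel_fraction,
    )
    aln.passed_filter = all(checks) if thr.rule == "all" else any(checks)
    return aln


def align_read(
    read: FastqRecord,
    ref: ReferenceAmplicon,
    scoring: ScoringScheme = ScoringScheme(),
    thresholds: FilterThresholds = FilterThresholds(),
) -> AlignedRead | None:
    """Trim, globally align and filter one demultiplexed read.

    Returns ``None`` when the trimming pass finds no positive-scoring
    overlap (the read is counted as unalignable upstream).
    """
    trimmed = trim_for_alignment(read.seq, ref.sequence, scoring)
    if not trimmed.alignable:
        return None
    aln = global_align(
        trimmed.query, trimmed.reference, scoring,
        read_id=read.id, ref_start=trimmed.ref_start,
    )
    return filter_by_indels(aln, thresholds)
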