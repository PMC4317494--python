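"""Per-cytosine conversion counting and target methylation calling.

After bisulfite conversion, an unmethylated C reads as T and an m5C reads
as C. At every reference-C alignment column we count read Cs and Ts; the
per-site C fraction at the designated target estimates methylation, and
the unweighted mean fraction over all *other* C sites estimates the
sample's conversion-failure background, which is subtracted from the raw
target fraction. Grubbs' outlier test then asks whether the target site
stands out among all cytosines of the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon_align import GAP, AlignedRead, ReferenceAmplicon


@dataclass
class SiteMethylationTable:
    """Per-C-position conversion counts for one sample.

    ``counts`` is indexed by 1-based local reference position, with columns
    ``c`` (reads showing C), ``t`` (reads showing T), ``other`` (gap or any
    other base), ``coverage`` (= c + t) and ``fraction`` (= c / coverage,
    NaN where uncovered). Gaps and non-C/T bases carry no conversion
    information and are excluded from the fraction denominator.
    """

    sample_id: str
    counts: pd.DataFrame

    def fraction(self, position: int) -> float:
        return float(self.counts.loc[position, "fraction"])

    def coverage(self, position: int) -> int:
        return int(self.counts.loc[position, "coverage"])


@dataclass
class MethylationCall:
    """Background-corrected methylation estimate at the target site."""

    sample_id: str
    target_position: int           # absolute rRNA coordinate
    raw_fraction: float
    background_rate: float
    corrected_value: float         # may be negative; reported as-is
    grubbs_statistic: float = float("nan")
    grubbs_critical: float = float("nan")
    is_outlier: bool | None = None
    alpha: float = 0.01


def count_conversion(
    alignments: list[AlignedRead],
    ref: ReferenceAmplicon,
    sample_id: str = "",
) -> SiteMethylationTable:
    """Count C/T (and other) read bases at every reference-C column.

    Only alignments with ``passed_filter`` True contribute. A read base C
    increments ``c``, T increments ``t``; gaps and any other base increment
    ``other`` only, leaving coverage untouched.
    """
    c_pos = np.asarray(ref.c_positions, dtype=np.int64)
    n_sites = c_pos.size
    # slot lookup: 1-based reference position -> row in the count arrays
    slot_of = np.full(len(ref.sequence) + 1, -1, dtype=np.int64)
    slot_of[c_pos] = np.arange(n_sites)
    c_arr = np.zeros(n_sites, dtype=np.int64)
    t_arr = np.zeros(n_sites, dtype=np.int64)
    other_arr = np.zeros(n_sites, dtype=np.int64)
    gap_code = ord(GAP)
    n_used = 0
    for aln in alignments:
        if not aln.passed_filter:
            continue
        n_used += 1
        ar = np.frombuffer(aln.aligned_reference.upper().encode(), np.uint8)
        aq = np.frombuffer(aln.aligned_query.upper().encode(), np.uint8)
        not_gap = ar != gap_code
        ref_pos = np.cumsum(not_gap) + aln.ref_start  # 1-based at ref columns
        slots = slot_of[ref_pos]
        sel = not_gap & (slots >= 0)
        qb = aq[sel]
        slots = slots[sel]
        np.add.at(c_arr, slots[qb == ord("C")], 1)
        np.add.at(t_arr, slots[qb == ord("T")], 1)
        np.add.at(other_arr, slots[(qb != ord("C")) & (qb != ord("T"))], 1)
    if n_used == 0:
        warnings.warn(
            f"sample {sample_id!r}: no passing alignments; all coverage 0",
            stacklevel=2,
        )
    coverage = c_arr + t_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(coverage > 0, c_arr / np.maximum(coverage, 1), np.nan)
    tab = pd.DataFrame(
        {
            "c": c_arr,
            "t": t_arr,
            "other": other_arr,
            "coverage": coverage,
            "fraction": fraction,
        },
        index=pd.Index(c_pos, name="position"),
    )
    return SiteMethylationTable(sample_id=sample_id, counts=tab)


def background_rate(
    table: SiteMethylationTable,
    excluded: set[int] = frozenset(),
    min_coverage: int = 10,
) -> float:
    """Mean per-position non-conversion rate over presumed-unmethylated Cs.

    The average is unweighted over positions (each covered site contributes
    its own fraction once, regardless of depth), matching a per-position
    rather than pooled-count estimate. Sites in ``excluded`` (normally just
    the target) and sites below ``min_coverage`` are ignored.
    """
    tab = table.counts
    mask = (~tab.index.isin(list(excluded))) & (tab["coverage"] >= max(min_coverage, 1))
    if not mask.any():
        raise ValueError(
            "no covered non-excluded C position to estimate background from"
        )
    return float(tab.loc[mask, "fraction"].mean())


def corrected_methylation(
    table: SiteMethylationTable,
    target: int,
    background: float,
    coordinate_offset: int = 0,
) -> MethylationCall:
    """Raw target C fraction minus the sample background rate."""
    if table.coverage(target) == 0:
        raise ValueError(f"target position {target} has zero coverage")
    raw = table.fraction(target)
    return MethylationCall(
        sample_id=table.sample_id,
        target_position=target + coordinate_offset,
        raw_fraction=raw,
        background_rate=background,
        corrected_value=raw - background,
    )


def grubbs_test(
    values: np.ndarray | list[float],
    alpha: float,
    target_index: int,
    two_sided: bool = False,
) -> tuple[float, float, bool]:
    """One-sided upper-tail Grubbs test for a single high outlier.

    G = (max - mean) / sd; the critical value is
    ((N-1)/sqrt(N)) * sqrt(t^2 / (N-2+t^2)) with t the upper alpha/N
    (alpha/(2N) if ``two_sided``) quantile of Student's t on N-2 df. The
    target is called an outlier only if it is itself the maximum and
    G exceeds the critical value.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Grubbs test degenerate: zero standard deviation")
    g = float((x.max() - x.mean()) / sd)
    level = alpha / (2 * n) if two_sided else alpha / n
    t = stats.t.ppf(1 - level, n - 2)
    g_crit = float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))
    is_outlier = bool(g > g_crit and int(np.argmax(x)) == target_index)
    return g, g_crit, is_outlier


def call_methylation(
    table: SiteMethylationTable,
    ref: ReferenceAmplicon,
    alpha: float = 0.01,
    min_coverage: int = 10,
    two_sided: bool = False,
) -> MethylationCall:
    """Full per-sample call: background, corrected value, Grubbs test.

    The Grubbs test runs on the raw C fractions of all covered C positions
    (target included); it is reported only when at least three sites have
    coverage and the fractions are not all identical.
    """
    target = ref.target_position
    bg = background_rate(table, excluded={target}, min_coverage=min_coverage)
    call = corrected_methylation(
        table, target, bg, coordinate_offset=ref.coordinate_offset
    )
    call.alpha = alpha
    tab = table.counts
    covered = tab[tab["coverage"] > 0]
    if len(covered) >= 3 and covered["fraction"].nunique() > 1:
        target_idx = int(np.flatnonzero(covered.index == target)[0])
        g, g_crit, flag = grubbs_test(
            covered["fraction"].to_numpy(), alpha, target_idx, two_sided
        )
        call.grubbs_statistic = g
        call.grubbs_critical = g_crit
        call.is_outlier = flag
    return call
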