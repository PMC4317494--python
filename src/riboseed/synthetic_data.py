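"""Synthetic data generators with known ground truth.

Two generators drive the test suite and worked examples:

* :func:`simulate_bisulfite_reads` emulates single-end, barcoded,
  IonTorrent-like amplicon reads after bisulfite conversion: at each
  reference cytosine the emitted base is C with probability
  ``m * (1 - conversion_on_methylated) + (1 - m) * conversion_failure``
  (``m`` the site's true methylation level), then substitution errors and
  homopolymer-weighted indels are applied and a (possibly truncated)
  sample barcode is prepended.

* :func:`simulate_expression_experiment` emulates paired two-channel
  log2 expression data (transcriptome / translatome from the same lysate),
  with per-gene residual standard deviations drawn from a scaled
  inverse-chi-square prior so the empirical-Bayes variance model holds
  exactly by construction.

Both are deterministic for a fixed seed and return a ground-truth table
alongside the data, enabling parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon_align import FastqRecord, ReferenceAmplicon, encode_seq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_QUALITY_CHAR = "I"  # Sanger Q40

# Synthetic 122-nt amplicon mimicking the targeted 25S rRNA stretch: the
# single m5C site sits at local position 62, and coordinate_offset is set
# so that it reports as 2278 in 25S numbering.
YEAST_LIKE_SEQUENCE = (
    "GGTAGCCAAATGCCTCGTCATCTAATTAGTGACGCGCATGAATGGATTAACGAGATTCCCA"
    "CTGTCCCTATCTACTATCTAGCGAAACCACAGCCAAGGGAACGGGCTTGGCAGAATCAGCG"
)
YEAST_LIKE_TARGET = 62
YEAST_LIKE_OFFSET = 2278 - YEAST_LIKE_TARGET


def make_toy_reference(
    sequence: str,
    target_position: int,
    id: str = "amplicon",
    coordinate_offset: int = 0,
) -> ReferenceAmplicon:
    """Build a reference amplicon, validating that the target holds a C."""
    return ReferenceAmplicon(
        id=id,
        sequence=sequence.upper(),
        target_position=target_position,
        coordinate_offset=coordinate_offset,
    )


def yeast_like_reference() -> ReferenceAmplicon:
    """The package's default synthetic rRNA-amplicon reference."""
    return make_toy_reference(
        YEAST_LIKE_SEQUENCE, YEAST_LIKE_TARGET,
        id="synthetic_25S_amplicon", coordinate_offset=YEAST_LIKE_OFFSET,
    )


@dataclass(frozen=True)
class MethylationProfile:
    """True per-site methylation and bisulfite conversion behaviour.

    ``probabilities`` maps 1-based reference positions (which must hold C)
    to methylation probability; unlisted C positions are unmethylated.
    ``conversion_failure`` is the probability that an unmethylated C
    survives conversion (the assay background); ``conversion_on_methylated``
    the probability that a true m5C is nonetheless converted to T.
    """

    probabilities: dict[int, float] = field(default_factory=dict)
    conversion_failure: float = 0.01
    conversion_on_methylated: float = 0.0

    def __post_init__(self):
        for pos, p in self.probabilities.items():
            if not 0 <= p <= 1:
                raise ValueError(f"methylation probability at {pos} outside [0,1]")
        for name in ("conversion_failure", "conversion_on_methylated"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0,1]")


@dataclass(frozen=True)
class ReadErrorModel:
    """Sequencer error and barcode model for simulated amplicon reads.

    Indels are placed uniformly per base; ``homopolymer_multiplier``
    optionally inflates the indel rate inside homopolymer runs (length
    >= 2), a coarse nod to flow-based chemistry.
    """

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    barcode: str = ""
    barcode_truncation_prob: float = 0.0
    homopolymer_multiplier: float = 1.0

    def __post_init__(self):
        for name in (
            "substitution_rate", "insertion_rate", "deletion_rate",
            "barcode_truncation_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0,1]")
        if self.homopolymer_multiplier < 0:
            raise ValueError("homopolymer_multiplier must be >= 0")
        if self.barcode:
            encode_seq(self.barcode)


def _homopolymer_weights(seq: str, multiplier: float) -> np.ndarray:
    """Per-position indel-rate multiplier (``multiplier`` inside runs)."""
    w = np.ones(len(seq))
    if multiplier == 1.0:
        return w
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        if j > i:
            w[i : j + 1] = multiplier
        i = j + 1
    return w


def simulate_bisulfite_reads(
    ref: ReferenceAmplicon,
    profile: MethylationProfile,
    error: ReadErrorModel,
    n_reads: int,
    seed: int,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Simulate bisulfite-converted amplicon reads with ground truth.

    Returns FASTQ records (constant quality) and a truth table with one
    row per read: the pre-error emitted base at every reference C position
    (columns ``pos_<p>``), the true inserted/deleted base counts, and
    whether the barcode was truncated.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    bad = [p for p in profile.probabilities if
           not (1 <= p <= len(ref.sequence)) or ref.sequence[p - 1] != "C"]
    if bad:
        raise ValueError(
            f"methylation profile keys non-C position(s): {sorted(bad)}"
        )
    rng = np.random.default_rng(seed)
    L = len(ref.sequence)
    seq_codes = encode_seq(ref.sequence)
    c_pos = np.asarray(ref.c_positions, dtype=np.int64)  # 1-based
    m = np.array([profile.probabilities.get(int(p), 0.0) for p in c_pos])
    p_c = m * (1 - profile.conversion_on_methylated) + (1 - m) * profile.conversion_failure

    # conversion outcomes at every C, all reads at once (pre-error truth)
    emit_c = rng.random((n_reads, c_pos.size)) < p_c
    base_mat = np.tile(seq_codes, (n_reads, 1))
    col = c_pos - 1
    base_mat[:, col] = np.where(emit_c, 1, 3)  # C=1, T=3

    # substitution errors: replace with one of the three other bases
    if error.substitution_rate > 0:
        sub = rng.random((n_reads, L)) < error.substitution_rate
        shift = rng.integers(1, 4, size=(n_reads, L), dtype=np.uint8)
        base_mat = np.where(sub, (base_mat + shift) % 4, base_mat)
        n_sub = sub.sum(axis=1)
    else:
        n_sub = np.zeros(n_reads, dtype=np.int64)

    hp = _homopolymer_weights(ref.sequence, error.homopolymer_multiplier)
    ins_p = np.clip(error.insertion_rate * hp, 0, 1)
    del_p = np.clip(error.deletion_rate * hp, 0, 1)
    ins_mask = (
        rng.random((n_reads, L)) < ins_p if error.insertion_rate > 0
        else np.zeros((n_reads, L), dtype=bool)
    )
    del_mask = (
        rng.random((n_reads, L)) < del_p if error.deletion_rate > 0
        else np.zeros((n_reads, L), dtype=bool)
    )
    ins_bases = rng.integers(0, 4, size=(n_reads, L), dtype=np.uint8)

    bc = error.barcode
    if bc and error.barcode_truncation_prob > 0:
        truncated = rng.random(n_reads) < error.barcode_truncation_prob
        n_dropped = np.where(
            truncated, rng.integers(1, len(bc) + 1, size=n_reads), 0
        )
    else:
        truncated = np.zeros(n_reads, dtype=bool)
        n_dropped = np.zeros(n_reads, dtype=np.int64)

    idx2b = "ACGT"
    char_mat = _BASES[base_mat]  # n_reads x L uint8 of ASCII codes
    any_indel = ins_mask.any(axis=1) | del_mask.any(axis=1)
    reads: list[FastqRecord] = []
    rows = []
    for i in range(n_reads):
        if any_indel[i]:
            codes = base_mat[i]
            chars = []
            for j in range(L):
                if ins_mask[i, j]:  # inserted base precedes position j
                    chars.append(idx2b[ins_bases[i, j]])
                if not del_mask[i, j]:
                    chars.append(idx2b[codes[j]])
            payload = "".join(chars)
        else:
            payload = char_mat[i].tobytes().decode("ascii")
        seq = bc[int(n_dropped[i]):] + payload if bc else payload
        read_id = f"read_{i:06d}"
        reads.append(FastqRecord(read_id, seq, DEFAULT_QUALITY_CHAR * len(seq)))
        row = {
            "read": read_id,
            "n_insertions_true": int(ins_mask[i].sum()),
            "n_deletions_true": int(del_mask[i].sum()),
            "n_substitutions_true": int(n_sub[i]),
            "barcode_truncated": bool(truncated[i]),
        }
        for k, p in enumerate(c_pos):
            row[f"pos_{int(p)}"] = "C" if emit_c[i, k] else "T"
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("read")
    return reads, truth


@dataclass(frozen=True)
class ExpressionTruth:
    """Latent structure of a paired transcriptome/translatome experiment.

    ``te_effects`` holds the true per-gene log2 translational-efficiency
    shifts (genes not listed have effect 0). Per-gene residual standard
    deviations are drawn from the scaled inverse-chi-square prior
    ``s0 * sqrt(d0 / chi2_d0)`` shared by both channels, unless
    ``fixed_noise_sd`` overrides them. ``pair_effect_sd`` scales a shared
    additive effect per gene and lysate pair, modelling that both channels
    of a pair derive from the same lysate.
    """

    te_effects: dict[str, float] = field(default_factory=dict)
    d0: float = 4.0
    s0: float = 0.25
    fixed_noise_sd: float | None = None
    n_replicates: int = 2
    pair_effect_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (variance undefined)")
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")
        for name in ("s0", "pair_effect_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fixed_noise_sd is not None and self.fixed_noise_sd < 0:
            raise ValueError("fixed_noise_sd must be >= 0")


def simulate_expression_experiment(
    truth: ExpressionTruth,
    n_genes: int,
    seed: int,
    condition: str = "cond",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a paired log2 expression matrix plus ground truth.

    Columns are named ``<condition>|<channel>|r<k>`` with channels
    ``transcriptome`` and ``translatome``; samples sharing ``r<k>`` form a
    lysate pair. The truth table holds each gene's true log2 TE, residual
    sd and baseline.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    te = np.array([truth.te_effects.get(g, 0.0) for g in genes])
    baseline = rng.normal(truth.baseline_mean, truth.baseline_sd, n_genes)
    if truth.fixed_noise_sd is not None:
        sd = np.full(n_genes, truth.fixed_noise_sd)
    elif np.isinf(truth.d0):
        sd = np.full(n_genes, truth.s0)
    else:
        chi2 = rng.chisquare(truth.d0, n_genes)
        sd = truth.s0 * np.sqrt(truth.d0 / chi2)
    n_rep = truth.n_replicates
    data = {}
    for r in range(1, n_rep + 1):
        pair = rng.normal(0.0, truth.pair_effect_sd, n_genes)
        tx = baseline + pair + rng.normal(0.0, 1.0, n_genes) * sd
        tl = baseline + pair + te + rng.normal(0.0, 1.0, n_genes) * sd
        data[f"{condition}|transcriptome|r{r}"] = tx
        data[f"{condition}|translatome|r{r}"] = tl
    matrix = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    truth_tab = pd.DataFrame(
        {"true_log2_te": te, "residual_sd": sd, "baseline": baseline},
        index=pd.Index(genes, name="gene"),
    )
    return matrix, truth_tab
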