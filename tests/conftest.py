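import numpy as np
import pytest

from riboseed import (
    AlignedRead,
    MethylationProfile,
    ReadErrorModel,
    yeast_like_reference,
)


@pytest.fixture(scope="session")
def ref():
    return yeast_like_reference()


@pytest.fixture()
def clean_profile(ref):
    """Truth 0.8 at the target, 1% conversion failure, no sequencing error."""
    return MethylationProfile(
        probabilities={ref.target_position: 0.8}, conversion_failure=0.01
    )


@pytest.fixture()
def no_error_model():
    return ReadErrorModel()


def make_alignment(n_cols, n_ins, n_del, read_id="r"):
    """Construct an AlignedRead with exactly the given indel counts."""
    assert n_ins + n_del <= n_cols
    aq = "A" * n_ins + "-" * n_del + "A" * (n_cols - n_ins - n_del)
    ar = "-" * n_ins + "A" * n_del + "A" * (n_cols - n_ins - n_del)
    return AlignedRead(
        read_id=read_id,
        aligned_query=aq,
        aligned_reference=ar,
        score=0.0,
        n_insertions=n_ins,
        n_deletions=n_del,
        n_columns=n_cols,
    )


def brute_force_nw(query, reference, match, mismatch, gap, memo=None):
    """Independent top-down recursion over all global alignments."""
    if memo is None:
        memo = {}
    key = (len(query), len(reference))
    if key in memo:
        return memo[key]
    if not query:
        best = gap * len(reference)
    elif not reference:
        best = gap * len(query)
    else:
        sub = match if query[-1] == reference[-1] else mismatch
        best = max(
            brute_force_nw(query[:-1], reference[:-1], match, mismatch, gap, memo) + sub,
            brute_force_nw(query[:-1], reference, match, mismatch, gap, memo) + gap,
            brute_force_nw(query, reference[:-1], match, mismatch, gap, memo) + gap,
        )
    memo[key] = best
    return best


def random_sequences(rng, n_pairs, max_len=8, min_len=1):
    out = []
    for _ in range(n_pairs):
        la = rng.integers(min_len, max_len + 1)
        lb = rng.integers(min_len, max_len + 1)
        a = "".join(rng.choice(list("ACGT"), la))
        b = "".join(rng.choice(list("ACGT"), lb))
        out.append((a, b))
    return out
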