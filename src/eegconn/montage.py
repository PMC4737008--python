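"""19-channel 10-20 montage and the upper-triangle feature index map.

The brain network has one node per electrode. The 19x19 correlation matrix is
symmetric, so its strict upper triangle is flattened row-major into a single
171-element feature vector. Feature indices are 1-based in every user-facing
table; montage positions are likewise 1-based (F7 is position 11, T3 is 13,
so the F7-T3 edge is feature #137).
"""

from __future__ import annotations

from typing import Sequence, Tuple

#: Canonical electrode order. Midline electrodes come last, Cz before Fz:
#: this is the only ordering consistent with the published feature indices
#: (e.g. #154 = T3-Cz, #155 = T3-Fz, #167 = T6-Fz).
MONTAGE_1020: Tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Cz", "Fz", "Pz",
)

N_CHANNELS = len(MONTAGE_1020)
N_PAIRS = N_CHANNELS * (N_CHANNELS - 1) // 2  # 171


def pair_to_index(i: int, j: int, n: int = N_CHANNELS) -> int:
    """Map a montage position pair (1-based, i < j) to its 1-based feature index.

    Row-major strict-upper-triangle order: (1,2)->1, (1,3)->2, ...,
    (1,19)->18, (2,3)->19, ..., (18,19)->171.
    """
    if not (1 <= i < j <= n):
        raise ValueError(f"need 1 <= i < j <= {n}, got ({i}, {j})")
    # rows above i contribute (n-1) + (n-2) + ... + (n-i+1) features
    return (i - 1) * n - i * (i - 1) // 2 + (j - i)


def index_to_pair(k: int, n: int = N_CHANNELS) -> Tuple[int, int]:
    """Inverse of :func:`pair_to_index` (both 1-based)."""
    n_pairs = n * (n - 1) // 2
    if not (1 <= k <= n_pairs):
        raise ValueError(f"feature index {k} outside 1..{n_pairs}")
    i = 1
    remaining = k
    while remaining > n - i:
        remaining -= n - i
        i += 1
    return i, i + remaining


def pair_label(i: int, j: int, montage: Sequence[str] = MONTAGE_1020) -> str:
    """Human-readable edge label, e.g. ``pair_label(11, 13) == 'F7-T3'``."""
    return f"{montage[i - 1]}-{montage[j - 1]}"


def label_to_pair(label: str, montage: Sequence[str] = MONTAGE_1020) -> Tuple[int, int]:
    """Parse an 'F7-T3'-style label into sorted 1-based montage positions."""
    a, b = label.split("-")
    order = {name: pos for pos, name in enumerate(montage, start=1)}
    try:
        i, j = order[a], order[b]
    except KeyError as exc:
        raise ValueError(f"unknown channel label in {label!r}") from exc
    if i == j:
        raise ValueError(f"self-pair {label!r}")
    return (i, j) if i < j else (j, i)


def feature_names(montage: Sequence[str] = MONTAGE_1020) -> Tuple[str, ...]:
    """All pair labels in feature-index order (length 171 for 19 channels)."""
    n = len(montage)
    return tuple(
        pair_label(i, j, montage) for i in range(1, n + 1) for j in range(i + 1, n + 1)
    )
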