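"""Seven-level db4 discrete wavelet decomposition and named-band reconstruction.

Each 1024-sample epoch channel is decomposed into detail components D1..D7 and
the final approximation A7 (Daubechies-4, periodized boundary handling,
which keeps the transform exactly orthogonal on 1024-sample epochs). Each
subband is returned as a full-length reconstruction — the inverse transform
with every other level's coefficients zeroed — so subbands stay time-aligned
across channels and Pearson correlation applies directly.

Band naming follows the clinical convention used throughout the analysis:

    delta -> A7,  theta -> D7,  alpha -> D6,  beta -> D5

At fs = 512 Hz the dyadic subband ranges are A7: 0-2, D7: 2-4, D6: 4-8,
D5: 8-16 Hz, which sit below the nominal clinical edges (delta 0-4, theta 4-8,
alpha 8-13, beta 13-20 Hz). The named mapping is applied verbatim as in the
original analysis; :func:`dyadic_range_hz` reports the actual Hz ranges so run
reports can document the discrepancy.
"""

from __future__ import annotations

from typing import Dict, Iterable, Tuple

import numpy as np
import pywt

from .preprocess import EpochSet

#: subband assigned to each clinical band name
SUBBAND_OF_BAND: Dict[str, str] = {"delta": "A7", "theta": "D7", "alpha": "D6", "beta": "D5"}

DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 7
DEFAULT_MODE = "periodization"


def subband_names(levels: int = DEFAULT_LEVELS) -> Tuple[str, ...]:
    """('A7', 'D7', 'D6', ..., 'D1') — coarse to fine, matching wavedec order."""
    return (f"A{levels}",) + tuple(f"D{k}" for k in range(levels, 0, -1))


def dyadic_range_hz(subband: str, fs: float, levels: int = DEFAULT_LEVELS) -> Tuple[float, float]:
    """Nominal dyadic frequency range of a subband, e.g. D5 at 512 Hz -> (8, 16)."""
    kind, k = subband[0], int(subband[1:])
    if kind == "A":
        return (0.0, fs / 2 ** (k + 1))
    if kind == "D":
        return (fs / 2 ** (k + 1), fs / 2 ** k)
    raise ValueError(f"unknown subband {subband!r}")


def dwt_subbands(
    x: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    mode: str = DEFAULT_MODE,
) -> Dict[str, np.ndarray]:
    """Decompose a 1-D signal and reconstruct every subband at full length.

    Returns ``{'A7': ..., 'D7': ..., ..., 'D1': ...}``; the reconstructions sum
    to the input (linearity of the inverse transform).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < 2 ** levels:
        raise ValueError(f"signal length {len(x)} < 2**levels = {2 ** levels}")
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=levels)
    names = subband_names(levels)  # index 0 = approximation, then D_levels..D1
    out: Dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        sel = [c if j == i else np.zeros_like(c) for j, c in enumerate(coeffs)]
        out[name] = pywt.waverec(sel, wavelet, mode=mode)[: len(x)]
    return out


def band_signal(subbands: Dict[str, np.ndarray], band: str) -> np.ndarray:
    """Pick the subband reconstruction for a clinical band name (beta -> D5...)."""
    try:
        return subbands[SUBBAND_OF_BAND[band]]
    except KeyError:
        raise ValueError(
            f"unknown band {band!r}; choose from {sorted(SUBBAND_OF_BAND)}"
        ) from None


def decompose_epochs(
    epochset: EpochSet,
    bands: Iterable[str] = ("delta", "theta", "alpha", "beta"),
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    mode: str = DEFAULT_MODE,
) -> Dict[str, np.ndarray]:
    """Band-filter a whole EpochSet via the DWT.

    Returns ``{band: array of shape (n_epochs, n_channels, epoch_len)}``. One
    wavedec per epoch channel; only the requested bands are reconstructed.
    """
    bands = tuple(bands)
    wanted = {band: SUBBAND_OF_BAND[band] for band in bands}  # validates names
    names = subband_names(levels)
    idx_of = {name: i for i, name in enumerate(names)}
    n_ep, n_ch, n_s = epochset.epochs.shape
    out = {band: np.empty((n_ep, n_ch, n_s)) for band in bands}
    for e in range(n_ep):
        for c in range(n_ch):
            coeffs = pywt.wavedec(epochset.epochs[e, c], wavelet, mode=mode, level=levels)
            for band, sub in wanted.items():
                i = idx_of[sub]
                sel = [co if j == i else np.zeros_like(co) for j, co in enumerate(coeffs)]
                out[band][e, c] = pywt.waverec(sel, wavelet, mode=mode)[:n_s]
    return out
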