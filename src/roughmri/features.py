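"""Texture features from 2-D wavelet-packet and DCT decompositions.

A brain ROI is decomposed with the biorthogonal spline wavelet ``bior2.2``
in a 2-D discrete wavelet packet transform (DWPT) at depths 1 and 2.  In
a packet transform every node — detail bands included — is decomposed
again, so depth 1 yields 4 sub-bands and depth 2 yields 16, for 20 band
matrices in total.  Each band is summarized by nine order statistics
(mean, median, max, min, range, mode, standard deviation, median absolute
value, mean absolute value), giving a 180-dimensional texture vector per
image.

An orthonormal whole-image type-II DCT serves as the comparison
transform: its coefficient matrix is partitioned into 2x2 quadrants and
4x4 blocks so the same 20-band x 9-statistic layout applies, keeping
classifiers trained on either transform directly comparable.

Conventions: symmetric (half-sample) boundary extension for the DWPT
(so a band of an n-sample parent has ``floor((n + L - 1)/2)`` samples,
L being the analysis filter length), natural band order (LL, LH, HL, HH
recursively), population standard deviation, and a 256-bin histogram
mode for continuous coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.fft import dctn
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WaveletFilter",
    "PacketDecomposition",
    "STAT_NAMES",
    "dwpt2",
    "idwpt2",
    "dct_bands",
    "band_stats",
    "extract_features",
    "feature_names",
    "TextureFeatureExtractor",
]

STAT_NAMES = (
    "mean",
    "median",
    "max",
    "min",
    "range",
    "mode",
    "std",
    "medabs",
    "meanabs",
)

_PYWT_TO_BAND = {"a": "LL", "h": "LH", "v": "HL", "d": "HH"}
_DEFAULT_WAVELET = "bior2.2"
_BOUNDARY_MODE = "symmetric"


@dataclass(frozen=True)
class WaveletFilter:
    """Analysis/synthesis filter quadruple of a biorthogonal wavelet."""

    name: str
    dec_lo: tuple[float, ...]
    dec_hi: tuple[float, ...]
    rec_lo: tuple[float, ...]
    rec_hi: tuple[float, ...]

    @classmethod
    def from_name(cls, name: str = _DEFAULT_WAVELET) -> "WaveletFilter":
        w = pywt.Wavelet(name)
        return cls(
            name=name,
            dec_lo=tuple(w.dec_lo),
            dec_hi=tuple(w.dec_hi),
            rec_lo=tuple(w.rec_lo),
            rec_hi=tuple(w.rec_hi),
        )

    def reconstruction_defect(self) -> float:
        """Max deviation from the biorthogonal perfect-reconstruction
        identities, probed by a round trip on an impulse train."""
        x = np.zeros(32)
        x[7] = 1.0
        w = pywt.Wavelet(self.name)
        a, d = pywt.dwt(x, w, mode="periodization")
        back = pywt.idwt(a, d, w, mode="periodization")
        return float(np.max(np.abs(back - x)))


@dataclass(frozen=True)
class PacketDecomposition:
    """Sub-bands of one depth of a 2-D packet decomposition."""

    depth: int
    bands: tuple[np.ndarray, ...]
    band_names: tuple[str, ...]
    source_shape: tuple[int, int]

    def __post_init__(self):
        if len(self.bands) != 4**self.depth:
            raise ValueError(
                f"depth {self.depth} requires {4**self.depth} bands, "
                f"got {len(self.bands)}"
            )


def _check_roi(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D gray image")
    if min(img.shape) < 8:
        raise ValueError("image must be at least 8x8")
    return img


def dwpt2(img: np.ndarray, depth: int, wavelet: str = _DEFAULT_WAVELET) -> PacketDecomposition:
    """2-D discrete wavelet packet transform at the given depth.

    Separable filtering with the named wavelet's analysis pair, symmetric
    boundary extension and dyadic downsampling; ALL nodes are decomposed
    at each level.  Bands are returned in natural order: LL, LH, HL, HH,
    recursively within each parent.
    """
    img = _check_roi(img)
    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    filt_len = len(pywt.Wavelet(wavelet).dec_lo)
    if min(img.shape) < 2 ** (depth - 1) * filt_len:
        raise ValueError(
            f"image of shape {img.shape} too small for depth {depth} "
            f"with filter length {filt_len}"
        )
    wp = pywt.WaveletPacket2D(data=img, wavelet=wavelet, mode=_BOUNDARY_MODE,
                              maxlevel=depth)
    names: list[str] = []
    bands: list[np.ndarray] = []
    for path_tuple in itertools.product("ahvd", repeat=depth):
        path = "".join(path_tuple)
        names.append("".join(_PYWT_TO_BAND[p] for p in path_tuple))
        bands.append(np.asarray(wp[path].data, dtype=float))
    return PacketDecomposition(
        depth=depth,
        bands=tuple(bands),
        band_names=tuple(names),
        source_shape=img.shape,
    )


def idwpt2(dec: PacketDecomposition, wavelet: str = _DEFAULT_WAVELET) -> np.ndarray:
    """Inverse packet transform; reconstructs the source image."""
    wp = pywt.WaveletPacket2D(
        data=np.zeros(dec.source_shape), wavelet=wavelet, mode=_BOUNDARY_MODE,
        maxlevel=dec.depth,
    )
    band_to_pywt = {v: k for k, v in _PYWT_TO_BAND.items()}
    for name, band in zip(dec.band_names, dec.bands):
        path = "".join(band_to_pywt[name[i:i + 2]] for i in range(0, len(name), 2))
        wp[path] = band
    rec = wp.reconstruct(update=False)
    return np.asarray(rec)[: dec.source_shape[0], : dec.source_shape[1]]


def _split_blocks(mat: np.ndarray, n: int) -> list[np.ndarray]:
    rows = np.array_split(mat, n, axis=0)
    return [blk for row in rows for blk in np.array_split(row, n, axis=1)]


def dct_bands(img: np.ndarray) -> tuple[PacketDecomposition, PacketDecomposition]:
    """Whole-image orthonormal DCT-II, partitioned to mirror the DWPT.

    The coefficient matrix is split into 2x2 quadrants ("depth 1", 4
    bands) and 4x4 blocks ("depth 2", 16 bands), both in row-major block
    order, giving the same 20-band layout as the packet transform.
    """
    img = _check_roi(img)
    coefs = dctn(img, norm="ortho")
    q = _split_blocks(coefs, 2)
    b = _split_blocks(coefs, 4)
    d1 = PacketDecomposition(
        depth=1,
        bands=tuple(q),
        band_names=tuple(f"Q{i}{j}" for i in range(2) for j in range(2)),
        source_shape=img.shape,
    )
    d2 = PacketDecomposition(
        depth=2,
        bands=tuple(b),
        band_names=tuple(f"B{i}{j}" for i in range(4) for j in range(4)),
        source_shape=img.shape,
    )
    return d1, d2


def band_stats(band: np.ndarray) -> np.ndarray:
    """The nine summary statistics of one coefficient band.

    Order: mean, median, max, min, range, mode, population standard
    deviation, median absolute value, mean absolute value.  The mode of
    the continuous coefficients is the center of the most populated of
    256 equal-width histogram bins over [min, max] (ties break to the
    lowest bin; a constant band is its own mode).
    """
    band = np.asarray(band, dtype=float)
    if band.size == 0:
        raise ValueError("empty band")
    flat = band.ravel()
    lo = float(flat.min())
    hi = float(flat.max())
    if lo == hi:
        mode = lo
    else:
        counts, edges = np.histogram(flat, bins=256, range=(lo, hi))
        k = int(np.argmax(counts))
        mode = 0.5 * (edges[k] + edges[k + 1])
    return np.array(
        [
            float(flat.mean()),
            float(np.median(flat)),
            hi,
            lo,
            hi - lo,
            mode,
            float(flat.std()),  # population (divide by N)
            float(np.median(np.abs(flat))),
            float(np.mean(np.abs(flat))),
        ]
    )


def _decompositions(roi: np.ndarray, transform: str) -> tuple[PacketDecomposition, PacketDecomposition]:
    transform = transform.lower()
    if transform == "dwpt":
        return dwpt2(roi, 1), dwpt2(roi, 2)
    if transform == "dct":
        return dct_bands(roi)
    raise ValueError(f"unknown transform {transform!r}; expected 'dwpt' or 'dct'")


def feature_names(transform: str = "dwpt") -> list[str]:
    """The 180 column names, regenerated deterministically from
    (transform, depth, band, statistic)."""
    transform = transform.lower()
    if transform == "dwpt":
        d1 = ["".join(p) for p in itertools.product(["LL", "LH", "HL", "HH"], repeat=1)]
        d2 = ["".join(p) for p in itertools.product(["LL", "LH", "HL", "HH"], repeat=2)]
    elif transform == "dct":
        d1 = [f"Q{i}{j}" for i in range(2) for j in range(2)]
        d2 = [f"B{i}{j}" for i in range(4) for j in range(4)]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    names = []
    for depth, bands in ((1, d1), (2, d2)):
        for band in bands:
            for stat in STAT_NAMES:
                names.append(f"{transform}_d{depth}{band}_{stat}")
    return names


def extract_features(roi: np.ndarray, transform: str = "dwpt") -> np.ndarray:
    """180-vector of band statistics (20 bands x 9 statistics).

    The ROI is the full rectangular image including its zeroed
    background — the transform sees the masked image, not only the mask
    interior.
    """
    d1, d2 = _decompositions(_check_roi(roi), transform)
    vals = [band_stats(b) for b in d1.bands] + [band_stats(b) for b in d2.bands]
    return np.concatenate(vals)


class TextureFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of 2-D ROI images -> (n_images, 180) matrix.

    Parameters
    ----------
    transform_kind : {'dwpt', 'dct'}
        Decomposition used before the nine band statistics.
    """

    def __init__(self, transform_kind: str = "dwpt"):
        self.transform_kind = transform_kind

    def fit(self, X, y=None):
        _decompositions(np.zeros((16, 16)), self.transform_kind)  # validate param
        self.feature_names_out_ = np.asarray(feature_names(self.transform_kind))
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([
            extract_features(np.asarray(img), self.transform_kind) for img in X
        ])

    def get_feature_names_out(self, input_features=None):
        return feature_names(self.transform_kind)
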