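"""Per-ROI texture/elasticity feature bank (57 features per ROI).

Families, per region of interest:

* MFAF (2): mean spectral frequency of the axial (column-wise) image lines,
  estimated two ways — a Burg maximum-entropy autoregressive model of order 8
  evaluated on a 256-point grid over [0, 0.5] cycles/pixel, and the average
  of K=4 sine-tapered periodograms.
* First-order statistics (7): integrated optical density (sum of gray
  values), mean, population standard deviation, variance, skewness m3/s^3,
  non-excess kurtosis m4/s^4, and histogram energy over the 256-bin
  normalized gray histogram.
* Haralick (6 statistics x 4 directions = 24): from single-direction,
  non-symmetrized gray-level co-occurrence matrices (GLCM) at distance 1 in
  directions 0/45/90/135 degrees.  Keeping the matrix non-symmetric makes
  the Symmetry statistic, 1 - 0.5*sum|P - P^T|, informative.
* Galloway (5 x 4 = 20): from gray-level run-length matrices (GLRLM) of
  maximal constant-gray runs along the same four directions.
* Local binary patterns (2): energy and entropy of the 256-bin histogram of
  classic 8-neighbor radius-1 integer LBP codes (comparison ``neighbor >=
  center``, bit 0 at the east neighbor, counter-clockwise).
* SWE (2): the acquisition-provided shear-wave elasticity mean and standard
  deviation, passed through unchanged.

Images are quantized to ``Q`` equal-width gray bins (default 32) before the
co-occurrence and run-length statistics.  Degenerate inputs follow fixed
conventions: zero-variance images have skewness/kurtosis 0, a GLCM with zero
marginal variance has correlation 0, and spectrally empty columns take the
flat-spectrum mean frequency 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import protocol
from .cohort import AcquisitionRecord, ROISample
from .protocol import (
    DIRECTIONS,
    FOS_STATS,
    GALLOWAY_STATS,
    HARALICK_STATS,
    FeatureName,
    ProtocolError,
    roi_feature_names,
    thickness_feature_names,
)

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = 32
BURG_ORDER = 8
N_FREQ = 256
N_TAPERS = 4
_FLAT_SPECTRUM_MF = 0.25

# Pixel offsets (drow, dcol) at distance 1 for the four directions.
_OFFSETS = {"0°": (0, 1), "45°": (-1, 1), "90°": (-1, 0), "135°": (-1, -1)}


# ---------------------------------------------------------------------------
# Quantization and first-order statistics

def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin 8-bit gray values [0, 255] into ``levels`` equal-width bins."""
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    img = np.asarray(image)
    return np.minimum((img.astype(np.int64) * levels) // 256, levels - 1).astype(np.int64)


def fos_features(image: np.ndarray) -> dict[str, float]:
    """First-order statistics of the gray-level histogram."""
    x = np.asarray(image, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty image")
    mean = x.mean()
    var = x.var()  # population variance
    std = np.sqrt(var)
    if std > 0:
        skew = np.mean((x - mean) ** 3) / std**3
        kurt = np.mean((x - mean) ** 4) / std**4
    else:
        logger.debug("constant image: skewness/kurtosis set to 0 by convention")
        skew = kurt = 0.0
    hist = np.bincount(np.asarray(image, dtype=np.int64).ravel(), minlength=256)
    p = hist / hist.sum()
    return {
        "IOD": float(x.sum()),
        "Mean": float(mean),
        "Std": float(std),
        "Variance": float(var),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Energy": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# Gray-level co-occurrence matrix and Haralick statistics

@dataclass(frozen=True)
class GLCM:
    levels: int
    matrix: np.ndarray  # (Q, Q), sums to 1
    direction: str


def glcm(image_q: np.ndarray, direction: str, levels: int) -> GLCM:
    """Single-direction, non-symmetrized co-occurrence distribution at distance 1."""
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {list(_OFFSETS)}")
    img = np.asarray(image_q, dtype=np.int64)
    dr, dc = _OFFSETS[direction]
    h, w = img.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError(f"image {img.shape} too small for direction {direction}")
    r0 = slice(max(0, -dr), h - max(0, dr))
    c0 = slice(max(0, -dc), w - max(0, dc))
    r1 = slice(max(0, dr), h + min(0, dr))
    c1 = slice(max(0, dc), w + min(0, dc))
    a = img[r0, c0].ravel()
    b = img[r1, c1].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels).astype(np.float64)
    return GLCM(levels=levels, matrix=(counts / counts.sum()).reshape(levels, levels), direction=direction)


def haralick_features(g: GLCM) -> dict[str, float]:
    p = g.matrix
    q = g.levels
    i = np.arange(q, dtype=np.float64)
    diff = i[:, None] - i[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = np.sum(i * pi)
    mu_j = np.sum(i * pj)
    var_i = np.sum((i - mu_i) ** 2 * pi)
    var_j = np.sum((i - mu_j) ** 2 * pj)
    if var_i > 0 and var_j > 0:
        correlation = float(np.sum((i[:, None] - mu_i) * (i[None, :] - mu_j) * p)
                            / np.sqrt(var_i * var_j))
    else:
        logger.debug("degenerate GLCM marginals: correlation set to 0 by convention")
        correlation = 0.0
    nz = p[p > 0]
    return {
        "Contrast": float(np.sum(diff**2 * p)),
        "Correlation": correlation,
        "Energy": float(np.sum(p**2)),
        "Entropy": float(-np.sum(nz * np.log(nz))),
        "Homogeneity": float(np.sum(p / (1.0 + np.abs(diff)))),
        "Symmetry": float(1.0 - 0.5 * np.sum(np.abs(p - p.T))),
    }


# ---------------------------------------------------------------------------
# Gray-level run-length matrix and Galloway statistics

@dataclass(frozen=True)
class GLRLM:
    levels: int
    max_run: int
    matrix: np.ndarray  # (Q, max_run) raw counts; column j-1 holds runs of length j
    n_runs: int
    n_pixels: int


def _direction_lines(img: np.ndarray, direction: str) -> list[np.ndarray]:
    h, w = img.shape
    if direction == "0°":
        return [img[r] for r in range(h)]
    if direction == "90°":
        return [img[:, c] for c in range(w)]
    if direction == "45°":  # anti-diagonals (up-right)
        flipped = img[:, ::-1]
        return [np.diagonal(flipped, k) for k in range(-(h - 1), w)]
    if direction == "135°":  # main diagonals (down-right)
        return [np.diagonal(img, k) for k in range(-(h - 1), w)]
    raise ValueError(f"direction must be one of {list(_OFFSETS)}")


def glrlm(image_q: np.ndarray, direction: str, levels: int) -> GLRLM:
    """Count maximal constant-gray runs along each line of the direction."""
    img = np.asarray(image_q, dtype=np.int64)
    if img.size == 0:
        raise ValueError("empty image")
    lines = _direction_lines(img, direction)
    max_run = max(len(ln) for ln in lines)
    # Concatenate lines with a -1 sentinel so runs never straddle lines.
    parts: list[np.ndarray] = []
    for ln in lines:
        parts.append(np.asarray(ln, dtype=np.int64))
        parts.append(np.array([-1], dtype=np.int64))
    buf = np.concatenate(parts)
    boundaries = np.flatnonzero(np.diff(buf) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [len(buf)]))
    grays = buf[starts]
    lengths = ends - starts
    keep = grays >= 0
    grays, lengths = grays[keep], lengths[keep]
    matrix = np.zeros((levels, max_run), dtype=np.float64)
    np.add.at(matrix, (grays, lengths - 1), 1.0)
    return GLRLM(levels=levels, max_run=max_run, matrix=matrix,
                 n_runs=int(len(grays)), n_pixels=int(img.size))


def galloway_features(r: GLRLM) -> dict[str, float]:
    if r.n_runs < 1:
        raise ValueError("GLRLM has no runs (empty image)")
    p = r.matrix
    j = np.arange(1, r.max_run + 1, dtype=np.float64)
    nr = float(r.n_runs)
    return {
        "SRE": float(np.sum(p / j[None, :] ** 2) / nr),
        "LRE": float(np.sum(p * j[None, :] ** 2) / nr),
        "GLNU": float(np.sum(p.sum(axis=1) ** 2) / nr),
        "RLNU": float(np.sum(p.sum(axis=0) ** 2) / nr),
        "RP": float(nr / r.n_pixels),
    }


# ---------------------------------------------------------------------------
# Local binary patterns

def lbp_codes(image: np.ndarray) -> np.ndarray:
    """Integer 8-neighbor radius-1 LBP codes of the interior pixels.

    Bit k is set when the k-th neighbor >= center; neighbors start east and
    proceed counter-clockwise (E, NE, N, NW, W, SW, S, SE).
    """
    img = np.asarray(image, dtype=np.int64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("LBP needs a 2-D image of at least 3x3 pixels")
    c = img[1:-1, 1:-1]
    neighbors = (
        img[1:-1, 2:],   # E
        img[:-2, 2:],    # NE
        img[:-2, 1:-1],  # N
        img[:-2, :-2],   # NW
        img[1:-1, :-2],  # W
        img[2:, :-2],    # SW
        img[2:, 1:-1],   # S
        img[2:, 2:],     # SE
    )
    codes = np.zeros_like(c)
    for bit, nb in enumerate(neighbors):
        codes |= (nb >= c).astype(np.int64) << bit
    return codes


def lbp_features(image: np.ndarray) -> dict[str, float]:
    codes = lbp_codes(image)
    hist = np.bincount(codes.ravel(), minlength=256)
    h = hist / hist.sum()
    nz = h[h > 0]
    return {"Energy": float(np.sum(h**2)), "Entropy": float(-np.sum(nz * np.log(nz)))}


# ---------------------------------------------------------------------------
# Mean frequency analysis (MFAF)

def burg_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    """Burg-method AR coefficients, vectorized over rows of ``x``.

    Returns ``a`` of shape (n_series, order) for the prediction polynomial
    A(z) = 1 + a_1 z^-1 + ... + a_p z^-p (power spectrum ∝ 1/|A|^2).
    Zero-power series yield all-zero coefficients (flat spectrum).
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    m, n = x.shape
    if n <= order:
        raise ValueError(f"series length {n} must exceed AR order {order}")
    f = x[:, 1:].copy()
    b = x[:, :-1].copy()
    a = np.zeros((m, 0))
    for _ in range(order):
        den = np.einsum("ij,ij->i", f, f) + np.einsum("ij,ij->i", b, b)
        num = -2.0 * np.einsum("ij,ij->i", f, b)
        rc = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        a = np.concatenate([a + rc[:, None] * a[:, ::-1], rc[:, None]], axis=1)
        f, b = f[:, 1:] + rc[:, None] * b[:, 1:], b[:, :-1] + rc[:, None] * f[:, :-1]
    return a


_FREQ_GRID = np.linspace(0.0, 0.5, N_FREQ)
# Local refinement offsets (in units of a pole's bandwidth) added around each
# AR pole frequency so that near-unit-circle resonances are integrated
# accurately; a fixed grid cannot resolve a pole of radius 1 - 1e-6.
_POLE_OFFSETS = np.concatenate([[0.0], *[[s, -s] for s in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)]])


def _mean_freq_from_psd(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Spectral centroid per row on a uniform grid; flat-spectrum convention
    0.25 for zero-power rows."""
    total = psd.sum(axis=1)
    ok = total > 0
    mf = np.full(psd.shape[0], _FLAT_SPECTRUM_MF)
    mf[ok] = (psd[ok] * freqs[None, :]).sum(axis=1) / total[ok]
    return mf


def _ar_mean_frequency(a: np.ndarray) -> np.ndarray:
    """Spectral centroid of the AR power spectrum 1/|A(e^{i2πf})|² per row of
    ``a``, trapezoid-integrated over [0, 0.5] on a pole-refined grid."""
    m, order = a.shape
    # Batched companion matrices -> AR poles per series.
    comp = np.zeros((m, order, order))
    comp[:, 0, :] = -a
    idx = np.arange(order - 1)
    comp[:, idx + 1, idx] = 1.0
    roots = np.linalg.eigvals(comp)
    pole_freq = np.abs(np.angle(roots)) / (2.0 * np.pi)
    bandwidth = np.maximum(1.0 - np.abs(roots), 1e-9) / (2.0 * np.pi)

    refined = pole_freq[:, :, None] + bandwidth[:, :, None] * _POLE_OFFSETS[None, None, :]
    grid = np.concatenate(
        [np.broadcast_to(_FREQ_GRID, (m, N_FREQ)), refined.reshape(m, -1)], axis=1
    )
    grid = np.sort(np.clip(grid, 0.0, 0.5), axis=1)

    # A(e^{i2πf}) = 1 + a_1 z + ... + a_p z^p with z = e^{-i2πf}, by Horner.
    z = np.exp(-2j * np.pi * grid)
    acc = np.broadcast_to(a[:, -1][:, None], grid.shape).astype(complex).copy()
    for j in range(order - 2, -1, -1):
        acc = acc * z + a[:, j][:, None]
    big_a = 1.0 + acc * z
    denom = big_a.real**2 + big_a.imag**2
    psd = 1.0 / np.maximum(denom, 1e-290)
    total = np.trapezoid(psd, grid, axis=1)
    first = np.trapezoid(psd * grid, grid, axis=1)
    ok = total > 0
    mf = np.full(m, _FLAT_SPECTRUM_MF)
    mf[ok] = first[ok] / total[ok]
    return mf


def mfaf(image: np.ndarray, method: str) -> float:
    """Mean axial spectral frequency (cycles/pixel), averaged over columns.

    ``method="maxent"``: Burg AR(8) spectrum on a 256-point grid over [0, 0.5].
    ``method="multiwindow"``: average of 4 sine-tapered periodograms.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 16:
        raise ValueError("MFAF needs a 2-D image with at least 16 rows")
    cols = img.T  # one series per row, along the axial (column) direction
    cols = cols - cols.mean(axis=1, keepdims=True)
    n = cols.shape[1]
    if method == "maxent":
        a = burg_coefficients(cols, BURG_ORDER)
        dead = np.all(a == 0.0, axis=1)
        if dead.any():
            # zero-power columns carry all-zero coefficients -> flat spectrum
            logger.debug("%d zero-power columns: mean frequency 0.25 by convention", dead.sum())
        return float(np.mean(_ar_mean_frequency(a)))
    if method == "multiwindow":
        nfft = 512
        t = np.arange(n)
        tapers = np.sqrt(2.0 / (n + 1)) * np.sin(
            np.pi * np.arange(1, N_TAPERS + 1)[:, None] * (t[None, :] + 1) / (n + 1)
        )
        psd = np.zeros((cols.shape[0], nfft // 2 + 1))
        for k in range(N_TAPERS):
            psd += np.abs(np.fft.rfft(cols * tapers[k][None, :], n=nfft, axis=1)) ** 2
        psd /= N_TAPERS
        freqs = np.fft.rfftfreq(nfft)
        return float(np.mean(_mean_freq_from_psd(freqs, psd)))
    raise ValueError(f"method must be 'maxent' or 'multiwindow', got {method!r}")


# ---------------------------------------------------------------------------
# Morphology and assembly

def thickness_feature(left_mm: float, right_mm: float) -> float:
    """Side-averaged muscle thickness."""
    if left_mm <= 0 or right_mm <= 0:
        raise ValueError("thickness values must be positive")
    return (left_mm + right_mm) / 2.0


def extract_roi_features(sample: ROISample, levels: int = DEFAULT_LEVELS) -> dict[FeatureName, float]:
    """The 57 named features of one ROI."""
    names = roi_feature_names(sample.key)
    img = np.asarray(sample.image)
    img_q = quantize(img, levels)

    values: dict[tuple, float] = {}
    for method in protocol.MFAF_METHODS:
        values[("mfaf", "", method)] = mfaf(img, method)
    for stat, v in fos_features(img).items():
        values[("fos", stat, None)] = v
    for direction in DIRECTIONS:
        for stat, v in haralick_features(glcm(img_q, direction, levels)).items():
            values[("haralick", stat, direction)] = v
        for stat, v in galloway_features(glrlm(img_q, direction, levels)).items():
            values[("galloway", stat, direction)] = v
    for stat, v in lbp_features(img).items():
        values[("lbp", stat, None)] = v
    values[("swe", "Mean", None)] = sample.swe_mean_kpa
    values[("swe", "Std", None)] = sample.swe_std_kpa

    return {name: values[(name.family, name.statistic, name.qualifier)] for name in names}


def assemble_subject_vector(
    record: AcquisitionRecord, levels: int = DEFAULT_LEVELS
) -> dict[FeatureName, float]:
    """The full 800-entry feature vector in canonical order."""
    collected: dict[FeatureName, float] = {}
    for key in protocol.PROTOCOL_KEYS:
        if key not in record.rois:
            raise ProtocolError(f"record is missing ROI {key.site_label()}")
        collected.update(extract_roi_features(record.rois[key], levels))
    # The record carries thicknesses already averaged over sides.
    tlf_name, tra_name = thickness_feature_names()
    collected[tlf_name] = record.tlf_thickness_mm
    collected[tra_name] = record.tra_thickness_mm
    return {name: collected[name] for name in protocol.feature_universe()}


def cohort_feature_table(records: list[AcquisitionRecord], levels: int = DEFAULT_LEVELS) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per subject, 800 serialized-name
    columns plus ``vas`` and ``group``."""
    columns = list(protocol.feature_universe_serialized())
    rows = []
    index = []
    for rec in records:
        vec = assemble_subject_vector(rec, levels)
        row = [vec[name] for name in protocol.feature_universe()]
        rows.append(row + [rec.meta.vas, rec.meta.group])
        index.append(rec.meta.subject_id)
    return pd.DataFrame(rows, columns=columns + ["vas", "group"], index=pd.Index(index, name="subject_id"))
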