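"""Evaluation triplet: SNR, SSIM and mean CIEDE2000 color difference.

SNR is reference-energy over error-energy in decibels (the reference is the
first argument and the quantity is deliberately asymmetric).  SSIM follows
the standard Gaussian-window form (11x11, sigma 1.5, K1=0.01, K2=0.03,
dynamic range 255).  CIEDE2000 is the mean per-pixel Delta-E00 after
sRGB -> CIE Lab conversion (D65, 2 degree observer).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.color import deltaE_ciede2000, rgb2gray, rgb2lab
from skimage.metrics import structural_similarity

SNR_CAP_DB = 300.0


@dataclass
class MetricReport:
    snr_db: float
    ssim: float
    ciede2000_mean: float

    def to_dict(self):
        return asdict(self)


def _pair(reference, recovered):
    ref = np.asarray(reference, dtype=float)
    rec = np.asarray(recovered, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {rec.shape}")
    return ref, rec


def snr(reference, recovered) -> float:
    """10 log10( sum(ref^2) / sum((ref-rec)^2) ), capped at 300 dB."""
    ref, rec = _pair(reference, recovered)
    err = float(np.sum((ref - rec) ** 2))
    if err == 0.0:
        return SNR_CAP_DB
    return min(10.0 * np.log10(float(np.sum(ref**2)) / err), SNR_CAP_DB)


def ssim(reference, recovered, data_range: float = 255.0) -> float:
    """Structural similarity on a single channel (Gaussian window)."""
    ref, rec = _pair(reference, recovered)
    if ref.ndim != 2:
        raise ValueError("ssim expects single-channel images")
    if min(ref.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            ref,
            rec,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def ciede2000(reference_rgb, recovered_rgb) -> float:
    """Mean per-pixel Delta-E00; inputs are HxWx3 in [0, 255]."""
    ref, rec = _pair(reference_rgb, recovered_rgb)
    if ref.ndim != 3 or ref.shape[2] != 3:
        raise ValueError("ciede2000 expects HxWx3 images")
    lab_ref = rgb2lab(np.clip(ref / 255.0, 0.0, 1.0))
    lab_rec = rgb2lab(np.clip(rec / 255.0, 0.0, 1.0))
    return float(np.mean(deltaE_ciede2000(lab_ref, lab_rec)))


def evaluate(reference, recovered) -> MetricReport:
    """All three metrics for a pair of images (gray or RGB, [0, 255]).

    SSIM is computed on luminance for color inputs; gray inputs are
    replicated to three channels for the color-difference term.
    """
    ref, rec = _pair(reference, recovered)
    if ref.ndim == 3:
        ssim_val = ssim(rgb2gray(ref / 255.0) * 255.0, rgb2gray(rec / 255.0) * 255.0)
        de = ciede2000(ref, rec)
        snr_val = snr(ref, rec)
    else:
        ssim_val = ssim(ref, rec)
        de = ciede2000(np.stack([ref] * 3, axis=-1), np.stack([rec] * 3, axis=-1))
        snr_val = snr(ref, rec)
    return MetricReport(snr_db=snr_val, ssim=ssim_val, ciede2000_mean=de)
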