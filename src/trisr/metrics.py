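"""Image quality metrics: PSNR, windowed SSIM, per-plane volume reports.

PSNR is 10*log10(MAX_I^2 / MSE) in decibels; under the package's intensity
convention (per-volume min-max normalization to [0, 1]) the dynamic range
MAX_I defaults to 1.0 and is configurable for 8-bit comparisons.  SSIM is the
mean over sliding windows of

    (2 mu_x mu_y + c1)(2 sigma_xy + c2)
    ------------------------------------
    (mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)

with the usual stabilizers c1 = (0.01 L)^2, c2 = (0.03 L)^2 and a 7x7 uniform
window by default (Gaussian 11x11 sigma 1.5 selectable).  Volume evaluation
scores every slice of each anatomical plane and reports mean +/- standard
deviation per plane, the layout used for method comparisons.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import PLANES, Volume
from .slicing import extract_slices

log = logging.getLogger(__name__)


def psnr(x: np.ndarray, y: np.ndarray, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if max_i <= 0:
        raise ValueError("max_i must be positive")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_i * max_i / mse)


def _window_stats(img: np.ndarray, window: int, gaussian: bool):
    """Local mean over all fully interior windows (valid region)."""
    if gaussian:
        f = ndimage.gaussian_filter(img, sigma=1.5, mode="constant", truncate=3.5)
    else:
        f = ndimage.uniform_filter(img, size=window, mode="constant")
    r = window // 2
    return f[r:img.shape[0] - r, r:img.shape[1] - r]


def ssim(x: np.ndarray, y: np.ndarray, window: int = 7,
         max_i: float = 1.0, gaussian: bool = False) -> float:
    """Mean structural similarity over sliding windows; in [-1, 1]."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if gaussian:
        window = 11
    if window > min(x.shape):
        raise ValueError(f"window {window} larger than image {x.shape}")
    c1 = (0.01 * max_i) ** 2
    c2 = (0.03 * max_i) ** 2
    mu_x = _window_stats(x, window, gaussian)
    mu_y = _window_stats(y, window, gaussian)
    mu_xx = _window_stats(x * x, window, gaussian)
    mu_yy = _window_stats(y * y, window, gaussian)
    mu_xy = _window_stats(x * y, window, gaussian)
    var_x = mu_xx - mu_x * mu_x
    var_y = mu_yy - mu_y * mu_y
    cov = mu_xy - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


@dataclass
class MetricReport:
    """Per-plane slicewise metric summary (mean +/- std, n slices)."""

    label: str
    max_i: float
    rows: list[dict] = field(default_factory=list)
    std_over: str = "slices"

    def add(self, plane: str, metric: str, values: list[float]):
        vals = np.asarray(values, dtype=np.float64)
        finite = vals[np.isfinite(vals)]
        n_inf = int(np.sum(~np.isfinite(vals)))
        if n_inf:
            log.warning("%d %s slice(s) identical on plane %s: infinite values "
                        "excluded from the mean", n_inf, metric, plane)
        if finite.size == 0:
            mean, std = math.inf, 0.0
        else:
            mean, std = float(finite.mean()), float(finite.std(ddof=0))
        self.rows.append({"plane": plane, "metric": metric, "mean": mean,
                          "std": std, "n_slices": int(vals.size),
                          "n_infinite": n_inf})

    def get(self, plane: str, metric: str) -> dict:
        for row in self.rows:
            if row["plane"] == plane and row["metric"] == metric:
                return row
        raise KeyError((plane, metric))

    def to_json(self) -> str:
        def enc(v):
            return "inf" if isinstance(v, float) and math.isinf(v) else v
        payload = {"label": self.label, "max_i": self.max_i,
                   "std_over": self.std_over,
                   "rows": [{k: enc(v) for k, v in r.items()} for r in self.rows]}
        return json.dumps(payload, indent=2)

    def to_table(self) -> str:
        lines = [f"# {self.label} (dynamic range MAX_I={self.max_i}, "
                 f"std over {self.std_over})",
                 f"{'plane':<10}{'metric':<8}{'mean +/- std':<24}{'n':>5}"]
        for r in self.rows:
            m = ("inf" if math.isinf(r["mean"])
                 else f"{r['mean']:.4f} +/- {r['std']:.4f}")
            lines.append(f"{r['plane']:<10}{r['metric']:<8}{m:<24}{r['n_slices']:>5}")
        return "\n".join(lines)


def evaluate_volume(pred: Volume, truth: Volume,
                    planes: tuple[str, ...] = PLANES,
                    metrics: tuple[str, ...] = ("psnr", "ssim"),
                    max_i: float = 1.0, label: str = "evaluation",
                    lpips_scorer=None, ssim_window: int = 7) -> MetricReport:
    """Slicewise per-plane PSNR/SSIM (and optional plug-in LPIPS) report."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    report = MetricReport(label=label, max_i=max_i)
    for plane in planes:
        sp = extract_slices(pred, plane)
        st = extract_slices(truth, plane)
        for metric in metrics:
            values = []
            for a, b in zip(sp.slices, st.slices):
                if metric == "psnr":
                    values.append(psnr(a, b, max_i))
                elif metric == "ssim":
                    values.append(ssim(a, b, window=ssim_window, max_i=max_i))
                elif metric == "lpips":
                    v = lpips_adapter(a, b, lpips_scorer)
                    if v is None:
                        values = None
                        break
                    values.append(v)
                else:
                    raise ValueError(f"unknown metric {metric!r}")
            if values is not None:
                report.add(plane, metric, values)
    return report


def lpips_adapter(pred_slice: np.ndarray, truth_slice: np.ndarray,
                  external_scorer=None):
    """Delegate to a user-supplied perceptual scorer; never a hard failure.

    Returns the scorer's value unchanged, or ``None`` (with a logged notice)
    when no scorer is available or it raises.
    """
    if external_scorer is None:
        log.info("no LPIPS scorer supplied; metric skipped")
        return None
    try:
        return float(external_scorer(pred_slice, truth_slice))
    except Exception as exc:  # error containment: a plug-in must not crash runs
        log.warning("LPIPS scorer failed (%s); metric skipped", exc)
        return None
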