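"""Generator and discriminator objectives.

The composite generator loss is

    L_G = L_percep + lambda * L_adv^Ra + eta * L1

where L1 is the mean-absolute pixel loss against the ground truth, L_percep
is an L1 distance in the feature space of a pluggable extractor (VGG-19
conv5_4 pre-activation when one is supplied; an identity extractor ships for
fully offline use, reducing L_percep to the pixel L1), and the adversarial
terms follow the relativistic-average GAN: with C(.) the raw (pre-sigmoid)
discriminator output,

    D_ra(x_r) = sigmoid(C(x_r) - E[C(x_f)])
    D_ra(x_f) = sigmoid(C(x_f) - E[C(x_r)])
    L_D = -E[log D_ra(x_r)] - E[log(1 - D_ra(x_f))]
    L_G^Ra = -E[log(1 - D_ra(x_r))] - E[log D_ra(x_f)]

Expectations are batch means; log arguments are clamped to [1e-8, 1] for
numerical safety.  Every function accepts numpy arrays or autodiff Tensors
and returns a scalar Tensor (use ``.item()`` for the float value).
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import autograd as ag
from .nn.autograd import Tensor, as_tensor

LOG_EPS = 1e-8


@dataclass
class LossWeights:
    """Coefficients balancing the generator loss terms."""

    lambda_adv: float = 5e-3
    eta_pix: float = 1e-2
    perceptual: float = 1.0
    stage1: bool = False   # L1-only pretraining schedule

    def __post_init__(self):
        if self.lambda_adv < 0 or self.eta_pix < 0 or self.perceptual < 0:
            raise ValueError("loss weights must be >= 0")


def _pair_check(logits_real, logits_fake) -> tuple[Tensor, Tensor]:
    lr, lf = as_tensor(logits_real), as_tensor(logits_fake)
    if lr.data.size == 0 or lf.data.size == 0:
        raise ValueError("empty logit batch")
    if lr.data.shape != lf.data.shape:
        raise ValueError("real/fake logit batches must have the same length")
    return lr, lf


def pixel_l1(sr, hr) -> Tensor:
    """Mean absolute difference between the SR output and the HR target."""
    sr, hr = as_tensor(sr), as_tensor(hr)
    if sr.data.shape != hr.data.shape:
        raise ValueError(f"shape mismatch {sr.data.shape} vs {hr.data.shape}")
    return ag.tmean(ag.tabs(sr - hr))


def identity_extractor(x):
    """Feature extractor that returns its input; L_percep collapses to L1."""
    return x


def perceptual_loss(sr, hr, feature_extractor=None) -> Tensor:
    """L1 distance between extractor features of SR and HR."""
    if feature_extractor is None:
        raise ValueError(
            "no feature extractor supplied: plug in a pretrained VGG-19 "
            "extractor, pass identity_extractor for offline use, or train "
            "stage-1 (L1-only) instead")
    sr, hr = as_tensor(sr), as_tensor(hr)
    if sr.data.shape != hr.data.shape:
        raise ValueError(f"shape mismatch {sr.data.shape} vs {hr.data.shape}")
    return ag.tmean(ag.tabs(feature_extractor(sr) - feature_extractor(hr)))


def _log_clamped(t: Tensor) -> Tensor:
    return ag.log(ag.clamp(t, LOG_EPS, 1.0))


def adversarial_g_loss(logits_real, logits_fake) -> Tensor:
    """Relativistic-average generator loss (wants fakes to beat the real mean)."""
    lr, lf = _pair_check(logits_real, logits_fake)
    d_real = ag.sigmoid(lr - ag.tmean(lf))
    d_fake = ag.sigmoid(lf - ag.tmean(lr))
    return (-ag.tmean(_log_clamped(1.0 - d_real))
            - ag.tmean(_log_clamped(d_fake)))


def adversarial_d_loss(logits_real, logits_fake) -> Tensor:
    """Relativistic-average discriminator loss."""
    lr, lf = _pair_check(logits_real, logits_fake)
    d_real = ag.sigmoid(lr - ag.tmean(lf))
    d_fake = ag.sigmoid(lf - ag.tmean(lr))
    return (-ag.tmean(_log_clamped(d_real))
            - ag.tmean(_log_clamped(1.0 - d_fake)))


def generator_total(sr, hr, logits_real, logits_fake,
                    weights: LossWeights,
                    feature_extractor=None) -> tuple[Tensor, dict]:
    """Composite generator loss and its per-term breakdown.

    In stage-1 mode only the pixel L1 is active (unit weight): the
    pretraining schedule excludes perceptual and adversarial terms.
    """
    if weights.stage1:
        pix = pixel_l1(sr, hr)
        return pix, {"pixel_l1": pix.item(), "perceptual": 0.0,
                     "adversarial": 0.0, "total": pix.item()}
    pix = pixel_l1(sr, hr)
    adv = adversarial_g_loss(logits_real, logits_fake)
    terms = [ag.mul(adv, weights.lambda_adv), ag.mul(pix, weights.eta_pix)]
    perc_val = 0.0
    if weights.perceptual > 0:
        perc = perceptual_loss(sr, hr, feature_extractor)
        terms.append(ag.mul(perc, weights.perceptual))
        perc_val = perc.item()
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total, {"pixel_l1": pix.item(), "perceptual": perc_val,
                   "adversarial": adv.item(), "total": total.item()}
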