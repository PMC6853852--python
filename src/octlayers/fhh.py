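"""Fuzzy histogram hyperbolization (FHH) contrast enhancement.

OCT speckle is multiplicative and spatially correlated, so linear filters
either leave it in place or blur the very layer boundaries the segmentation
needs. FHH instead remaps grey levels through a fuzzy membership function
followed by an exponential (hyperbolic) transform,

    mu(g)  = (g - g_min) / (g_max - g_min)
    g'     = (L - 1) / (e^-1 - 1) * (exp(-mu(g)^beta) - 1)

which stretches contrast between bright and dark retinal bands while
flattening intensity variation inside each band. The fuzzifier ``beta``
controls the character of the remap: values near 0 behave like histogram
equalization, values of 5 and above quantize the image towards a
segmentation-like result.

``beta`` is selected per image from the linear index of fuzziness

    gamma(I) = 2 / (M N) * sum min(mu, 1 - mu)

scaled by a configurable factor, then shifted by a stabilizer constant and
clamped to an admissible window — so enhancement adapts to each scan
without user input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateImageError, ParameterError
from .image import BScanImage

__all__ = [
    "FhhConfig",
    "compute_membership",
    "linear_fuzziness_index",
    "select_beta",
    "hyperbolize",
    "enhance",
]

logger = logging.getLogger(__name__)


@dataclass
class FhhConfig:
    """Parameters of the fuzzifier selection rule.

    ``beta`` starts at ``k * gamma(I)``, is shifted by the stabilizer ``c``
    and clamped to ``[t_min, t_max]``. ``beta_override``, when set, bypasses
    selection entirely (no clamping) — useful for reproducing a fixed-beta
    enhancement.
    """

    t_min: float = 0.5
    t_max: float = 5.0
    c: float = 0.5
    k: float = 4.0
    beta_override: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.t_min <= self.t_max):
            raise ParameterError(
                f"need 0 < t_min <= t_max, got ({self.t_min}, {self.t_max})"
            )
        if not math.isfinite(self.c):
            raise ParameterError("stabilizer c must be finite")


def compute_membership(image: BScanImage) -> np.ndarray:
    """Min–max membership map: 0 at the darkest pixel, 1 at the brightest.

    Raises :class:`DegenerateImageError` on a constant image, for which the
    membership function is undefined.
    """
    g = image.pixels
    g_min, g_max = g.min(), g.max()
    if g_max == g_min:
        raise DegenerateImageError("constant image: membership undefined")
    return (g - g_min) / (g_max - g_min)


def linear_fuzziness_index(membership: np.ndarray) -> float:
    """Linear index of fuzziness gamma in [0, 1].

    0 for a crisp map (all memberships in {0, 1}), 1 when every membership
    equals 0.5.
    """
    mu = np.asarray(membership, dtype=np.float64)
    if mu.min() < 0 or mu.max() > 1:
        raise ParameterError("membership values must lie in [0, 1]")
    return float(2.0 / mu.size * np.minimum(mu, 1.0 - mu).sum())


def select_beta(gamma: float, config: FhhConfig | None = None) -> float:
    """Map the image fuzziness to the fuzzifier actually applied.

    beta0 = k * gamma, then the stabilizer is added and the result clamped
    into [t_min, t_max]. An explicit ``beta_override`` wins unconditionally.
    """
    config = config or FhhConfig()
    if config.beta_override is not None:
        return float(config.beta_override)
    if not (0 <= gamma <= 1):
        raise ParameterError(f"gamma must be in [0, 1], got {gamma}")
    beta = config.k * gamma + config.c
    return float(min(max(beta, config.t_min), config.t_max))


def hyperbolize(membership: np.ndarray, beta: float, max_grey: int) -> np.ndarray:
    """Hyperbolic grey-level transform of a membership map.

    Returns continuous values in ``[0, max_grey - 1]``; monotone
    non-decreasing in the membership. Quantization is deferred to image
    export.
    """
    if beta <= 0:
        raise ParameterError(f"beta must be positive, got {beta}")
    if max_grey < 2:
        raise ParameterError(f"max_grey must be >= 2, got {max_grey}")
    mu = np.asarray(membership, dtype=np.float64)
    # expm1 ratio form: mu = 0 -> exactly 0, mu = 1 -> exactly L-1
    out = (max_grey - 1) * (np.expm1(-np.power(mu, beta)) / math.expm1(-1.0))
    return np.clip(out, 0.0, max_grey - 1)


def enhance(
    image: BScanImage, config: FhhConfig | None = None
) -> tuple[BScanImage, float]:
    """Full FHH enhancement of a B-scan.

    Composes membership computation, fuzziness measurement, fuzzifier
    selection and hyperbolization. Returns the enhanced image together with
    the beta actually applied, which is also logged along with gamma.
    """
    config = config or FhhConfig()
    mu = compute_membership(image)
    gamma = linear_fuzziness_index(mu)
    beta = select_beta(gamma, config)
    logger.info("fhh: gamma=%.4f beta=%.4f", gamma, beta)
    out = hyperbolize(mu, beta, image.max_grey)
    return BScanImage(out, image.max_grey, image.crop_offset), beta
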