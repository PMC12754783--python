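"""K+ adduct specificity and G-quartet counting.

Potassium binds G-quadruplexes two ways: specifically, sandwiched between
consecutive G-quartets (n stacked quartets hold n-1 cations, so n specific
K+ indicate n+1 quartets), and nonspecifically, as electrospray adducts
whose count distribution is well approximated by a Poisson law. An adduct
channel n is called specific when it clearly dominates its neighbors n-1
and n+1 AND exceeds the fitted Poisson background by more than three
background standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import poisson

DEFAULT_MIN_EXCESS = 1.5  # ratio to both neighbors ("significantly more populated")
DEFAULT_N_MAX = 6
BACKGROUND_SIGMAS = 3.0


@dataclass
class AdductProfile:
    """Intensities per K+ adduct count n = 0..n_max for one stoichiometry."""

    counts: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size < 2:
            raise ValueError("profile needs n_max >= 1 (at least 2 channels)")
        if np.any(self.counts < 0):
            raise ValueError("intensities must be non-negative")
        if not np.any(self.counts > 0):
            raise ValueError("profile needs at least one positive entry")


@dataclass
class PoissonBackground:
    lam: float  # Poisson mean of the nonspecific adduct count
    scale: float  # total background amplitude (sum over all channels)
    masked: tuple[int, ...] = ()
    lam_variance: float = 0.0  # inverse observed information of the fit
    unmasked_total: float = 0.0

    def predicted(self, n_channels: int) -> np.ndarray:
        return self.scale * poisson.pmf(np.arange(n_channels), self.lam)

    def predicted_sigma(self, n: int) -> float:
        """Standard deviation of the background at channel n.

        Combines the Poisson counting variance of the channel with the
        propagated uncertainty of the fitted background (delta method on
        lambda, plus the sampling variance of the unmasked amplitude)."""
        pred = self.scale * poisson.pmf(n, self.lam)
        var = max(pred, 1.0)
        if self.unmasked_total > 0:
            var += pred**2 / self.unmasked_total
        if self.lam_variance > 0:
            keep = np.array(
                [k for k in range(int(max(n, self.lam * 4 + 6)) + 1)
                 if k not in self.masked]
            )
            h = 1e-4 * max(self.lam, 1e-2)

            def pred_at(lam):
                z = poisson.pmf(keep, lam).sum()
                return self.unmasked_total / z * poisson.pmf(n, lam)

            dpred = (pred_at(self.lam + h) - pred_at(self.lam - h)) / (2 * h)
            var += dpred**2 * self.lam_variance
        return float(np.sqrt(var))


@dataclass
class SpecificityCall:
    specific_n: set[int]
    lambda_nonspecific: float
    quartet_count: Optional[int]
    background: Optional[PoissonBackground] = None
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.specific_n:
            assert self.quartet_count == max(self.specific_n) + 1


def _local_maxima(counts: np.ndarray, min_excess: float) -> list[int]:
    """Channels dominating both neighbors by the excess ratio (edge channels
    compare against their single neighbor)."""
    out = []
    for n in range(counts.size):
        left = counts[n - 1] if n > 0 else 0.0
        right = counts[n + 1] if n < counts.size - 1 else 0.0
        ref = max(left, right)
        if counts[n] > 0 and counts[n] > min_excess * ref:
            out.append(n)
    return out


def fit_poisson_background(
    profile: AdductProfile, masked: tuple[int, ...] = ()
) -> PoissonBackground:
    """Maximum-likelihood Poisson fit treating masked channels as missing.

    With channels M masked, the conditional likelihood over the remaining
    channels is maximized in lambda:
        L(lam) = prod_{n not in M} [pmf(n; lam) / Z(lam)]^{c_n},
    Z(lam) = sum_{n not in M} pmf(n; lam); the amplitude then rescales the
    unmasked mass back to a full distribution.
    """
    counts = profile.counts
    keep = np.array([n for n in range(counts.size) if n not in masked])
    if keep.size < 2 or counts[keep].sum() <= 0:
        raise ValueError("degenerate profile: too few unmasked channels")
    c = counts[keep]
    total = c.sum()
    mean_keep = float((keep * c).sum() / total)

    def nll(lam: float) -> float:
        p = poisson.pmf(keep, lam)
        z = p.sum()
        if z <= 0:
            return np.inf
        return -float((c * (np.log(np.maximum(p, 1e-300)) - np.log(z))).sum())

    res = minimize_scalar(
        nll, bounds=(1e-6, max(4.0 * mean_keep + 1.0, 10.0)), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(res.x)
    z = float(poisson.pmf(keep, lam).sum())
    # observed information for the delta-method uncertainty of the fit
    h = 1e-3 * max(lam, 1e-2)
    info = (nll(lam + h) - 2.0 * nll(lam) + nll(lam - h)) / h**2
    lam_var = 1.0 / info if info > 0 else 0.0
    return PoissonBackground(
        lam=lam, scale=total / z, masked=tuple(masked),
        lam_variance=float(lam_var), unmasked_total=float(total),
    )


def call_specific(
    profile: AdductProfile,
    min_excess: float = DEFAULT_MIN_EXCESS,
    background_sigmas: float = BACKGROUND_SIGMAS,
) -> SpecificityCall:
    """Classify adduct channels as specific vs Poisson background and count
    G-quartets as max(specific n) + 1.

    Candidates are local maxima exceeding both neighbors by ``min_excess``;
    the Poisson background is fitted with candidates masked; a candidate is
    confirmed only if its intensity exceeds the background prediction by
    more than ``background_sigmas`` Poisson standard deviations.
    """
    counts = profile.counts
    candidates = _local_maxima(counts, min_excess)
    try:
        bg = fit_poisson_background(profile, masked=tuple(candidates))
    except ValueError:
        bg = None
    specific: set[int] = set()
    for n in candidates:
        if bg is None:
            specific.add(n)
            continue
        pred = bg.scale * poisson.pmf(n, bg.lam)
        sigma = bg.predicted_sigma(n)
        if counts[n] > pred + background_sigmas * sigma:
            specific.add(n)
    return SpecificityCall(
        specific_n=specific,
        lambda_nonspecific=bg.lam if bg is not None else float("nan"),
        quartet_count=max(specific) + 1 if specific else None,
        background=bg,
        thresholds={
            "min_excess": min_excess,
            "background_sigmas": background_sigmas,
        },
    )
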