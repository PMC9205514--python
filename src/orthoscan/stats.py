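"""The mixed Student's t-test and its conservation/effect-size diagnostics.

The test asks whether one raw score (``one``, the target promoter) is
significantly different from the mean of a background score sample
(``bkg``), while borrowing variance information from the ortholog score
sample (``obs``, which contains ``one``).  It combines the one-sample and
independent two-sample t statistics:

    t' = (mean(bkg) - one) /
         ( sqrt(((n_obs-1)*s2_obs + (n_bkg-1)*s2_bkg) / (n_obs+n_bkg-2))
           * sqrt(1/n_obs + 1/n_bkg) )

with Welch-Satterthwaite degrees of freedom built from s2_obs/n_obs and
s2_bkg/n_bkg.  A strongly scoring target (one >> mean(bkg)) drives t' far
negative, so binding is detected in the lower tail.

Two companion diagnostics describe *why* a call is made:

  - CCV (coefficient of conserved variation): |mean(obs)| over the RMS
    deviation of obs around ``one``; large when ortholog scores cluster
    tightly near the target's score, i.e. the site is conserved.
  - SD (standard difference): (one - mean(bkg)) / |mean(bkg)|, the relative
    excess of the target's score over background.

Note that because ``one`` is a single draw while the denominator scales as
sqrt(1/n_obs + 1/n_bkg), t' is not null-calibrated for n_obs > 1: under the
null its spread is inflated by sqrt((1 + 1/n_bkg) / (1/n_obs + 1/n_bkg)).
The statistic is implemented exactly as defined; see the methods note for
the practical consequences.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class MixedTestResult:
    """t', degrees of freedom, p-value and the CCV/SD diagnostics."""

    t_prime: float
    df: float
    p: float
    ccv: float
    sd: float


def _as_sample(x: Sequence[float], name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < min_n:
        raise ValueError(f"{name} must be a 1-d sample with n >= {min_n}, got size {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mixed_t(one: float, obs: Sequence[float], bkg: Sequence[float]) -> Tuple[float, float]:
    """The mixed t statistic and its Welch-Satterthwaite degrees of freedom.

    ``obs`` is the ortholog score sample (containing ``one``); ``bkg`` the
    background score sample.  Both need n >= 2 so sample variances exist,
    and not both variances may be zero.
    """
    obs = _as_sample(obs, "obs")
    bkg = _as_sample(bkg, "bkg")
    n_obs, n_bkg = obs.size, bkg.size
    s2_obs = obs.var(ddof=1)
    s2_bkg = bkg.var(ddof=1)
    pooled = ((n_obs - 1) * s2_obs + (n_bkg - 1) * s2_bkg) / (n_obs + n_bkg - 2)
    if pooled == 0.0:
        raise ValueError("degenerate variance: both samples are constant")
    denom = math.sqrt(pooled) * math.sqrt(1.0 / n_obs + 1.0 / n_bkg)
    t_prime = (bkg.mean() - one) / denom
    a = s2_obs / n_obs
    b = s2_bkg / n_bkg
    df = (a + b) ** 2 / (a**2 / (n_obs - 1) + b**2 / (n_bkg - 1))
    return float(t_prime), float(df)


def p_value(t_prime: float, df: float, tail: str = "lower") -> float:
    """P-value of the mixed t statistic from the t-distribution CDF.

    The default lower tail, P(T_df <= t'), is small when the target scores
    far above the background mean (t' << 0); ``tail="two_sided"`` is also
    available.  Non-finite t' maps to 0 (-inf) or 1 (+inf) with a warning.
    """
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    if tail not in ("lower", "two_sided"):
        raise ValueError(f"tail must be 'lower' or 'two_sided', got {tail!r}")
    if not math.isfinite(t_prime):
        logger.warning("non-finite t' (%s); clamping p-value", t_prime)
        if tail == "two_sided":
            return 0.0
        return 0.0 if t_prime < 0 else 1.0
    if tail == "lower":
        return float(sps.t.cdf(t_prime, df))
    return float(2.0 * sps.t.sf(abs(t_prime), df))


def ccv(one: float, obs: Sequence[float]) -> float:
    """Coefficient of conserved variation: |mean(obs)| / RMS(obs - one).

    Returns ``inf`` when every ortholog score equals ``one`` (perfect
    conservation); 0 when the ortholog mean is 0 with nonzero spread.
    """
    obs = _as_sample(obs, "obs", min_n=1)
    denom = math.sqrt(float(np.mean((obs - one) ** 2)))
    num = abs(float(obs.mean()))
    if denom == 0.0:
        return math.inf
    return num / denom


def sd_effect(one: float, bkg: Sequence[float]) -> float:
    """Standard difference: (one - mean(bkg)) / |mean(bkg)|.

    Positive whenever the target outscores the background mean, regardless
    of the sign of that mean.  Undefined (raises) when mean(bkg) is 0.
    """
    bkg = _as_sample(bkg, "bkg", min_n=1)
    m = float(bkg.mean())
    if m == 0.0:
        raise ValueError("SD undefined: background mean is zero")
    return (one - m) / abs(m)


def mixed_test(
    one: float, obs: Sequence[float], bkg: Sequence[float], tail: str = "lower"
) -> MixedTestResult:
    """Run the full mixed t-test and compute both diagnostics."""
    t_prime, df = mixed_t(one, obs, bkg)
    return MixedTestResult(
        t_prime=t_prime,
        df=df,
        p=p_value(t_prime, df, tail),
        ccv=ccv(one, obs),
        sd=sd_effect(one, bkg),
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j>=i} (p_(j) * m / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return np.empty(0)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
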