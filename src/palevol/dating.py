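"""Dating duplicate divergence by linear scaling of substitution counts.

If ``k_cal`` substitutions of a given site class accumulated over a known
calibration time ``T_cal`` (e.g. synonymous substitutions separating two
species of known divergence time), then ``k_obs`` substitutions of the same
class on a focal comparison correspond to ``T = T_cal * k_obs / k_cal``.
The point estimate is reported to one decimal (round half-up); a 95%
interval from the exact Poisson bounds on ``k_obs`` is supplementary
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np
from scipy import stats

from palevol.divergence import CodonAlignment, _codon_contributions, flag_cpg_codons
from palevol.errors import ParameterError

_round1 = lambda x: float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class DatingEstimate:
    t_myr: float        # point estimate, one decimal, round half-up
    t_raw: float
    ci_low: float       # 95% interval treating k_obs as Poisson
    ci_high: float
    k_obs: float
    k_cal: float
    t_cal: float


def scale_time(k_obs: float, k_cal: float, t_cal: float) -> DatingEstimate:
    """Scale a calibration time by a substitution-count ratio.

    ``T = T_cal * k_obs / k_cal``, with a 95% interval obtained by scaling
    the exact (Garwood) Poisson interval for ``k_obs`` by ``T_cal/k_cal``.
    The calibration time is always a caller input.
    """
    if k_cal <= 0:
        raise ParameterError("k_cal must be > 0 (rate undefined otherwise)")
    if t_cal <= 0:
        raise ParameterError("t_cal must be > 0")
    if k_obs < 0:
        raise ParameterError("k_obs must be >= 0")
    scale = t_cal / k_cal
    t_raw = scale * k_obs
    lo = 0.0 if k_obs == 0 else 0.5 * stats.chi2.ppf(0.025, 2 * k_obs)
    hi = 0.5 * stats.chi2.ppf(0.975, 2 * k_obs + 2)
    return DatingEstimate(
        t_myr=_round1(t_raw),
        t_raw=t_raw,
        ci_low=scale * lo,
        ci_high=scale * hi,
        k_obs=k_obs,
        k_cal=k_cal,
        t_cal=t_cal,
    )


def count_class_substitutions(
    codons: CodonAlignment,
    row_a: int = 0,
    row_b: int = 1,
    site_class: str = "synonymous",
    cpg_only: bool = False,
    boundary_rule: str = "spanning",
) -> int:
    """Count synonymous or nonsynonymous codon differences between two rows.

    Differences are classified by the Nei-Gojobori pathway logic (fractional
    for multi-hit codons, rounded half-up at the end).  With ``cpg_only``,
    only differences inside CpG-flagged codons are counted; the complement
    (``cpg_only=False`` on the unflagged set) is obtained by subtraction.
    """
    if site_class not in ("synonymous", "nonsynonymous"):
        raise ValueError(f"unknown site class {site_class!r}")
    mask = None
    if cpg_only:
        flags, _ = flag_cpg_codons(codons, boundary_rule)
        mask = flags
    _, _, _, sd, nd = _codon_contributions(codons, row_a, row_b, mask)
    total = sd.sum() if site_class == "synonymous" else nd.sum()
    return int(np.floor(total + 0.5))
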