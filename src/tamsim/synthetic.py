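"""Synthetic inputs: covariate pool, placeholder PK parameters, raw fixtures.

The original covariate pool (age and body weight of the 1388 patients whose
data underpinned the joint PK model) is not publicly deposited, so the
package emulates it: truncated log-normal draws calibrated to the published
medians (55 years, 67 kg) and clipped to the published ranges (22-95 years,
39-150 kg).  Only the marginal median and range are matched — the joint
age-weight distribution of the real cohort is unknown and the two are
sampled independently.

The published model's parameter estimates are likewise external to this
package; :func:`placeholder_parameters` provides a complete, schema-valid
stand-in with physiologically plausible magnitudes, prominently flagged as
NOT the published estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pk import PKParameters
from .population import RawFrequencyRecord

#: Group label used by the synthetic raw-frequency fixture.
SYNTHETIC_GROUP = "synthetic-demo"


@dataclass(frozen=True)
class CovariatePoolSpec:
    """Specification of the synthetic age/body-weight pool.

    Defaults emulate the model-development cohort: n = 1388 patients, age
    median 55 years (range 22-95), body weight median 67 kg (range 39-150).
    """

    n: int = 1388
    age_median: float = 55.0
    age_min: float = 22.0
    age_max: float = 95.0
    wt_median: float = 67.0
    wt_min: float = 39.0
    wt_max: float = 150.0
    seed: object = 12345

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("pool size must be >= 1")
        if not self.age_min < self.age_median < self.age_max:
            raise ValueError("need age_min < age_median < age_max")
        if not self.wt_min < self.wt_median < self.wt_max:
            raise ValueError("need wt_min < wt_median < wt_max")


def _truncated_lognormal(
    rng: np.random.Generator,
    n: int,
    median: float,
    lo: float,
    hi: float,
    sigma: float,
    median_rtol: float = 0.02,
) -> np.ndarray:
    """Draw n values in [lo, hi] from a log-normal calibrated to the median.

    Truncation shifts the realized median away from exp(mu), so the scale
    ``mu`` is first calibrated on a large probe sample, then refined against
    the realized median of the pool itself (skipped for pools too small for
    a stable median estimate).
    """

    def draw(rng, count, mu):
        out = np.empty(0)
        while out.size < count:
            batch = rng.lognormal(mu, sigma, size=max(2 * count, 64))
            batch = batch[(batch >= lo) & (batch <= hi)]
            out = np.concatenate([out, batch])
        return out[:count]

    mu = np.log(median)
    for _ in range(10):  # coarse fixed point on a low-noise probe
        realized = float(np.median(draw(rng, 20_000, mu)))
        if abs(realized - median) <= 0.1 * median_rtol * median:
            break
        mu += np.log(median / realized)

    draws = draw(rng, n, mu)
    if n < 200:  # median of a tiny pool is dominated by sampling noise
        return draws
    for _ in range(10):
        realized = float(np.median(draws))
        if abs(realized - median) <= 0.5 * median_rtol * median:
            return draws
        mu += np.log(median / realized)
        draws = draw(rng, n, mu)
    if abs(realized - median) <= median_rtol * median:
        return draws
    raise RuntimeError(
        f"median calibration failed: target {median}, realized {realized}"
    )


def generate_covariate_pool(spec: CovariatePoolSpec = CovariatePoolSpec()) -> pd.DataFrame:
    """Generate the paired age/weight pool (columns age_years, weight_kg).

    Ages and weights are drawn independently; the pairing carries no
    correlation.  Pure function of the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    ages = _truncated_lognormal(
        rng, spec.n, spec.age_median, spec.age_min, spec.age_max, sigma=0.28
    )
    weights = _truncated_lognormal(
        rng, spec.n, spec.wt_median, spec.wt_min, spec.wt_max, sigma=0.22
    )
    return pd.DataFrame({"age_years": ages, "weight_kg": weights})


def placeholder_parameters() -> PKParameters:
    """A complete, plausible — but NOT published — parameter set.

    Magnitudes reflect general tamoxifen clinical pharmacology: slow
    apparent tamoxifen elimination (half-life ~5 days via a large apparent
    volume), endoxifen half-life ~2-3 days, a small endoxifen formation
    fraction at the wildtype activity score, and fractional reductions of
    the formation clearance that deepen as CYP2D6 activity falls.  The
    ``is_placeholder`` flag propagates into manifests and report headers.
    """
    return PKParameters(
        ka=0.4,           # 1/h
        tlag=0.5,         # h
        v_tam_f=1000.0,   # L
        v_endx_f=400.0,   # L
        cl20_f_typ=5.5,   # L/h, non-endoxifen pathways
        cl23_f_typ=0.25,  # L/h, endoxifen formation at AS 2
        cl30_f=5.0,       # L/h, endoxifen elimination
        theta_age=-0.25,
        theta_wt=0.75,
        ref_age=55.0,
        ref_wt=67.0,
        frac_change={
            "0": -0.85,
            "0.5": -0.65,
            "1": -0.45,
            "1.5": -0.10,
            "2": 0.0,
            ">2": 0.20,
        },
        omega2_cl20=0.09,  # ~30% CV
        omega2_cl23=0.16,  # ~40% CV
        sigma_resid=None,
        is_placeholder=True,
    )


def raw_frequency_fixture() -> list[RawFrequencyRecord]:
    """Small raw AS-frequency sheet exercising every normalization branch.

    Contains 0.25-step labels (fold up to the next 0.5 step), an explicit
    ``missing`` record, labels at 2.25 and >= 2.5 (aggregate into >2), and
    frequencies summing to 0.94 so the shortfall-to-1 rule fires.
    """
    rows = [
        ("0", 0.02),
        ("0.25", 0.03),
        ("0.5", 0.05),
        ("0.75", 0.04),
        ("1", 0.20),
        ("1.25", 0.06),
        ("1.5", 0.10),
        ("1.75", 0.07),
        ("2", 0.25),
        ("2.25", 0.01),
        ("2.5", 0.02),
        ("3", 0.03),
        ("6", 0.01),
        ("missing", 0.05),
    ]
    return [
        RawFrequencyRecord(group=SYNTHETIC_GROUP, score_label=lbl, frequency=f)
        for lbl, f in rows
    ]


def raw_frequency_fixture_expected() -> dict[str, float]:
    """Hand-computed six-class table for :func:`raw_frequency_fixture`.

    0.25->0.5, 0.75->1, 1.25->1.5, 1.75->2; 2.25 and >=2.5 -> >2;
    missing 0.05 plus shortfall 0.06 -> class 2.
    """
    return {
        "0": 0.02,
        "0.5": 0.08,
        "1": 0.24,
        "1.5": 0.16,
        "2": 0.43,
        ">2": 0.07,
    }
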