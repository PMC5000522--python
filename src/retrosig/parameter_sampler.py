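"""Latin-hypercube sampling of cascade biochemical parameters.

The parameter scan draws the 18 dimensional constants of a 3-tier cascade --
per tier the totals ``Y_iT`` and ``E_iT``, the Michaelis constants ``K0_i``
and ``K1_i`` and the catalytic rates ``k0_i`` and ``k1_i`` -- log10-uniformly
on [-2, 2] (4 decades around a free reference concentration) with Latin
hypercube stratification: each dimension is cut into ``n_samples`` equal
strata and every stratum receives exactly one draw.  Complex dissociation
rates are fixed to 1 and association rates derived from the sampled
Michaelis constants, so the ODE engine and the map see the same chemistry.

The upstream activator total and the drug constants are not sampled: the
scan evaluates the exact stimulus -> infinity and drug in {0, infinity}
limits, in which they drop out.

From each sample the module also derives the 18 dimensionless ratios
(lambda) analyzed by the likelihood machinery; each ratio is a signed
product of 2 or 4 sampled parameters, which is what makes its log10 prior an
exact convolution of uniforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "SAMPLED_NAMES",
    "LAMBDA_DEFS",
    "SampleSet",
    "latin_hypercube",
    "sample_biochemical",
    "dimensionless_ratios",
    "lambda_support",
]

#: sampled biochemical parameters, tier-major order
SAMPLED_NAMES: tuple[str, ...] = tuple(
    f"{base}_{i}" for i in (1, 2, 3) for base in ("Y_T", "E_T", "K0", "K1", "k0", "k1")
)

#: dimensionless ratios: name -> list of (sampled parameter, sign of log10)
LAMBDA_DEFS: dict[str, list[tuple[str, int]]] = {
    # phosphatase sequestration per tier
    "E_1T/Y_1T": [("E_T_1", 1), ("Y_T_1", -1)],
    "E_2T/Y_2T": [("E_T_2", 1), ("Y_T_2", -1)],
    "E_3T/Y_3T": [("E_T_3", 1), ("Y_T_3", -1)],
    # within-cycle enzymatic asymmetry
    "K0_1/K1_1": [("K0_1", 1), ("K1_1", -1)],
    "K0_2/K1_2": [("K0_2", 1), ("K1_2", -1)],
    "K0_3/K1_3": [("K0_3", 1), ("K1_3", -1)],
    # junction asymmetry
    "K0_2/K1_1": [("K0_2", 1), ("K1_1", -1)],
    "K0_3/K1_2": [("K0_3", 1), ("K1_2", -1)],
    # bottom-tier kinase saturation
    "K0_3/Y_3T": [("K0_3", 1), ("Y_T_3", -1)],
    # cycle activation 1/e_i = k0_i Y_{i-1,T} / (k1_i E_iT)
    "1/e_2": [("k0_2", 1), ("Y_T_1", 1), ("k1_2", -1), ("E_T_2", -1)],
    "1/e_3": [("k0_3", 1), ("Y_T_2", 1), ("k1_3", -1), ("E_T_3", -1)],
    # protein progression
    "Y_1T/Y_2T": [("Y_T_1", 1), ("Y_T_2", -1)],
    "Y_2T/Y_3T": [("Y_T_2", 1), ("Y_T_3", -1)],
    # phosphatase saturation per tier
    "K1_1/Y_1T": [("K1_1", 1), ("Y_T_1", -1)],
    "K1_2/Y_2T": [("K1_2", 1), ("Y_T_2", -1)],
    "K1_3/Y_3T": [("K1_3", 1), ("Y_T_3", -1)],
    # kinase saturation, tiers 1-2
    "K0_1/Y_1T": [("K0_1", 1), ("Y_T_1", -1)],
    "K0_2/Y_2T": [("K0_2", 1), ("Y_T_2", -1)],
}
assert len(LAMBDA_DEFS) == 18


@dataclass
class SampleSet:
    """One Latin-hypercube draw of biochemical parameter sets."""

    seed: int
    n_samples: int
    log10_range: tuple[float, float]
    params: pd.DataFrame  # columns SAMPLED_NAMES, linear scale
    log10_params: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        if self.log10_params is None:
            self.log10_params = np.log10(self.params)

    def ratios(self, names=None) -> pd.DataFrame:
        """log10 of the dimensionless ratios, one column per lambda."""
        return dimensionless_ratios(self.log10_params, names=names, log10=True)


def latin_hypercube(n_samples: int, n_dims: int, seed: int) -> np.ndarray:
    """Unit-cube Latin hypercube sample: one point per stratum per dimension.

    Strata are assigned by independent random permutations (sampling without
    replacement at the stratum level) with uniform within-stratum jitter;
    deterministic for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sampler = qmc.LatinHypercube(d=n_dims, seed=int(seed))
    return sampler.random(n=n_samples)


def sample_biochemical(
    n_samples: int,
    log10_range: tuple[float, float] = (-2.0, 2.0),
    seed: int = 0,
) -> SampleSet:
    """Draw the 18 biochemical parameters of a 3-tier cascade by LHS."""
    lo, hi = map(float, log10_range)
    if not hi > lo:
        raise ValueError(f"empty log10 range {log10_range}")
    unit = latin_hypercube(n_samples, len(SAMPLED_NAMES), seed)
    logs = pd.DataFrame(lo + (hi - lo) * unit, columns=list(SAMPLED_NAMES))
    return SampleSet(
        seed=int(seed),
        n_samples=int(n_samples),
        log10_range=(lo, hi),
        params=10.0 ** logs,
        log10_params=logs,
    )


def dimensionless_ratios(params: pd.DataFrame, names=None, log10: bool = False):
    """Derive the named dimensionless ratios from sampled parameters.

    ``params`` holds the sampled values, in log10 if ``log10=True`` else
    linear.  Returns a DataFrame of log10(lambda) values.
    """
    logs = params if log10 else np.log10(params)
    names = list(LAMBDA_DEFS) if names is None else list(names)
    out = {}
    for name in names:
        terms = LAMBDA_DEFS.get(name)
        if terms is None:
            if name in logs.columns:  # raw sampled parameter (m = 1)
                terms = [(name, 1)]
            else:
                raise KeyError(f"unknown dimensionless parameter {name!r}")
        acc = np.zeros(len(logs))
        for pname, sign in terms:
            acc = acc + sign * logs[pname].to_numpy()
        out[name] = acc
    return pd.DataFrame(out, index=logs.index)


def lambda_signs(name: str) -> list[int]:
    """Signs of the log10 factors composing a ratio (m = 1, 2 or 4)."""
    if name in LAMBDA_DEFS:
        return [sign for _, sign in LAMBDA_DEFS[name]]
    if name in SAMPLED_NAMES:
        return [1]
    raise KeyError(f"unknown dimensionless parameter {name!r}")


def lambda_support(name: str, log10_range=(-2.0, 2.0)) -> tuple[float, float]:
    """Support of log10(lambda) given the sampling range."""
    lo, hi = map(float, log10_range)
    signs = lambda_signs(name)
    low = sum(lo if s > 0 else -hi for s in signs)
    high = sum(hi if s > 0 else -lo for s in signs)
    return low, high
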