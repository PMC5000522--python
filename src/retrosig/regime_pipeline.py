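"""Per-sample signaling amplitudes, regime classification and summary tables.

For every sampled 3-tier cascade the pipeline measures three steady-state
response amplitudes in the exact scan limits (stimulus -> infinity; drug
either absent or saturating, the latter realized as the 2-tier truncated
cascade):

* ``dx1`` -- second-order retroactivity: change of tier-1 activity when the
  drug saturates, ``x_1(d->inf) - x_1(d=0)`` (non-positive for n = 3);
* ``dx2`` -- first-order retroactivity: same difference at tier 2
  (non-negative for n = 3, by the alternation of upstream responses);
* ``dx3`` -- forward activity: the drug-free dose-response amplitude
  ``x_3(s->inf) - x_3(0)``, i.e. the saturation value alpha.

A sample's regime is the binary triple (jkl): j and k flag |dx1| and |dx2|
above the retroactivity threshold, l flags an efficient forward response --
amplitude above threshold and, optionally, initial slope above 1 or initial
curvature at least 1.  Tables aggregate regime frequencies with binomial
standard errors, the four signaling modes, and the conditional probability
of bidirectional signaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade_model import BiochemicalParams, _limit_profile_batch
from .parameter_sampler import SampleSet
from .response_analytics import slope_curvature_batch

__all__ = [
    "Thresholds",
    "THRESHOLD_SET_1",
    "THRESHOLD_SET_2",
    "REGIMES",
    "response_amplitudes",
    "amplitudes_table",
    "classify",
    "regime_table",
    "aggregate_modes",
    "conditional_bidirectional",
    "motif_descriptor",
]

#: the 8 concrete regimes, in the reporting order of the probability tables
REGIMES: tuple[str, ...] = ("000", "001", "010", "011", "110", "100", "111", "101")


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds for the regime label (jkl)."""

    retro_min: float = 0.05  # |dx1|, |dx2| must exceed this for j, k = 1
    forward_min: float = 0.50  # dx3 must exceed this for l = 1
    slope_min: float = 1.0  # sigma threshold in the optional l clause
    curv_min: float = 1.0  # chi threshold in the optional l clause
    use_slope_curv_clause: bool = True

    def __post_init__(self):
        if min(self.retro_min, self.forward_min) <= 0:
            raise ValueError("amplitude thresholds must be positive")


THRESHOLD_SET_1 = Thresholds(retro_min=0.05, forward_min=0.50)
THRESHOLD_SET_2 = Thresholds(retro_min=0.10, forward_min=0.75)


# ---------------------------------------------------------------------------
# amplitudes
# ---------------------------------------------------------------------------

def _dimensionless_arrays(params: pd.DataFrame):
    """Stack sampled biochemical columns into (m, 3) map-parameter arrays."""
    get = lambda name: params[name].to_numpy(dtype=float)
    Y = np.stack([get(f"Y_T_{i}") for i in (1, 2, 3)], axis=-1)
    E = np.stack([get(f"E_T_{i}") for i in (1, 2, 3)], axis=-1)
    K0 = np.stack([get(f"K0_{i}") for i in (1, 2, 3)], axis=-1)
    K1 = np.stack([get(f"K1_{i}") for i in (1, 2, 3)], axis=-1)
    k0 = np.stack([get(f"k0_{i}") for i in (1, 2, 3)], axis=-1)
    k1 = np.stack([get(f"k1_{i}") for i in (1, 2, 3)], axis=-1)
    a = K1 / Y
    b = K0 / Y
    c = (1.0 + k1 / k0) * E / Y
    e = np.empty_like(a)
    e[..., 0] = 1.0  # tier-1 ratio never enters the map
    e[..., 1:] = (k1[..., 1:] * E[..., 1:]) / (k0[..., 1:] * Y[..., :-1])
    return a, b, c, e


def response_amplitudes(
    samples: SampleSet | pd.DataFrame, engine: str = "map"
) -> pd.DataFrame:
    """Amplitudes (dx1, dx2, dx3) and origin analytics for every sample.

    ``engine="map"`` evaluates the exact branch-limit states of the full and
    truncated cascades (vectorized); ``engine="ode"`` integrates the
    mass-action system per sample and is the slow validation path.  Returns
    a DataFrame with columns dx1, dx2, dx3, sigma, chi, converged.
    """
    params = samples.params if isinstance(samples, SampleSet) else samples
    if engine == "ode":
        from . import ode_engine

        return ode_engine.response_amplitudes_ode(params)
    if engine != "map":
        raise ValueError(f"unknown engine {engine!r}")
    a, b, c, e = _dimensionless_arrays(params)
    x_full, _ = _limit_profile_batch(a, b, c, e, 0.0, 1.0)
    x_trunc, _ = _limit_profile_batch(a[..., :2], b[..., :2], c[..., :2],
                                      e[..., :2], 0.0, 1.0)
    sigma, chi = slope_curvature_batch(a, b, c, e)
    return pd.DataFrame(
        {
            "dx1": x_trunc[..., 0] - x_full[..., 0],
            "dx2": x_trunc[..., 1] - x_full[..., 1],
            "dx3": x_full[..., 2],
            "sigma": sigma,
            "chi": chi,
            "converged": True,
        },
        index=params.index,
    )


def amplitudes_table(samples: SampleSet, engine: str = "map") -> pd.DataFrame:
    """Records table: sampled parameters joined with amplitudes and labels
    under both predefined threshold sets."""
    rec = response_amplitudes(samples, engine=engine)
    rec["regime_t1"] = classify(rec, THRESHOLD_SET_1)
    rec["regime_t2"] = classify(rec, THRESHOLD_SET_2)
    return rec


# ---------------------------------------------------------------------------
# classification and tables
# ---------------------------------------------------------------------------

def classify(records: pd.DataFrame, th: Thresholds) -> pd.Series:
    """Regime label (jkl) per record.

    j and k compare |dx1| and |dx2| to the retroactivity threshold (the two
    amplitudes have opposite signs by alternation, hence the absolute
    values).  l requires dx3 above the forward threshold and, when the
    clause is enabled, an initial slope above ``slope_min`` or curvature at
    least ``curv_min``.
    """
    j = np.abs(records["dx1"].to_numpy()) > th.retro_min
    k = np.abs(records["dx2"].to_numpy()) > th.retro_min
    l = records["dx3"].to_numpy() > th.forward_min
    if th.use_slope_curv_clause:
        l &= (records["sigma"].to_numpy() > th.slope_min) | (
            records["chi"].to_numpy() >= th.curv_min
        )
    labels = np.char.add(
        np.char.add(j.astype(int).astype(str), k.astype(int).astype(str)),
        l.astype(int).astype(str),
    )
    return pd.Series(labels, index=records.index, name="regime")


def regime_table(labels: pd.Series, converged=None) -> pd.DataFrame:
    """Percentage of each of the 8 regimes with binomial standard errors."""
    if converged is not None:
        labels = labels[np.asarray(converged, bool)]
    n = len(labels)
    if n == 0:
        raise ValueError("no converged records to tabulate")
    counts = labels.value_counts()
    rows = []
    for regime in REGIMES:
        cnt = int(counts.get(regime, 0))
        p = cnt / n
        rows.append(
            {
                "regime": regime,
                "count": cnt,
                "pct": 100.0 * p,
                "stderr": 100.0 * np.sqrt(p * (1.0 - p) / n),
            }
        )
    return pd.DataFrame(rows).set_index("regime")


def aggregate_modes(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the 8 regimes into the 4 signaling modes."""
    groups = {
        "none": ["000"],
        "forward_only": ["001"],
        "retro_only": ["010", "100", "110"],
        "both": ["011", "101", "111"],
    }
    rows = []
    for mode, members in groups.items():
        pct = float(table.loc[members, "pct"].sum())
        err = float(np.sqrt((table.loc[members, "stderr"] ** 2).sum()))
        rows.append({"mode": mode, "pct": pct, "stderr": err})
    return pd.DataFrame(rows).set_index("mode")


def conditional_bidirectional(table: pd.DataFrame) -> float:
    """Probability of bidirectional signaling given any signaling:
    100 * P(both) / (100 - P(000))."""
    p000 = float(table.loc["000", "pct"])
    if p000 >= 100.0:
        raise ZeroDivisionError("no signaling samples: conditional undefined")
    both = float(table.loc[["011", "101", "111"], "pct"].sum())
    return 100.0 * both / (100.0 - p000)


# ---------------------------------------------------------------------------
# symbolic motif descriptor
# ---------------------------------------------------------------------------

def motif_descriptor(
    p: BiochemicalParams, much_factor: float = 10.0, magnitude_factor: float = 100.0
) -> dict:
    """Symbolic signaling-motif record for a 3-tier cascade.

    Encodes, as text, the pictorial rules summarizing which parameter
    relations promote each regime: relative sizes of the protein and
    phosphatase totals, arrow directions from the cycle activation ratios,
    fill flags from enzyme saturation, and contour cusps marking
    second-order retroactivity (start) and forward signaling (end).
    ``much_factor`` quantifies ">>" generally; ``magnitude_factor`` the
    "magnitude difference larger than 100" comparisons between protein
    totals.
    """
    if p.n != 3:
        raise ValueError("motif rules are defined for 3-tier cascades")
    Y, E, K0, K1 = p.Y_T, p.E_T, p.K0, p.K1
    e = np.empty(3)
    e[0] = np.nan
    e[1:] = (p.k1[1:] * E[1:]) / (p.k0[1:] * Y[:-1])

    y_size = ["medium", "medium", "medium"]
    if Y[1] / Y[2] > magnitude_factor:  # Y_2T >> Y_3T
        y_size[1], y_size[2] = "large", "medium"
        if Y[1] / Y[0] > much_factor:
            y_size[0] = "medium"
    elif Y[2] / Y[1] > magnitude_factor:  # Y_2T << Y_3T
        y_size[1], y_size[2] = "medium", "large"
        if Y[0] / Y[1] > much_factor:
            y_size[0] = "large"
    elif Y[1] < Y[2]:  # moderate increase
        y_size[1], y_size[2] = "medium", "large"
        y_size[0] = "small" if Y[0] < Y[1] else "medium"

    e_size = []
    for i in range(3):
        if Y[i] / E[i] > much_factor:
            e_size.append("small")
        elif E[i] / Y[i] > much_factor:
            e_size.append("extra large")
        else:
            e_size.append(y_size[i])

    arrows = {
        f"junction_{i + 1}": ("up" if e[i] > 1 else "down") for i in (1, 2)
    }
    fills = {
        "red_triangle": bool(Y[0] / K0[0] > much_factor),
        "blue_ellipse_1": bool(Y[1] / K0[1] > much_factor),
        "blue_ellipse_2": bool(Y[2] / K0[2] > much_factor),
        "green_ellipse_1": bool(Y[0] / K1[0] > much_factor),
        "green_ellipse_2": bool(Y[1] / K1[1] > much_factor),
        "green_ellipse_3": bool(Y[2] / K1[2] > much_factor),
    }
    start_cusp = (not fills["red_triangle"]) and fills["blue_ellipse_1"]
    end_cusp = bool(e_size[2] == "small")  # bottom phosphatase in small amount
    return {
        "Y_sizes": dict(zip(("Y_1T", "Y_2T", "Y_3T"), y_size)),
        "E_sizes": dict(zip(("E_1T", "E_2T", "E_3T"), e_size)),
        "arrows": arrows,
        "fills": fills,
        "start_cusp": start_cusp,
        "end_cusp": end_cusp,
    }
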