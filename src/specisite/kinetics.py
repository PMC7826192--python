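"""Michaelis--Menten kinetics: fitting, catalytic efficiency, and
mutant-vs-wild-type fold changes.

Initial-rate data ``v([S])`` are fit to ``v = V_max [S] / (K_M + [S])``
by unweighted nonlinear least squares on the untransformed rates (no
Lineweaver--Burk linearization).  Units are fixed: [S] and K_M in µM,
rates in µM/s, k_cat = V_max/[E] in 1/s, catalytic efficiency
k_cat/K_M in mM^-1 s^-1.  Replicates are fit independently and the
parameters averaged (mean ± SD) — which is why a reported mean
efficiency need not equal the ratio of the mean k_cat and mean K_M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class RateSeries:
    """One replicate's rate-vs-substrate curve for an enzyme/substrate pair."""

    enzyme: str
    substrate: str
    enzyme_conc_uM: float
    S_uM: np.ndarray
    v_uM_per_s: np.ndarray
    replicate: int = 1

    def __post_init__(self) -> None:
        self.S_uM = np.asarray(self.S_uM, dtype=float)
        self.v_uM_per_s = np.asarray(self.v_uM_per_s, dtype=float)
        if self.S_uM.shape != self.v_uM_per_s.shape:
            raise ValueError("S and v must have equal length")
        if np.any(self.S_uM < 0) or np.any(self.v_uM_per_s < 0):
            raise ValueError("concentrations and rates must be non-negative")
        if len(np.unique(self.S_uM)) != len(self.S_uM):
            raise ValueError("duplicate substrate concentrations in one series")
        if self.enzyme_conc_uM <= 0:
            raise ValueError("enzyme concentration must be positive")
        if len(self.S_uM) < 4:
            warnings.warn(
                f"{self.enzyme}/{self.substrate}: fewer than 4 concentrations; "
                "fit may be ill-posed"
            )


@dataclass
class KineticsFit:
    enzyme: str
    substrate: str
    V_max: float  # µM/s
    K_M: float  # µM
    k_cat: float  # 1/s
    efficiency: float  # k_cat/K_M in mM^-1 s^-1
    V_max_se: float = np.nan
    K_M_se: float = np.nan
    converged: bool = True
    n_points: int = 0

    @staticmethod
    def efficiency_from(k_cat: float, K_M_uM: float) -> float:
        """k_cat/K_M with the single µM -> mM conversion the package uses."""
        return k_cat / (K_M_uM / 1000.0)


def michaelis_menten(S: np.ndarray, V_max: float, K_M: float) -> np.ndarray:
    return V_max * S / (K_M + S)


def _initial_guess(S: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    V0 = float(v.max())
    half = V0 / 2.0
    order = np.argsort(S)
    S_sorted, v_sorted = S[order], v[order]
    K0 = float(S_sorted[np.argmin(np.abs(v_sorted - half))])
    if len(S_sorted) > 1:  # linear interpolation around the half-max crossing
        above = np.where(v_sorted >= half)[0]
        if above.size and above[0] > 0:
            i = above[0]
            s0, s1 = S_sorted[i - 1], S_sorted[i]
            v0, v1 = v_sorted[i - 1], v_sorted[i]
            if v1 > v0:
                K0 = float(s0 + (half - v0) * (s1 - s0) / (v1 - v0))
    return V0, max(K0, 1e-6)


def fit_mm(series: RateSeries) -> KineticsFit:
    """Fit one replicate to the Michaelis--Menten equation.

    Initialization: V_max at the maximum observed rate, K_M at the
    interpolated half-maximal substrate concentration.  Standard errors
    come from the fit covariance.  Non-convergence (or a fit pinned at
    the parameter bounds) is flagged rather than raised.
    """
    S, v = series.S_uM, series.v_uM_per_s
    if len(np.unique(S)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    p0 = _initial_guess(S, v)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                michaelis_menten,
                S,
                v,
                p0=p0,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=10000,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        se = np.sqrt(np.diag(pcov))
    except RuntimeError:
        popt, se = np.array(p0), np.array([np.nan, np.nan])
        converged = False
    V_max, K_M = float(popt[0]), float(popt[1])
    k_cat = V_max / series.enzyme_conc_uM
    return KineticsFit(
        enzyme=series.enzyme,
        substrate=series.substrate,
        V_max=V_max,
        K_M=K_M,
        k_cat=k_cat,
        efficiency=KineticsFit.efficiency_from(k_cat, K_M),
        V_max_se=float(se[0]),
        K_M_se=float(se[1]),
        converged=converged,
        n_points=len(S),
    )


@dataclass
class AveragedFit:
    """Replicate fits averaged parameter-wise (mean ± SD)."""

    enzyme: str
    substrate: str
    k_cat_mean: float
    k_cat_sd: float
    K_M_mean: float
    K_M_sd: float
    efficiency_mean: float  # mean of per-replicate efficiencies
    efficiency_sd: float
    efficiency_of_means: float  # ratio computed from the mean parameters
    n_replicates: int
    replicate_fits: list[KineticsFit] = field(default_factory=list)


def fit_replicates(series_list: Sequence[RateSeries]) -> AveragedFit:
    """Fit each replicate independently, then average parameters."""
    fits = [fit_mm(s) for s in series_list]
    good = [f for f in fits if f.converged]
    if not good:
        raise RuntimeError("no replicate converged")
    k_cats = np.array([f.k_cat for f in good])
    K_Ms = np.array([f.K_M for f in good])
    effs = np.array([f.efficiency for f in good])
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return AveragedFit(
        enzyme=good[0].enzyme,
        substrate=good[0].substrate,
        k_cat_mean=float(k_cats.mean()),
        k_cat_sd=sd(k_cats),
        K_M_mean=float(K_Ms.mean()),
        K_M_sd=sd(K_Ms),
        efficiency_mean=float(effs.mean()),
        efficiency_sd=sd(effs),
        efficiency_of_means=KineticsFit.efficiency_from(
            float(k_cats.mean()), float(K_Ms.mean())
        ),
        n_replicates=len(good),
        replicate_fits=fits,
    )


_FOLD_PARAMS = {"V_max", "K_M", "k_cat", "efficiency"}


def fold_change(param: str, a, b) -> float:
    """Fold change of ``param`` in ``b`` relative to ``a`` (``b/a``).

    ``a`` and ``b`` may be :class:`KineticsFit` objects, averaged fits
    (the ``*_mean`` field is used), or plain numbers — the latter lets
    published parameter tables be compared directly.
    """

    def value(x) -> float:
        if isinstance(x, (int, float)):
            return float(x)
        if hasattr(x, param):
            if isinstance(x, KineticsFit) and not x.converged:
                raise ValueError("fold change of a non-converged fit")
            return float(getattr(x, param))
        if hasattr(x, f"{param}_mean"):
            return float(getattr(x, f"{param}_mean"))
        raise AttributeError(f"cannot read parameter {param!r} from {type(x)}")

    if param not in _FOLD_PARAMS:
        raise ValueError(f"unknown parameter {param!r}")
    denom = value(a)
    if denom == 0:
        raise ZeroDivisionError("reference parameter is zero")
    return value(b) / denom


def normalize_slopes(
    slopes: dict[str, float], reference: str
) -> dict[str, float]:
    """Express assay slopes as fold change over a reference enzyme.

    Used for fluorogenic deacetylation (FDL-style) initial slopes: each
    enzyme's slope is divided by the wild-type slope, so the reference
    maps to exactly 1.0.
    """
    if reference not in slopes:
        raise KeyError(f"reference {reference!r} not among slopes")
    ref = slopes[reference]
    if ref <= 0:
        raise ValueError("reference slope must be positive")
    return {k: v / ref for k, v in slopes.items()}


def read_rate_table(path) -> list[RateSeries]:
    """Read a rates CSV with columns enzyme, substrate, replicate, E_uM,
    S_uM, v_uM_per_s into per-replicate :class:`RateSeries`."""
    df = pd.read_csv(path)
    required = {"enzyme", "substrate", "replicate", "E_uM", "S_uM", "v_uM_per_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    out = []
    for (enz, sub, rep), grp in df.groupby(
        ["enzyme", "substrate", "replicate"], sort=True
    ):
        out.append(
            RateSeries(
                enzyme=str(enz),
                substrate=str(sub),
                enzyme_conc_uM=float(grp["E_uM"].iloc[0]),
                S_uM=grp["S_uM"].to_numpy(),
                v_uM_per_s=grp["v_uM_per_s"].to_numpy(),
                replicate=int(rep),
            )
        )
    return out


def summary_table(avg_fits: Sequence[AveragedFit]) -> pd.DataFrame:
    """Kinetic-parameter table: one row per enzyme/substrate pair with
    mean ± SD columns, mirroring the conventional presentation."""
    rows = []
    for f in avg_fits:
        rows.append(
            {
                "enzyme": f.enzyme,
                "substrate": f.substrate,
                "k_cat_per_s": f.k_cat_mean,
                "k_cat_sd": f.k_cat_sd,
                "K_M_uM": f.K_M_mean,
                "K_M_sd": f.K_M_sd,
                "efficiency_mM_s": f.efficiency_mean,
                "efficiency_sd": f.efficiency_sd,
                "efficiency_of_means": f.efficiency_of_means,
                "n_replicates": f.n_replicates,
            }
        )
    return pd.DataFrame(rows)
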