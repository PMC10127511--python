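"""Quantification of intracellular/extracellular pH dynamics.

Covers the wet-lab arithmetic around pH-sensitive fluorophore recordings:

* linear nigericin calibration mapping fluorescence ratio to pH;
* intrinsic buffering capacity from the NH4Cl prepulse (NH3 assumed in
  transmembrane equilibrium, so [NH4+]_i = [NH4+]_o * 10**(pH_o - pH_i));
* CO2/HCO3- buffering, beta = 2.3 * [HCO3-]_i with [HCO3-]_i inferred from
  transmembrane CO2 equilibration, [HCO3-]_i = [HCO3-]_o * 10**(pH_i - pH_o);
* net acid extrusion J = (dpH_i/dt) * beta_total(pH_i), binned on pH_i,
  and its Na+-dependent component by with/without-Na differencing;
* the CO2-hydration assay (steepest acidification after CO2 addition);
* core-periphery pH gradients, microdialysis recovery correction, and
  qPCR relative expression 2**(-dCT) against the mean of two references.

Flux units: buffering capacities in mM per pH unit, recovery rates in pH/s,
fluxes reported in mM/min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

EPOCH_LABELS = (
    "baseline",
    "NH4_add",
    "NH4_washout",
    "Na_free",
    "Na_restored",
    "CO2_on",
    "CO2_off",
)

PKA_NH4_37C = 8.9  # NH4+/NH3 at 37 degrees C


@dataclass
class Epoch:
    label: str
    start: float


@dataclass
class FluorescenceTrace:
    """A single-ROI time series of pH (or raw ratio) with epoch markers."""

    time: np.ndarray
    value: np.ndarray
    unit: str = "pH"  # "pH" or "ratio"
    compartment: str = "intracellular"
    region: str = "bath"
    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must align")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for ep in self.epochs:
            if not self.time[0] <= ep.start <= self.time[-1]:
                raise ValueError(f"epoch {ep.label} starts outside the trace")

    def epoch_start(self, label: str) -> float:
        for ep in self.epochs:
            if ep.label == label:
                return ep.start
        raise KeyError(f"trace has no epoch {label!r}")

    def has_epoch(self, label: str) -> bool:
        return any(ep.label == label for ep in self.epochs)

    def segment(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Time/value slice from an epoch start to the next epoch start."""
        starts = sorted(ep.start for ep in self.epochs)
        t0 = self.epoch_start(label)
        later = [s for s in starts if s > t0]
        t1 = later[0] if later else self.time[-1] + 1.0
        mask = (self.time >= t0) & (self.time < t1)
        return self.time[mask], self.value[mask]

    def to_frame(self) -> pd.DataFrame:
        labels = np.full(self.time.shape, "", dtype=object)
        for ep in self.epochs:
            idx = int(np.searchsorted(self.time, ep.start))
            idx = min(idx, len(labels) - 1)
            labels[idx] = ep.label
        return pd.DataFrame({"time_s": self.time, "value": self.value, "epoch_label": labels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "FluorescenceTrace":
        epochs = [
            Epoch(str(row.epoch_label), float(row.time_s))
            for row in df.itertuples()
            if isinstance(row.epoch_label, str) and row.epoch_label
        ]
        return cls(
            time=df["time_s"].to_numpy(),
            value=df["value"].to_numpy(),
            epochs=epochs,
            **kwargs,
        )


@dataclass
class Solution:
    """Bath/superfusate composition relevant to the buffering equations."""

    pH_o: float = 7.4
    HCO3_o: float = 22.0  # mM
    NH4Cl_total: float = 0.0  # mM
    Na_present: bool = True
    CO2_present: bool = True
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if not 6.0 < self.pH_o < 8.5:
            raise ValueError("pH_o out of physiological range (6, 8.5)")
        if self.HCO3_o < 0 or self.NH4Cl_total < 0:
            raise ValueError("concentrations must be >= 0")


class RatioCalibration(RegressorMixin, BaseEstimator):
    """Linear high-[K+]/nigericin calibration pH = slope * ratio + intercept.

    ``fit(ratio, pH)`` is ordinary least squares; ``predict`` maps ratios to
    pH and ``inverse`` maps pH back to ratio (round trip is exact).
    """

    def fit(self, ratio, ph):
        ratio = np.asarray(ratio, dtype=float)
        ph = np.asarray(ph, dtype=float)
        if ratio.size < 2 or np.unique(ratio).size < 2:
            raise ValueError("need >=2 distinct calibration ratios")
        res = stats.linregress(ratio, ph)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        resid = ph - self.predict(ratio)
        dof = max(ratio.size - 2, 1)
        self.residual_sd_ = float(np.sqrt((resid**2).sum() / dof))
        self.points_ = np.column_stack([ratio, ph])
        return self

    def predict(self, ratio):
        return self.slope_ * np.asarray(ratio, dtype=float) + self.intercept_

    def inverse(self, ph):
        return (np.asarray(ph, dtype=float) - self.intercept_) / self.slope_


def fit_calibration(points) -> RatioCalibration:
    """Functional form: ``points`` is a sequence of (ratio, known pH)."""
    arr = np.asarray(points, dtype=float)
    return RatioCalibration().fit(arr[:, 0], arr[:, 1])


def ammonium_out(sol: Solution, pKa: float = PKA_NH4_37C) -> float:
    """Extracellular [NH4+] from total NH4Cl by Henderson-Hasselbalch."""
    return sol.NH4Cl_total / (1.0 + 10.0 ** (sol.pH_o - pKa))


def ammonium_in(pH_i: float, sol: Solution, pKa: float = PKA_NH4_37C) -> float:
    """Intracellular [NH4+] assuming NH3 equilibrates across the membrane."""
    return ammonium_out(sol, pKa) * 10.0 ** (sol.pH_o - pH_i)


@dataclass
class BufferingModel:
    """Total intracellular buffering beta_total(pH_i).

    ``beta_intrinsic`` may be a scalar (single-value estimate, the default
    usage) or a callable of pH_i (piecewise estimates).  When the solution
    contains CO2/HCO3- the open-system bicarbonate buffering
    2.3 * [HCO3-]_i(pH_i) is added.
    """

    beta_intrinsic: float | object
    solution: Solution = field(default_factory=Solution)

    def intrinsic(self, pH_i):
        if callable(self.beta_intrinsic):
            return np.asarray(self.beta_intrinsic(pH_i), dtype=float)
        return np.full_like(np.asarray(pH_i, dtype=float), float(self.beta_intrinsic))

    def bicarbonate(self, pH_i):
        return bicarbonate_buffering(pH_i, self.solution)

    def total(self, pH_i):
        return self.intrinsic(pH_i) + self.bicarbonate(pH_i)


def intrinsic_buffering(
    trace: FluorescenceTrace,
    sol_before_washout: Solution,
    pKa_NH4: float = PKA_NH4_37C,
    noise_floor: float = 0.05,
    smooth_s: float = 5.0,
) -> dict:
    """Intrinsic buffering capacity from the NH4Cl washout acidification.

    beta_i = delta[NH4+]_i / delta pH_i, where delta[NH4+]_i is the
    intracellular ammonium present at the pre-washout plateau (it drops to
    zero on washout) and delta pH_i is plateau minus post-washout nadir.
    The plateau is the mean of the last 10 s of the NH4 epoch; the nadir is
    the minimum of a rolling-mean-smoothed washout segment (``smooth_s``
    seconds), so photometric noise does not systematically deepen the
    nadir.  Requires a CO2/HCO3--free solution so only intrinsic buffers
    act.
    """
    if sol_before_washout.CO2_present:
        raise ValueError("intrinsic buffering requires a CO2/HCO3–-free solution")
    if sol_before_washout.NH4Cl_total <= 0:
        raise ValueError("solution carries no NH4Cl")
    t_add, v_add = trace.segment("NH4_add")
    t_wo, v_wo = trace.segment("NH4_washout")
    if trace.has_epoch("Na_free"):
        t_nf, v_nf = trace.segment("Na_free")
        t_wo = np.concatenate([t_wo, t_nf])
        v_wo = np.concatenate([v_wo, v_nf])
    # plateau: mean of the last 10 s of the NH4 epoch
    tail = t_add >= t_add[-1] - 10.0
    ph_plateau = float(v_add[tail].mean())
    if smooth_s > 0 and len(t_wo) > 2:
        dt = float(np.median(np.diff(t_wo)))
        v_wo = _smooth(v_wo, max(int(round(smooth_s / dt)), 1))
    ph_nadir = float(v_wo.min())
    dph = ph_plateau - ph_nadir
    if dph < noise_floor:
        raise ValueError(
            f"washout acidification {dph:.3f} below noise floor {noise_floor}"
        )
    nh4_i = ammonium_in(ph_plateau, sol_before_washout, pKa_NH4)
    beta = nh4_i / dph
    return {
        "beta_intrinsic": beta,
        "pH_plateau": ph_plateau,
        "pH_nadir": ph_nadir,
        "delta_pH": dph,
        "NH4_i_mM": nh4_i,
    }


def bicarbonate_buffering(pH_i, sol: Solution):
    """Open-system CO2/HCO3- buffering, beta = 2.3 * [HCO3-]_i.

    [HCO3-]_i follows from transmembrane CO2 equilibration:
    [HCO3-]_i = [HCO3-]_o * 10**(pH_i - pH_o).  Returns 0 when the solution
    is CO2-free (noted in the log).
    """
    pH_i = np.asarray(pH_i, dtype=float)
    if not sol.CO2_present:
        logger.info("bicarbonate_buffering: CO2-free solution, beta_b = 0")
        return np.zeros_like(pH_i) if pH_i.ndim else 0.0
    hco3_i = sol.HCO3_o * 10.0 ** (pH_i - sol.pH_o)
    beta = 2.3 * hco3_i
    return beta if pH_i.ndim else float(beta)


@dataclass
class FluxEstimate:
    """Net acid extrusion J (mM/min) per pH_i bin."""

    bin_centers: np.ndarray
    J: np.ndarray  # mM/min
    n_samples: np.ndarray
    na_dependent: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pH_bin": self.bin_centers, "J_mM_per_min": self.J, "n": self.n_samples}
        )


def _smooth(values: np.ndarray, n: int) -> np.ndarray:
    n = min(n, len(values))
    if n <= 1:
        return values
    kernel = np.ones(n) / n
    pad = n // 2
    padded = np.concatenate([np.full(pad, values[0]), values, np.full(n - 1 - pad, values[-1])])
    return np.convolve(padded, kernel, mode="valid")


def net_acid_extrusion(
    trace: FluorescenceTrace,
    buffering: BufferingModel,
    bin_width: float = 0.05,
    recovery_epoch: str | None = None,
    smooth_s: float = 5.0,
    min_samples: int = 3,
) -> FluxEstimate:
    """Net acid extrusion flux J(pH_i) = (dpH_i/dt) x beta_total(pH_i).

    The recovery segment (``Na_restored`` if present, else the washout
    epoch) is cut into fixed pH_i bins; within each bin the recovery rate
    is the least-squares slope of the raw pH samples against time.  Bin
    membership is decided on a rolling-mean-smoothed copy of the trace so
    that photometric noise does not bias the within-bin slope.  Bins with
    fewer than ``min_samples`` samples are skipped (logged).
    """
    if recovery_epoch is None:
        recovery_epoch = "Na_restored" if trace.has_epoch("Na_restored") else "NH4_washout"
    t, ph = trace.segment(recovery_epoch)
    if t.size < min_samples:
        raise ValueError("recovery segment too short")
    dt = float(np.median(np.diff(t)))
    ph_s = _smooth(ph, max(int(round(smooth_s / dt)), 1))

    lo = np.floor(ph_s.min() / bin_width) * bin_width
    hi = np.ceil(ph_s.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers, fluxes, counts = [], [], []
    for b0, b1 in zip(edges[:-1], edges[1:]):
        mask = (ph_s >= b0) & (ph_s < b1)
        n = int(mask.sum())
        if n < min_samples:
            if n:
                logger.info("flux bin [%.2f, %.2f): only %d samples, skipped", b0, b1, n)
            continue
        slope = float(np.polyfit(t[mask], ph[mask], 1)[0])  # pH per second
        center = (b0 + b1) / 2.0
        beta = float(buffering.total(center))
        centers.append(center)
        fluxes.append(slope * 60.0 * beta)  # mM/min
        counts.append(n)
    return FluxEstimate(
        bin_centers=np.asarray(centers),
        J=np.asarray(fluxes),
        n_samples=np.asarray(counts, dtype=int),
    )


def na_dependent_flux(flux_with_na: FluxEstimate, flux_without_na: FluxEstimate) -> FluxEstimate:
    """Per-bin difference J_withNa - J_withoutNa on common pH bins."""
    common, ia, ib = np.intersect1d(
        np.round(flux_with_na.bin_centers, 6),
        np.round(flux_without_na.bin_centers, 6),
        return_indices=True,
    )
    if common.size == 0:
        raise ValueError("flux estimates share no pH bins")
    return FluxEstimate(
        bin_centers=common,
        J=flux_with_na.J[ia] - flux_without_na.J[ib],
        n_samples=np.minimum(flux_with_na.n_samples[ia], flux_without_na.n_samples[ib]),
        na_dependent=True,
    )


def co2_hydration_rate(trace: FluorescenceTrace, window_s: float = 5.0) -> float:
    """Initial acidification rate after CO2 addition (pH units/s, positive).

    Least-squares slopes over a sliding window after the ``CO2_on`` epoch;
    the steepest negative slope is reported with positive sign.  A trace
    with no pH decrease returns 0.
    """
    if not trace.has_epoch("CO2_on"):
        raise ValueError("trace has no CO2_on epoch")
    t, ph = trace.segment("CO2_on")
    if t.size < 2:
        raise ValueError("CO2_on segment too short")
    dt = float(np.median(np.diff(t)))
    w = max(int(round(window_s / dt)), 2)
    if t.size <= w:
        slopes = [np.polyfit(t, ph, 1)[0]]
    else:
        # vectorized sliding-window OLS slope
        tc = np.arange(w) - (w - 1) / 2.0
        denom = (tc**2).sum() * dt
        kernel = tc[::-1]
        slopes = np.convolve(ph, kernel, mode="valid") / denom
    steepest = float(np.min(slopes))
    return max(-steepest, 0.0)


def gradient(
    core_trace: FluorescenceTrace, periphery_trace: FluorescenceTrace
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Core-minus-periphery pH difference over time and per-epoch means.

    The periphery trace is linearly interpolated onto the core time grid
    (restricted to the overlap); epoch windows come from the core trace.
    """
    t0 = max(core_trace.time[0], periphery_trace.time[0])
    t1 = min(core_trace.time[-1], periphery_trace.time[-1])
    mask = (core_trace.time >= t0) & (core_trace.time <= t1)
    if not mask.any():
        raise ValueError("traces do not overlap in time")
    t = core_trace.time[mask]
    delta = core_trace.value[mask] - np.interp(
        t, periphery_trace.time, periphery_trace.value
    )
    series = pd.DataFrame({"time_s": t, "delta_pH": delta})
    epoch_means: dict[str, float] = {}
    for ep in core_trace.epochs:
        ts, _ = core_trace.segment(ep.label)
        m = np.isin(t, ts)
        if m.any():
            epoch_means[ep.label] = float(delta[m].mean())
    if not core_trace.epochs:
        epoch_means["all"] = float(delta.mean())
    return series, epoch_means


def microdialysis_interstitial(dialysate_conc, recovery_fraction: float):
    """True interstitial concentration = dialysate / relative recovery."""
    if not 0 < recovery_fraction <= 1:
        raise ValueError("recovery fraction must be in (0, 1]")
    return np.asarray(dialysate_conc, dtype=float) / recovery_fraction


def qpcr_relative(ct_target, ct_ref1, ct_ref2):
    """Relative expression 2**(-dCT) against the mean of two references."""
    ct_target = np.asarray(ct_target, dtype=float)
    ref_mean = (np.asarray(ct_ref1, dtype=float) + np.asarray(ct_ref2, dtype=float)) / 2.0
    return 2.0 ** (-(ct_target - ref_mean))
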