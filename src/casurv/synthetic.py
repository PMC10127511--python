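"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the analysis assumes:

* multi-study probe-level expression with gene-wise affine batch effects
  (per-study scale/shift applied to the complete observed value), multiple
  probes per gene, molecular-subtype-dependent mean shifts for the
  signature genes, and within-signature gene-gene correlation (signature
  genes are co-regulated, so averaging them denoises);
* proportional-hazards survival times: exponential baseline hazard with
  log-hazard linear in the true signature score, random uniform censoring
  plus an administrative follow-up horizon;
* NH4Cl-prepulse pH traces built from the same buffering algebra the
  estimators invert (NH3 transmembrane equilibrium, recovery integrated as
  dpH/dt = J(pH)/beta), and CO2-hydration traces with a known initial
  slope;
* caliper-style tumor growth tables from per-arm quadratic volume curves,
  inverted to width/length pairs so the volume formula round-trips.

All randomness flows through one ``numpy.random.default_rng`` (PCG64, a
documented integer-seeded algorithm): the same config and seed reproduce
outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .harmonize import ProbeMatrix
from .physiology import Epoch, FluorescenceTrace, Solution, ammonium_in
from .signatures import BUILTIN_SIGNATURES

SUBTYPES = ("LuminalA", "LuminalB", "HER2", "Basal")

FILLER_GENES = (
    "ACTB", "RPS18", "GAPDH", "EEF1A1", "TBP", "B2M", "HPRT1", "TUBB", "PGK1", "PPIA",
)


def default_gene_list() -> list[str]:
    genes: list[str] = []
    for sig in BUILTIN_SIGNATURES.values():
        genes.extend(sorted(sig.genes))
    genes.append("PTPRC")
    genes.extend(FILLER_GENES)
    return genes


def _default_subtype_shifts() -> dict[str, dict[str, float]]:
    # Signature-level mean shifts (z-scale) per molecular subtype; chosen to
    # mirror the qualitative pattern of CA and immune expression across
    # subtypes: extracellular CA high in Basal-like, CD45 infiltration high
    # in HER2-enriched, inflammation markers high in Basal-like.
    return {
        "extracellular_CA": {"Basal": 0.8, "HER2": 0.4, "LuminalA": -0.3, "LuminalB": 0.0},
        "cytosolic_CA": {"LuminalA": 0.3, "Basal": -0.2},
        "mitochondrial_CA": {},
        "inflammation": {"Basal": 0.5, "HER2": -0.3},
        "leukocyte": {"HER2": 0.6, "Basal": 0.2},
    }


@dataclass
class ExpressionConfig:
    n_studies: int = 3
    samples_per_study: int = 200
    genes: list[str] = field(default_factory=default_gene_list)
    probe_multiplicity: tuple[int, int] = (1, 3)  # inclusive uniform range
    batch_effects: bool = True
    batch_shift_range: tuple[float, float] = (-2.0, 2.0)
    batch_scale_range: tuple[float, float] = (0.5, 2.0)
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: {"LuminalA": 0.45, "LuminalB": 0.20, "HER2": 0.15, "Basal": 0.20}
    )
    subtype_shifts: dict[str, dict[str, float]] = field(default_factory=_default_subtype_shifts)
    within_signature_rho: float = 0.5
    gene_noise_sd: float = 1.0
    probe_offset_sd: float = 0.3
    probe_noise_sd: float = 0.15


@dataclass
class SurvivalConfig:
    baseline_hazard: float = 0.02  # events per month at score 0
    log_hr_per_z: float = 0.0  # null effect unless configured
    censor_max_months: float = 160.0  # uniform censoring window
    horizon_months: float = 120.0  # administrative follow-up horizon

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")


@dataclass
class TraceConfig:
    sample_hz: float = 10.0
    noise_sd: float = 0.005  # pH units
    pH_baseline: float = 7.2
    pH_o: float = 7.4
    nh4cl_mM: float = 20.0
    pKa_NH4: float = 8.9
    beta_intrinsic: float = 95.0  # mM per pH unit
    pH_plateau: float = 7.1  # pre-washout plateau
    nh4_peak_delta: float = 0.25
    j_eq_pH: float = 7.35  # pH at which net acid extrusion vanishes
    j_na_slope: float = 10.0  # Na-dependent flux, mM/min per pH unit below j_eq_pH
    j_na_indep_slope: float = 1.5  # Na-independent flux slope
    baseline_s: float = 60.0
    nh4_s: float = 180.0
    na_free_s: float = 240.0
    recovery_s: float = 1200.0
    # CO2-hydration assay trace
    co2_amplitude: float = 0.6
    co2_rate_per_s: float = 0.005
    co2_noise_sd: float = 0.0005
    co2_baseline_s: float = 30.0
    co2_segment_s: float = 600.0

    def true_flux(self, ph, with_na: bool = True):
        """Ground-truth J(pH) in mM/min."""
        slope = self.j_na_indep_slope + (self.j_na_slope if with_na else 0.0)
        return slope * np.maximum(self.j_eq_pH - np.asarray(ph, dtype=float), 0.0)


@dataclass
class GrowthConfig:
    n_animals_per_arm: int = 17
    days: tuple[float, ...] = (0.0, 3.5, 7.0, 10.5, 14.0, 17.5, 21.0, 24.5)
    coef_arm_a: tuple[float, float, float] = (30.0, 10.0, 0.8)  # c0 + c1 d + c2 d^2, uL
    coef_arm_b: tuple[float, float, float] = (30.0, 10.0, 1.4)
    noise_sd: float = 30.0  # uL
    skin_mm: float = 2.0


@dataclass
class SyntheticConfig:
    seed: int = 0
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    trace: TraceConfig = field(default_factory=TraceConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _gene_signature_membership(genes) -> dict[str, str]:
    member: dict[str, str] = {}
    for name, sig in BUILTIN_SIGNATURES.items():
        for g in sig.genes:
            member[g] = name
    member["PTPRC"] = "leukocyte"
    return {g: member[g] for g in genes if g in member}


def gen_expression_studies(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProbeMatrix], pd.DataFrame, pd.DataFrame]:
    """Simulate per-study probe matrices plus annotations and ground truth.

    Returns ``(probe_matrices, annotations, truth)``.  ``truth`` holds the
    per-sample true signature scores (population-standardized latent gene
    values averaged over each built-in signature, plus the CD45/PTPRC
    latent z), which the survival generator links to hazard.

    The random stream is consumed identically whether or not batch effects
    are enabled, so two runs from the same seed differing only in
    ``batch_effects`` share every latent value, probe offset and noise draw.
    """
    ec = cfg.expression
    missing = [
        g
        for sig in BUILTIN_SIGNATURES.values()
        for g in sig.genes
        if g not in ec.genes
    ]
    if missing or "PTPRC" not in ec.genes:
        raise ValueError(f"gene list must include all built-in signature genes; missing {missing}")
    rng = cfg.rng() if rng is None else rng

    genes = list(ec.genes)
    n_total = ec.n_studies * ec.samples_per_study
    subtype_names = list(ec.subtype_proportions)
    props = np.array([ec.subtype_proportions[s] for s in subtype_names], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("subtype proportions must sum to 1")
    subtypes = rng.choice(subtype_names, size=n_total, p=props)

    member = _gene_signature_membership(genes)
    sig_names = sorted({*member.values()})
    factors = {s: rng.normal(size=n_total) for s in sig_names}

    rho = ec.within_signature_rho
    latent = np.empty((len(genes), n_total))
    for i, g in enumerate(genes):
        eps = rng.normal(size=n_total)
        signame = member.get(g)
        if signame is not None:
            shifts = ec.subtype_shifts.get(signame, {})
            mu = np.array([shifts.get(s, 0.0) for s in subtypes])
            latent[i] = mu + ec.gene_noise_sd * (
                np.sqrt(rho) * factors[signame] + np.sqrt(1 - rho) * eps
            )
        else:
            latent[i] = ec.gene_noise_sd * eps

    # population-standardized latent values -> true signature scores
    lat_sd = latent.std(axis=1, ddof=1)
    lat_z = (latent - latent.mean(axis=1, keepdims=True)) / np.where(lat_sd > 0, lat_sd, 1.0)[
        :, None
    ]
    lat_z_df = pd.DataFrame(lat_z, index=genes)
    truth_cols = {}
    for name, sig in BUILTIN_SIGNATURES.items():
        rows = [g for g in sig.genes if g in lat_z_df.index]
        truth_cols[name] = lat_z_df.loc[rows].mean(axis=0).to_numpy()
    truth_cols["PTPRC_z"] = lat_z_df.loc["PTPRC"].to_numpy()

    matrices: list[ProbeMatrix] = []
    sample_ids: list[str] = []
    dataset_ids: list[str] = []
    lo, hi = ec.probe_multiplicity
    for k in range(ec.n_studies):
        cols = [f"study{k}_s{j:04d}" for j in range(ec.samples_per_study)]
        sl = slice(k * ec.samples_per_study, (k + 1) * ec.samples_per_study)
        sample_ids.extend(cols)
        dataset_ids.extend([f"study{k}"] * ec.samples_per_study)

        mult = rng.integers(lo, hi + 1, size=len(genes))
        probe_rows = []
        probe_ids = []
        probe_genes = []
        for i, g in enumerate(genes):
            for p in range(mult[i]):
                offset = rng.normal(scale=ec.probe_offset_sd)
                noise = rng.normal(scale=ec.probe_noise_sd, size=ec.samples_per_study)
                probe_rows.append(latent[i, sl] + offset + noise)
                probe_ids.append(f"{g}_p{p}")
                probe_genes.append(g)
        base = np.asarray(probe_rows)

        scale = rng.uniform(*ec.batch_scale_range, size=len(genes))
        shift = rng.uniform(*ec.batch_shift_range, size=len(genes))
        if ec.batch_effects:
            gene_idx = np.array([genes.index(g) for g in probe_genes])
            base = scale[gene_idx, None] * base + shift[gene_idx, None]

        values = pd.DataFrame(base, index=probe_ids, columns=cols)
        matrices.append(
            ProbeMatrix(
                dataset_id=f"study{k}",
                platform_id=f"simPlatform{k % 2}",
                values=values,
                probe_gene_map=pd.Series(probe_genes, index=probe_ids),
            )
        )

    truth = pd.DataFrame(truth_cols, index=sample_ids)
    annotations = pd.DataFrame(
        {
            "dataset_id": dataset_ids,
            "subtype": subtypes,
            "time_months": np.nan,
            "event": 0,
            "censor_reason": "",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return matrices, annotations, truth


def gen_survival(
    scores, cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Proportional-hazards survival records linked to a score vector.

    Event times are exponential with hazard ``h0 * exp(log_hr_per_z * z)``;
    the censoring time is ``min(Uniform(0, censor_max), horizon)``; the
    record keeps the earlier of the two with ``event = 1`` iff the event
    came first.
    """
    sc = cfg.survival
    rng = cfg.rng() if rng is None else rng
    scores = pd.Series(scores, dtype=float)
    hazard = sc.baseline_hazard * np.exp(sc.log_hr_per_z * scores.to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    t_cens = np.minimum(
        rng.uniform(0.0, sc.censor_max_months, size=len(scores)), sc.horizon_months
    )
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    reason = np.where(
        event == 1,
        "",
        np.where(t_cens >= sc.horizon_months, "administrative", "lost_to_followup"),
    )
    return pd.DataFrame(
        {"time_months": time, "event": event, "censor_reason": reason},
        index=scores.index,
    )


def gen_cohort_inputs(
    cfg: SyntheticConfig, score_for_hazard: str = "extracellular_CA"
) -> tuple[list[ProbeMatrix], pd.DataFrame, pd.DataFrame]:
    """Expression studies plus survival-completed annotations.

    The hazard is driven by the true (latent) score named by
    ``score_for_hazard``; with the default null ``log_hr_per_z = 0`` the
    survival times are independent of expression.
    """
    rng = cfg.rng()
    matrices, annotations, truth = gen_expression_studies(cfg, rng)
    surv = gen_survival(truth[score_for_hazard], cfg, rng)
    annotations = annotations.assign(
        time_months=surv["time_months"],
        event=surv["event"],
        censor_reason=surv["censor_reason"],
    )
    return matrices, annotations, truth


def gen_two_arm_survival(
    true_hr: float,
    n_per_arm: int,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Two proportional-hazards arms with a known hazard ratio A:B."""
    rng = cfg.rng() if rng is None else rng
    scores = pd.Series(
        np.r_[np.ones(n_per_arm), np.zeros(n_per_arm)],
        index=[f"a{i}" for i in range(n_per_arm)] + [f"b{i}" for i in range(n_per_arm)],
    )
    cfg2 = replace(cfg, survival=replace(cfg.survival, log_hr_per_z=float(np.log(true_hr))))
    rec = gen_survival(scores, cfg2, rng)
    a = rec.iloc[:n_per_arm]
    b = rec.iloc[n_per_arm:]
    return (
        (a["time_months"].to_numpy(), a["event"].to_numpy()),
        (b["time_months"].to_numpy(), b["event"].to_numpy()),
    )


def _integrate_recovery(ph0, t, tc: TraceConfig, beta: float, with_na: bool) -> np.ndarray:
    """Euler integration of dpH/dt = J(pH)/beta (J in mM/min, t in s)."""
    ph = np.empty_like(t)
    ph[0] = ph0
    for i in range(1, len(t)):
        j = float(tc.true_flux(ph[i - 1], with_na=with_na))
        ph[i] = ph[i - 1] + (j / beta) / 60.0 * (t[i] - t[i - 1])
    return ph


def gen_ph_trace(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    kind: str = "prepulse",
    na_during_recovery: bool = True,
) -> tuple[FluorescenceTrace, Solution]:
    """Simulate a pH_i trace (NH4+ prepulse or CO2-hydration assay).

    For the prepulse the washout acidification step is computed from the
    same Henderson-Hasselbalch/buffering algebra the estimators use
    (nadir = plateau - [NH4+]_i/beta_intrinsic), and the recovery obeys
    dpH/dt = J(pH)/beta with the configured ground-truth J.
    """
    tc = cfg.trace
    rng = cfg.rng() if rng is None else rng
    dt = 1.0 / tc.sample_hz
    if kind == "co2":
        t = np.arange(0.0, tc.co2_baseline_s + tc.co2_segment_s, dt)
        on = tc.co2_baseline_s
        ph = np.where(
            t < on,
            tc.pH_baseline,
            tc.pH_baseline - tc.co2_amplitude * (1.0 - np.exp(-tc.co2_rate_per_s * (t - on))),
        )
        ph = ph + rng.normal(scale=tc.co2_noise_sd, size=t.size)
        trace = FluorescenceTrace(
            time=t,
            value=ph,
            unit="pH",
            region="lysate",
            epochs=[Epoch("baseline", 0.0), Epoch("CO2_on", on)],
        )
        sol = Solution(pH_o=tc.pH_o, HCO3_o=0.0, CO2_present=False, Na_present=True)
        return trace, sol
    if kind != "prepulse":
        raise ValueError(f"unknown trace kind {kind!r}")

    sol = Solution(
        pH_o=tc.pH_o,
        HCO3_o=0.0,
        NH4Cl_total=tc.nh4cl_mM,
        CO2_present=False,
        Na_present=False,
    )
    beta = tc.beta_intrinsic
    nh4_i = ammonium_in(tc.pH_plateau, sol, tc.pKa_NH4)
    ph_nadir = tc.pH_plateau - nh4_i / beta

    t0, t1 = 0.0, tc.baseline_s
    t2 = t1 + tc.nh4_s
    t3 = t2 + tc.na_free_s
    t4 = t3 + tc.recovery_s
    t = np.arange(0.0, t4, dt)
    ph = np.empty_like(t)

    seg = t < t1
    ph[seg] = tc.pH_baseline
    # NH4 addition: overshoot decaying onto the plateau (tau 25 s)
    seg = (t >= t1) & (t < t2)
    peak = tc.pH_baseline + tc.nh4_peak_delta
    ph[seg] = tc.pH_plateau + (peak - tc.pH_plateau) * np.exp(-(t[seg] - t1) / 25.0)
    # washout in Na-free solution: step to the nadir, then slow Na-independent recovery
    seg = (t >= t2) & (t < t3)
    ph[seg] = _integrate_recovery(ph_nadir, t[seg], tc, beta, with_na=False)
    ph_at_t3 = ph[seg][-1] if seg.any() else ph_nadir
    # Na restored: full recovery
    seg = t >= t3
    ph[seg] = _integrate_recovery(ph_at_t3, t[seg], tc, beta, with_na=na_during_recovery)

    ph = ph + rng.normal(scale=tc.noise_sd, size=t.size)
    trace = FluorescenceTrace(
        time=t,
        value=ph,
        unit="pH",
        region="core",
        epochs=[
            Epoch("baseline", 0.0),
            Epoch("NH4_add", t1),
            Epoch("NH4_washout", t2),
            Epoch("Na_restored", t3),
        ],
    )
    return trace, sol


def gen_growth(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Caliper measurement table for two treatment arms.

    Volumes follow the per-arm quadratic plus Gaussian noise; each volume is
    inverted to a width/length pair (W = L assumed) with the skin thickness
    re-added, so ``tumor_volume`` recovers the noisy volume exactly.
    """
    gc = cfg.growth
    rng = cfg.rng() if rng is None else rng
    rows = []
    for arm, coef in (("A", gc.coef_arm_a), ("B", gc.coef_arm_b)):
        for a in range(gc.n_animals_per_arm):
            for day in gc.days:
                v = coef[0] + coef[1] * day + coef[2] * day**2
                v = max(v + rng.normal(scale=gc.noise_sd), 1.0)
                dim = (6.0 * v / np.pi) ** (1.0 / 3.0)  # W = L
                rows.append(
                    {
                        "animal_id": f"{arm}{a:02d}",
                        "arm": arm,
                        "day": day,
                        "width_mm": dim + gc.skin_mm,
                        "length_mm": dim + gc.skin_mm,
                    }
                )
    return pd.DataFrame(rows)
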