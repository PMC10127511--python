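"""End-to-end subtype-stratified signature survival analysis.

For each molecular subtype present in the cohort annotations, the pipeline
scores the configured signature, stratifies the patients (binary z>0/z<0 or
fixed +/-0.25 tertiles), runs the configured log-rank variant, and
estimates the high-vs-low hazard ratio with a 95% CI.  Every CLI stage
calls the same library functions used here, so serialized results match the
in-memory values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .harmonize import HarmonizedCohort, harmonize_studies
from .signatures import score_signature, stratify
from .survival import (
    HazardRatioEstimator,
    KaplanMeierEstimator,
    logrank_test,
    logrank_trend,
)

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "signature",
    "scheme",
    "test",
    "hr_method",
    "seed",
    "outdir",
    "log_level",
    "min_group_size",
}


@dataclass
class PipelineConfig:
    signature: str = "extracellular_CA"
    scheme: str = "binary0"  # binary0 | tertile025
    test: str = "mantel_cox"  # mantel_cox | gehan_breslow_wilcoxon | trend
    hr_method: str = "cox_efron"
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"
    min_group_size: int = 2

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SubtypeResult:
    subtype: str
    n: int
    groups: dict[str, int]
    test: dict
    hazard_ratio: dict | None
    km_curves: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "subtype": self.subtype,
            "n": self.n,
            "groups": self.groups,
            "test": self.test,
            "hazard_ratio": self.hazard_ratio,
        }
        return out


_ORDER = {"binary0": ("low", "high"), "tertile025": ("low", "moderate", "high")}


def run_pipeline(
    cohort: HarmonizedCohort,
    config: PipelineConfig | dict | None = None,
) -> dict:
    """Per-subtype signature scoring, stratification and survival testing.

    Returns ``{"results": [SubtypeResult...], "manifest": {...}}``.  A
    subtype with fewer than two populated strata is skipped with a warning.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)

    ann = cohort.annotations
    scores = score_signature(cohort, config.signature)["score"]
    strata = stratify(scores, config.scheme)
    order = _ORDER[config.scheme]

    results: list[SubtypeResult] = []
    for subtype in pd.unique(ann["subtype"]):
        mask = (ann["subtype"] == subtype).to_numpy()
        sub_ann = ann.loc[mask]
        sub_strata = strata.loc[sub_ann.index]
        groups = {}
        for label in order:
            idx = sub_strata.index[sub_strata == label]
            rec = sub_ann.loc[idx]
            rec = rec.dropna(subset=["time_months"])
            if len(rec) >= config.min_group_size:
                groups[label] = (
                    rec["time_months"].to_numpy(float),
                    rec["event"].to_numpy(int),
                )
        if len(groups) < 2:
            logger.warning("subtype %s: <2 strata after stratification, skipped", subtype)
            continue

        labels = [l for l in order if l in groups]
        pairs = [groups[l] for l in labels]
        if config.test == "trend" and len(pairs) >= 3:
            test_res = logrank_trend(pairs)
        else:
            variant = "mantel_cox" if config.test == "trend" else config.test
            lo, hi = groups[labels[0]], groups[labels[-1]]
            test_res = logrank_test(hi, lo, variant=variant)
        test_dict = {
            "variant": test_res.variant,
            "statistic": test_res.statistic,
            "df": test_res.df,
            "p_value": test_res.p_value,
        }

        hr_dict = None
        if labels[0] != labels[-1]:
            hi_t, hi_e = groups[labels[-1]]
            lo_t, lo_e = groups[labels[0]]
            try:
                est = HazardRatioEstimator(method=config.hr_method).fit(
                    np.concatenate([hi_t, lo_t]),
                    np.concatenate([hi_e, lo_e]),
                    np.r_[np.ones(hi_t.size, bool), np.zeros(lo_t.size, bool)],
                )
                hr_dict = {
                    "hr": est.hazard_ratio_,
                    "log_hr": est.log_hr_,
                    "se_log_hr": est.se_log_hr_,
                    "ci95": list(est.ci95_),
                    "method": config.hr_method,
                    "comparison": f"{labels[-1]}_vs_{labels[0]}",
                }
            except ValueError as exc:
                logger.warning("subtype %s: HR unavailable (%s)", subtype, exc)

        km = {
            label: KaplanMeierEstimator().fit(*groups[label]).export_table()
            for label in labels
        }
        results.append(
            SubtypeResult(
                subtype=str(subtype),
                n=int(mask.sum()),
                groups={l: len(groups[l][0]) for l in labels},
                test=test_dict,
                hazard_ratio=hr_dict,
                km_curves=km,
            )
        )

    manifest = {
        "casurv_version": __version__,
        "signature": config.signature,
        "scheme": config.scheme,
        "test": config.test,
        "hr_method": config.hr_method,
        "seed": config.seed,
        "n_samples": int(len(ann)),
        "n_genes": int(cohort.z.shape[0]),
    }
    return {"results": results, "manifest": manifest}


def pipeline_from_studies(probe_matrices, annotations, config=None) -> dict:
    """Harmonize raw studies, then run the subtype survival pipeline."""
    cohort = harmonize_studies(probe_matrices, annotations)
    return run_pipeline(cohort, config)


def results_to_json(bundle: dict) -> dict:
    return {
        "manifest": bundle["manifest"],
        "results": [r.to_json_dict() for r in bundle["results"]],
    }


def export_bundle(bundle: dict, outdir) -> None:
    """Write result JSON, HR table TSV, and per-group KM curve TSVs."""
    from .io import write_json, write_table_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(results_to_json(bundle), outdir / "results.json")
    rows = []
    for r in bundle["results"]:
        row = {"subtype": r.subtype, "n": r.n, **{f"n_{k}": v for k, v in r.groups.items()}}
        row.update({f"test_{k}": v for k, v in r.test.items()})
        if r.hazard_ratio:
            row.update(
                hr=r.hazard_ratio["hr"],
                hr_ci_low=r.hazard_ratio["ci95"][0],
                hr_ci_high=r.hazard_ratio["ci95"][1],
            )
        rows.append(row)
        for label, km in r.km_curves.items():
            write_table_tsv(km, outdir / f"km_{r.subtype}_{label}.tsv")
    write_table_tsv(pd.DataFrame(rows), outdir / "hazard_ratios.tsv")
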