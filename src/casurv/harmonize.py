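"""Cross-study harmonization of microarray expression matrices.

Per-study probe-level matrices are reduced to one gene-level row per gene
(the probe with the maximum mean intensity), z-scored within each study,
pooled across studies by gene symbol, and z-scored a second time across all
pooled samples.  The resulting matrix holds, for every gene and patient,

    z = (individual expression score - population mean) / SD

with the sample (n-1) standard deviation, so that signature averages and
strata thresholds are comparable across genes and cohorts.

Input intensities are assumed to be on a log scale already; no re-logging
is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

SUBTYPE_LABELS = ("LuminalA", "LuminalB", "HER2", "Basal", "other")

ANNOTATION_COLUMNS = ("dataset_id", "subtype", "time_months", "event", "censor_reason")


@dataclass
class ProbeMatrix:
    """Probe-level expression for one study.

    ``values`` is a probes x samples DataFrame of log-scale intensities and
    ``probe_gene_map`` maps probe ids to gene symbols.  Probes without a
    mapping are dropped (with a log message) at collapse time.
    """

    dataset_id: str
    values: pd.DataFrame
    probe_gene_map: pd.Series
    platform_id: str = ""

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")
        if not isinstance(self.probe_gene_map, pd.Series):
            self.probe_gene_map = pd.Series(self.probe_gene_map)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneMatrix:
    """Gene-level expression for one study; one row per gene symbol."""

    dataset_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError(f"{self.dataset_id}: duplicate gene symbols")


@dataclass
class HarmonizedCohort:
    """Pooled gene x sample z-score matrix with aligned sample annotations."""

    z: pd.DataFrame
    annotations: pd.DataFrame
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.z.columns.equals(self.annotations.index):
            raise ValueError("annotation rows must align with z-matrix columns")


def collapse_probes(pm: ProbeMatrix) -> GeneMatrix:
    """Collapse multi-probe genes to the probe with maximum mean intensity.

    Genes measured by one probe pass through unchanged.  Ties on mean
    intensity are broken by the lexicographically smallest probe id (logged).
    Probes mapping to no gene are dropped with a log message.
    """
    if pm.values.empty:
        raise ValueError(f"{pm.dataset_id}: empty probe matrix")
    mapped = pm.values.index.intersection(pm.probe_gene_map.index)
    unmapped = pm.values.index.difference(mapped)
    if len(unmapped):
        logger.warning(
            "%s: dropping %d unmapped probes (e.g. %s)",
            pm.dataset_id, len(unmapped), list(unmapped[:3]),
        )
    if not len(mapped):
        raise ValueError(f"{pm.dataset_id}: no probe maps to a gene")
    values = pm.values.loc[mapped]
    genes = pm.probe_gene_map.loc[mapped]
    means = values.mean(axis=1)

    rows: dict[str, pd.Series] = {}
    for gene, probe_ids in genes.groupby(genes).groups.items():
        probe_ids = sorted(probe_ids)  # lexicographic tie-break
        sub = means.loc[probe_ids]
        best = sub.idxmax()  # idxmax on sorted index -> smallest id on ties
        if len(probe_ids) > 1 and (sub == sub.max()).sum() > 1:
            logger.info("%s: probe tie for %s broken to %s", pm.dataset_id, gene, best)
        rows[str(gene)] = values.loc[best]
    out = pd.DataFrame(rows).T
    out.columns = pm.values.columns
    out = out.sort_index()
    return GeneMatrix(dataset_id=pm.dataset_id, values=out)


def standardize_within_dataset(gm: GeneMatrix) -> GeneMatrix:
    """Center/scale each gene row to mean 0, sample SD 1 within one study.

    Zero-variance genes carry no ranking information and are removed with a
    warning.  Requires at least two samples.
    """
    if gm.values.shape[1] < 2:
        raise ValueError(f"{gm.dataset_id}: need >=2 samples to standardize")
    vals = gm.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning(
            "%s: dropping %d zero-variance genes: %s",
            gm.dataset_id, int((~keep).sum()), list(vals.index[~keep][:5]),
        )
    z = vals.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return GeneMatrix(dataset_id=gm.dataset_id, values=z)


def merge_and_restandardize(
    gms: list[GeneMatrix], annotations: pd.DataFrame
) -> HarmonizedCohort:
    """Pool per-study standardized matrices and re-standardize per gene.

    Genes are joined by symbol as a union; a gene absent from one platform
    is missing (NaN) for that study's samples and those samples are excluded
    from the gene's pooled mean/SD and from downstream signature averages.
    """
    if not gms:
        raise ValueError("no gene matrices to merge")
    all_samples: list[str] = []
    for gm in gms:
        all_samples.extend(gm.values.columns)
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("duplicate sample ids across datasets")

    merged = pd.concat([gm.values for gm in gms], axis=1, join="outer")
    merged = merged[all_samples]  # keep input sample order

    mean = merged.mean(axis=1)
    sd = merged.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = {"zero_variance_after_merge": list(merged.index[~keep])}
    if (~keep).any():
        logger.warning("dropping %d pooled zero-variance genes", int((~keep).sum()))
    z = merged.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)

    ann = annotations.copy()
    if "sample_id" in ann.columns:
        ann = ann.set_index("sample_id")
    missing = [s for s in all_samples if s not in ann.index]
    if missing:
        raise ValueError(f"annotations missing for samples: {missing[:5]}")
    ann = ann.loc[all_samples]
    return HarmonizedCohort(z=z, annotations=ann, dropped_genes=dropped)


def harmonize_studies(
    probe_matrices: list[ProbeMatrix], annotations: pd.DataFrame
) -> HarmonizedCohort:
    """Full pipeline: collapse -> within-study z -> merge -> pooled z."""
    gms = [standardize_within_dataset(collapse_probes(pm)) for pm in probe_matrices]
    return merge_and_restandardize(gms, annotations)


class CohortHarmonizer(BaseEstimator):
    """Estimator wrapper around the collapse/standardize/merge procedure.

    ``fit`` consumes a list of :class:`ProbeMatrix` plus an annotation table
    and exposes the harmonized cohort through fitted attributes.

    Attributes
    ----------
    cohort_ : HarmonizedCohort
    z_ : DataFrame, genes x samples
    annotations_ : DataFrame aligned with the columns of ``z_``
    """

    def fit(self, X: list[ProbeMatrix], y: pd.DataFrame | None = None):
        if y is None:
            raise ValueError("annotations table required as y")
        self.cohort_ = harmonize_studies(X, y)
        self.z_ = self.cohort_.z
        self.annotations_ = self.cohort_.annotations
        return self

    def fit_transform(self, X: list[ProbeMatrix], y: pd.DataFrame | None = None):
        return self.fit(X, y).z_
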