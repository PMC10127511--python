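"""Gene-signature scoring and patient stratification.

A signature score is the arithmetic mean of a sample's z-scores over a fixed
gene set; genes missing for a sample (platform gaps) are simply left out of
that sample's mean.  Built-in signatures cover the carbonic anhydrase
localization groups (extracellular, cytosolic, mitochondrial) and a chronic
inflammation marker panel.

Stratification schemes:

* ``binary0`` — high if z > 0, low if z < 0 (z == 0 excluded, logged);
* ``tertile025`` — high z > 0.25, low z < -0.25, moderate in between with
  the boundary values assigned to moderate;
* ``extremes2d`` — discordant extremes of leukocyte infiltration (CD45/PTPRC
  z) against the inflammation signature score, by marginal quantiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .harmonize import HarmonizedCohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureDefinition:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")


BUILTIN_SIGNATURES: dict[str, SignatureDefinition] = {
    s.name: s
    for s in (
        SignatureDefinition("extracellular_CA", frozenset({"CA4", "CA6", "CA9", "CA12", "CA14"})),
        SignatureDefinition("cytosolic_CA", frozenset({"CA1", "CA2", "CA3", "CA7", "CA13"})),
        SignatureDefinition("mitochondrial_CA", frozenset({"CA5A", "CA5B"})),
        SignatureDefinition(
            "inflammation",
            frozenset({"IL1A", "IL1B", "IL4", "IL6", "NFKB1", "STAT3", "CXCL2"}),
        ),
    )
}

# CD45 is the common name of the leukocyte marker; HGNC symbol is PTPRC.
CD45_ALIASES = ("PTPRC", "CD45")


def _as_z(cohort) -> pd.DataFrame:
    return cohort.z if isinstance(cohort, HarmonizedCohort) else cohort


def resolve_signature(sig) -> SignatureDefinition:
    if isinstance(sig, SignatureDefinition):
        return sig
    if isinstance(sig, str):
        try:
            return BUILTIN_SIGNATURES[sig]
        except KeyError:
            raise KeyError(
                f"unknown signature {sig!r}; built-ins: {sorted(BUILTIN_SIGNATURES)}"
            ) from None
    name, genes = sig
    return SignatureDefinition(name, frozenset(genes))


def score_signature(cohort, sig) -> pd.DataFrame:
    """Mean z over the available signature genes, per sample.

    Returns a DataFrame indexed by sample id with columns ``score`` and
    ``n_genes_used``.  Samples with no signature gene measured get NaN score
    and ``n_genes_used`` 0.  Raises if no signature gene is present at all.
    """
    z = _as_z(cohort)
    sig = resolve_signature(sig)
    present = sorted(g for g in sig.genes if g in z.index)
    missing = sorted(sig.genes - set(present))
    if not present:
        raise ValueError(
            f"no gene of signature {sig.name!r} present in cohort; missing: {missing}"
        )
    if missing:
        logger.warning("signature %s: genes absent from cohort: %s", sig.name, missing)
    sub = z.loc[present]
    score = sub.mean(axis=0, skipna=True)
    n_used = sub.notna().sum(axis=0)
    score[n_used == 0] = np.nan
    return pd.DataFrame({"score": score, "n_genes_used": n_used.astype(int)})


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Transformer computing one signature score per sample.

    Parameters
    ----------
    signature : str or SignatureDefinition, default "extracellular_CA"
    """

    def __init__(self, signature="extracellular_CA"):
        self.signature = signature

    def fit(self, X, y=None):
        sig = resolve_signature(self.signature)
        z = _as_z(X)
        self.genes_used_ = sorted(g for g in sig.genes if g in z.index)
        if not self.genes_used_:
            raise ValueError(f"no gene of signature {sig.name!r} in input")
        self.signature_ = sig
        return self

    def transform(self, X) -> pd.Series:
        table = score_signature(X, self.signature)
        return table["score"].rename(resolve_signature(self.signature).name)


def stratify_binary(scores: pd.Series) -> pd.Series:
    """high if score > 0, low if score < 0; exactly 0 -> excluded (logged)."""
    scores = pd.Series(scores)
    if not np.isfinite(scores.dropna()).all():
        raise ValueError("scores must be finite")
    labels = pd.Series("excluded", index=scores.index, dtype=object)
    labels[scores > 0] = "high"
    labels[scores < 0] = "low"
    n_zero = int((scores == 0).sum())
    if n_zero:
        logger.info("binary0: %d samples at z==0 excluded", n_zero)
    return labels


def stratify_tertile_fixed(scores: pd.Series, threshold: float = 0.25) -> pd.Series:
    """high > +threshold, low < -threshold, moderate otherwise.

    Scores exactly on a boundary fall in the moderate stratum (logged): the
    defining inequalities are strict, so the closed interval is moderate.
    """
    scores = pd.Series(scores)
    labels = pd.Series("moderate", index=scores.index, dtype=object)
    labels[scores > threshold] = "high"
    labels[scores < -threshold] = "low"
    labels[scores.isna()] = "excluded"
    n_bound = int((scores.abs() == threshold).sum())
    if n_bound:
        logger.info("tertile025: %d boundary scores assigned to moderate", n_bound)
    return labels


def classify_extremes(
    cd45_z: pd.Series, inflammation_score: pd.Series, q: float = 0.25
) -> pd.Series:
    """Discordant infiltration/inflammation extremes by marginal quantiles.

    ``hiInfilLoInflam``: CD45 z above its (1-q) quantile AND inflammation
    score below its q quantile; ``loInfilHiInflam`` is the mirror image; all
    other samples are ``excluded``.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must be in (0, 0.5]")
    cd45_z = pd.Series(cd45_z)
    infl = pd.Series(inflammation_score)
    if not cd45_z.index.equals(infl.index):
        infl = infl.reindex(cd45_z.index)
    for name, v in (("CD45", cd45_z), ("inflammation", infl)):
        if v.dropna().nunique() < 2:
            raise ValueError(f"{name} scores are degenerate (constant)")
    cd_hi = cd45_z > cd45_z.quantile(1 - q)
    cd_lo = cd45_z < cd45_z.quantile(q)
    in_hi = infl > infl.quantile(1 - q)
    in_lo = infl < infl.quantile(q)
    labels = pd.Series("excluded", index=cd45_z.index, dtype=object)
    labels[cd_hi & in_lo] = "hiInfilLoInflam"
    labels[cd_lo & in_hi] = "loInfilHiInflam"
    return labels


def cd45_scores(cohort) -> pd.Series:
    """Per-sample CD45 z-scores, looked up under PTPRC with CD45 accepted."""
    z = _as_z(cohort)
    for symbol in CD45_ALIASES:
        if symbol in z.index:
            return z.loc[symbol]
    raise KeyError(f"cohort carries neither of {CD45_ALIASES}")


def stratify(scores: pd.Series, scheme: str, **kwargs) -> pd.Series:
    """Dispatch on scheme name: binary0 | tertile025."""
    if scheme == "binary0":
        return stratify_binary(scores)
    if scheme == "tertile025":
        return stratify_tertile_fixed(scores, **kwargs)
    raise ValueError(f"unknown scheme {scheme!r} (extremes2d needs classify_extremes)")
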