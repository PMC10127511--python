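"""External-validation registry for the full-data survival analysis.

The hazard ratios reported for the pooled multi-cohort breast cancer
analysis (about 38 public microarray cohorts, ~5,889 patients with PAM50
subtype labels) cannot be recomputed without downloading those cohorts, so
they are kept here as fixed reference targets for a full-data rerun.  Each
entry records the stratification that produced it: signature or isoform,
molecular subtype, binary z>0 vs z<0 split (high relative to low), and, for
the inflammation-conditioned entries, the inflammation stratum analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ExternalHazardRatio:
    signature_or_gene: str
    subtype: str
    hr: float
    condition: str = ""
    desk_scale: bool = False  # requires the full public cohorts


EXTERNAL_HAZARD_RATIOS: tuple[ExternalHazardRatio, ...] = (
    ExternalHazardRatio("extracellular_CA", "LuminalA", 0.984),
    ExternalHazardRatio("extracellular_CA", "LuminalB", 1.064),
    ExternalHazardRatio("extracellular_CA", "HER2", 0.581),
    ExternalHazardRatio("extracellular_CA", "Basal", 1.541),
    ExternalHazardRatio("cytosolic_CA", "HER2", 0.753),
    ExternalHazardRatio("CA7", "HER2", 0.661),
    ExternalHazardRatio("CA9", "Basal", 1.313),
    ExternalHazardRatio("CA13", "Basal", 1.502),
    ExternalHazardRatio("extracellular_CA", "HER2", 0.441, condition="low_inflammation"),
    ExternalHazardRatio("extracellular_CA", "HER2", 0.798, condition="high_inflammation"),
    ExternalHazardRatio("extracellular_CA", "Basal", 1.581, condition="low_inflammation"),
    ExternalHazardRatio("extracellular_CA", "Basal", 1.529, condition="high_inflammation"),
)
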