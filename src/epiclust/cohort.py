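"""Synthetic cohort generation.

Emulates a clinically referred adolescent cohort: bivariate CBCL T-scores
(Internalizing, Externalizing) drawn from a two-component Gaussian mixture,
binary environmental-risk indicators (stressful life events, perinatal
risk), demographics (age, sex, socioeconomic status), and per-CpG
methylation percentages for 54 CpG sites across six candidate-gene
amplicons.  The default parameters (:func:`study_cohort_spec`) are the
published characterization of the two severity clusters; the generator
returns the true component label of every subject alongside the table, so
downstream clustering and inference can be validated against ground truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "study_cohort_spec",
    "generate_cohort",
    "inject_missingness",
    "METHYLATION_SITES",
    "ID_COLUMNS",
]

ID_COLUMNS = ("subject_id",)

# Per-CpG methylation percentage (mean, SD) for the LOW- and HIGH-severity
# components, one row per analyzed CpG site of the six amplicons.
_METHYLATION_TABLE = """\
site,low_mean,low_sd,high_mean,high_sd
BDNF_CpG1,1.71,0.51,1.65,0.44
BDNF_CpG2,0.40,0.32,0.41,0.18
BDNF_CpG3,0.40,0.20,0.42,0.17
BDNF_CpG4,0.33,0.14,0.28,0.17
BDNF_CpG5,0.54,0.25,0.46,0.16
BDNF_CpG6,0.47,0.17,0.46,0.21
BDNF_CpG7,0.53,0.41,0.46,0.18
BDNF_CpG8,0.79,0.36,0.77,0.25
BDNF_CpG9,0.63,0.27,0.65,0.27
BDNF_CpG10,0.83,0.29,0.83,0.29
BDNF_CpG11,0.59,0.19,0.51,0.15
FKBP5_CpG1,72.38,4.66,72.32,5.59
FKBP5_CpG2,92.87,3.81,92.76,3.95
FKBP5_CpG3,90.22,4.59,89.89,5.03
IGF2_CpG1,49.58,5.73,48.95,5.04
IGF2_CpG2,39.05,3.86,37.65,5.29
IGF2_CpG3,40.42,4.60,39.47,4.67
IGF2_CpG4,34.61,4.92,33.48,5.16
IGF2_CpG5,0.08,0.05,0.08,0.05
OXTR_E3_CpG1,7.94,3.38,7.93,3.10
OXTR_E3_CpG2,6.56,3.01,6.44,2.87
OXTR_E3_CpG3,4.65,2.59,4.70,2.14
OXTR_E3_CpG4,4.48,2.83,4.56,2.42
OXTR_E3_CpG5,2.01,1.42,1.98,1.19
OXTR_E3_CpG6,8.30,3.72,8.49,3.98
OXTR_E3_CpG7,5.86,3.12,5.93,2.96
OXTR_E3_CpG8,2.95,1.93,3.12,1.89
OXTR_E3_CpG9,5.24,3.02,5.40,2.85
OXTR_E3_CpG10,5.80,3.16,5.81,2.92
OXTR_E3_CpG11,5.67,3.51,5.84,3.34
OXTR_E3_CpG12,3.04,2.24,3.09,2.01
OXTR_E3_CpG13,4.82,3.43,5.10,3.15
OXTR_E3_CpG14,3.02,2.09,2.93,1.98
OXTR_E3_CpG15,4.26,2.51,3.40,2.33
OXTR_I1_CpG1,1.76,0.73,1.69,0.81
OXTR_I1_CpG2,2.76,0.94,2.73,1.10
OXTR_I1_CpG3,7.36,2.04,7.15,2.09
OXTR_I1_CpG4,2.92,1.71,2.75,1.06
OXTR_I1_CpG5,36.33,4.87,35.89,4.97
OXTR_I1_CpG6,38.70,5.60,38.29,5.58
OXTR_I1_CpG7,62.71,4.91,61.45,5.17
OXTR_I1_CpG8,43.77,4.57,43.25,5.24
OXTR_I1_CpG9,23.43,5.00,23.32,4.79
OXTR_I1_CpG10,8.55,2.58,7.97,2.25
OXTR_I1_CpG11,10.92,2.99,10.44,3.00
OXTR_I1_CpG12,12.37,3.97,11.77,3.15
OXTR_I1_CpG13,13.40,3.45,13.03,3.26
OXTR_PR_CpG1,91.63,2.29,91.05,2.20
OXTR_PR_CpG2,78.71,4.09,78.39,4.68
OXTR_PR_CpG3,79.64,4.13,78.87,3.94
OXTR_PR_CpG4,64.66,5.94,63.93,4.64
OXTR_PR_CpG5,85.13,2.81,84.34,2.65
OXTR_PR_CpG6,47.53,5.07,46.42,4.96
OXTR_PR_CpG7,71.09,4.92,70.19,3.78
"""

_METH_DF = pd.read_csv(io.StringIO(_METHYLATION_TABLE))
METHYLATION_SITES: tuple[str, ...] = tuple(_METH_DF["site"])


@dataclass
class CohortSpec:
    """Generating parameters of a synthetic cohort.

    Per-component arrays are indexed in the same order everywhere;
    component 0 is conventionally the lower-severity ("LOW") component.

    ``methylation_means`` / ``methylation_sds`` have shape
    ``(n_components, n_sites)`` in percent; draws are truncated to
    [0, 100].  ``sle_prevalence`` / ``perinatal_prevalence`` are
    per-component probabilities of the risk being present.
    """

    n: int = 200
    mixing: tuple[float, ...] = (0.51, 0.49)
    component_means: tuple[tuple[float, float], ...] = ((51.0, 47.1), (63.7, 58.9))
    component_sds: tuple[tuple[float, float], ...] = ((6.91, 6.51), (5.97, 7.10))
    sle_prevalence: tuple[float, ...] = (0.37, 0.48)
    perinatal_prevalence: tuple[float, ...] = (0.46, 0.66)
    age_mean: tuple[float, ...] = (14.5, 14.4)
    age_sd: tuple[float, ...] = (2.02, 2.31)
    male_frac: tuple[float, ...] = (76 / 102, 77 / 98)
    ses_mean: tuple[float, ...] = (50.8, 47.0)
    ses_sd: tuple[float, ...] = (20.3, 18.3)
    methylation_sites: tuple[str, ...] = METHYLATION_SITES
    methylation_means: np.ndarray = field(
        default_factory=lambda: _METH_DF[["low_mean", "high_mean"]].to_numpy().T
    )
    methylation_sds: np.ndarray = field(
        default_factory=lambda: _METH_DF[["low_sd", "high_sd"]].to_numpy().T
    )

    @property
    def n_components(self) -> int:
        return len(self.mixing)

    def __post_init__(self) -> None:
        self.methylation_means = np.asarray(self.methylation_means, float)
        self.methylation_sds = np.asarray(self.methylation_sds, float)
        k, s = self.n_components, len(self.methylation_sites)
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not np.isclose(sum(self.mixing), 1.0) or any(
            not 0 <= w <= 1 for w in self.mixing
        ):
            raise ValueError("mixing weights must lie in [0,1] and sum to 1")
        for name in ("component_means", "component_sds", "sle_prevalence",
                     "perinatal_prevalence", "age_mean", "age_sd",
                     "male_frac", "ses_mean", "ses_sd"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per component")
        if any(sd <= 0 for pair in self.component_sds for sd in pair):
            raise ValueError("T-score SDs must be positive")
        for p in (*self.sle_prevalence, *self.perinatal_prevalence, *self.male_frac):
            if not 0 <= p <= 1:
                raise ValueError("prevalences must lie in [0,1]")
        if self.methylation_means.shape != (k, s) or self.methylation_sds.shape != (k, s):
            raise ValueError("methylation parameter arrays must be (n_components, n_sites)")
        if ((self.methylation_means < 0) | (self.methylation_means > 100)).any():
            raise ValueError("methylation means must lie in [0,100]")
        if (self.methylation_sds <= 0).any():
            raise ValueError("methylation SDs must be positive")


def study_cohort_spec(n: int = 200) -> CohortSpec:
    """The published two-cluster cohort model (defaults of CohortSpec)."""
    return CohortSpec(n=n)


def generate_cohort(
    spec: CohortSpec, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a cohort table plus the true component label of each subject.

    T-scores come from the specified bivariate (diagonal) Gaussian mixture;
    methylation percentages are per-component truncated normals clipped to
    [0, 100]; risks are per-component Bernoulli.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    n, k = spec.n, spec.n_components
    labels = rng.choice(k, size=n, p=np.asarray(spec.mixing))

    means = np.asarray(spec.component_means)[labels]
    sds = np.asarray(spec.component_sds)[labels]
    tscores = rng.normal(means, sds)

    age = rng.normal(np.asarray(spec.age_mean)[labels], np.asarray(spec.age_sd)[labels])
    sex = np.where(rng.random(n) < np.asarray(spec.male_frac)[labels], "M", "F")
    ses = rng.normal(np.asarray(spec.ses_mean)[labels], np.asarray(spec.ses_sd)[labels])
    sle = (rng.random(n) < np.asarray(spec.sle_prevalence)[labels]).astype(int)
    perinatal = (rng.random(n) < np.asarray(spec.perinatal_prevalence)[labels]).astype(int)

    meth = rng.normal(spec.methylation_means[labels], spec.methylation_sds[labels])
    np.clip(meth, 0.0, 100.0, out=meth)

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "ses": ses,
            "internalizing": tscores[:, 0] if n else np.array([]),
            "externalizing": tscores[:, 1] if n else np.array([]),
            "sle": sle,
            "perinatal_risk": perinatal,
        }
    )
    for j, site in enumerate(spec.methylation_sites):
        table[site] = meth[:, j] if n else np.array([])
    return table, labels


def inject_missingness(
    table: pd.DataFrame, rate: float, seed: int = 0
) -> pd.DataFrame:
    """Mask each non-identifier cell independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0.0 or out.empty:
        return out
    rng = np.random.default_rng(seed)
    cols = [c for c in out.columns if c not in ID_COLUMNS]
    mask = rng.random((len(out), len(cols))) < rate
    for j, c in enumerate(cols):
        col = out[c]
        if mask[:, j].any():
            if col.dtype.kind in "iu":  # int columns cannot hold NaN
                out[c] = col.astype(float)
            out.loc[mask[:, j], c] = np.nan
    return out
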