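"""Seeded synthetic-data generators with known ground truth.

These generators emulate the statistical structure of the real inputs the
pipeline targets — a tumor-tissue methylation population, a healthy-plasma
population with a subset of differentially methylated probes, and
longitudinal patient cohorts whose cfDNA is a known tumor/healthy mixture —
so every stage (DMP selection, deconvolution training, monitoring) can be
exercised and scored against planted truth without any download.

Per-probe noise is Beta-distributed under a mean/concentration
parameterization (``a = mean * kappa``, ``b = (1 - mean) * kappa``), which
respects the [0, 1] support of beta-values; at concentration kappa the noise
SD is about ``sqrt(mean * (1 - mean) / (kappa + 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cfdeconv.diffmeth import GroupDesign
from cfdeconv.errors import ValidationError


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted-truth methylation populations.

    ``n_dmp`` probes are tumor-specific (methylation differs only in tumor),
    ``n_tissue_dmp`` are tissue-specific (tissue differs from plasma — the
    selection rule must exclude them), the rest are background. Stratum means
    follow the canonical hyper/hypo/intermediate trichotomy of array data.
    """

    n_probes: int = 2000
    n_dmp: int = 400
    n_tissue_dmp: int = 100
    n_tumor: int = 50
    n_normal: int = 50
    n_plasma: int = 60
    hyper_mean: float = 0.8
    hypo_mean: float = 0.2
    background_mean: float = 0.5
    kappa: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dmp + self.n_tissue_dmp > self.n_probes:
            raise ValidationError("planted probes exceed n_probes")
        for m in (self.hyper_mean, self.hypo_mean, self.background_mean):
            if not 0 < m < 1:
                raise ValidationError(f"stratum mean {m} must lie in (0, 1)")
        if self.kappa <= 0:
            raise ValidationError("concentration kappa must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Longitudinal cohort design with a known tumor-fraction schedule.

    The ``sensitive`` arm models therapy response: baseline tumor fraction
    ~ U(0.2, 0.6), each follow-up suppressed to baseline x U(0, 0.3). The
    ``resistant`` arm models no response: follow-up = baseline + N(0, 0.05)
    truncated to [0, 1].
    """

    n_patients: int = 16
    timepoints: int = 2
    arm: str = "sensitive"
    kappa: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in {"sensitive", "resistant"}:
            raise ValidationError("arm must be 'sensitive' or 'resistant'")
        if self.timepoints < 1 or self.n_patients < 1:
            raise ValidationError("need >= 1 patient and >= 1 timepoint")


def _beta_draw(
    rng: np.random.Generator, means: np.ndarray, kappa: float
) -> np.ndarray:
    return rng.beta(means * kappa, (1.0 - means) * kappa)


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def make_reference(
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two-population reference matrix with planted DMPs.

    Returns ``(ref, true_means, planted)``: a probe x sample beta matrix
    whose columns are named ``plasma_1..`` and ``tumor_1..``, the true
    per-probe population means (columns ``healthy``, ``tumor``), and the IDs
    of the planted tumor-differential probes. Planted probes alternate
    between hypermethylated in tumor (tumor = hyper stratum, plasma = hypo)
    and the reverse; background probes share the background mean.
    """
    rng = np.random.default_rng(spec.seed)
    probes = _probe_ids(spec.n_probes)
    healthy_mean = np.full(spec.n_probes, spec.background_mean)
    tumor_mean = np.full(spec.n_probes, spec.background_mean)
    planted = probes[: spec.n_dmp]
    for j in range(spec.n_dmp):
        if j % 2 == 0:
            tumor_mean[j], healthy_mean[j] = spec.hyper_mean, spec.hypo_mean
        else:
            tumor_mean[j], healthy_mean[j] = spec.hypo_mean, spec.hyper_mean

    plasma = _beta_draw(
        rng, np.tile(healthy_mean[:, None], (1, spec.n_plasma)), spec.kappa
    )
    tumor = _beta_draw(
        rng, np.tile(tumor_mean[:, None], (1, spec.n_tumor)), spec.kappa
    )
    ref = pd.DataFrame(
        np.hstack([plasma, tumor]),
        index=pd.Index(probes, name="probe_id"),
        columns=[f"plasma_{i + 1}" for i in range(spec.n_plasma)]
        + [f"tumor_{i + 1}" for i in range(spec.n_tumor)],
    )
    true_means = pd.DataFrame(
        {"healthy": healthy_mean, "tumor": tumor_mean},
        index=pd.Index(probes, name="probe_id"),
    )
    return ref, true_means, planted


def make_tissue_groups(
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, GroupDesign, dict[str, list[str]]]:
    """Three-group tissue dataset for end-to-end DMP selection.

    Groups are tumor tissue, adjacent normal tissue and healthy plasma.
    Tumor-specific planted probes differ only in the tumor group; planted
    tissue-specific probes differ between both tissue groups and plasma, so
    a correct selector must reject them. Returns the beta matrix, the group
    design, and ``{"tumor_specific": [...], "tissue_specific": [...]}``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    probes = _probe_ids(spec.n_probes)
    tumor_mean = np.full(spec.n_probes, spec.background_mean)
    normal_mean = np.full(spec.n_probes, spec.background_mean)
    plasma_mean = np.full(spec.n_probes, spec.background_mean)

    tumor_specific = probes[: spec.n_dmp]
    for j in range(spec.n_dmp):
        tumor_mean[j] = spec.hyper_mean if j % 2 == 0 else spec.hypo_mean
    tissue_specific = probes[spec.n_dmp : spec.n_dmp + spec.n_tissue_dmp]
    for idx, j in enumerate(range(spec.n_dmp, spec.n_dmp + spec.n_tissue_dmp)):
        level = spec.hyper_mean if idx % 2 == 0 else spec.hypo_mean
        tumor_mean[j] = normal_mean[j] = level

    blocks, labels, sample_ids = [], [], []
    for group, size, mean in (
        ("tumor_tissue", spec.n_tumor, tumor_mean),
        ("normal_tissue", spec.n_normal, normal_mean),
        ("normal_plasma", spec.n_plasma, plasma_mean),
    ):
        blocks.append(_beta_draw(rng, np.tile(mean[:, None], (1, size)), spec.kappa))
        labels.extend([group] * size)
        sample_ids.extend(f"{group}_{i + 1}" for i in range(size))

    beta = pd.DataFrame(
        np.hstack(blocks),
        index=pd.Index(probes, name="probe_id"),
        columns=sample_ids,
    )
    design = GroupDesign(sample_ids=tuple(sample_ids), labels=tuple(labels))
    return beta, design, {
        "tumor_specific": tumor_specific,
        "tissue_specific": tissue_specific,
    }


def cohort_fraction_schedule(spec: CohortSpec) -> pd.DataFrame:
    """True per-visit tumor fractions for a cohort arm.

    Returns a DataFrame with sample_id, patient_id, phenotype, timepoint and
    tumor_fraction following the arm's response schedule.
    """
    rng = np.random.default_rng(spec.seed)
    phenotype = "Sensitive" if spec.arm == "sensitive" else "Resistant"
    rows = []
    for p in range(spec.n_patients):
        patient = f"{spec.arm}_p{p + 1:02d}"
        baseline = rng.uniform(0.2, 0.6)
        fractions = [baseline]
        for _t in range(1, spec.timepoints):
            if spec.arm == "sensitive":
                fractions.append(baseline * rng.uniform(0.0, 0.3))
            else:
                fractions.append(
                    float(np.clip(baseline + rng.normal(0.0, 0.05), 0.0, 1.0))
                )
        for t, frac in enumerate(fractions):
            rows.append(
                {
                    "sample_id": f"{patient}_t{t}",
                    "patient_id": patient,
                    "phenotype": phenotype,
                    "timepoint": t,
                    "tumor_fraction": float(frac),
                }
            )
    return pd.DataFrame(rows)


def make_cohort(
    atlas_means: pd.DataFrame,
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Longitudinal cfDNA cohort mixed from population mean profiles.

    Each sample's expected profile is the true-fraction-weighted blend of
    the ``healthy`` and ``tumor`` columns of ``atlas_means``; observed values
    add Beta-distributed probe noise at concentration ``spec.kappa``.

    Returns ``(beta, metadata, fractions)`` where ``beta`` is probe x sample,
    ``metadata`` has the sample/patient/phenotype/timepoint columns, and
    ``fractions`` carries the planted truth for recovery scoring.
    """
    for col in ("healthy", "tumor"):
        if col not in atlas_means.columns:
            raise ValidationError(f"atlas_means lacks column '{col}'")
    fractions = cohort_fraction_schedule(spec)
    rng = np.random.default_rng(spec.seed + 1)
    mu = atlas_means[["healthy", "tumor"]].to_numpy(dtype=float)
    eps = 1e-4  # keep Beta parameters strictly positive
    columns = {}
    for row in fractions.itertuples(index=False):
        w = np.array([1.0 - row.tumor_fraction, row.tumor_fraction])
        mean_profile = np.clip(mu @ w, eps, 1 - eps)
        columns[row.sample_id] = _beta_draw(rng, mean_profile, spec.kappa)
    beta = pd.DataFrame(columns, index=atlas_means.index)
    metadata = fractions[["sample_id", "patient_id", "phenotype", "timepoint"]].copy()
    return beta, metadata, fractions
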