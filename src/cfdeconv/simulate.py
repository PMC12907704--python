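"""Simulated cfDNA mixtures with known tumor-fraction labels.

Real plasma cfDNA samples come with an unknown tumor fraction, so the
deconvolution model is trained on simulated mixtures: each sample blends a
tumor-tissue profile and a healthy-plasma profile at fractions drawn from a
Dirichlet (or Uniform) scheme. Per-sample profiles are the per-probe mean of
``k`` reference columns drawn with replacement from the population, which
keeps every simulated value inside the reference convex hull while adding
between-sample heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cfdeconv.errors import ValidationError
from cfdeconv.io import read_matrix

DEFAULT_PRIOR = (0.8, 0.2)  # (healthy, tumor) Dirichlet concentration
DEFAULT_SAMPLENUM = 5000
DEFAULT_K = 5
_CHUNK = 10_000  # samples per profile-averaging chunk, bounds peak memory


@dataclass(frozen=True)
class SimulatedSet:
    """Mixture matrix plus fraction labels.

    ``x`` is samples x probes (beta scale); ``y`` is samples x 2 with column
    0 the healthy fraction and column 1 the tumor fraction; rows of ``y``
    sum to 1.
    """

    x: np.ndarray
    y: np.ndarray
    probe_ids: tuple[str, ...]
    seed: int
    method: str

    def __post_init__(self) -> None:
        if self.x.shape[0] != self.y.shape[0]:
            raise ValidationError("x and y must have the same number of samples")
        if self.y.shape[1] != 2:
            raise ValidationError("y must have exactly two fraction columns")


def split_reference_populations(
    ref: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a reference matrix into (plasma, tumor) column blocks.

    Population membership is read from sample-name prefixes: columns named
    ``plasma_*`` are healthy plasma, ``tumor_*`` tumor tissue.
    """
    plasma_cols = [c for c in ref.columns if str(c).startswith("plasma")]
    tumor_cols = [c for c in ref.columns if str(c).startswith("tumor")]
    if not tumor_cols or not plasma_cols:
        raise ValidationError(
            "could not identify reference populations: expected column names "
            "with prefixes 'tumor_' and 'plasma_' (e.g. tumor_1, plasma_1); "
            f"got {list(ref.columns[:6])}..."
        )
    if ref.isna().any().any():
        raise ValidationError("reference matrix must not contain missing values")
    return ref[plasma_cols], ref[tumor_cols]


def reference_population_means(ref: pd.DataFrame) -> pd.DataFrame:
    """Per-probe mean beta of each population: columns (healthy, tumor)."""
    plasma, tumor = split_reference_populations(ref)
    return pd.DataFrame(
        {"healthy": plasma.mean(axis=1), "tumor": tumor.mean(axis=1)},
        index=ref.index,
    )


def generate_simulated_data(
    ref: pd.DataFrame | str | Path,
    prior: tuple[float, float] = DEFAULT_PRIOR,
    samplenum: int = DEFAULT_SAMPLENUM,
    random_state: int = 1,
    method: str = "Dirichlet",
    k: int = DEFAULT_K,
    logit_noise_sd: float = 0.0,
) -> SimulatedSet:
    """Generate ``samplenum`` simulated cfDNA samples with fraction labels.

    Parameters
    ----------
    ref
        Probe-by-sample reference beta matrix (or path to one) whose columns
        are prefixed ``tumor_`` / ``plasma_``; no missing values.
    prior
        Dirichlet concentration for (healthy, tumor); the expected tumor
        fraction is ``prior[1] / sum(prior)``.
    samplenum
        Number of mixtures to generate.
    random_state
        Seed; identical inputs give bit-identical output.
    method
        ``"Dirichlet"`` draws (w_h, w_t) from Dirichlet(prior);
        ``"Uniform"`` draws w_t ~ U(0, 1) and sets w_h = 1 - w_t.
    k
        Number of reference columns averaged (with replacement) into each
        per-sample population profile; ``k=1`` blends single donors.
    logit_noise_sd
        Optional Gaussian noise on the logit scale added to the mixed
        profile; off by default.
    """
    if isinstance(ref, (str, Path)):
        ref = read_matrix(ref)
    if samplenum < 1:
        raise ValidationError("samplenum must be >= 1")
    if k < 1:
        raise ValidationError("k must be >= 1")
    prior_arr = np.asarray(prior, dtype=float)
    if prior_arr.shape != (2,) or (prior_arr <= 0).any():
        raise ValidationError("prior must be two positive concentrations")
    method_norm = method.lower()
    if method_norm not in {"dirichlet", "uniform"}:
        raise ValidationError(f"unknown method '{method}'; use Dirichlet or Uniform")

    plasma, tumor = split_reference_populations(ref)
    plasma_vals = plasma.to_numpy(dtype=float).T  # columns-as-rows for fancy indexing
    tumor_vals = tumor.to_numpy(dtype=float).T
    n_probes = plasma_vals.shape[1]

    rng = np.random.default_rng(random_state)
    if method_norm == "dirichlet":
        y = rng.dirichlet(prior_arr, size=samplenum)
    else:
        w_t = rng.uniform(0.0, 1.0, size=samplenum)
        y = np.column_stack([1.0 - w_t, w_t])

    idx_h = rng.integers(0, plasma_vals.shape[0], size=(samplenum, k))
    idx_t = rng.integers(0, tumor_vals.shape[0], size=(samplenum, k))

    x = np.empty((samplenum, n_probes), dtype=float)
    for start in range(0, samplenum, _CHUNK):
        stop = min(start + _CHUNK, samplenum)
        p_h = plasma_vals[idx_h[start:stop]].mean(axis=1)
        p_t = tumor_vals[idx_t[start:stop]].mean(axis=1)
        x[start:stop] = (
            y[start:stop, 0:1] * p_h + y[start:stop, 1:2] * p_t
        )
    if logit_noise_sd > 0:
        eps = 1e-6
        logit = np.log(np.clip(x, eps, 1 - eps) / np.clip(1 - x, eps, 1 - eps))
        logit += rng.normal(0.0, logit_noise_sd, size=x.shape)
        x = 1.0 / (1.0 + np.exp(-logit))

    return SimulatedSet(
        x=x,
        y=y,
        probe_ids=tuple(str(p) for p in ref.index),
        seed=random_state,
        method="Uniform" if method_norm == "uniform" else "Dirichlet",
    )
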