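"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without any external data:

* correlated Gaussian descriptor matrices whose marginal means/SDs and 4×4
  correlation structure default to those of the bundled descriptor table;
* linear IC50 responses ``y = Xβ + β₀ + ε`` with iid Gaussian noise, whose
  default coefficients and noise SD match the fitted study model
  (β = (0.183, −0.359, −3.181, 10.627), β₀ = −9.859, σ ≈ 0.49 μM);
* decoy descriptor pools (independent noise columns appended to the signal
  block) for selection-power experiments;
* 4PL viability plates with multiplicative noise for the dose-response
  fitter.

All generators are pure functions of (spec, seed).  A single global seed is
expanded into fixed per-stage substreams so each stage is individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import DESCRIPTOR_NAMES, load_fixture
from .dose_response import four_pl
from .errors import SpecError

__all__ = [
    "SyntheticSpec",
    "table_matched_spec",
    "gen_descriptor_matrix",
    "gen_response",
    "gen_decoy_pool",
    "gen_viability_plate",
]

# fixed substream offsets: one global seed, reproducible per stage
_STREAM_DESCRIPTORS = 0
_STREAM_RESPONSE = 1_000_003
_STREAM_DECOYS = 2_000_003
_STREAM_PLATE = 3_000_017

#: published model coefficients and intercept (μM per descriptor unit, μM)
STUDY_COEFFICIENTS = (0.183, -0.359, -3.181, 10.627)
STUDY_INTERCEPT = -9.859
#: residual scale of the training fit (μM)
STUDY_NOISE_SD = 0.49


@dataclass(frozen=True)
class SyntheticSpec:
    n_compounds: int
    target_correlation: np.ndarray       # symmetric positive definite, unit diagonal
    descriptor_means: np.ndarray
    descriptor_sds: np.ndarray
    descriptor_names: tuple[str, ...]
    true_coefficients: np.ndarray
    true_intercept: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        k = len(self.descriptor_names)
        corr = np.asarray(self.target_correlation, dtype=float)
        if corr.shape != (k, k):
            raise SpecError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(corr, corr.T):
            raise SpecError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise SpecError("correlation matrix must have unit diagonal")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise SpecError("correlation matrix not positive definite") from exc
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.n_compounds < 3:
            raise SpecError("n_compounds must be >= 3")
        if (np.asarray(self.descriptor_sds) <= 0).any():
            raise SpecError("descriptor SDs must be positive")

    def with_(self, **changes) -> "SyntheticSpec":
        return replace(self, **changes)


def table_matched_spec(
    seed: int = 0, n_compounds: int = 24, noise_sd: float = STUDY_NOISE_SD
) -> SyntheticSpec:
    """Default spec matched to the bundled descriptor table.

    Means, SDs and the 4×4 correlation structure are the sample statistics
    of the 31-compound descriptor table; the response model defaults to the
    published coefficients with a residual SD equal to the training RMSE.
    ``n_compounds`` defaults to the training-set size of the study design.
    """
    desc = load_fixture("descriptors")[list(DESCRIPTOR_NAMES)].to_numpy()
    return SyntheticSpec(
        n_compounds=n_compounds,
        target_correlation=np.corrcoef(desc.T),
        descriptor_means=desc.mean(axis=0),
        descriptor_sds=desc.std(axis=0, ddof=1),
        descriptor_names=DESCRIPTOR_NAMES,
        true_coefficients=np.asarray(STUDY_COEFFICIENTS, dtype=float),
        true_intercept=STUDY_INTERCEPT,
        noise_sd=noise_sd,
        seed=seed,
    )


def gen_descriptor_matrix(spec: SyntheticSpec) -> pd.DataFrame:
    """Multivariate-normal descriptor matrix via Cholesky factorisation of
    the target correlation, scaled to the requested marginals."""
    rng = np.random.default_rng(spec.seed + _STREAM_DESCRIPTORS)
    k = len(spec.descriptor_names)
    L = np.linalg.cholesky(np.asarray(spec.target_correlation, dtype=float))
    z = rng.standard_normal((spec.n_compounds, k)) @ L.T
    values = np.asarray(spec.descriptor_means) + np.asarray(spec.descriptor_sds) * z
    out = pd.DataFrame(values, columns=list(spec.descriptor_names))
    out.insert(0, "compound_id", np.arange(1, spec.n_compounds + 1))
    return out


def gen_response(
    X: pd.DataFrame | np.ndarray,
    true_coefficients: np.ndarray,
    true_intercept: float,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Linear response y = Xβ + β₀ + ε with ε ~ N(0, noise_sd²) iid."""
    if isinstance(X, pd.DataFrame):
        mat = X[[c for c in X.columns if c != "compound_id"]].to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
    beta = np.asarray(true_coefficients, dtype=float)
    if mat.shape[1] != len(beta):
        raise SpecError(f"X has {mat.shape[1]} columns but beta has {len(beta)}")
    rng = np.random.default_rng(seed + _STREAM_RESPONSE)
    return mat @ beta + true_intercept + noise_sd * rng.standard_normal(mat.shape[0])


def gen_decoy_pool(spec: SyntheticSpec, n_decoys: int) -> pd.DataFrame:
    """Signal descriptor block plus independent standard-normal decoy columns.

    Decoys are labelled ``decoy_01`` ... so selection experiments know the
    ground truth; with ``n_decoys = 0`` this is exactly the signal matrix.
    """
    if n_decoys < 0:
        raise SpecError("n_decoys must be >= 0")
    out = gen_descriptor_matrix(spec)
    if n_decoys:
        rng = np.random.default_rng(spec.seed + _STREAM_DECOYS)
        noise = rng.standard_normal((spec.n_compounds, n_decoys))
        for j in range(n_decoys):
            out[f"decoy_{j + 1:02d}"] = noise[:, j]
    return out


def gen_viability_plate(
    ic50: float,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    concentrations: np.ndarray | None = None,
    cv_noise: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated viability plate on a 0–20 μM daunorubicin design.

    The mean response follows a 4PL; wells get multiplicative Gaussian noise
    with coefficient of variation ``cv_noise``.  Zero-concentration vehicle
    wells (mean = top) are included for normalisation.  Columns: ``well``,
    ``concentration`` (μM), ``absorbance``.
    """
    if concentrations is None:
        concentrations = np.array([0.3125, 0.625, 1.25, 2.5, 5.0, 10.0, 20.0])
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any() or (conc > 20).any():
        raise SpecError("concentrations must lie in (0, 20] μM")
    if replicates < 1:
        raise SpecError("replicates must be >= 1")
    rng = np.random.default_rng(seed + _STREAM_PLATE)
    grid = np.concatenate([[0.0], conc])
    mean = np.concatenate([[top], four_pl(conc, top, bottom, ic50, hill)])
    rows = []
    well = 0
    for c, m in zip(grid, mean):
        for _ in range(replicates):
            noise = 1.0 + cv_noise * rng.standard_normal() if cv_noise > 0 else 1.0
            rows.append({"well": f"W{well:03d}", "concentration": c, "absorbance": m * noise})
            well += 1
    return pd.DataFrame(rows)
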