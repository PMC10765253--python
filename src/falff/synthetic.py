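"""Synthetic cohorts and BOLD-like voxel data with known ground truth.

Real resting-state acquisitions of the kind this package analyses (multiband
EPI, TR = 0.735 s, 490 volumes, 2.4 mm isotropic) cannot be redistributed, so
every pipeline stage is exercised on simulated data whose generating model is
known exactly:

* **Cohorts** — hypertensive and normotensive participants whose age, BMI and
  sex distributions are shifted between groups (confounding the hypertension
  label) and whose systolic/diastolic pressures follow group-dependent
  normals.  Defaults reproduce the scale of the motivating study: 2054
  hypertensives against a 1724-strong normotensive donor pool.
* **Voxels** — each voxel is a sum of a band-limited Gaussian "neuronal"
  process (white noise spectrally shaped into 0.01-0.08 Hz, amplitude set per
  region with optional group and group-by-region effects), a slow scanner
  drift below 0.01 Hz, cardiac and respiratory sinusoids (the cardiac
  fundamental of 1 Hz lies above the 0.680 Hz Nyquist limit and therefore
  appears aliased, as it does in the real acquisition), and white thermal
  noise.  CSF-labelled voxels carry almost no band-limited component and are
  scaled by a broadband multiplier, giving them uniformly higher but flatter
  power spectra than parenchyma — the configuration in which the fractional
  correction suppresses their contribution.

All randomness flows through one integer seed via ``numpy``'s seed-sequence
spawning, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .roi import RoiSet
from .spectral import NARROW, BandSpec, TimeSeriesGrid, nyquist

__all__ = [
    "GroupParams",
    "RegionSpec",
    "SimulationConfig",
    "build_rois",
    "default_regions",
    "interaction_cohens_f",
    "simulate_cohort",
    "simulate_regional_zscores",
    "simulate_voxels",
]

REFERENCE_REGION = "frontal_gm"
CSF_REGION = "csf"


@dataclass(frozen=True)
class RegionSpec:
    """One labelled region: voxel count and baseline neuronal amplitude.

    ``base_amplitude`` is the standard deviation of the region's stochastic
    component in arbitrary signal units.  For parenchymal regions that
    component is band-limited ("neuronal", 0.01-0.08 Hz); for ``is_csf``
    regions it is flat across the whole detectable spectrum (pulsatile CSF
    power is broadband), and the finished voxel series is additionally
    scaled by the broadband multiplier.
    """

    name: str
    n_voxels: int
    base_amplitude: float
    is_csf: bool = False


def default_regions() -> list[RegionSpec]:
    """Region roster: frontal grey matter reference, 15 analysis regions, CSF.

    The 15 analysis regions are the three brainstem subdivisions, bilateral
    amygdala/hippocampus/thalamus/insula/visual cortex, the midline
    hypothalamus and one cortical control region.  Baseline amplitudes vary
    across regions (caudal structures lower) so a regional fALFF gradient
    exists by construction.
    """
    return [
        RegionSpec(REFERENCE_REGION, 40, 1.00),
        RegionSpec("midbrain", 12, 0.76),
        RegionSpec("pons", 12, 0.72),
        RegionSpec("medulla", 12, 0.68),
        RegionSpec("amygdala_left", 12, 0.84),
        RegionSpec("amygdala_right", 12, 0.86),
        RegionSpec("hippocampus_left", 12, 0.88),
        RegionSpec("hippocampus_right", 12, 0.90),
        RegionSpec("thalamus_left", 12, 0.92),
        RegionSpec("thalamus_right", 12, 0.94),
        RegionSpec("insula_left", 12, 0.96),
        RegionSpec("insula_right", 12, 0.98),
        RegionSpec("visual_cortex_left", 12, 1.10),
        RegionSpec("visual_cortex_right", 12, 1.12),
        RegionSpec("hypothalamus", 8, 0.80),
        RegionSpec("precentral_control", 12, 1.02),
        RegionSpec(CSF_REGION, 8, 1.50, is_csf=True),
    ]


@dataclass(frozen=True)
class GroupParams:
    """Covariate and blood-pressure distributions for one group."""

    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    p_male: float
    systolic_mean: float
    systolic_sd: float
    diastolic_mean: float
    diastolic_sd: float


@dataclass
class SimulationConfig:
    """Full generating model for one synthetic study.

    Cohort defaults mirror the motivating study's scale and baseline table
    (hypertensives older, heavier and more often male than the unmatched
    normotensive pool; systolic 149 +/- 18.1 vs 137 +/- 17.0 mmHg).  Voxel
    defaults mirror its acquisition (490 timepoints at TR 0.735 s) and the
    standard taxonomy of rsfMRI signal sources: neuronal band 0.01-0.08 Hz,
    drift < 0.01 Hz, respiration near 0.25 Hz, cardiac fundamental 1 Hz
    (aliased), plus white thermal noise.  Group amplitude effects default to
    a small uniform shift and no region-specific (interaction) effect,
    matching the tiny-effect regime of interest; tests that need power
    inject larger documented deltas.
    """

    seed: int = 0
    n_hypertensive: int = 2054
    n_normotensive: int = 1724
    n_timepoints: int = 490
    tr: float = 0.735
    regions: list[RegionSpec] = field(default_factory=default_regions)
    neuronal_band: BandSpec = NARROW
    # group-level amplitude effects, in the same units as base_amplitude
    group_delta: float = 0.01
    interaction_deltas: dict[str, float] = field(default_factory=dict)
    # between-participant variability: each participant's regional neuronal
    # amplitude is scaled by Normal(1, amplitude_between_sd), floored at 0
    amplitude_between_sd: float = 0.10
    # nuisance model
    drift_freq: float = 0.005
    drift_amplitude: float = 0.30
    cardiac_freq: float = 1.0
    cardiac_amplitude: float = 0.20
    respiratory_freq: float = 0.25
    respiratory_amplitude: float = 0.20
    noise_sd: float = 0.50
    csf_multiplier: float = 5.0
    hypertensive: GroupParams = field(
        default_factory=lambda: GroupParams(57.7, 6.7, 27.8, 4.0, 0.60,
                                            149.0, 18.1, 87.0, 10.6)
    )
    normotensive: GroupParams = field(
        default_factory=lambda: GroupParams(55.5, 6.9, 26.6, 4.4, 0.52,
                                            137.0, 17.0, 81.2, 9.7)
    )

    def __post_init__(self):
        if self.n_hypertensive < 1 or self.n_normotensive < 1:
            raise ParameterError("group sizes must be at least 1")
        if min(r.base_amplitude for r in self.regions) < 0:
            raise ParameterError("region amplitudes must be nonnegative")
        if self.group_delta < 0 and any(
            r.base_amplitude + self.group_delta < 0 for r in self.regions
        ):
            raise ParameterError("group delta drives an amplitude negative")
        for amp in (self.drift_amplitude, self.cardiac_amplitude,
                    self.respiratory_amplitude, self.noise_sd,
                    self.csf_multiplier, self.amplitude_between_sd):
            if amp < 0:
                raise ParameterError("nuisance amplitudes must be nonnegative")

    def region(self, name: str) -> RegionSpec:
        for spec in self.regions:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def amplitude(self, region: str, group: str) -> float:
        """True neuronal amplitude of one region for one group."""
        base = self.region(region).base_amplitude
        if group == "hypertensive":
            base = base + self.group_delta + self.interaction_deltas.get(region, 0.0)
        return base

    def ground_truth(self) -> dict:
        """JSON-serialisable echo of the config and the per-cell amplitudes."""
        cfg = dataclasses.asdict(self)
        cfg["regions"] = [dataclasses.asdict(r) for r in self.regions]
        cfg["neuronal_band"] = {"low": self.neuronal_band.f_low,
                                "high": self.neuronal_band.f_high}
        return {
            "config": cfg,
            "amplitude_by_group": {
                grp: {r.name: self.amplitude(r.name, grp) for r in self.regions}
                for grp in ("hypertensive", "normotensive")
            },
        }


def build_rois(cfg: SimulationConfig) -> RoiSet:
    """Label volume implied by the config's region roster (labels 1..K)."""
    labels = np.concatenate(
        [np.full(r.n_voxels, i + 1) for i, r in enumerate(cfg.regions)]
    )
    names = {i + 1: r.name for i, r in enumerate(cfg.regions)}
    reference = next(
        i + 1 for i, r in enumerate(cfg.regions) if r.name == REFERENCE_REGION
    )
    return RoiSet(labels, names, reference)


def simulate_cohort(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Draw a participant table with group-dependent covariates and BP.

    Ages and BMI are normal, sex Bernoulli, systolic/diastolic pressures
    normal, each with the group's parameters; the group shifts make age, sex
    and BMI genuine confounders of the hypertension label.  Returns the table
    and a ground-truth record.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    frames = []
    for group, n, prefix in (
        ("hypertensive", cfg.n_hypertensive, "H"),
        ("normotensive", cfg.n_normotensive, "N"),
    ):
        p: GroupParams = getattr(cfg, group)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{prefix}{i:05d}" for i in range(n)],
                    "group": group,
                    "age": np.round(rng.normal(p.age_mean, p.age_sd, n), 2),
                    "sex": np.where(rng.random(n) < p.p_male, "male", "female"),
                    "bmi": np.round(
                        np.clip(rng.normal(p.bmi_mean, p.bmi_sd, n), 15, None), 2
                    ),
                    "systolic": np.round(
                        np.clip(rng.normal(p.systolic_mean, p.systolic_sd, n),
                                70, None), 1
                    ),
                    "diastolic": np.round(
                        np.clip(rng.normal(p.diastolic_mean, p.diastolic_sd, n),
                                40, None), 1
                    ),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table, cfg.ground_truth()


def _nearest_bin_freq(freq: float, n: int, tr: float) -> float:
    """Fold a frequency into (0, Nyquist] by aliasing, then snap to the
    nearest DFT bin centre k/(n*tr), k >= 1.

    Snapping avoids spectral leakage of the sinusoidal nuisances across many
    bins; a frequency exactly between two bins is nudged to the lower one
    (round-half-down via ``floor(x + 0.5)`` on the bin index).
    """
    fs = 1.0 / tr
    folded = freq % fs
    folded = min(folded, fs - folded)
    df = 1.0 / (n * tr)
    k = max(1, int(np.floor(folded / df + 0.5)))
    k = min(k, n // 2)
    return k * df


def _band_limited_noise(
    rng: np.random.Generator, n_voxels: int, n: int, tr: float, band: BandSpec
) -> np.ndarray:
    """Unit-sd Gaussian processes with power confined to ``band``."""
    white = rng.standard_normal((n_voxels, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=tr)
    spec[:, ~band.mask(freqs)] = 0.0
    shaped = np.fft.irfft(spec, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_voxels(
    cfg: SimulationConfig,
    group: str,
    seed: int,
    rois: RoiSet | None = None,
) -> tuple[TimeSeriesGrid, RoiSet, dict]:
    """Simulate one participant's voxel time series.

    Each voxel is neuronal + drift + cardiac + respiratory + thermal noise.
    The cardiac and respiratory phases are shared across voxels (systemic
    physiology); drift phase and all stochastic components are voxelwise.
    CSF voxels have the whole sum scaled by ``csf_multiplier``.
    """
    if group not in ("hypertensive", "normotensive"):
        raise ParameterError(f"unknown group {group!r}")
    if rois is None:
        rois = build_rois(cfg)
    rng = np.random.default_rng(seed)
    n = cfg.n_timepoints
    tr = cfg.tr
    t = np.arange(n) * tr
    n_vox = rois.labels.size

    is_csf = np.zeros(n_vox, dtype=bool)
    for label, name in rois.names.items():
        if cfg.region(name).is_csf:
            is_csf |= rois.labels == label

    neuronal = _band_limited_noise(rng, n_vox, n, tr, cfg.neuronal_band)
    if is_csf.any():
        # CSF fluctuations are broadband: flat over (0, Nyquist]
        neuronal[is_csf] = _band_limited_noise(
            rng, int(is_csf.sum()), n, tr, BandSpec(0.0, nyquist(tr))
        )
    amplitudes = np.empty(n_vox)
    for label, name in rois.names.items():
        scale = max(0.0, rng.normal(1.0, cfg.amplitude_between_sd))
        amplitudes[rois.labels == label] = cfg.amplitude(name, group) * scale
    series = neuronal * amplitudes[:, None]

    drift_f = _nearest_bin_freq(cfg.drift_freq, n, tr)
    drift_phase = rng.uniform(0, 2 * np.pi, size=(n_vox, 1))
    series += cfg.drift_amplitude * np.sqrt(2) * np.cos(
        2 * np.pi * drift_f * t[None, :] + drift_phase
    )

    for freq, amp in (
        (cfg.cardiac_freq, cfg.cardiac_amplitude),
        (cfg.respiratory_freq, cfg.respiratory_amplitude),
    ):
        if amp == 0:
            continue
        f_eff = _nearest_bin_freq(freq, n, tr)
        phase = rng.uniform(0, 2 * np.pi)
        series += amp * np.sqrt(2) * np.cos(2 * np.pi * f_eff * t + phase)

    series += cfg.noise_sd * rng.standard_normal((n_vox, n))
    series[is_csf] *= cfg.csf_multiplier

    truth = cfg.ground_truth()
    truth["participant"] = {"group": group, "seed": int(seed)}
    return TimeSeriesGrid(series, tr), rois, truth


# ---------------------------------------------------------------------------
# Regional-level generator for Monte-Carlo statistical experiments
# ---------------------------------------------------------------------------

DEFAULT_REGION_EFFECTS = {
    r.name: round(1.2 * (r.base_amplitude - 1.0), 4)
    for r in default_regions()
    if r.name not in (REFERENCE_REGION, CSF_REGION)
}


def simulate_regional_zscores(
    n_per_group: int,
    seed: int,
    region_effects: dict[str, float] | None = None,
    group_delta: float = 0.0,
    interaction_deltas: dict[str, float] | None = None,
    covariate_betas: tuple[float, float, float] = (0.005, 0.01, 0.05),
    residual_sd: float = 1.0,
    intercept: float = -0.6,
) -> pd.DataFrame:
    """Draw participant-by-region mean fALFF z-scores from the ANCOVA model.

    The response is generated directly from the group/region/covariate linear
    model with Gaussian residuals of sd ``residual_sd``, bypassing the voxel
    level; this makes the null distribution and the noncentrality of injected
    effects exact, which is what Monte-Carlo calibration experiments
    (type-I error, power curves) need.  ``interaction_deltas`` adds a
    region-specific shift for hypertensives on top of ``group_delta``;
    covariates are age, BMI and sex with the given coefficients (applied to
    centred age/BMI).

    Returns a long table with one row per participant-region pair.
    """
    rng = np.random.default_rng(seed)
    if region_effects is None:
        region_effects = DEFAULT_REGION_EFFECTS
    interaction_deltas = interaction_deltas or {}
    regions = list(region_effects)
    n_regions = len(regions)
    beta_age, beta_bmi, beta_sex = covariate_betas
    frames = []
    for group, prefix in (("hypertensive", "H"), ("normotensive", "N")):
        age = rng.normal(57.6, 6.8, n_per_group)
        bmi = rng.normal(27.7, 4.2, n_per_group)
        sex = (rng.random(n_per_group) < 0.6).astype(float)
        base = (
            intercept
            + beta_age * (age - 57.6)
            + beta_bmi * (bmi - 27.7)
            + beta_sex * sex
        )
        offsets = np.array([region_effects[r] for r in regions])
        if group == "hypertensive":
            base = base + group_delta
            offsets = offsets + np.array(
                [interaction_deltas.get(r, 0.0) for r in regions]
            )
        mu = base[:, None] + offsets[None, :]
        z = mu + rng.normal(0, residual_sd, (n_per_group, n_regions))
        ids = np.array([f"{prefix}{i:05d}" for i in range(n_per_group)])
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(ids, n_regions),
                    "group": group,
                    "region": np.tile(regions, n_per_group),
                    "mean_z": z.ravel(),
                    "age": np.repeat(age, n_regions),
                    "bmi": np.repeat(bmi, n_regions),
                    "sex": np.repeat(sex, n_regions),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def interaction_cohens_f(
    regions: list[str],
    interaction_deltas: dict[str, float],
    residual_sd: float = 1.0,
) -> float:
    """Cohen's f of the group-by-region interaction for equal cell sizes.

    Builds the 2 x R cell-mean matrix implied by hypertensive-only deltas,
    double-centres it to isolate the interaction component, and returns the
    root-mean-square interaction effect over the residual sd.  With equal
    cell sizes the F-test noncentrality is ``f^2 * N``.
    """
    mat = np.zeros((2, len(regions)))
    for j, region in enumerate(regions):
        mat[0, j] = interaction_deltas.get(region, 0.0)  # hypertensive row
    centred = (
        mat
        - mat.mean(axis=0, keepdims=True)
        - mat.mean(axis=1, keepdims=True)
        + mat.mean()
    )
    return float(np.sqrt((centred**2).mean()) / residual_sd)
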