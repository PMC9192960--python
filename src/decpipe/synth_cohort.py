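"""Synthetic resting-state cohorts with known directed connectivity.

Every downstream stage of the pipeline (deconvolution, Kalman dMVAR,
summaries, group statistics) is validated against data generated here,
where the ground truth is known exactly.  Subjects' latent neural
signals follow a time-varying vector autoregression

    y_t = sum_k A_k(t) y_{t-k} + e_t,       e_t ~ N(0, diag(sigma^2)),

whose coefficient trajectories (constant, sinusoidal or step) are the
generative twin of the dynamic MVAR model estimated downstream.  The
cohort layer adds subject-level clinical structure: a group offset on
one target connection's mean coefficient, a symptom score linearly
related to that coefficient, and plausible covariate marginals (age,
gender, motion, medication status).

Defaults emulate the OCD-regime study design: 43 patients vs 24
controls, TR 2.0 s, a negative patient offset of 0.109 on the
L vlPFC -> L putamen (A) connection, and a positive symptom slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .containers import NeuralTimeSeries
from .roi import DEFAULT_ROI_SET, RoiSet, sphere_mask

logger = logging.getLogger(__name__)

__all__ = [
    "VarSpec",
    "CohortDesign",
    "Cohort",
    "constant_coeffs",
    "sinusoidal_coeffs",
    "step_coeffs",
    "companion_spectral_radius",
    "generate_tv_var",
    "generate_cohort",
    "series_to_nifti",
    "null_design",
    "ARBITRATION_CONNECTIONS",
]


# ---------------------------------------------------------------------------
# coefficient trajectories
# ---------------------------------------------------------------------------

def constant_coeffs(A: np.ndarray) -> Callable[[int], np.ndarray]:
    """Time-invariant coefficients. ``A`` has shape (p, n, n) or (n, n)."""
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        A = A[None]
    return lambda t: A


def sinusoidal_coeffs(
    base: np.ndarray,
    entry: tuple[int, int, int],
    amplitude: float,
    period: float,
    phase: float = 0.0,
) -> Callable[[int], np.ndarray]:
    """Sinusoidally varying single entry ``(lag, target, source)`` around ``base``."""
    base = np.asarray(base, dtype=float)
    if base.ndim == 2:
        base = base[None]
    k, i, j = entry

    def traj(t: int) -> np.ndarray:
        A = base.copy()
        A[k, i, j] += amplitude * np.sin(2 * np.pi * t / period + phase)
        return A

    return traj


def step_coeffs(
    base: np.ndarray,
    entry: tuple[int, int, int],
    delta: float,
    change_point: int,
) -> Callable[[int], np.ndarray]:
    """Single entry jumps by ``delta`` at ``change_point``."""
    base = np.asarray(base, dtype=float)
    if base.ndim == 2:
        base = base[None]
    k, i, j = entry

    def traj(t: int) -> np.ndarray:
        A = base.copy()
        if t >= change_point:
            A[k, i, j] += delta
        return A

    return traj


def companion_spectral_radius(A_stack: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix for coefficients (p, n, n)."""
    A_stack = np.asarray(A_stack, dtype=float)
    p, n, _ = A_stack.shape
    comp = np.zeros((n * p, n * p))
    comp[:n] = A_stack.transpose(1, 0, 2).reshape(n, n * p)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


# ---------------------------------------------------------------------------
# time-varying VAR generator
# ---------------------------------------------------------------------------

@dataclass
class VarSpec:
    """Specification of a (time-varying) vector autoregressive process.

    ``coeff_trajectories`` maps a time index to the stacked coefficient
    matrices ``A_1..A_p`` of shape (p, n_regions, n_regions); a
    pre-tabulated array of shape (length, p, n, n) is also accepted.
    """

    n_regions: int
    order: int
    coeff_trajectories: Callable[[int], np.ndarray] | np.ndarray
    innovation_sd: float | np.ndarray = 1.0
    length: int = 500
    dt: float = 2.0
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.order < 1:
            raise ValueError("n_regions and order must be >= 1")
        if self.length <= self.order:
            raise ValueError("length must exceed the model order")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        sd = np.broadcast_to(np.asarray(self.innovation_sd, dtype=float), (self.n_regions,))
        if np.any(sd < 0):
            raise ValueError("innovation_sd must be nonnegative")
        self._sd = np.array(sd)

    def coeffs_at(self, t: int) -> np.ndarray:
        if callable(self.coeff_trajectories):
            A = np.asarray(self.coeff_trajectories(t), dtype=float)
        else:
            A = np.asarray(self.coeff_trajectories[t], dtype=float)
        if A.ndim == 2:
            A = A[None]
        if A.shape != (self.order, self.n_regions, self.n_regions):
            raise ValueError(
                f"coefficients at t={t} have shape {A.shape}, expected "
                f"({self.order}, {self.n_regions}, {self.n_regions})"
            )
        return A

    def tabulate(self) -> np.ndarray:
        """Materialize coefficients for all time indices, shape (T, p, n, n)."""
        return np.stack([self.coeffs_at(t) for t in range(self.length)])

    def check_stationary(self) -> None:
        """Raise if the companion spectral radius reaches 1 at any time index.

        Repeated coefficient stacks are deduplicated before the eigen
        decomposition, so constant trajectories cost one check.
        """
        tab = self.tabulate()
        flat = tab.reshape(self.length, -1)
        _, first_idx, inverse = np.unique(flat, axis=0, return_index=True, return_inverse=True)
        radii = np.array([companion_spectral_radius(tab[i]) for i in first_idx])
        bad = radii[inverse] >= 1.0
        if bad.any():
            t_bad = int(np.argmax(bad))
            raise ValueError(
                f"non-stationary VAR: companion spectral radius "
                f"{radii[inverse][t_bad]:.4f} >= 1 first at time index {t_bad}"
            )


def generate_tv_var(spec: VarSpec, seed: int | None = None) -> NeuralTimeSeries:
    """Simulate a time-varying VAR with Gaussian innovations.

    The first ``p`` samples are drawn from the innovation distribution.
    Reproducible for a fixed seed; refuses non-stationary specifications
    with the first violating time index in the message.
    """
    spec.check_stationary()
    rng = np.random.default_rng(seed)
    T, n, p = spec.length, spec.n_regions, spec.order
    e = rng.normal(0.0, 1.0, (T, n)) * spec._sd
    y = np.zeros((T, n))
    y[:p] = e[:p]
    tab = spec.tabulate()
    for t in range(p, T):
        acc = e[t].copy()
        for k in range(p):
            acc += tab[t, k] @ y[t - 1 - k]
        y[t] = acc
    return NeuralTimeSeries(y, dt=spec.dt, region_labels=spec.region_labels)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: The three arbitration connections analyzed downstream (source, target).
ARBITRATION_CONNECTIONS = [
    ("vlPFC_L", "putamen_L_A"),
    ("vlPFC_R", "putamen_L_B"),
    ("FPC_R", "putamen_R"),
]


@dataclass
class CohortDesign:
    """Design of a two-group synthetic cohort.

    ``group_dec_offset`` is the patients-minus-controls difference in the
    expected ground-truth coefficient on ``target_connection``;
    ``symptom_slope`` maps a subject's true mean coefficient to the
    symptom score (YBOCS scale, clipped to 0-40).  ``subject_dec_sd``
    is the between-subject SD of the true coefficient.
    """

    n_patients: int = 43
    n_controls: int = 24
    region_labels: tuple[str, ...] = tuple(DEFAULT_ROI_SET.labels)
    target_connection: tuple[str, str] = ("vlPFC_L", "putamen_L_A")
    control_dec_mean: float = 0.05
    group_dec_offset: float = -0.109
    subject_dec_sd: float = 0.15
    symptom_intercept: float = 25.0
    symptom_slope: float = 12.157
    symptom_noise_sd: float = 4.3
    age_mean: float = 30.0
    age_sd: float = 10.0
    gender_p_female: float = 0.5
    dvars_log_mean: float = 3.4
    dvars_log_sd: float = 0.3
    medication_fraction: float = 14.0 / 43.0
    self_coupling: float = 0.3
    baseline_coupling: float = 0.05
    length: int = 300
    tr: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be positive")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if not 0.0 <= self.medication_fraction <= 1.0:
            raise ValueError("medication_fraction must lie in [0, 1]")
        if not 0.0 <= self.gender_p_female <= 1.0:
            raise ValueError("gender_p_female must lie in [0, 1]")
        for conn in [self.target_connection]:
            if conn[0] not in self.region_labels or conn[1] not in self.region_labels:
                raise ValueError(f"target_connection {conn} not within region_labels")


@dataclass
class Cohort:
    """A generated cohort: subject table, ground truth, and optional series."""

    table: pd.DataFrame
    truth: pd.DataFrame  # subject x connection ground-truth coefficients
    series: dict[str, NeuralTimeSeries] = field(default_factory=dict)
    design: CohortDesign | None = None

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size)
    while np.any(out < low):
        bad = out < low
        out[bad] = rng.normal(mean, sd, bad.sum())
    return out


def generate_cohort(design: CohortDesign, seed: int | None = None, make_series: bool = True) -> Cohort:
    """Generate a two-group cohort with known ground-truth connectivity.

    Each subject receives a true coefficient on every default
    connection, drawn ``N(group mean, subject_dec_sd)``; only
    ``target_connection`` has a group-dependent mean.  Symptom scores
    are ``intercept + slope * true_coeff + noise`` for patients, clipped
    to the 0-40 instrument range (clipping is logged).  With
    ``make_series`` each subject also gets a simulated neural series
    whose constant VAR coefficients equal that subject's ground truth.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    labels = list(design.region_labels)
    n_reg = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    n_total = design.n_patients + design.n_controls

    connections = [c for c in ARBITRATION_CONNECTIONS if c[0] in idx and c[1] in idx]
    if design.target_connection not in connections:
        connections = [design.target_connection] + connections

    rows = []
    truth_rows = []
    series: dict[str, NeuralTimeSeries] = {}
    child_seeds = np.random.SeedSequence(rng.integers(0, 2**31 - 1)).spawn(n_total)
    n_clipped = 0

    for s in range(n_total):
        is_patient = s < design.n_patients
        sid = f"sub-{s:03d}"
        coeffs = {}
        for conn in connections:
            mu = design.control_dec_mean
            if conn == design.target_connection and is_patient:
                mu += design.group_dec_offset
            coeffs[conn] = float(np.clip(rng.normal(mu, design.subject_dec_sd), -0.45, 0.45))

        true_target = coeffs[design.target_connection]
        ybocs = np.nan
        if is_patient:
            raw = design.symptom_intercept + design.symptom_slope * true_target + rng.normal(
                0.0, design.symptom_noise_sd
            )
            ybocs = float(np.clip(raw, 0.0, 40.0))
            if raw != ybocs:
                n_clipped += 1
        madrs = float(np.clip(rng.normal(15.0, 9.5) if is_patient else rng.normal(1.2, 1.3), 0, 60))
        hama = float(np.clip(rng.normal(12.0, 5.5) if is_patient else rng.normal(1.5, 1.3), 0, 56))

        rows.append(
            {
                "subject_id": sid,
                "group": "patient" if is_patient else "control",
                "age": float(_truncated_normal(rng, design.age_mean, design.age_sd, 18.0, 1)[0]),
                "gender": int(rng.random() < design.gender_p_female),
                "medicated": int(is_patient and rng.random() < design.medication_fraction),
                "dvars": float(rng.lognormal(design.dvars_log_mean, design.dvars_log_sd)),
                "ybocs": ybocs,
                "madrs": madrs,
                "hama": hama,
            }
        )
        truth_rows.append({"subject_id": sid, **{f"{a}->{b}": v for (a, b), v in coeffs.items()}})

        if make_series:
            A = np.eye(n_reg) * design.self_coupling
            for (src, tgt), v in coeffs.items():
                A[idx[tgt], idx[src]] = v
            spec = VarSpec(
                n_regions=n_reg,
                order=1,
                coeff_trajectories=constant_coeffs(A),
                innovation_sd=1.0,
                length=design.length,
                dt=design.tr,
                region_labels=labels,
            )
            series[sid] = generate_tv_var(spec, seed=int(child_seeds[s].generate_state(1)[0] % (2**31)))

    if n_clipped:
        logger.info("clipped %d symptom scores to the [0, 40] instrument range", n_clipped)

    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows).set_index("subject_id")
    return Cohort(table=table, truth=truth, series=series, design=design)


# ---------------------------------------------------------------------------
# NIfTI export (to exercise ROI extraction end to end)
# ---------------------------------------------------------------------------

def series_to_nifti(ts: NeuralTimeSeries, rois: RoiSet | None = None, margin_mm: float = 12.0):
    """Embed region signals as spherical blobs in a 4-D NIfTI image.

    Builds a 2 mm isotropic grid covering the seed coordinates plus a
    margin and paints each region's series into the sphere around its
    seed.  Region order must match ``rois``.
    """
    import nibabel as nib

    rois = rois or DEFAULT_ROI_SET
    if len(rois) != ts.n_regions:
        raise ValueError(f"series has {ts.n_regions} regions but ROI set has {len(rois)}")

    centers = np.array([r.center for r in rois])
    radius = max(r.radius for r in rois)
    lo = centers.min(axis=0) - margin_mm - radius
    hi = centers.max(axis=0) + margin_mm + radius
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / 2.0)) + 1 for i in range(3))
    affine = np.array(
        [
            [2.0, 0, 0, lo[0]],
            [0, 2.0, 0, lo[1]],
            [0, 0, 2.0, lo[2]],
            [0, 0, 0, 1.0],
        ]
    )

    data = np.zeros(shape + (ts.n_samples,), dtype=np.float32)
    for j, roi in enumerate(rois):
        vox = sphere_mask(affine, shape, roi.center, roi.radius)
        if len(vox) == 0:
            raise ValueError(f"ROI {roi.label!r} falls outside the synthetic grid")
        data[vox[:, 0], vox[:, 1], vox[:, 2], :] = ts.values[:, j].astype(np.float32)

    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((2.0, 2.0, 2.0, ts.dt))
    return img


def null_design(design: CohortDesign | None = None, **overrides) -> CohortDesign:
    """A copy of ``design`` with all group/symptom effects set to zero."""
    base = design or CohortDesign()
    return replace(base, group_dec_offset=0.0, symptom_slope=0.0, **overrides)
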