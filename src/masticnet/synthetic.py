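"""Synthetic cohort generation with known ground truth.

Raw subject-level MRI for this kind of study is generally unavailable, so
every downstream stage is validated against cohorts whose structure is
planted and therefore recoverable:

* ROI signals are Gaussian AR(1) processes, identically autocorrelated per
  node and colored across nodes by the symmetric square root of a target
  correlation matrix, so the sample inter-node correlation converges to the
  design and the lag-1 autocorrelation to the AR coefficient.
* Motion traces are cumulative Gaussian random walks in six rigid-body
  parameters.
* Phenotypes follow the emulated study design: an older and a younger half
  with disjoint age ranges, a within-older age-related decline in the
  behavioral score, and a linear-additive coupling between the score and
  chosen realized edge weights or degree centralities.
* The behavioral score is the masticatory performance index (MPI), the
  color change Delta-E of a color-changeable chewing gum in CIE L*a*b*
  space; :func:`compute_delta_e` implements the CIE76 form.

Everything is deterministic given the :class:`CohortSpec` seed, and a
:class:`GroundTruthRecord` stores each planted quantity for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net
from .motion import MotionTrace
from .preprocess import ROITimeSeries, LabelMap, default_preprocess

__all__ = [
    "LabColor",
    "SubjectPhenotype",
    "CohortSpec",
    "GroundTruthRecord",
    "compute_delta_e",
    "default_covariance_design",
    "generate_subject_timeseries",
    "generate_motion_trace",
    "generate_nuisance_signals",
    "render_labelled_volume",
    "generate_cohort",
]

PSD_TOL = 1e-10


@dataclass(frozen=True)
class LabColor:
    """A CIE L*a*b* color triple (dimensionless coordinates)."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("L", "a", "b"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite Lab component {name}")


def compute_delta_e(before: LabColor, after: LabColor) -> float:
    """CIE76 color difference: Euclidean distance in L*a*b* space.

    This is the simplest Delta-E formula; perceptually weighted variants
    (CIE94, CIEDE2000) are intentionally not implemented.
    """
    return math.sqrt(
        (after.L - before.L) ** 2
        + (after.a - before.a) ** 2
        + (after.b - before.b) ** 2
    )


@dataclass(frozen=True)
class SubjectPhenotype:
    subject_id: str
    age: float
    gender: str
    group: str
    mpi: float

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not math.isfinite(self.mpi):
            raise ValueError("mpi must be finite")
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        if self.group not in ("older", "younger", "unassigned"):
            raise ValueError(f"unknown group {self.group!r}")


def default_covariance_design(node_labels=None) -> np.ndarray:
    """Block-structured target correlation over the default 24 nodes.

    Qualitative blocks: a sensorimotor block (M1, PMC, S1, S2), a cerebellar
    block (CAnt, CPost67, CPost8), cortico-cerebellar cross-links, a weaker
    subcortical pair, elevated bilateral-homologue correlations, and a low
    baseline everywhere else.  The numeric values are free parameters of the
    generator, chosen to be positive semidefinite and broadly brain-like.
    """
    labels = tuple(node_labels) if node_labels is not None else net.default_node_labels()
    n = len(labels)
    roi = [lab.rsplit("_", 1)[0] for lab in labels]
    sm = {"M1", "PMC", "S1", "S2"}
    cb = {"CAnt", "CPost67", "CPost8"}
    sub = {"CaN", "THA"}
    c = np.full((n, n), 0.10)
    for i in range(n):
        for j in range(n):
            ri, rj = roi[i], roi[j]
            if ri in sm and rj in sm:
                c[i, j] = 0.45
            elif ri in cb and rj in cb:
                c[i, j] = 0.45
            elif (ri in sm and rj in cb) or (ri in cb and rj in sm):
                c[i, j] = 0.25
            elif ri in sub and rj in sub:
                c[i, j] = 0.30
            if ri == rj:
                c[i, j] = max(c[i, j], 0.60)  # bilateral homologues
    np.fill_diagonal(c, 1.0)
    return c


def _check_psd(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n) or not np.allclose(cov, cov.T):
        raise ValueError("covariance_design must be square and symmetric")
    if not np.allclose(np.diag(cov), 1.0):
        raise ValueError("covariance_design must have unit diagonal")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] < -PSD_TOL:
        raise ValueError(
            f"covariance_design is not positive semidefinite: smallest "
            f"eigenvalue {eigvals[0]:.3e} < -{PSD_TOL}"
        )
    return cov


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults emulate the acquisition and study design being reproduced:
    183 volumes at TR = 2 s over 24 nodes; an even older/younger split with
    ages 55-74 vs 23-54 years; an MPI baseline near the printed cohort mean
    with a within-older age decline of about -0.32 Delta-E units per year;
    and a planted positive coupling between MPI and the degree centrality of
    the left anterior cerebellum and right posterior (lobule VIII)
    cerebellum nodes.
    """

    n_subjects: int
    seed: int
    n_timepoints: int = 183
    sampling_interval_s: float = 2.0
    n_nodes: int = 24
    node_labels: tuple[str, ...] = field(default_factory=net.default_node_labels)
    covariance_design: np.ndarray = None  # default built in __post_init__
    ar_coefficient: float = 0.85
    coupling_plan: tuple = (("CAnt_L", 0.8), ("CPost8_R", 0.8))
    behavior_noise_sd: float = 2.0
    mpi_intercept: float = 73.3
    age_range_by_group: tuple = ((55.0, 74.0), (23.0, 54.0))
    age_mpi_slope_older: float = -0.32
    p_male: float = 19.0 / 52.0
    motion_step_sd_mm: float = 0.02
    motion_step_sd_deg: float = 0.015
    n_discard: int = 3
    low_hz: float = 0.01
    high_hz: float = 0.08

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 10 or self.n_nodes < 2:
            raise ValueError("n_subjects >= 1, n_timepoints >= 10, n_nodes >= 2 required")
        labels = tuple(self.node_labels)
        if len(labels) != self.n_nodes or len(set(labels)) != self.n_nodes:
            raise ValueError("node_labels must be n_nodes distinct strings")
        object.__setattr__(self, "node_labels", labels)
        cov = self.covariance_design
        if cov is None:
            cov = default_covariance_design(labels)
        cov = _check_psd(cov)
        if cov.shape[0] != self.n_nodes:
            raise ValueError("covariance_design size must match n_nodes")
        cov = cov.copy(); cov.setflags(write=False)
        object.__setattr__(self, "covariance_design", cov)
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must lie in [0, 1) for stationarity")
        if self.behavior_noise_sd < 0:
            raise ValueError("behavior_noise_sd must be nonnegative")
        if not 0.0 <= self.p_male <= 1.0:
            raise ValueError("p_male must lie in [0, 1]")
        plan = []
        for target, coef in self.coupling_plan:
            plan.append((self._normalize_target(target), float(coef)))
        object.__setattr__(self, "coupling_plan", tuple(plan))

    def _normalize_target(self, target):
        """Node targets are labels; edge targets are (label_i, label_j), i < j."""
        if isinstance(target, str) and "--" in target:
            target = tuple(target.split("--"))
        if isinstance(target, str):
            if target not in self.node_labels:
                raise ValueError(f"coupling target {target!r} is not a node label")
            return target
        a, b = target
        for lab in (a, b):
            if lab not in self.node_labels:
                raise ValueError(f"coupling edge endpoint {lab!r} is not a node label")
        if a == b:
            raise ValueError("coupling edge endpoints must differ")
        ia, ib = self.node_labels.index(a), self.node_labels.index(b)
        return (a, b) if ia < ib else (b, a)


@dataclass(frozen=True)
class GroundTruthRecord:
    """Everything planted in a generated cohort, for recovery tests."""

    seed: int
    mpi_intercept: float
    coupling_plan: tuple
    age_mpi_slope_older: float
    behavior_noise_sd: float
    feature_values: pd.DataFrame  # subjects x coupling targets (realized)
    feature_means: dict[str, float]  # cohort means subtracted before coupling
    covariance_design: np.ndarray
    preprocess_params: dict
    subject_seeds: dict[str, int]


def _sqrt_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def generate_subject_timeseries(
    covariance_design: np.ndarray,
    n_timepoints: int,
    ar_coefficient: float,
    sampling_interval_s: float,
    seed: int,
    node_labels=None,
) -> ROITimeSeries:
    """One subject's ROI signals: AR(1) innovations colored by the design.

    Each node is a stationary unit-variance AR(1) process; applying the
    symmetric square root of the target correlation across nodes makes the
    inter-node sample correlation converge to the design while leaving the
    per-node lag-1 autocorrelation at the AR coefficient.
    """
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be at least 10")
    if not (0.0 <= ar_coefficient < 1.0):
        raise ValueError(
            f"ar_coefficient must lie in [0, 1) for a stationary process, "
            f"got {ar_coefficient}"
        )
    cov = _check_psd(covariance_design)
    n_nodes = cov.shape[0]
    labels = (
        tuple(node_labels)
        if node_labels is not None
        else tuple(f"node{k:02d}" for k in range(n_nodes))
    )
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_timepoints, n_nodes))
    u = np.empty_like(eps)
    u[0] = eps[0]  # stationary start: unit marginal variance
    scale = math.sqrt(1.0 - ar_coefficient**2)
    for t in range(1, n_timepoints):
        u[t] = ar_coefficient * u[t - 1] + scale * eps[t]
    data = u @ _sqrt_psd(cov)
    return ROITimeSeries(
        data=data,
        node_labels=labels,
        sampling_interval_s=sampling_interval_s,
        stage="raw",
    )


def generate_motion_trace(
    n_timepoints: int,
    step_sd_mm: float,
    step_sd_deg: float,
    seed: int,
) -> MotionTrace:
    """Cumulative Gaussian random walk starting at zero in all six parameters."""
    if step_sd_mm < 0 or step_sd_deg < 0:
        raise ValueError("step standard deviations must be nonnegative")
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = np.random.default_rng(seed)
    steps = np.column_stack(
        [
            rng.normal(0.0, step_sd_mm, size=(n_timepoints - 1, 3)),
            rng.normal(0.0, step_sd_deg, size=(n_timepoints - 1, 3)),
        ]
    )
    data = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return MotionTrace(data=data)


def generate_nuisance_signals(n_timepoints: int, seed: int, ar: float = 0.9) -> pd.DataFrame:
    """Stand-in ventricle and deep-white-matter mean signals (unit-variance AR(1))."""
    rng = np.random.default_rng(seed)
    out = {}
    scale = math.sqrt(1.0 - ar * ar)
    for name in ("ventricle", "white_matter"):
        eps = rng.standard_normal(n_timepoints)
        x = np.empty(n_timepoints)
        x[0] = eps[0]
        for t in range(1, n_timepoints):
            x[t] = ar * x[t - 1] + scale * eps[t]
        out[name] = x
    return pd.DataFrame(out)


def render_labelled_volume(
    roi_ts: ROITimeSeries,
    grid_shape: tuple[int, int, int],
    voxels_per_roi: int,
    voxel_noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, LabelMap]:
    """Paint each node's signal into a block of voxels on a 3-D grid.

    Voxel ``k``-labelled signals equal node-``k`` signal plus independent
    Gaussian noise; label 0 marks background.  With zero noise, region-mean
    extraction reproduces the input series exactly.
    """
    if voxels_per_roi < 1:
        raise ValueError("voxels_per_roi must be at least 1")
    n_vox = int(np.prod(grid_shape))
    needed = roi_ts.n_nodes * voxels_per_roi
    if n_vox < needed:
        raise ValueError(
            f"grid of {n_vox} voxels too small: need at least {needed} "
            f"({roi_ts.n_nodes} ROIs x {voxels_per_roi} voxels)"
        )
    rng = np.random.default_rng(seed)
    labels_flat = np.zeros(n_vox, dtype=np.int32)
    volume_flat = np.zeros((n_vox, roi_ts.n_timepoints))
    for k in range(roi_ts.n_nodes):
        sl = slice(k * voxels_per_roi, (k + 1) * voxels_per_roi)
        labels_flat[sl] = k + 1
        noise = (
            rng.normal(0.0, voxel_noise_sd, size=(voxels_per_roi, roi_ts.n_timepoints))
            if voxel_noise_sd > 0
            else 0.0
        )
        volume_flat[sl, :] = roi_ts.data[:, k][None, :] + noise
    label_map = LabelMap(
        grid=labels_flat.reshape(grid_shape),
        label_names={k + 1: roi_ts.node_labels[k] for k in range(roi_ts.n_nodes)},
    )
    return volume_flat.reshape(grid_shape + (roi_ts.n_timepoints,)), label_map


def _realized_features(spec: CohortSpec, series: ROITimeSeries) -> dict[str, float]:
    """Coupling features measured the way the analysis pipeline measures them."""
    prep = default_preprocess(
        series,
        n_discard=spec.n_discard,
        low_hz=spec.low_hz,
        high_hz=min(spec.high_hz, series.nyquist_hz),
    )
    cm = net.compute_connectivity(prep, clip=True)
    dc = net.degree_centrality(cm)
    feats = {}
    for target, _ in spec.coupling_plan:
        if isinstance(target, str):
            feats[target] = float(dc.dc[spec.node_labels.index(target)])
        else:
            i, j = (spec.node_labels.index(t) for t in target)
            feats["--".join(target)] = float(cm.weight[i, j])
    return feats


def _target_key(target) -> str:
    return target if isinstance(target, str) else "--".join(target)


def generate_cohort(spec: CohortSpec):
    """Generate a full cohort: phenotypes, time series, motion, ground truth.

    Returns
    -------
    ``(phenotypes, series_by_subject, motion_by_subject, ground_truth)``
    where phenotypes is a list of :class:`SubjectPhenotype` and the maps are
    keyed by subject id.  Bit-identical for a fixed spec (including seed).

    The behavioral score is
    ``mpi = intercept + sum_c coef_c (feature_c - cohort mean)``
    ``+ slope_older (age - older_min)  [older half only]  + N(0, noise_sd)``;
    centering the realized features keeps the intercept interpretable as the
    cohort baseline regardless of the coupling plan.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects + 1)
    pheno_rng = np.random.default_rng(children[0])

    n_older = spec.n_subjects // 2
    series_by_subject: dict[str, ROITimeSeries] = {}
    motion_by_subject: dict[str, MotionTrace] = {}
    subject_seeds: dict[str, int] = {}
    raw_phenos = []
    features_rows = []

    for i in range(spec.n_subjects):
        sid = f"sub-{i + 1:03d}"
        group = "older" if i < n_older else "younger"
        lo, hi = spec.age_range_by_group[0 if group == "older" else 1]
        age = float(pheno_rng.uniform(lo, hi))
        gender = "M" if pheno_rng.random() < spec.p_male else "F"
        sub_seed = int(children[i + 1].generate_state(1)[0] % (2**31))
        subject_seeds[sid] = sub_seed
        series = generate_subject_timeseries(
            spec.covariance_design,
            spec.n_timepoints,
            spec.ar_coefficient,
            spec.sampling_interval_s,
            seed=sub_seed,
            node_labels=spec.node_labels,
        )
        motion = generate_motion_trace(
            spec.n_timepoints,
            spec.motion_step_sd_mm,
            spec.motion_step_sd_deg,
            seed=sub_seed + 1,
        )
        series_by_subject[sid] = series
        motion_by_subject[sid] = motion
        feats = _realized_features(spec, series) if spec.coupling_plan else {}
        features_rows.append(feats)
        raw_phenos.append((sid, age, gender, group))

    feature_df = pd.DataFrame(
        features_rows, index=[sid for sid, *_ in raw_phenos]
    )
    feature_means = {c: float(feature_df[c].mean()) for c in feature_df.columns}

    older_min = spec.age_range_by_group[0][0]
    phenotypes = []
    noise = pheno_rng.normal(0.0, spec.behavior_noise_sd, size=spec.n_subjects) \
        if spec.behavior_noise_sd > 0 else np.zeros(spec.n_subjects)
    for idx, (sid, age, gender, group) in enumerate(raw_phenos):
        mpi = spec.mpi_intercept
        for target, coef in spec.coupling_plan:
            key = _target_key(target)
            mpi += coef * (feature_df.loc[sid, key] - feature_means[key])
        if group == "older":
            mpi += spec.age_mpi_slope_older * (age - older_min)
        mpi += noise[idx]
        phenotypes.append(
            SubjectPhenotype(subject_id=sid, age=age, gender=gender, group=group, mpi=float(mpi))
        )

    ground_truth = GroundTruthRecord(
        seed=spec.seed,
        mpi_intercept=spec.mpi_intercept,
        coupling_plan=spec.coupling_plan,
        age_mpi_slope_older=spec.age_mpi_slope_older,
        behavior_noise_sd=spec.behavior_noise_sd,
        feature_values=feature_df,
        feature_means=feature_means,
        covariance_design=np.asarray(spec.covariance_design),
        preprocess_params={
            "n_discard": spec.n_discard,
            "low_hz": spec.low_hz,
            "high_hz": spec.high_hz,
        },
        subject_seeds=subject_seeds,
    )
    return phenotypes, series_by_subject, motion_by_subject, ground_truth
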