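"""Time-series preprocessing for resting-state ROI signals.

The preprocessing chain mirrors a standard resting-state functional-MRI
pipeline operating on regional mean time series:

1. discard the first few volumes (magnetic-saturation transient),
2. remove a linear trend from each node signal,
3. bandpass filter to the low-frequency band (default 0.01-0.08 Hz),
4. regress out nuisance signals (six rigid-body motion parameters and,
   optionally, ventricle / deep-white-matter mean signals).

The chain order is enforced: each :class:`ROITimeSeries` carries a ``stage``
tag and every operation checks that its input is at an admissible stage.
Spatial registration (slice timing, realignment, template normalisation) is
out of scope -- motion parameters are consumed as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ROITimeSeries",
    "LabelMap",
    "NuisanceSet",
    "PipelineOrderError",
    "discard_initial_volumes",
    "linear_detrend",
    "bandpass_filter",
    "nuisance_regress",
    "extract_roi_timeseries",
    "threshold_probabilistic_map",
    "default_preprocess",
]

#: processing stages in mandatory order
STAGES = ("raw", "discarded", "detrended", "filtered", "residualized")


class PipelineOrderError(RuntimeError):
    """Raised when a preprocessing step is applied out of order."""


@dataclass(frozen=True)
class ROITimeSeries:
    """A timepoints x nodes matrix of regional mean signals.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_timepoints, n_nodes)``; must be finite.
    node_labels
        Distinct node names, one per column.
    sampling_interval_s
        Repetition time (TR) in seconds.
    stage
        Which preprocessing stage produced this series (see ``STAGES``).
    """

    data: np.ndarray
    node_labels: tuple[str, ...]
    sampling_interval_s: float
    stage: str = "raw"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (timepoints x nodes), got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("at least 2 timepoints required")
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite values in time series")
        labels = tuple(str(x) for x in self.node_labels)
        if len(labels) != data.shape[1]:
            raise ValueError(
                f"{len(labels)} node labels for {data.shape[1]} columns"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be distinct")
        if not (self.sampling_interval_s > 0):
            raise ValueError("sampling_interval_s must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        data = data.copy()
        data.setflags(write=False)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.sampling_interval_s)


@dataclass(frozen=True)
class LabelMap:
    """Integer 3-D parcellation; label 0 is background."""

    grid: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError("label grid must be 3-D")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError("label grid must be integer-valued")
        present = set(np.unique(grid).tolist()) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels present in grid but unnamed: {sorted(missing)}")
        grid = grid.copy()
        grid.setflags(write=False)
        object.__setattr__(self, "grid", grid)

    @property
    def labels(self) -> list[int]:
        """Sorted nonzero labels present in the grid."""
        return sorted(set(np.unique(self.grid).tolist()) - {0})


@dataclass(frozen=True)
class NuisanceSet:
    """Confound regressors aligned with a time series.

    Typically the six rigid-body motion parameters plus the lateral-ventricle
    and deep-white-matter mean signals.  The whole-brain global signal is
    deliberately not part of the default set.
    """

    regressors: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        reg = np.asarray(self.regressors, dtype=float)
        if reg.ndim != 2 or reg.shape[1] < 1:
            raise ValueError("regressors must be a timepoints x k matrix with k >= 1")
        if not np.all(np.isfinite(reg)):
            raise ValueError("non-finite nuisance regressor values")
        names = tuple(str(n) for n in self.names)
        if len(names) != reg.shape[1]:
            raise ValueError(f"{len(names)} names for {reg.shape[1]} regressors")
        reg = reg.copy()
        reg.setflags(write=False)
        object.__setattr__(self, "regressors", reg)
        object.__setattr__(self, "names", names)

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]


def _require_stage(series: ROITimeSeries, allowed: tuple[str, ...], op: str) -> None:
    if series.stage not in allowed:
        raise PipelineOrderError(
            f"{op} expects a series at stage {allowed}, got {series.stage!r}; "
            f"the chain order is {' -> '.join(STAGES[1:])}"
        )


def discard_initial_volumes(series: ROITimeSeries, n_discard: int) -> ROITimeSeries:
    """Drop the first ``n_discard`` timepoints (saturation transient)."""
    _require_stage(series, ("raw",), "discard_initial_volumes")
    n_discard = int(n_discard)
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= series.n_timepoints - 1:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_timepoints} timepoints "
            "(fewer than 2 would remain)"
        )
    return replace(series, data=series.data[n_discard:], stage="discarded")


def linear_detrend(series: ROITimeSeries) -> ROITimeSeries:
    """Remove the least-squares straight line from every node signal.

    The output has exactly zero linear trend and zero mean per column.
    """
    _require_stage(series, ("raw", "discarded"), "linear_detrend")
    if series.n_timepoints < 3:
        raise ValueError("linear detrend needs at least 3 timepoints")
    t = np.arange(series.n_timepoints, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    return replace(series, data=series.data - design @ coef, stage="detrended")


def bandpass_filter(
    series: ROITimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> ROITimeSeries:
    """Ideal rectangular bandpass in the discrete Fourier domain.

    Fourier coefficients with frequency in the closed band
    ``[low_hz, high_hz]`` are kept, all others (including DC) zeroed, and the
    inverse transform returned.  The filter is exactly idempotent.
    """
    _require_stage(series, ("detrended", "filtered"), "bandpass_filter")
    if not (0.0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz > series.nyquist_hz + 1e-12:
        raise ValueError(
            f"high_hz={high_hz} exceeds the Nyquist frequency "
            f"{series.nyquist_hz} at TR={series.sampling_interval_s}s"
        )
    n = series.n_timepoints
    freqs = np.fft.rfftfreq(n, d=series.sampling_interval_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(series.data, axis=0)
    spec[~keep, :] = 0.0
    out = np.fft.irfft(spec, n=n, axis=0)
    return replace(series, data=out, stage="filtered")


def nuisance_regress(series: ROITimeSeries, nuisance: NuisanceSet) -> ROITimeSeries:
    """OLS residualisation of every node signal on [intercept | regressors].

    Residuals are orthogonal to every regressor and have zero mean.  The
    global signal is never added implicitly.
    """
    _require_stage(series, ("filtered",), "nuisance_regress")
    if nuisance.n_timepoints != series.n_timepoints:
        raise ValueError(
            f"nuisance has {nuisance.n_timepoints} timepoints, "
            f"series has {series.n_timepoints}"
        )
    design = np.column_stack(
        [np.ones(series.n_timepoints), nuisance.regressors]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the first regressor that adds no rank
        names = ("intercept",) + nuisance.names
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) < j + 1:
                raise ValueError(
                    f"rank-deficient nuisance design: column {names[j]!r} is "
                    "linearly dependent on the preceding columns"
                )
        raise ValueError("rank-deficient nuisance design")
    coef, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    return replace(series, data=series.data - design @ coef, stage="residualized")


def extract_roi_timeseries(
    volume: np.ndarray,
    labels: LabelMap,
    sampling_interval_s: float = 2.0,
) -> ROITimeSeries:
    """Mean signal over each labelled region at every timepoint.

    ``volume`` is a 4-D array ``(x, y, z, t)``.  Columns are ordered by
    sorted label integer and named via the label map.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, t)")
    if volume.shape[:3] != labels.grid.shape:
        raise ValueError(
            f"spatial shape mismatch: volume {volume.shape[:3]} vs "
            f"label map {labels.grid.shape}"
        )
    lab_ints = sorted(labels.label_names)
    columns = []
    names = []
    for k in lab_ints:
        mask = labels.grid == k
        if not mask.any():
            raise ValueError(f"label {k} ({labels.label_names[k]!r}) has zero voxels")
        columns.append(volume[mask, :].mean(axis=0))
        names.append(labels.label_names[k])
    return ROITimeSeries(
        data=np.column_stack(columns),
        node_labels=tuple(names),
        sampling_interval_s=sampling_interval_s,
        stage="raw",
    )


def threshold_probabilistic_map(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary ROI mask: voxel included iff probability >= threshold."""
    prob = np.asarray(prob, dtype=float)
    if not np.all(np.isfinite(prob)):
        raise ValueError("non-finite probabilities")
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError(
            f"probabilities must lie in [0, 1]; range is "
            f"[{prob.min():.3g}, {prob.max():.3g}]"
        )
    return prob >= threshold


def default_preprocess(
    series: ROITimeSeries,
    nuisance: NuisanceSet | None = None,
    n_discard: int = 3,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> ROITimeSeries:
    """Run the full chain discard -> detrend -> bandpass [-> nuisance].

    ``nuisance`` regressors, when given, must already be trimmed to the
    post-discard length; they are used as supplied (not re-filtered).
    """
    out = discard_initial_volumes(series, n_discard)
    out = linear_detrend(out)
    out = bandpass_filter(out, low_hz=low_hz, high_hz=high_hz)
    if nuisance is not None:
        out = nuisance_regress(out, nuisance)
    return out
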