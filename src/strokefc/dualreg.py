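"""Two-stage dual regression and the frame-to-frame head-motion metric.

Stage 1 regresses a set of group spatial maps (optionally augmented with a
binary lesion mask) into each frame of a subject's 4D dataset, yielding one
time series per map. Stage 2 regresses those time series back into the
dataset, yielding subject-specific spatial maps. The lesion time series is
estimated jointly with the node time series — so shared variance is
assigned to the lesion — and then discarded before network modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SpatialRegressorSet:
    """Group maps plus an optional lesion column (appended as column K+1)."""

    maps: np.ndarray                      # V x K
    lesion_column: np.ndarray | None = None

    def design(self) -> np.ndarray:
        X = np.asarray(self.maps, dtype=float)
        if self.lesion_column is not None:
            lc = np.asarray(self.lesion_column, dtype=float).reshape(-1, 1)
            if lc.shape[0] != X.shape[0]:
                raise ValueError("lesion column length does not match maps")
            X = np.hstack([X, lc])
        return X


@dataclass
class SubjectDualRegOutput:
    timeseries: np.ndarray                 # T x K, lesion removed
    lesion_timeseries: np.ndarray | None   # T-vector if a lesion regressor was used
    subject_maps: np.ndarray | None = None


def _demean(X: np.ndarray, axis: int = 0) -> np.ndarray:
    return X - X.mean(axis=axis, keepdims=True)


def _check_full_rank(X: np.ndarray, what: str) -> None:
    # name near-collinear columns via the R factor of a QR decomposition
    R = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(R))
    scale = d.max() if d.max() > 0 else 1.0
    bad = np.where(d < 1e-10 * scale)[0]
    if bad.size:
        raise ValueError(f"{what} design is rank deficient; collinear columns: {bad.tolist()}")


def stage1_spatial_regression(
    volume: np.ndarray,
    regressors: SpatialRegressorSet | np.ndarray,
    variance_normalize: bool = False,
) -> np.ndarray:
    """Spatial multiple regression of each frame on the (demeaned) maps.

    Returns the T×(K or K+1) matrix of per-frame OLS coefficients — the
    subject-specific time series, one per spatial regressor.
    """
    if not isinstance(regressors, SpatialRegressorSet):
        regressors = SpatialRegressorSet(np.asarray(regressors))
    X = regressors.design()
    V, p = X.shape
    volume = np.asarray(volume, dtype=float)
    if volume.shape[0] != V:
        raise ValueError("volume and regressors disagree on voxel count")
    if V <= p:
        raise ValueError("need more voxels than spatial regressors")
    Xd = _demean(X, axis=0)
    if variance_normalize:
        sd = Xd.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot variance-normalize a constant spatial regressor")
        Xd = Xd / sd
    _check_full_rank(Xd, "stage-1 spatial")
    Y = _demean(volume, axis=0)
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)   # p x T
    return beta.T


def stage2_temporal_regression(volume: np.ndarray, timeseries: np.ndarray) -> np.ndarray:
    """Temporal multiple regression of each voxel on the (demeaned) time series.

    Returns V×K subject-specific spatial maps (per-voxel OLS coefficients).
    """
    volume = np.asarray(volume, dtype=float)
    ts = np.asarray(timeseries, dtype=float)
    V, T = volume.shape
    if ts.shape[0] != T:
        raise ValueError("volume and time series disagree on frame count")
    if T <= ts.shape[1]:
        raise ValueError("need more frames than temporal regressors")
    Xd = _demean(ts, axis=0)
    _check_full_rank(Xd, "stage-2 temporal")
    Y = _demean(volume.T, axis=0)          # T x V
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)  # K x V
    return beta.T


def drop_lesion_component(
    timeseries: np.ndarray,
    lesion_present: bool,
    n_components: int | None = None,
) -> SubjectDualRegOutput:
    """Separate and store the lesion time series (last column) if present."""
    ts = np.asarray(timeseries, dtype=float)
    if lesion_present:
        if ts.shape[1] < 2:
            raise ValueError("lesion flagged but fewer than 2 columns present")
        if n_components is not None and ts.shape[1] != n_components + 1:
            raise ValueError(
                f"expected {n_components}+1 columns with a lesion regressor, got {ts.shape[1]}"
            )
        return SubjectDualRegOutput(timeseries=ts[:, :-1], lesion_timeseries=ts[:, -1])
    if n_components is not None and ts.shape[1] != n_components:
        raise ValueError(f"expected {n_components} columns, got {ts.shape[1]}")
    return SubjectDualRegOutput(timeseries=ts, lesion_timeseries=None)


def dual_regress(
    volume: np.ndarray,
    maps: np.ndarray,
    lesion_mask: np.ndarray | None = None,
) -> SubjectDualRegOutput:
    """Full per-subject dual regression with optional lesion regressor."""
    regs = SpatialRegressorSet(np.asarray(maps), lesion_mask)
    ts_all = stage1_spatial_regression(volume, regs)
    out = drop_lesion_component(ts_all, lesion_mask is not None, n_components=np.asarray(maps).shape[1])
    out.subject_maps = stage2_temporal_regression(volume, ts_all)[:, : np.asarray(maps).shape[1]]
    return out


def regress_confounds(timeseries: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize node time series on a confound matrix (e.g. a T×6 motion trace)."""
    ts = _demean(np.asarray(timeseries, dtype=float))
    C = _demean(np.asarray(confounds, dtype=float))
    if C.shape[0] != ts.shape[0]:
        raise ValueError("confounds and time series disagree on frame count")
    beta, *_ = np.linalg.lstsq(C, ts, rcond=None)
    return ts - C @ beta


# ---------------------------------------------------------------------------
# Head motion


def _euler_to_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation applied in x, y, z order (extrinsic): R = Rz @ Ry @ Rx."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def mean_relative_rms(trace: np.ndarray, sphere_radius: float = 80.0) -> float:
    """Average frame-to-frame RMS displacement of a radius-R sphere.

    ``trace`` is F×6: three translations (mm) then three rotations
    (radians). For each consecutive frame pair the RMS displacement over
    a sphere of radius R centred at the rotation centre is
    sqrt(R²/5 · tr(MᵀM) + tᵀt) with M the difference of the two rotation
    matrices and t the difference of the two translations; the mean over
    the F−1 pairs is returned.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must be F x 6")
    F = trace.shape[0]
    if F < 2:
        raise ValueError("need at least 2 frames for a relative motion metric")
    t = trace[:, :3]
    rots = [_euler_to_matrix(*row) for row in trace[:, 3:]]
    vals = np.empty(F - 1)
    for k in range(F - 1):
        M = rots[k + 1] - rots[k]
        dt = t[k + 1] - t[k]
        vals[k] = np.sqrt(sphere_radius**2 / 5.0 * np.trace(M.T @ M) + dt @ dt)
    return float(vals.mean())
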