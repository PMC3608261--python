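"""ODF maxima extraction and angular-error statistics.

Local maxima of a reconstructed profile are found on an icosahedral mesh by
one-ring comparison, merged over antipodes (even-order SH profiles are
exactly antipodally symmetric, so every maximum appears as a +/- pair), and
thresholded on min-max-normalized amplitude.  Detected peaks are matched to
the simulated (true) fiber axes by greedy nearest assignment under the
antipodal angular metric arccos|<u, v>|; a realization is a *success* when
both true axes receive distinct peaks.  Over noise realizations the summary
statistics are the mean angular error mu and its standard deviation s over
successful realizations, plus the detection-success fraction p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere_math import SphereMesh

__all__ = [
    "PeakSet",
    "MatchResult",
    "TrialResult",
    "find_maxima",
    "angular_error",
    "summarize_realizations",
    "min_max_normalize",
]

#: Icosahedron-face circumradius in degrees; the nearest-vertex distance of
#: an order-k subdivision is bounded by roughly this value / 2^k.
_ORDER0_MAX_DIST_DEG = 37.3774


def mesh_resolution_deg(order: int) -> float:
    """Approximate maximum nearest-vertex distance at a subdivision order."""
    return _ORDER0_MAX_DIST_DEG / 2.0**order


def min_max_normalize(values) -> np.ndarray:
    """Affine rescaling of vertex values to [0, 1]."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("constant profile: min-max normalization is degenerate")
    return (v - lo) / (hi - lo)


@dataclass
class PeakSet:
    """Antipodally merged local maxima, sorted by amplitude (descending)."""

    directions: np.ndarray  # (k, 3)
    amplitudes: np.ndarray  # raw profile values
    rel_threshold: float
    mesh_order: int
    degenerate: bool = False

    def __len__(self) -> int:
        return self.directions.shape[0]

    def save_csv(self, path) -> None:
        """Write peaks as CSV rows (x, y, z, amplitude)."""
        with open(path, "w") as fh:
            fh.write("x,y,z,amplitude\n")
            for d, a in zip(self.directions, self.amplitudes):
                fh.write(f"{d[0]:.17g},{d[1]:.17g},{d[2]:.17g},{a:.17g}\n")


def find_maxima(
    values,
    mesh: SphereMesh,
    rel_threshold: float = 0.5,
) -> PeakSet:
    """Thresholded, antipodally merged local maxima of a profile on a mesh.

    A vertex is a candidate when its value is >= all one-ring neighbors.
    Candidates whose min-max-normalized amplitude falls below
    ``rel_threshold`` are discarded; each +/- antipodal pair keeps a single
    representative (the higher-amplitude one, ties to the lower vertex
    index).  A constant profile yields an empty, degenerate PeakSet.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (mesh.n_vertices,):
        raise ValueError("values must provide one scalar per mesh vertex")
    if not np.all(np.isfinite(v)):
        raise ValueError("profile values must be finite")
    if not (0.0 <= rel_threshold < 1.0):
        raise ValueError("rel_threshold must be in [0, 1)")
    if v.max() == v.min():
        return PeakSet(
            directions=np.empty((0, 3)),
            amplitudes=np.empty(0),
            rel_threshold=rel_threshold,
            mesh_order=mesh.order,
            degenerate=True,
        )
    nbr = mesh.neighbors
    padded = np.where(nbr >= 0, v[np.where(nbr >= 0, nbr, 0)], -np.inf)
    is_max = np.all(v[:, None] >= padded, axis=1)
    cand = np.flatnonzero(is_max)
    norm = (v[cand] - v.min()) / (v.max() - v.min())
    cand = cand[norm >= rel_threshold]
    # sort by amplitude desc, index asc for deterministic ties
    order = np.lexsort((cand, -v[cand]))
    cand = cand[order]
    merge_cos = np.cos(np.radians(2.5 * mesh_resolution_deg(mesh.order)))
    kept_dirs: list[np.ndarray] = []
    kept_amp: list[float] = []
    for idx in cand:
        u = mesh.vertices[idx]
        if any(abs(u @ k) >= merge_cos for k in kept_dirs):
            continue  # same (or antipodal) peak already kept
        kept_dirs.append(u)
        kept_amp.append(float(v[idx]))
    return PeakSet(
        directions=np.array(kept_dirs).reshape(-1, 3),
        amplitudes=np.array(kept_amp),
        rel_threshold=rel_threshold,
        mesh_order=mesh.order,
    )


@dataclass
class MatchResult:
    """Outcome of matching detected peaks against two true axes."""

    error_deg: float  # mean over the two assignments; NaN on failure
    success: bool
    n_extra_peaks: int = 0  # spurious peaks beyond the assigned ones

    def __iter__(self):
        # tuple-style unpacking: error, success
        yield self.error_deg
        yield self.success


def _antipodal_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(abs(u @ v), 0.0, 1.0))))


def angular_error(true_axes, peaks: PeakSet) -> MatchResult:
    """Greedy assignment of detected peaks to two true fiber axes.

    Success requires at least two retained peaks and a distinct peak per
    axis; the reported error is the mean of the two assignment angles under
    the antipodal metric.  Extra peaks are counted but do not fail the
    trial.  Assignment is greedy on smallest angle; ties go to the
    higher-amplitude peak.
    """
    axes = np.asarray(true_axes, dtype=float)
    if axes.shape != (2, 3):
        raise ValueError("exactly two true axes are required")
    axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    if abs(axes[0] @ axes[1]) > 1.0 - 1e-12:
        raise ValueError("true axes must be non-collinear")
    if len(peaks) < 2:
        return MatchResult(error_deg=float("nan"), success=False)
    ang = np.array(
        [[_antipodal_angle_deg(a, p) for p in peaks.directions] for a in axes]
    )
    free_axes = {0, 1}
    free_peaks = set(range(len(peaks)))
    errors = []
    while free_axes:
        # greedy: globally smallest remaining angle; ties favor the
        # higher-amplitude peak (peaks are amplitude-sorted, so lower j)
        _, i, j = min(
            ((ang[i, j], j), i, j) for i in free_axes for j in free_peaks
        )
        errors.append(ang[i, j])
        free_axes.remove(i)
        free_peaks.remove(j)
    return MatchResult(
        error_deg=float(np.mean(errors)),
        success=True,
        n_extra_peaks=len(peaks) - 2,
    )


@dataclass
class TrialResult:
    """Angular-error summary over noise realizations."""

    mean_error_deg: float  # mu, over successful realizations (NaN if none)
    std_error_deg: float  # s, sample std over successes
    success_fraction: float  # p
    n_realizations: int
    errors_deg: np.ndarray = field(default_factory=lambda: np.empty(0))


def summarize_realizations(results: list[MatchResult]) -> TrialResult:
    """Aggregate per-realization matches into (mu, s, p)."""
    if not results:
        raise ValueError("need at least one realization")
    succ = np.array([r.error_deg for r in results if r.success])
    p = succ.size / len(results)
    if succ.size == 0:
        return TrialResult(float("nan"), float("nan"), 0.0, len(results))
    if succ.size > 1 and np.ptp(succ) > 0:
        s = float(succ.std(ddof=1))
    else:
        s = 0.0  # exact repetitions (noiseless reruns) give s = 0 exactly
    return TrialResult(
        mean_error_deg=float(succ.mean()),
        std_error_deg=s,
        success_fraction=p,
        n_realizations=len(results),
        errors_deg=succ,
    )
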