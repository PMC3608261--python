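"""Protocol sweeps, optimal-parameter selection, and SNR estimation.

``run_sweep`` executes the full factorial study over crossing angle,
b-value, gradient count, SH order and SNR: simulate a two-cylinder phantom
on a static-repulsion scheme, corrupt with Rician-magnitude noise, apply
the chosen reconstruction, extract mesh maxima, and summarize the angular
error over noise realizations into one tidy row per cell (mu, s, p).

Seeding is counter-based: every cell derives an independent stream from the
master seed via ``numpy.random.SeedSequence(master_seed, spawn_key=...)``,
so a single rerun cell reproduces its value inside the full sweep.
Gradient schemes depend only on (master seed, NG): the same direction table
serves every cell of a sweep, as a fixed acquisition table would.

``select_optimal`` applies the smallest-b selection rule: among successful
cells whose mean error lies within a tolerance (default 5 degrees) of the
best cell, prefer the smallest b-value, then the smallest SH order.

``snr_difference`` implements the two-volume difference estimator
``SNR = mean(B0 + B0') / (sqrt(2) std(B0 - B0'))`` and
``median_pairwise_snr`` the median over temporally adjacent b0 pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import peak_analysis as pk
from . import reconstruction as rc
from . import signal_sim as sim
from .sphere_math import n_sh_coeffs, real_sh_basis, tessellate_icosahedron

__all__ = [
    "SweepConfig",
    "run_sweep",
    "select_optimal",
    "NO_CROSSING",
    "snr_difference",
    "median_pairwise_snr",
    "run_trial",
]

logger = logging.getLogger(__name__)

NO_CROSSING = "No crossing!"

METHODS = ("qball", "dot_odf_analytic", "dot_odf_numeric", "dot_modf")

SWEEP_COLUMNS = [
    "method", "angle_deg", "b", "n_gradients", "lmax", "snr",
    "mean_error_deg", "std_error_deg", "success_fraction",
    "n_realizations", "seed",
]


@dataclass
class SweepConfig:
    """Grid definition for a simulation sweep."""

    angles_deg: tuple[float, ...] = (40.0, 45.0, 50.0, 55.0, 60.0, 90.0)
    b_values: tuple[float, ...] = (1000.0, 1500.0, 2000.0, 3000.0, 4000.0)
    n_gradients: tuple[int, ...] = (24, 36, 48, 60, 72, 96, 120)
    l_orders: tuple[int, ...] = (4, 6, 8)
    snrs: tuple[float, ...] = (np.inf,)  # inf = noiseless
    n_realizations: int = 100
    methods: tuple[str, ...] = ("qball",)
    master_seed: int = 0
    mesh_order: int = 7
    rel_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("angles_deg", "b_values", "n_gradients", "l_orders",
                     "snrs", "methods"):
            if not len(getattr(self, name)):
                raise ValueError(f"{name} must be non-empty")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")


@lru_cache(maxsize=8)
def _mesh_basis(order: int, lmax: int) -> np.ndarray:
    mesh = tessellate_icosahedron(order)
    return real_sh_basis(mesh.vertices, lmax)


def _reconstruct(method, signal, scheme, b, t_ms, lmax) -> rc.ODFProfile:
    if method == "qball":
        return rc.qball_odf(signal, scheme, lmax=lmax, b=b)
    adc = rc.estimate_adc(signal, scheme, b, lmax=lmax)
    if method == "dot_odf_analytic":
        return rc.dot_odf_analytical(adc, t_ms)
    if method == "dot_odf_numeric":
        return rc.dot_odf_numerical(adc, t_ms, quad_order=3)
    if method == "dot_modf":
        return rc.dot_odf_numerical(adc, t_ms, weight="r_squared", quad_order=3)
    raise ValueError(f"unknown method tag {method!r}")


def run_trial(
    method: str,
    angle_deg: float,
    b: float,
    scheme: sim.GradientScheme,
    lmax: int,
    snr: float,
    n_realizations: int,
    seed_seq: np.random.SeedSequence,
    mesh_order: int = 7,
    rel_threshold: float = 0.5,
) -> pk.TrialResult:
    """One sweep cell: simulate, reconstruct, extract peaks, summarize."""
    protocol = sim.protocol_for_b(b)
    phantom = sim.two_fiber_phantom(angle_deg)
    axes = np.array([f.axis for f in phantom])
    clean = sim.crossing_signal(phantom, scheme, protocol)
    mesh = tessellate_icosahedron(mesh_order)
    basis = _mesh_basis(mesh_order, lmax)
    noise_seeds = seed_seq.generate_state(n_realizations) >> 1  # < 2^31
    matches = []
    for r in range(n_realizations):
        signal = (
            clean
            if np.isinf(snr)
            else sim.add_complex_noise(clean, snr, seed=int(noise_seeds[r]))
        )
        odf = _reconstruct(method, signal, scheme, b, protocol.t_ms, lmax)
        values = basis @ odf.sh.coeffs
        peaks = pk.find_maxima(values, mesh, rel_threshold)
        matches.append(pk.angular_error(axes, peaks))
        if np.isinf(snr):
            # noiseless realizations are identical; replicate the outcome
            matches = matches * n_realizations
            break
    return pk.summarize_realizations(matches[:n_realizations])


def run_sweep(config: SweepConfig, out_csv=None) -> pd.DataFrame:
    """Full factorial sweep; one SweepRecord row per feasible cell.

    Cells with NG below the SH coefficient count are skipped with a log
    entry.  With ``out_csv`` the table is (re)written incrementally after
    every cell.
    """
    rows = []
    cell_index = 0
    schemes = {
        ng: sim.generate_gradient_scheme(
            ng, seed=int(np.random.SeedSequence(
                entropy=config.master_seed, spawn_key=(0x5C4E3E, ng)
            ).generate_state(1)[0] >> 1)
        )
        for ng in config.n_gradients
    }
    for method in config.methods:
        for angle in config.angles_deg:
            for b in config.b_values:
                for ng in config.n_gradients:
                    for lmax in config.l_orders:
                        for snr in config.snrs:
                            cell_index += 1
                            if ng < n_sh_coeffs(lmax):
                                logger.info(
                                    "skip infeasible cell NG=%d < %d coefficients (lmax=%d)",
                                    ng, n_sh_coeffs(lmax), lmax,
                                )
                                continue
                            seq = np.random.SeedSequence(
                                entropy=config.master_seed, spawn_key=(cell_index,)
                            )
                            cell_seed = int(seq.generate_state(1)[0] >> 1)
                            trial = run_trial(
                                method, angle, b, schemes[ng], lmax, snr,
                                config.n_realizations, seq,
                                config.mesh_order, config.rel_threshold,
                            )
                            logger.info(
                                "cell %s angle=%g b=%g NG=%d l=%d SNR=%s -> "
                                "mu=%.2f s=%.2f p=%.2f",
                                method, angle, b, ng, lmax, snr,
                                trial.mean_error_deg, trial.std_error_deg,
                                trial.success_fraction,
                            )
                            rows.append(
                                {
                                    "method": method,
                                    "angle_deg": angle,
                                    "b": b,
                                    "n_gradients": ng,
                                    "lmax": lmax,
                                    "snr": snr,
                                    "mean_error_deg": trial.mean_error_deg,
                                    "std_error_deg": trial.std_error_deg,
                                    "success_fraction": trial.success_fraction,
                                    "n_realizations": trial.n_realizations,
                                    "seed": cell_seed,
                                }
                            )
                            if out_csv is not None:
                                pd.DataFrame(rows, columns=SWEEP_COLUMNS).to_csv(
                                    out_csv, index=False
                                )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def select_optimal(
    records: pd.DataFrame,
    tolerance_deg: float = 5.0,
    min_success: float = 1.0,
):
    """Smallest-b optimal cell under the angular-error tolerance rule.

    ``records`` holds the cells of one (method, angle, NG) slice.  Cells
    with success fraction below ``min_success`` are not considered.  Among
    the remaining cells whose mean error is within ``tolerance_deg`` of the
    minimum, the smallest b wins, then the smallest SH order, then the
    smallest error.  Returns ``(b, lmax, mean_error_deg)`` or the
    ``NO_CROSSING`` marker when no cell qualifies.
    """
    ok = records[
        (records["success_fraction"] >= min_success)
        & np.isfinite(records["mean_error_deg"])
    ]
    if ok.empty:
        return NO_CROSSING
    best_mu = ok["mean_error_deg"].min()
    cand = ok[ok["mean_error_deg"] <= best_mu + tolerance_deg]
    cand = cand.sort_values(["b", "lmax", "mean_error_deg"])
    row = cand.iloc[0]
    return float(row["b"]), int(row["lmax"]), float(row["mean_error_deg"])


def snr_difference(b0, b0_prime) -> float:
    """Difference-method SNR of two repeated unweighted volumes over an ROI."""
    a = np.asarray(b0, dtype=float).ravel()
    b = np.asarray(b0_prime, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equally sized ROIs of at least 2 voxels")
    sd = float(np.std(a - b, ddof=1))
    if sd == 0.0:
        raise ValueError("identical volumes: difference-method SNR is infinite")
    return float(np.mean(a + b) / (np.sqrt(2.0) * sd))


def median_pairwise_snr(b0_volumes, roi_mask=None) -> float:
    """Median difference-method SNR over temporally adjacent b0 pairs."""
    vols = [np.asarray(v, dtype=float) for v in b0_volumes]
    if len(vols) < 2:
        raise ValueError("need at least two unweighted volumes")
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        vols = [v[roi_mask] for v in vols]
    snrs = [snr_difference(vols[i], vols[i + 1]) for i in range(len(vols) - 1)]
    return float(np.median(snrs))
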