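"""Environment electric-field descriptors for the two reaction steps.

Deprotonation step — the point charges of everything around the site
(protein, solvent, ions; the site's own fragment/segment atoms excluded)
generate one electric-field vector per frame at the centre of mass of the
five-atom backbone segment. The spread of those vector heads over the
trajectory, measured as the occupied volume of a 50^3 grid (VolE), proxies
how often the environment visits acidity-enhancing configurations.

Ring-closure step — over frames whose fragment geometry resembles the
gas-phase reactant (RMSD < 0.15 nm), the field is dotted into the reactant
and transition-state dipoles; frames with (E·mu)_TS − (E·mu)_R > 0 favour
cyclisation. The percentage of favouring frames, damped by conformational
accessibility, is the ring-closure stabilisation (RCS):

    RCS = Delta(E·mu) × (1 − dA_conf / dA_conf_max).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geometry import kabsch_rmsd, minimum_image
from .conformation import ReferenceStates
from .ensemble_io import AsnSite, TrajectoryEnsemble, fragment_coords

__all__ = [
    "COULOMB_K",
    "FieldSeries",
    "RcsResult",
    "field_series",
    "field_spread_volume",
    "dataset_extent",
    "reactive_frame_mask",
    "ring_closure_stabilization",
]

COULOMB_K = 33.206  # kcal mol^-1 nm e^-2
DEFAULT_RMSD_CUT = 0.15  # nm
DEFAULT_GRID_N = 50
STABILIZATION_CUT = 6.0  # kcal/mol, |delta| >= cut labels (de)stabilizing


class ChargeModelError(ValueError):
    """Partial charges missing or unusable."""


@dataclass
class FieldSeries:
    """Per-frame environment field at the segment COM (kcal mol^-1 e^-1 nm^-1)."""

    vectors: np.ndarray        # (n_frames, 3)
    com_used: np.ndarray       # (n_frames, 3) nm
    excluded_atoms: np.ndarray
    replicate_id: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite field components")


def field_series(ensemble: TrajectoryEnsemble, site: AsnSite) -> FieldSeries:
    """Direct Coulomb field of all surrounding point charges, per frame.

    E(COM) = k_e * sum_i q_i (r_COM - r_i)/|r_COM - r_i|^3 over every atom
    outside the site's fragment∪segment, with minimum-image displacements;
    the COM is mass-weighted over the 5 backbone-segment atoms. No distance
    cutoff is applied.
    """
    topo = ensemble.topology
    charges = np.asarray(topo.charges, dtype=float)
    if not np.all(np.isfinite(charges)):
        raise ChargeModelError("non-finite charges in topology")

    excluded = site.excluded_atoms
    env = np.setdiff1d(np.arange(topo.n_atoms), excluded)
    seg = site.segment_atoms
    masses = topo.masses[seg]
    com = (
        np.sum(ensemble.coords[:, seg, :] * masses[None, :, None], axis=1)
        / masses.sum()
    )

    q = charges[env]
    src = env[q != 0.0]
    qs = charges[src]
    vectors = np.zeros((ensemble.n_frames, 3))
    if len(src):
        d = minimum_image(com[:, None, :] - ensemble.coords[:, src, :],
                          ensemble.box[:, None, :])
        r = np.linalg.norm(d, axis=-1)
        if np.any(r < 1e-9):
            raise ValueError("charged atom coincident with segment COM")
        vectors = COULOMB_K * np.sum(qs[None, :, None] * d / r[..., None] ** 3, axis=1)
    return FieldSeries(vectors, com, excluded, ensemble.replicate_id.copy())


def dataset_extent(series_list) -> tuple[np.ndarray, float]:
    """Shared bounding cube (origin, edge) over all sites' vector heads.

    A single cube keeps occupied-volume values comparable across sites.
    """
    allv = np.concatenate([s.vectors for s in series_list], axis=0)
    lo = allv.min(axis=0)
    hi = allv.max(axis=0)
    edge = float(np.max(hi - lo))
    if edge == 0.0:
        edge = 1.0
    return lo, edge


def field_spread_volume(
    series: FieldSeries,
    grid_n: int = DEFAULT_GRID_N,
    extent: tuple[np.ndarray, float] | None = None,
) -> dict:
    """Occupied volume of field-vector-head space on a grid_n^3 grid.

    Returns VolE = occupied-cell count × cell volume (field-units³), the
    occupied-cell count overall and per replicate (the replicate counts are
    the convergence check). Heads outside the extent are clipped into the
    boundary cells with a warning.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    if extent is None:
        extent = dataset_extent([series])
    origin, edge = np.asarray(extent[0], dtype=float), float(extent[1])
    if edge <= 0:
        raise ValueError("degenerate extent")
    cell = edge / grid_n
    rel = (series.vectors - origin) / cell
    if np.any(rel < -1e-9) or np.any(rel > grid_n + 1e-9):
        warnings.warn("field vectors outside extent; clipped into boundary cells")
    idx = np.clip(np.floor(rel).astype(int), 0, grid_n - 1)
    flat = idx[:, 0] * grid_n * grid_n + idx[:, 1] * grid_n + idx[:, 2]
    occupied = len(np.unique(flat))
    per_rep = {
        int(r): int(len(np.unique(flat[series.replicate_id == r])))
        for r in np.unique(series.replicate_id)
    }
    return {
        "VolE": occupied * cell**3,
        "occupied_cells": occupied,
        "occupied_cells_per_replicate": per_rep,
        "cell_edge": cell,
        "origin": origin,
        "edge": edge,
        "grid_n": grid_n,
    }


def reactive_frame_mask(
    ensemble: TrajectoryEnsemble,
    site: AsnSite,
    reference: np.ndarray,
    rmsd_cut: float = DEFAULT_RMSD_CUT,
) -> np.ndarray:
    """Frames whose fragment superposes onto the reactant reference below
    ``rmsd_cut`` (heavy-atom Kabsch RMSD, nm)."""
    reference = np.asarray(reference, dtype=float)
    frames = fragment_coords(ensemble, site)
    return np.array(
        [kabsch_rmsd(frames[i], reference) < rmsd_cut for i in range(frames.shape[0])]
    )


@dataclass
class RcsResult:
    pct_favoring: float
    mean_delta: float
    pct_stabilizing_6: float
    pct_destabilizing_6: float
    rcs: float
    n_reactive_frames: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_favoring <= 100.0:
            raise ValueError("pct_favoring out of range")
        if self.pct_stabilizing_6 + self.pct_destabilizing_6 > 100.0 + 1e-9:
            raise ValueError("stabilizing/destabilizing percentages exceed 100")


def ring_closure_stabilization(
    series: FieldSeries,
    mask: np.ndarray,
    refs: ReferenceStates,
    dAconf: float,
    dAmax: float,
    mode: str = "percent",
) -> RcsResult:
    """RCS over reactant-like frames.

    For each masked frame, delta = E·mu_TS − E·mu_R (kcal/mol, dipoles in
    e·nm). ``pct_favoring`` counts delta > 0; |delta| ≥ 6 kcal/mol labels a
    frame (de)stabilizing. The Delta(E·mu) factor of the RCS product is the
    favouring percentage (``mode="percent"``, default) or the mean delta
    (``mode="mean"``); a sentinel-valued dA_conf (no reactive conformation
    sampled) forces RCS = 0.
    """
    if dAmax <= 0:
        raise ValueError("dAmax must be positive")
    if mode not in {"percent", "mean"}:
        raise ValueError("mode must be 'percent' or 'mean'")
    mask = np.asarray(mask, dtype=bool)
    sentinel = not np.isfinite(dAconf)
    masked = series.vectors[mask]
    n = int(masked.shape[0])
    if n == 0:
        if not sentinel:
            warnings.warn("no reactant-like frames; Delta(E.mu) term set to 0")
        pct_fav = mean_delta = pct_s = pct_d = 0.0
    else:
        delta = masked @ refs.mu_TS - masked @ refs.mu_R
        pct_fav = 100.0 * float(np.mean(delta > 0))
        mean_delta = float(np.mean(delta))
        pct_s = 100.0 * float(np.mean(delta >= STABILIZATION_CUT))
        pct_d = 100.0 * float(np.mean(delta <= -STABILIZATION_CUT))
    term = pct_fav if mode == "percent" else mean_delta
    rcs = 0.0 if sentinel else term * (1.0 - dAconf / dAmax)
    return RcsResult(
        pct_favoring=pct_fav,
        mean_delta=mean_delta,
        pct_stabilizing_6=pct_s,
        pct_destabilizing_6=pct_d,
        rcs=float(rcs),
        n_reactive_frames=n,
    )
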