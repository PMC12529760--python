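"""Local conformational analysis of the Asn/(n+1) fragment.

The conformational feature asks: how often, and at what free-energy cost,
does the fragment visit geometries resembling the quantum-chemical
reactive references? Two reference geometries are used — R, the ring-closure
reactant of the AsnNHMe model, and R*, which resembles the tetrahedral
intermediate (they differ only in the N_(n+1)–Cγ distance). For each
reference, every trajectory frame of the 10-heavy-atom fragment is
superposed onto the reference (Kabsch), a Cartesian PCA of the 30
coordinates is built on the concatenated frames, and the free energy along
PC1,

    dA(bin) = -kB T ln( n_bin / n_max ),

is read at PC1 = ±0.02 and ±0.05 nm. The average of all finite readings
over both references is the feature dA_conf (kcal/mol); a fragment that
never samples the targeted region carries a sentinel later resolved to ten
times the dataset maximum.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from ._geometry import dihedral, kabsch_fit
from .ensemble_io import AsnSite, TrajectoryEnsemble, fragment_coords

__all__ = [
    "KB_KCAL_MOL_K",
    "CONF_SENTINEL",
    "ReferenceStates",
    "LocalPcaModel",
    "FreeEnergyProfile",
    "monitor_dihedrals",
    "local_pca",
    "project_fragments",
    "free_energy_profile",
    "conf_free_energy_feature",
    "subspace_convergence",
]

KB_KCAL_MOL_K = 0.0019872  # Boltzmann constant, kcal/(mol K)
DEBYE_TO_E_NM = 0.020819   # 1 debye in e*nm
DEFAULT_TEMPERATURE = 310.0  # K, the simulation temperature
DEFAULT_BIN_WIDTH = 0.005    # nm along PC1
DEFAULT_PC1_TARGETS = (0.02, 0.05)  # nm, reactive-like PC1 readings

#: marker for "no reactive-like conformation sampled"; resolved at table
#: assembly to 10x the dataset maximum finite dA_conf.
CONF_SENTINEL = math.inf


class DegenerateInputError(ValueError):
    """Not enough frames/variance to build a PCA model."""


@dataclass
class ReferenceStates:
    """QM-derived reference data consumed as input.

    ``R_geometry``/``Rstar_geometry`` are 10x3 fragment coordinates (nm) in
    the canonical fragment atom order; ``mu_R``/``mu_TS`` are the gas-phase
    dipole vectors of the reactant and ring-closure transition state in
    e*nm (1 debye = 0.020819 e*nm).
    """

    R_geometry: np.ndarray
    Rstar_geometry: np.ndarray
    mu_R: np.ndarray
    mu_TS: np.ndarray

    def __post_init__(self) -> None:
        self.R_geometry = np.asarray(self.R_geometry, dtype=float)
        self.Rstar_geometry = np.asarray(self.Rstar_geometry, dtype=float)
        self.mu_R = np.asarray(self.mu_R, dtype=float)
        self.mu_TS = np.asarray(self.mu_TS, dtype=float)
        for g in (self.R_geometry, self.Rstar_geometry):
            if g.shape != (10, 3):
                raise ValueError("reference geometries must be 10x3 (fragment order)")
        for mu in (self.mu_R, self.mu_TS):
            if mu.shape != (3,) or not np.all(np.isfinite(mu)):
                raise ValueError("dipoles must be finite 3-vectors")

    @classmethod
    def from_json(cls, path) -> "ReferenceStates":
        with open(path) as fh:
            doc = json.load(fh)
        scale = 1.0
        if str(doc.get("dipole_units", "e_nm")).lower() in {"debye", "d"}:
            scale = DEBYE_TO_E_NM
        return cls(
            R_geometry=np.asarray(doc["R_geometry"], dtype=float),
            Rstar_geometry=np.asarray(doc["Rstar_geometry"], dtype=float),
            mu_R=np.asarray(doc["mu_R"], dtype=float) * scale,
            mu_TS=np.asarray(doc["mu_TS"], dtype=float) * scale,
        )

    def to_json(self, path) -> None:
        doc = {
            "dipole_units": "e_nm",
            "R_geometry": self.R_geometry.tolist(),
            "Rstar_geometry": self.Rstar_geometry.tolist(),
            "mu_R": self.mu_R.tolist(),
            "mu_TS": self.mu_TS.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def monitor_dihedrals(ensemble: TrajectoryEnsemble, site: AsnSite) -> dict[str, np.ndarray]:
    """Per-frame dihedrals (deg) and the N_(n+1)–Cγ distance (nm).

    Monitored: psi (N–CA–C–N), phi (C_(n-1)–N–CA–C, absent for an
    N-terminal Asn), phi_n1 (C–N_(n+1)–CA_(n+1)–C_(n+1)), chi1
    (N–CA–CB–CG), chi2 (CA–CB–CG–ND2) and delta (N–CA–C–O).
    """
    topo = ensemble.topology
    f = site.fragment_atoms  # N CA CB CG ND2 OD1 C O | N1 CA1
    X = ensemble.coords
    out: dict[str, np.ndarray] = {}

    def dih(i, j, k, l):
        return dihedral(X[:, i], X[:, j], X[:, k], X[:, l])

    out["psi"] = dih(f[0], f[1], f[6], f[8])
    if site.prev_C is not None:
        out["phi"] = dih(site.prev_C, f[0], f[1], f[6])
    out["chi1"] = dih(f[0], f[1], f[2], f[3])
    out["chi2"] = dih(f[1], f[2], f[3], f[4])
    out["delta"] = dih(f[0], f[1], f[6], f[7])
    try:
        next_C = topo.atom_index(site.chain, site.asn_residue + 1, "C")
        out["phi_n1"] = dih(f[6], f[8], f[9], next_C)
    except Exception:
        pass
    out["d_NCgamma"] = np.linalg.norm(X[:, f[8]] - X[:, f[3]], axis=-1)
    return out


@dataclass
class LocalPcaModel:
    """Cartesian PCA of the superposed 10-atom fragment (30 coordinates)."""

    mean: np.ndarray          # (30,)
    eigenvectors: np.ndarray  # (30, 30), columns are PCs
    eigenvalues: np.ndarray   # (30,), nm^2, descending
    reference_projection: tuple[float, float]
    variance_fraction_2pc: float
    reference: np.ndarray     # (10, 3) geometry frames are fitted onto

    def project(self, fragments: np.ndarray, n_components: int = 2) -> np.ndarray:
        """Fit frames onto the reference and project into the PC basis."""
        flat = _fit_and_flatten(fragments, self.reference)
        return (flat - self.mean) @ self.eigenvectors[:, :n_components]


def _fit_and_flatten(fragments: np.ndarray, reference: np.ndarray) -> np.ndarray:
    fitted = np.empty_like(fragments)
    for i in range(fragments.shape[0]):
        fitted[i] = kabsch_fit(fragments[i], reference)
    return fitted.reshape(fragments.shape[0], -1)


def local_pca(
    ensemble: TrajectoryEnsemble,
    sites,
    reference: np.ndarray,
) -> LocalPcaModel:
    """PCA of all listed sites' fragment frames, concatenated.

    Every frame is least-squares superposed onto the reference geometry
    before the covariance (about the ensemble mean) is diagonalised; PC sign
    is fixed so the reference projects at PC1 >= 0. The fraction of variance
    carried by the leading two PCs ("essential subspace") is recorded.
    """
    reference = np.asarray(reference, dtype=float)
    if isinstance(sites, AsnSite):
        sites = [sites]
    blocks = [fragment_coords(ensemble, s) for s in sites]
    frames = np.concatenate(blocks, axis=0)
    if frames.shape[0] < 2:
        raise DegenerateInputError("PCA needs at least 2 frames")
    flat = _fit_and_flatten(frames, reference)
    mean = flat.mean(axis=0)
    cov = np.cov(flat, rowvar=False, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude component positive
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    ref_proj = (reference.reshape(-1) - mean) @ evecs
    if ref_proj[0] < 0:
        evecs[:, 0] = -evecs[:, 0]
        ref_proj[0] = -ref_proj[0]
    total = float(np.sum(evals))
    vf = float((evals[0] + evals[1]) / total) if total > 0 else 0.0
    return LocalPcaModel(
        mean=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        reference_projection=(float(ref_proj[0]), float(ref_proj[1])),
        variance_fraction_2pc=vf,
        reference=reference,
    )


def project_fragments(model: LocalPcaModel, ensemble: TrajectoryEnsemble,
                      site: AsnSite, n_components: int = 2) -> np.ndarray:
    return model.project(fragment_coords(ensemble, site), n_components)


@dataclass
class FreeEnergyProfile:
    """Boltzmann-inverted histogram along PC1 (kcal/mol, minimum at 0)."""

    pc1_centers: np.ndarray
    deltaA: np.ndarray      # kcal/mol; NaN where the bin is empty
    temperature: float      # K
    empty_bins: np.ndarray  # bool mask

    def value_at(self, pc1: float) -> float:
        """dA in the bin containing ``pc1``; NaN when empty or out of range."""
        half = 0.5 * (self.pc1_centers[1] - self.pc1_centers[0]) if len(self.pc1_centers) > 1 else np.inf
        idx = np.flatnonzero(np.abs(self.pc1_centers - pc1) <= half + 1e-12)
        if len(idx) == 0:
            return float("nan")
        i = idx[np.argmin(np.abs(self.pc1_centers[idx] - pc1))]
        return float(self.deltaA[i])


def free_energy_profile(
    projections: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> FreeEnergyProfile:
    """dA(PC1) = -kB*T*ln(count/max_count), referenced to the deepest bin."""
    proj = np.asarray(projections, dtype=float).ravel()
    if proj.size == 0:
        raise ValueError("no projections supplied")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    lo = math.floor(proj.min() / bin_width) * bin_width
    hi = math.ceil(proj.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(proj, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    empty = counts == 0
    dA = np.full_like(centers, np.nan)
    with np.errstate(divide="ignore"):
        dA[~empty] = -KB_KCAL_MOL_K * temperature * np.log(counts[~empty] / counts.max())
    return FreeEnergyProfile(centers, dA, temperature, empty)


def conf_free_energy_feature(
    profiles: dict[str, FreeEnergyProfile],
    pc1_targets=DEFAULT_PC1_TARGETS,
) -> float:
    """Average dA over PC1 = ±t for each target t and each reference profile.

    ``profiles`` maps reference names (R, Rstar) to their PC1 profiles. Both
    signs of each target are read (the reactive-like region is defined by
    |PC1|); empty readings are skipped, and when *no* targeted bin is
    occupied in any profile the sentinel (inf) is returned.
    """
    temps = {round(p.temperature, 6) for p in profiles.values()}
    if len(temps) > 1:
        raise ValueError("profiles must share a temperature")
    readings = []
    for prof in profiles.values():
        for t in pc1_targets:
            for signed in (t, -t):
                v = prof.value_at(signed)
                if np.isfinite(v):
                    readings.append(v)
    if not readings:
        return CONF_SENTINEL
    return float(np.mean(readings))


def subspace_convergence(models) -> float:
    """Mean pairwise RMSIP of the 2-PC essential subspaces across replicates.

    RMSIP = sqrt( (1/2) * sum_{i,j<=2} (v_i . w_j)^2 ), 1 for identical
    subspaces, ~0 for orthogonal ones.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least 2 replicate models")
    vals = []
    for a in range(len(models)):
        for b in range(a + 1, len(models)):
            V = models[a].eigenvectors[:, :2]
            W = models[b].eigenvectors[:, :2]
            vals.append(math.sqrt(np.sum((V.T @ W) ** 2) / 2.0))
    return float(np.mean(vals))
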