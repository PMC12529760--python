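"""Hydrogen-bond classes of the Asn / (n+1) amide pair.

Per frame, a geometric donor–H···acceptor criterion in the Baker–Hubbard
style (H···A distance ≤ 0.25 nm and D–H···A angle ≥ 120°) is evaluated for
three interaction classes around the site:

* the Asn backbone C=O oxygen acting as acceptor,
* the (n+1) backbone N–H acting as donor,
* the (n+1) backbone N acting as acceptor.

Each class is reported as the percentage of frames in which at least one
qualifying partner exists (per-class normalisation: 100% = interaction
retained through the whole trajectory). Persistent backbone H-bonds encode
secondary structure, so buried beta-sheet amides show high donor/acceptor
percentages; the two N-based percentages are the ML features, the O-based
one is reported for completeness.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import minimum_image
from .ensemble_io import AsnSite, MalformedResidueError, TrajectoryEnsemble

__all__ = ["HbondProfile", "classify_amide_hbonds"]

DEFAULT_D_HA = 0.25     # nm, H...acceptor distance ceiling
DEFAULT_THETA = 120.0   # deg, D-H...A angle floor
_COVALENT_DH = 0.125    # nm, H considered bonded to nearest N/O within this

CLASSES = ("O_acceptor", "N_donor", "N_acceptor")


@dataclass
class HbondProfile:
    pct_O_acceptor: float
    pct_N_donor: float
    pct_N_acceptor: float
    partners: list = field(default_factory=list)  # (partner residue, class, pct)

    def __post_init__(self) -> None:
        for p in (self.pct_O_acceptor, self.pct_N_donor, self.pct_N_acceptor):
            if not 0.0 <= p <= 100.0:
                raise ValueError("H-bond percentages must lie in [0, 100]")

    def as_dict(self) -> dict:
        return {
            "pct_O_acceptor": self.pct_O_acceptor,
            "pct_N_donor": self.pct_N_donor,
            "pct_N_acceptor": self.pct_N_acceptor,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.partners, columns=["partner", "class", "percent"])


def _donor_pairs(topology, frame0: np.ndarray, box0: np.ndarray) -> np.ndarray:
    """(n, 2) array of (heavy donor, hydrogen) pairs inferred by proximity.

    Each hydrogen is attached to the nearest N/O *of its own residue* within
    a covalent cutoff in the first frame (covalent bonds never cross residue
    boundaries, and the restriction keeps the assignment independent of
    frame order and of other residues' motion).
    """
    h_idx = topology.hydrogen_indices
    heavy = np.flatnonzero(np.isin(topology.elements, ("N", "O")))
    if len(h_idx) == 0 or len(heavy) == 0:
        return np.empty((0, 2), dtype=int)
    same_res = (
        (topology.chains[h_idx][:, None] == topology.chains[heavy][None, :])
        & (topology.resids[h_idx][:, None] == topology.resids[heavy][None, :])
    )
    d = minimum_image(frame0[h_idx][:, None, :] - frame0[heavy][None, :, :], box0)
    dist = np.linalg.norm(d, axis=-1)
    dist[~same_res] = np.inf
    nearest = np.argmin(dist, axis=1)
    ok = dist[np.arange(len(h_idx)), nearest] <= _COVALENT_DH
    return np.column_stack([heavy[nearest[ok]], h_idx[ok]])


def _pair_hits(coords, box, donors, hydrogens, acceptors, d_ha, theta_min):
    """Boolean (n_frames, n_pairs) of geometric H-bond matches."""
    h = coords[:, hydrogens, :]
    a = coords[:, acceptors, :]
    d = coords[:, donors, :]
    v_ha = minimum_image(a - h, box[:, None, :])
    r_ha = np.linalg.norm(v_ha, axis=-1)
    v_hd = minimum_image(d - h, box[:, None, :])
    r_hd = np.linalg.norm(v_hd, axis=-1)
    cosang = np.sum(v_ha * v_hd, axis=-1) / np.maximum(r_ha * r_hd, 1e-12)
    # angle D-H...A >= theta  <=>  cos(angle) <= cos(theta)
    return (r_ha <= d_ha) & (cosang <= np.cos(np.radians(theta_min)))


def classify_amide_hbonds(
    ensemble: TrajectoryEnsemble,
    site: AsnSite,
    include_water: bool = False,
    d_ha: float = DEFAULT_D_HA,
    theta_min: float = DEFAULT_THETA,
) -> HbondProfile:
    """Classify the site's amide hydrogen bonds frame by frame.

    Partners are protein atoms by default (``include_water`` adds solvent);
    donor/acceptor pairs within the partner's own residue are not excluded
    globally, but a partner must belong to a different residue than the site
    atom it bonds to.
    """
    topo = ensemble.topology
    coords, box = ensemble.coords, ensemble.box
    frame0, box0 = coords[0], box[0]

    asn_O = int(site.fragment_atoms[7])
    n1_N = int(site.n1_N)
    n1_H = site.n1_H

    allowed = topo.is_protein.copy()
    if include_water:
        allowed |= topo.is_water

    pairs = _donor_pairs(topo, frame0, box0)
    if n1_H is None:
        hit = (pairs[:, 0] == n1_N)
        if hit.any():
            n1_H = int(pairs[hit][0, 1])
        elif topo.resnames[n1_N] != "PRO":
            raise MalformedResidueError(
                f"no amide hydrogen found on n+1 N of Asn {site.asn_residue}"
            )

    res_of = np.array([f"{c}:{r}" for c, r in zip(topo.chains, topo.resids)], dtype=object)

    def other_residue(idx_arr, ref_atom):
        return idx_arr[res_of[idx_arr] != res_of[ref_atom]]

    results: dict[str, float] = {}
    partner_rows: list[tuple[str, str, float]] = []

    def tally(cls, donors, hydrogens, acceptors, partner_atoms):
        if len(donors) == 0 or len(acceptors) == 0:
            results[cls] = 0.0
            return
        hits = _pair_hits(coords, box, donors, hydrogens, acceptors, d_ha, theta_min)
        results[cls] = 100.0 * float(np.mean(hits.any(axis=1)))
        for partner in np.unique(res_of[partner_atoms]):
            sel = res_of[partner_atoms] == partner
            pct = 100.0 * float(np.mean(hits[:, sel].any(axis=1)))
            if pct > 0:
                partner_rows.append((str(partner), cls, pct))

    # (i) Asn backbone O as acceptor: all external donor pairs
    dp = pairs[allowed[pairs[:, 0]]]
    dp = dp[res_of[dp[:, 0]] != res_of[asn_O]]
    if len(dp):
        tally("O_acceptor", dp[:, 0], dp[:, 1], np.full(len(dp), asn_O), dp[:, 0])
    else:
        results["O_acceptor"] = 0.0

    # (ii) n+1 N-H as donor: external N/O acceptors
    if n1_H is not None:
        acc = np.flatnonzero(np.isin(topo.elements, ("N", "O")) & allowed)
        acc = other_residue(acc, n1_N)
        if len(acc):
            d_arr = np.full(len(acc), n1_N)
            h_arr = np.full(len(acc), n1_H)
            tally("N_donor", d_arr, h_arr, acc, acc)
        else:
            results["N_donor"] = 0.0
    else:
        results["N_donor"] = 0.0

    # (iii) n+1 N as acceptor: external donor pairs (excluding its own H)
    dp = pairs[allowed[pairs[:, 0]]]
    dp = dp[res_of[dp[:, 0]] != res_of[n1_N]]
    if len(dp):
        a_arr = np.full(len(dp), n1_N)
        tally("N_acceptor", dp[:, 0], dp[:, 1], a_arr, dp[:, 0])
    else:
        results["N_acceptor"] = 0.0

    return HbondProfile(
        pct_O_acceptor=results["O_acceptor"],
        pct_N_donor=results["N_donor"],
        pct_N_acceptor=results["N_acceptor"],
        partners=partner_rows,
    )
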