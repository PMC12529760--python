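"""Trajectory/topology ingestion and Asn-site definition.

Readers are backed by MDAnalysis, so every coordinate format it understands
(PDB, GRO, XTC, DCD, TRR, multi-model PDB, ...) is accepted. Internally all
coordinates and box lengths are stored in **nm** (MDAnalysis reports Å); all
downstream descriptor cutoffs (0.4 nm solvation shell, 0.15 nm RMSD gate,
0.25 nm H-bond distance) are expressed in nm.

An :class:`AsnSite` bundles the atom indices a descriptor needs for one
asparagine: the 10 heavy atoms of the Asn/(n+1) fragment used for local PCA
and the RMSD gate, the 5-atom backbone segment whose centre of mass anchors
the electric-field descriptors, and the (n+1) backbone nitrogen whose
solvation and H-bonding are measured. Sites followed by proline are excluded
(no backbone amide to deprotonate).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "TrajectoryEnsemble",
    "AsnSite",
    "FormatError",
    "EmptyEnsembleError",
    "MalformedResidueError",
    "load_topology",
    "load_ensemble",
    "write_ensemble",
    "select_asn_sites",
]

NM_PER_ANGSTROM = 0.1

WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP3P", "T3P"})
ION_RESNAMES = frozenset({"NA", "CL", "K", "MG", "CA2", "ZN", "SOD", "CLA", "ION"})

#: side-chain amide aliases: the amide N/O of Asn appear in the literature as
#: N-gamma / O-gamma; PDB convention is ND2 / OD1.
ATOM_ALIASES = {"NG": "ND2", "OG": "OD1", "AD1": "OD1", "AD2": "ND2"}

_FRAGMENT_ASN_NAMES = ("N", "CA", "CB", "CG", "ND2", "OD1", "C", "O")
_FRAGMENT_NEXT_NAMES = ("N", "CA")

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "ZN": 65.38, "F": 18.998,
}


class FormatError(ValueError):
    """Input files are inconsistent (e.g. atom counts disagree)."""


class EmptyEnsembleError(ValueError):
    """No frames survive loading/truncation."""


class MalformedResidueError(ValueError):
    """A required heavy atom of an Asn site cannot be resolved."""


def _guess_element(name: str) -> str:
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        return "X"
    if stripped[:2] in ("NA", "CL", "MG", "ZN") and len(name) <= 2:
        return stripped[:2]
    return stripped[0]


@dataclass
class Topology:
    """Static atom model: names, residue assignment and partial charges (e)."""

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    charges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr_name in ("elements", "resnames", "resids", "chains", "charges", "masses"):
            if len(getattr(self, arr_name)) != n:
                raise FormatError(f"topology field {arr_name!r} length mismatch")
        if not np.all(np.isfinite(self.charges)):
            raise FormatError("non-finite partial charges in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.resnames, list(WATER_RESNAMES))

    @property
    def is_ion(self) -> np.ndarray:
        return np.isin(self.resnames, list(ION_RESNAMES))

    @property
    def is_protein(self) -> np.ndarray:
        return ~(self.is_water | self.is_ion)

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        """Index of the first O-element atom of each water residue."""
        mask = self.is_water & (self.elements == "O")
        idx = np.flatnonzero(mask)
        # one oxygen per water residue: keep first O per (chain, resid)
        seen: set[tuple[str, int]] = set()
        keep = []
        for i in idx:
            key = (str(self.chains[i]), int(self.resids[i]))
            if key not in seen:
                seen.add(key)
                keep.append(i)
        return np.asarray(keep, dtype=int)

    @property
    def hydrogen_indices(self) -> np.ndarray:
        return np.flatnonzero(self.elements == "H")

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resid, resname) in file order."""
        keys: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for ch, ri, rn in zip(self.chains, self.resids, self.resnames):
            k = (str(ch), int(ri))
            if k not in seen:
                seen.add(k)
                keys.append((str(ch), int(ri), str(rn)))
        return keys

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        """Resolve one atom by residue and (alias-normalised) name."""
        want = ATOM_ALIASES.get(name, name)
        for i in np.flatnonzero((self.chains == chain) & (self.resids == resid)):
            have = ATOM_ALIASES.get(str(self.names[i]), str(self.names[i]))
            if have == want:
                return int(i)
        raise MalformedResidueError(
            f"atom {name} not found in residue {chain}:{resid}"
        )


@dataclass
class TrajectoryEnsemble:
    """Concatenated frames from one or more replicate runs (coordinates nm)."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    box: np.ndarray     # (n_frames, 3) orthorhombic lengths, nm
    replicate_id: np.ndarray  # (n_frames,) int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.replicate_id = np.asarray(self.replicate_id, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise FormatError("frame atom count does not match topology")
        if self.coords.shape[0] == 0:
            raise EmptyEnsembleError("ensemble holds zero frames")
        if self.box.shape != (self.coords.shape[0], 3) or np.any(self.box <= 0):
            raise FormatError("box must be per-frame positive orthorhombic lengths")
        if len(self.replicate_id) != self.coords.shape[0]:
            raise FormatError("replicate_id length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def replicates(self) -> np.ndarray:
        return np.unique(self.replicate_id)

    def frames_of(self, replicate: int) -> np.ndarray:
        return np.flatnonzero(self.replicate_id == replicate)


@dataclass
class AsnSite:
    """One asparagine and its (n+1) partner, resolved to atom indices.

    ``fragment_atoms`` holds the 10 heavy atoms in fixed order
    (Asn N, CA, CB, CG, ND2, OD1, C, O; next N, CA);
    ``segment_atoms`` the backbone segment (Asn CA, C, O; next N, CA).
    """

    protein_id: str
    asn_residue: int
    next_residue_name: str
    fragment_atoms: np.ndarray
    segment_atoms: np.ndarray
    n1_N: int
    n1_H: int | None = None
    chain: str = "A"
    label: str = "unknown"
    prev_C: int | None = None  # C of residue n-1, needed for phi
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fragment_atoms = np.asarray(self.fragment_atoms, dtype=int)
        self.segment_atoms = np.asarray(self.segment_atoms, dtype=int)
        if len(self.fragment_atoms) != 10 or len(np.unique(self.fragment_atoms)) != 10:
            raise MalformedResidueError("fragment must be 10 distinct heavy atoms")
        if len(self.segment_atoms) != 5:
            raise MalformedResidueError("backbone segment must be 5 atoms")
        if self.n1_N not in self.segment_atoms:
            raise MalformedResidueError("n+1 N must belong to the backbone segment")

    @property
    def excluded_atoms(self) -> np.ndarray:
        """Atoms that are part of the site itself (never field sources)."""
        return np.unique(np.concatenate([self.fragment_atoms, self.segment_atoms]))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _universe(topology_path, *traj_paths):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if traj_paths:
            return mda.Universe(str(topology_path), *[str(p) for p in traj_paths])
        return mda.Universe(str(topology_path))


def load_topology(topology_path, charge_table=None) -> Topology:
    """Read a PDB/GRO-class topology; partial charges from the file when the
    format carries them, else from a sidecar CSV (columns atom_index,charge),
    else zero."""
    u = _universe(topology_path)
    atoms = u.atoms
    names = np.array([a.name for a in atoms], dtype=object)
    try:
        elements = np.array([str(e).upper() for e in atoms.elements], dtype=object)
        if np.any(elements == ""):
            raise AttributeError
    except Exception:
        elements = np.array([_guess_element(n) for n in names], dtype=object)
    resnames = np.array([a.resname for a in atoms], dtype=object)
    resids = np.array([a.resid for a in atoms], dtype=int)
    try:
        chains = np.array([str(a.chainID) or "A" for a in atoms], dtype=object)
    except Exception:
        chains = np.array([str(a.segid) or "A" for a in atoms], dtype=object)
    try:
        charges = np.asarray(atoms.charges, dtype=float)
    except Exception:
        charges = np.zeros(len(atoms))
    if charge_table is not None:
        tab = pd.read_csv(charge_table)
        charges = charges.copy()
        charges[tab["atom_index"].to_numpy(int)] = tab["charge"].to_numpy(float)
    masses = np.array([_ELEMENT_MASS.get(e, 12.011) for e in elements], dtype=float)
    return Topology(names, elements, resnames, resids, chains, charges, masses)


def _header_cryst1(path) -> np.ndarray | None:
    """Box lengths (Å) from a file-level CRYST1 record.

    Multi-model PDBs often carry one CRYST1 in the header, which MDAnalysis
    does not attach to the per-MODEL frames.
    """
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    return np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                if line.startswith(("ATOM", "HETATM")):
                    break
    except (OSError, UnicodeDecodeError, ValueError):
        return None
    return None


def _read_frames(topology_path, traj_path):
    try:
        u = _universe(topology_path, traj_path) if traj_path else _universe(topology_path)
    except Exception as exc:  # reader-level mismatch (atom counts, parse)
        raise FormatError(
            f"cannot read {traj_path or topology_path} with topology "
            f"{topology_path}: {exc}"
        ) from exc
    fallback = _header_cryst1(traj_path or topology_path)
    coords, boxes = [], []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float) * NM_PER_ANGSTROM)
        dims = ts.dimensions
        if dims is None or np.all(dims[:3] == 0):
            if fallback is None:
                raise FormatError(
                    f"frame without box dimensions in {traj_path or topology_path}"
                )
            box_A = fallback
        else:
            box_A = np.asarray(dims[:3], dtype=float)
        boxes.append(box_A * NM_PER_ANGSTROM)
    return np.asarray(coords), np.asarray(boxes)


def load_ensemble(
    topology_path,
    trajectory_paths=(),
    discard_fraction: float = 0.0,
    charge_table=None,
) -> TrajectoryEnsemble:
    """Load one ensemble from one or more replicate runs.

    Each trajectory file is one replicate; from each, only the last
    ``1 - discard_fraction`` portion of frames is retained (equilibration
    discard), mirroring the use of the final stretch of each production run.
    With no trajectory paths the topology file itself supplies the frames
    (e.g. a multi-model PDB → one replicate).
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    topo = load_topology(topology_path, charge_table=charge_table)
    runs = list(trajectory_paths) or [None]
    all_coords, all_box, rep_ids = [], [], []
    for rep, traj in enumerate(runs):
        coords, boxes = _read_frames(topology_path, traj)
        if coords.shape[1] != topo.n_atoms:
            raise FormatError(
                f"atom count mismatch: topology {topo.n_atoms}, trajectory {coords.shape[1]}"
            )
        keep = math.floor((1.0 - discard_fraction) * len(coords))
        if keep == 0:
            raise EmptyEnsembleError(f"no frames retained from run {rep}")
        all_coords.append(coords[-keep:])
        all_box.append(boxes[-keep:])
        rep_ids.append(np.full(keep, rep, dtype=int))
    return TrajectoryEnsemble(
        topology=topo,
        coords=np.concatenate(all_coords),
        box=np.concatenate(all_box),
        replicate_id=np.concatenate(rep_ids),
    )


# ---------------------------------------------------------------------------
# writing (fixtures and round-trips)
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: TrajectoryEnsemble, topology_path, trajectory_path=None,
                   charge_table_path=None) -> None:
    """Write topology+frames back to disk through MDAnalysis.

    ``topology_path`` receives a PDB (single frame, or all frames as models
    when no separate trajectory path is given); ``trajectory_path`` may be
    any MDAnalysis-writable format (.xtc/.dcd/.trr/.pdb). Charges go to a
    sidecar CSV when requested (PDB carries no charge column).
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    topo = ensemble.topology
    resk = topo.residue_keys()
    res_lookup = {(c, r): i for i, (c, r, _) in enumerate(resk)}
    resindex = np.array(
        [res_lookup[(str(c), int(r))] for c, r in zip(topo.chains, topo.resids)], dtype=int
    )
    u = mda.Universe.empty(
        n_atoms=topo.n_atoms,
        n_residues=len(resk),
        atom_resindex=resindex,
        residue_segindex=np.zeros(len(resk), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(topo.names))
    u.add_TopologyAttr("elements", [str(e).capitalize() for e in topo.elements])
    u.add_TopologyAttr("resnames", [rn for _, _, rn in resk])
    u.add_TopologyAttr("resids", [r for _, r, _ in resk])
    u.add_TopologyAttr("chainIDs", [str(c)[:1] for c in topo.chains])
    u.add_TopologyAttr("occupancies", np.ones(topo.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(topo.n_atoms))

    coords_A = ensemble.coords / NM_PER_ANGSTROM
    dims = np.zeros((ensemble.n_frames, 6))
    dims[:, :3] = ensemble.box / NM_PER_ANGSTROM
    dims[:, 3:] = 90.0
    u.load_new(coords_A, format=MemoryReader, dimensions=dims)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            with mda.Writer(str(topology_path), multiframe=True) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
        else:
            u.trajectory[0]
            u.atoms.write(str(topology_path))
            with mda.Writer(str(trajectory_path), n_atoms=topo.n_atoms) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
    if charge_table_path is not None:
        pd.DataFrame(
            {"atom_index": np.arange(topo.n_atoms), "charge": topo.charges}
        ).to_csv(charge_table_path, index=False)


# ---------------------------------------------------------------------------
# site selection
# ---------------------------------------------------------------------------

def _normalise_label(raw) -> str:
    s = str(raw).strip().lower()
    if s in {"yes", "y", "1", "true", "reactive"}:
        return "reactive"
    if s in {"no", "not", "n", "0", "false", "nonreactive"}:
        return "nonreactive"
    return "unknown"


def select_asn_sites(
    topology: Topology,
    annotations: pd.DataFrame | None = None,
    protein_id: str = "protein",
) -> list[AsnSite]:
    """Enumerate featurizable Asn sites.

    Rules: an Asn must have an (n+1) residue (C-terminal Asn skipped with a
    warning); proline at n+1 disqualifies the site (no backbone amide);
    sites without an experimental annotation are retained with
    ``label="unknown"`` so they stay featurizable but drop out of the ML
    table. Missing heavy atoms raise :class:`MalformedResidueError`.
    """
    ann_lookup: dict[int, str] = {}
    if annotations is not None and len(annotations):
        sub = annotations
        if "protein_id" in sub.columns:
            sub = sub[sub["protein_id"].astype(str) == str(protein_id)]
        for _, row in sub.iterrows():
            ann_lookup[int(row["residue_number"])] = _normalise_label(row["label"])

    resk = topology.residue_keys()
    sites: list[AsnSite] = []
    for i, (chain, resid, resname) in enumerate(resk):
        if resname != "ASN":
            continue
        nxt = None
        if i + 1 < len(resk):
            c2, r2, rn2 = resk[i + 1]
            if c2 == chain and r2 == resid + 1:
                nxt = (c2, r2, rn2)
        if nxt is None:
            warnings.warn(f"Asn {chain}:{resid} has no n+1 residue; skipped")
            continue
        if nxt[2] == "PRO":
            continue
        frag = [topology.atom_index(chain, resid, nm) for nm in _FRAGMENT_ASN_NAMES]
        frag += [topology.atom_index(nxt[0], nxt[1], nm) for nm in _FRAGMENT_NEXT_NAMES]
        seg = [
            topology.atom_index(chain, resid, "CA"),
            topology.atom_index(chain, resid, "C"),
            topology.atom_index(chain, resid, "O"),
            topology.atom_index(nxt[0], nxt[1], "N"),
            topology.atom_index(nxt[0], nxt[1], "CA"),
        ]
        n1_N = seg[3]
        n1_H: int | None = None
        for hname in ("H", "HN", "H1", "HN1"):
            try:
                n1_H = topology.atom_index(nxt[0], nxt[1], hname)
                break
            except MalformedResidueError:
                continue
        prev_C: int | None = None
        if i > 0:
            c0, r0, _ = resk[i - 1]
            if c0 == chain and r0 == resid - 1:
                try:
                    prev_C = topology.atom_index(c0, r0, "C")
                except MalformedResidueError:
                    prev_C = None
        sites.append(
            AsnSite(
                protein_id=str(protein_id),
                asn_residue=int(resid),
                next_residue_name=str(nxt[2]),
                fragment_atoms=np.array(frag),
                segment_atoms=np.array(seg),
                n1_N=int(n1_N),
                n1_H=n1_H,
                chain=str(chain),
                label=ann_lookup.get(int(resid), "unknown"),
                prev_C=prev_C,
            )
        )
    return sites


def fragment_coords(ensemble: TrajectoryEnsemble, site: AsnSite) -> np.ndarray:
    """(n_frames, 10, 3) fragment coordinates in nm."""
    return ensemble.coords[:, site.fragment_atoms, :]
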