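"""Desk-scale synthetic ensembles and feature tables with known ground truth.

Nothing here is a physical MD model: each generator realises exactly the
statistical structure one descriptor measures — a controllable first-shell
water count for CN, rigid ideal/impossible H-bond geometries for the
H-bond classes, a discrete conformer mixture with chosen populations for
the PC1 free-energy profile, and a point-charge layout for the field
descriptors — so every module's output can be asserted against analytic
truth. The reference states shipped with a fixture are hand-constructed
synthetic stand-ins for the QM-derived R/R*/dipole inputs, with the
defining property preserved (R and R* differ only in the N_(n+1)–Cγ
distance).

Fixture files are written through :mod:`deamidkit.ensemble_io`'s writers so
the I/O paths are exercised rather than bypassed.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .conformation import KB_KCAL_MOL_K, ReferenceStates
from .ensemble_io import Topology, TrajectoryEnsemble, write_ensemble
from .featureset import FEATURES

__all__ = [
    "FixtureSpec",
    "base_fragment_geometry",
    "make_reference_states",
    "make_toy_ensemble",
    "make_feature_dataset",
    "write_fixture",
]

#: hand-built Asn–Gly fragment heavy-atom geometry (nm), canonical order:
#: Asn N, CA, CB, CG, ND2, OD1, C, O; Gly N, CA.  Bond lengths are
#: plausible but the geometry is synthetic, not an optimised structure.
_BASE_FRAGMENT = np.array(
    [
        [0.000, 0.000, 0.000],   # N
        [0.147, 0.000, 0.000],   # CA
        [0.196, 0.144, 0.030],   # CB
        [0.343, 0.160, 0.000],   # CG
        [0.400, 0.270, 0.050],   # ND2
        [0.400, 0.070, -0.060],  # OD1
        [0.200, -0.120, 0.085],  # C
        [0.150, -0.230, 0.060],  # O
        [0.320, -0.100, 0.150],  # N (n+1)
        [0.390, -0.210, 0.210],  # CA (n+1)
    ]
)

_FRAGMENT_NAMES = ["N", "CA", "CB", "CG", "ND2", "OD1", "C", "O"]


def base_fragment_geometry() -> np.ndarray:
    """Copy of the canonical 10-atom fragment geometry (nm)."""
    return _BASE_FRAGMENT.copy()


def make_reference_states(d_rstar: float = 0.25) -> ReferenceStates:
    """Synthetic stand-in reference states.

    R is the base fragment; R* is identical except the (n+1) N is moved
    along the N–Cγ axis to ``d_rstar`` nm from Cγ (ring-closure approach).
    The dipoles are synthetic but distinct in direction and magnitude
    (|mu| of order 0.1 e·nm ≈ 5 D, amide-scale).
    """
    R = base_fragment_geometry()
    Rstar = R.copy()
    cg, n1 = R[3], R[8]
    u = (n1 - cg) / np.linalg.norm(n1 - cg)
    Rstar[8] = cg + d_rstar * u
    return ReferenceStates(
        R_geometry=R,
        Rstar_geometry=Rstar,
        mu_R=np.array([0.083, 0.000, 0.000]),
        mu_TS=np.array([0.020, 0.100, 0.000]),
    )


@dataclass
class FixtureSpec:
    """Declarative description of a toy ensemble.

    ``water_shell`` = (count inside 0.4 nm of the (n+1) N, bulk number
    density in nm^-3; bulk waters are kept outside 0.45 nm so the shell
    count is the exact CN truth). ``conformer_model`` lists
    (population, 10x3 geometry) states; default a single state at the
    reactant reference. ``hbond_model`` switches ideal rigid partners per
    class on/off. ``charge_layout`` lists (charge e, xyz position nm) fixed
    point sources.
    """

    n_frames: int = 100
    n_replicates: int = 1
    box: float = 3.0
    water_shell: tuple[int, float] = (0, 0.0)
    conformer_model: list[tuple[float, np.ndarray]] | None = None
    hbond_model: dict = dc_field(default_factory=dict)
    charge_layout: list[tuple[float, tuple[float, float, float]]] = dc_field(default_factory=list)
    jitter: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conformer_model is not None:
            pops = [p for p, _ in self.conformer_model]
            if abs(sum(pops) - 1.0) > 1e-9 or any(p < 0 for p in pops):
                raise ValueError("conformer populations must be >=0 and sum to 1")
        if self.water_shell[0] < 0 or self.water_shell[1] < 0:
            raise ValueError("water counts/densities must be non-negative")
        if self.box <= 1.0:
            raise ValueError("box too small for minimum-image validity")


def _independent_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Superposition RMSD via scipy's align_vectors (independent of the
    package's own Kabsch path)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(bc, ac)
    return float(np.sqrt(np.mean(np.sum((rot.apply(ac) - bc) ** 2, axis=1))))


def make_toy_ensemble(spec: FixtureSpec) -> tuple[TrajectoryEnsemble, dict]:
    """Build a toy Asn–Gly ensemble plus its ground-truth record.

    The ground truth carries the analytic CN (shell count), the expected
    H-bond percentage per class, the conformer populations and the
    free-energy gap they imply at the generation temperature, the expected
    reactant-like mask fraction, and the charge layout for field oracles.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.full(3, spec.box / 2.0)
    states = spec.conformer_model or [(1.0, base_fragment_geometry())]
    geoms = [np.asarray(g, dtype=float) for _, g in states]
    pops = np.array([p for p, _ in states])

    base = geoms[0]
    n1 = base[8]
    frag_centroid = base.mean(axis=0)

    # --- static atom table -------------------------------------------------
    names: list[str] = []
    elements: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    chains: list[str] = []
    charges: list[float] = []

    def add(name, element, resname, resid, chain, charge=0.0):
        names.append(name)
        elements.append(element)
        resnames.append(resname)
        resids.append(resid)
        chains.append(chain)
        charges.append(charge)

    for nm in _FRAGMENT_NAMES:
        add(nm, nm[0], "ASN", 1, "A")
    add("N", "N", "GLY", 2, "A")
    add("H", "H", "GLY", 2, "A")
    add("CA", "C", "GLY", 2, "A")
    frag_rows = [0, 1, 2, 3, 4, 5, 6, 7, 8, 10]  # heavy fragment atoms
    h_row = 9

    # amide H direction: 0.10 nm from N1, pointing away from the backbone
    away = n1 - 0.5 * (base[6] + base[9])
    away /= np.linalg.norm(away)

    # ideal H-bond partners (separate non-water residue "PTN"); their
    # positions are recomputed per frame from the jittered amide geometry so
    # each enabled class stays exactly satisfied in every frame
    next_resid = 3
    hb = {k: bool(spec.hbond_model.get(k, False)) for k in ("N_donor", "N_acceptor", "O_acceptor")}
    n_partner_atoms = 0
    if hb["N_donor"]:
        add("OX", "O", "PTN", next_resid, "A")
        n_partner_atoms += 1
        next_resid += 1
    if hb["N_acceptor"]:
        add("OY", "O", "PTN", next_resid, "A")
        add("HY", "H", "PTN", next_resid, "A")
        n_partner_atoms += 2
        next_resid += 1
    if hb["O_acceptor"]:
        add("OZ", "O", "PTN", next_resid, "A")
        add("HZ", "H", "PTN", next_resid, "A")
        n_partner_atoms += 2
        next_resid += 1

    def _partner_positions(frag_now: np.ndarray, h_now: np.ndarray) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        n1_now = frag_now[8]
        cen_now = frag_now.mean(axis=0)
        if hb["N_donor"]:
            # acceptor O collinear with the N1-H axis, H...A = 0.19 nm
            u = h_now - n1_now
            u /= np.linalg.norm(u)
            out.append(h_now + 0.19 * u)
        if hb["N_acceptor"]:
            # hydroxyl donor pointing straight at N1 from outside
            u = n1_now - cen_now
            u /= np.linalg.norm(u)
            u = _rotate_away(u, (h_now - n1_now) / np.linalg.norm(h_now - n1_now))
            out.extend([n1_now + 0.29 * u, n1_now + 0.19 * u])
        if hb["O_acceptor"]:
            o_now = frag_now[7]
            u = o_now - cen_now
            u /= np.linalg.norm(u)
            out.extend([o_now + 0.29 * u, o_now + 0.19 * u])
        return out

    shell_count, bulk_density = spec.water_shell
    n_bulk = int(np.floor(bulk_density * spec.box**3))
    water_rows_start = len(names)
    wres = 1
    for _ in range(shell_count + n_bulk):
        add("OW", "O", "SOL", wres, "W")
        add("HW1", "H", "SOL", wres, "W")
        add("HW2", "H", "SOL", wres, "W")
        wres += 1

    ion_rows_start = len(names)
    for qi, (q, _) in enumerate(spec.charge_layout):
        add("Q", "NA", "ION", qi + 1, "I", q)

    topo = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        chains=np.array(chains, dtype=object),
        charges=np.array(charges, dtype=float),
        masses=np.array(
            [{"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "NA": 22.99}.get(e, 12.011)
             for e in elements],
            dtype=float,
        ),
    )

    # --- frames ------------------------------------------------------------
    n_total = spec.n_frames * spec.n_replicates
    coords = np.empty((n_total, len(names), 3))
    state_draws = rng.choice(len(states), size=n_total, p=pops)
    for f in range(n_total):
        g = geoms[state_draws[f]] + rng.normal(0.0, spec.jitter, size=(10, 3))
        frame = np.empty((len(names), 3))
        frame[frag_rows] = g + center
        # amide H rides the jittered N so the covalent bond stays intact
        frame[h_row] = g[8] + center + 0.10 * away + rng.normal(0.0, 0.2 * spec.jitter, 3)
        for k, p in enumerate(_partner_positions(frame[frag_rows], frame[h_row])):
            frame[water_rows_start - n_partner_atoms + k] = p
        row = water_rows_start
        n1_abs = frame[8]  # actual (jittered) position of the n+1 N
        avoid = [frame[h_row]] + [frame[water_rows_start - n_partner_atoms + k]
                                  for k in range(n_partner_atoms)]
        for _ in range(shell_count):
            while True:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                o = n1_abs + rng.uniform(0.26, 0.38) * u
                if all(np.linalg.norm(o - a) > 0.15 for a in avoid):
                    break
            frame[row] = o
            frame[row + 1] = o + 0.095 * _random_unit(rng)
            frame[row + 2] = o + 0.095 * _random_unit(rng)
            row += 3
        for _ in range(n_bulk):
            while True:
                o = rng.uniform(0.0, spec.box, 3)
                if np.linalg.norm(_min_image(o - n1_abs, spec.box)) > 0.45:
                    break
            frame[row] = o
            frame[row + 1] = o + 0.095 * _random_unit(rng)
            frame[row + 2] = o + 0.095 * _random_unit(rng)
            row += 3
        for k, (_, pos) in enumerate(spec.charge_layout):
            frame[ion_rows_start + k] = np.asarray(pos, dtype=float)
        coords[f] = frame

    ensemble = TrajectoryEnsemble(
        topology=topo,
        coords=coords,
        box=np.full((n_total, 3), spec.box),
        replicate_id=np.repeat(np.arange(spec.n_replicates), spec.n_frames),
    )

    refs = make_reference_states()
    rmsds = [_independent_rmsd(g, refs.R_geometry) for g in geoms]
    mask_fraction = float(np.sum(pops[np.array(rmsds) < 0.15]))
    truth = {
        "cn_expected": float(shell_count),
        "hbond_expected": {
            "N_donor": 100.0 if hb["N_donor"] else 0.0,
            "N_acceptor": 100.0 if hb["N_acceptor"] else 0.0,
            "O_acceptor": 100.0 if hb["O_acceptor"] else 0.0,
        },
        "populations": pops.tolist(),
        "state_rmsd_to_R": rmsds,
        "mask_fraction_expected": mask_fraction,
        "charge_layout": [(float(q), tuple(map(float, p))) for q, p in spec.charge_layout],
        "state_draws": state_draws,
        "kT_310": KB_KCAL_MOL_K * 310.0,
    }
    return ensemble, truth


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _min_image(d, box):
    return d - box * np.round(d / box)


def _rotate_away(u: np.ndarray, blocked: np.ndarray) -> np.ndarray:
    """Nudge direction u away from 'blocked' if nearly parallel (avoids the
    acceptor partner colliding with the donor partner or the amide H)."""
    if abs(float(u @ blocked)) > 0.9:
        v = np.cross(blocked, [0.0, 0.0, 1.0])
        if np.linalg.norm(v) < 1e-6:
            v = np.cross(blocked, [0.0, 1.0, 0.0])
        return v / np.linalg.norm(v)
    return u


# ---------------------------------------------------------------------------
# labeled feature tables
# ---------------------------------------------------------------------------

#: class-conditional generative model: nonreactive mean, per-feature sd, and
#: the sign of the reactive-class shift (matching each feature's expected
#: mechanistic role: solvation/electrostatic spread/stabilisation up,
#: H-bond engagement and conformational cost down).
_TABLE_MODEL = {
    "CN": (1.5, 0.8, +1),
    "VolE": (40.0, 15.0, +1),
    "pctN": (45.0, 15.0, -1),
    "pctNH": (50.0, 15.0, -1),
    "dAconf": (6.0, 2.0, -1),
    "RCS": (15.0, 12.0, +1),
}


def make_feature_dataset(
    n_sites: int = 63,
    n_positive: int = 13,
    effect: float | dict = 1.75,
    noise: float | np.ndarray = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian class-conditional 6-feature table with study-scale balance.

    Defaults mirror the reference dataset size (63 sites, 13 reactive).
    ``effect`` is the reactive-class mean shift in units of each feature's
    sd (scalar, or per-feature dict); shift signs follow the mechanistic
    expectations. The default 1.75 sd per feature gives a ~4.3 sd
    Mahalanobis separation in the 6-D space. ``noise`` scales the per-class
    sds (scalar) or is a full 6x6 covariance. Percentages are clipped to
    [0, 100], CN/dAconf/VolE to >= 0, RCS to [0, 100].
    """
    if not 0 < n_positive < n_sites:
        raise ValueError("need 0 < n_positive < n_sites")
    rng = np.random.default_rng(seed)
    shifts = {f: (effect[f] if isinstance(effect, dict) else effect) for f in FEATURES}
    mu0 = np.array([_TABLE_MODEL[f][0] for f in FEATURES])
    sd = np.array([_TABLE_MODEL[f][1] for f in FEATURES])
    sign = np.array([_TABLE_MODEL[f][2] for f in FEATURES])
    mu1 = mu0 + sign * np.array([shifts[f] for f in FEATURES]) * sd
    if np.isscalar(noise):
        cov = np.diag((sd * float(noise)) ** 2)
    else:
        cov = np.asarray(noise, dtype=float)
        if cov.shape != (6, 6):
            raise ValueError("noise covariance must be 6x6")
        np.linalg.cholesky(cov)  # raises if not positive definite

    n_neg = n_sites - n_positive
    X0 = rng.multivariate_normal(mu0, cov, size=n_neg)
    X1 = rng.multivariate_normal(mu1, cov, size=n_positive)
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_positive, dtype=int)])
    df = pd.DataFrame(X, columns=FEATURES)
    for col in ("pctN", "pctNH", "RCS"):
        df[col] = df[col].clip(0.0, 100.0)
    for col in ("CN", "VolE", "dAconf"):
        df[col] = df[col].clip(lower=0.0)
    df["label"] = y
    df.insert(0, "residue", np.arange(1, n_sites + 1))
    df.insert(0, "protein_id", "synthetic")
    order = rng.permutation(n_sites)
    return df.iloc[order].reset_index(drop=True)


def write_fixture(outdir, spec: FixtureSpec | None = None) -> dict:
    """Emit a complete on-disk fixture: multi-model PDB topology+frames,
    charge sidecar CSV, annotation CSV and synthetic reference-state JSON.

    Returns the paths plus the ground-truth record.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or FixtureSpec(
        n_frames=20, n_replicates=2, water_shell=(3, 0.0),
        hbond_model={"N_donor": True},
        charge_layout=[(1.0, (0.5, 0.5, 0.5))],
        # jitter wide enough that PC1 visits the reactive-like readings,
        # so the default fixture's dA_conf is finite
        jitter=0.02,
    )
    ensemble, truth = make_toy_ensemble(spec)
    paths = {
        "topology": outdir / "fixture.pdb",
        "charges": outdir / "fixture_charges.csv",
        "annotations": outdir / "fixture_annotations.csv",
        "references": outdir / "fixture_references.json",
    }
    write_ensemble(ensemble, paths["topology"], charge_table_path=paths["charges"])
    pd.DataFrame(
        [{"protein_id": "fixture", "residue_number": 1, "label": "Yes"}]
    ).to_csv(paths["annotations"], index=False)
    make_reference_states().to_json(paths["references"])
    truth.pop("state_draws", None)
    return {"paths": {k: str(v) for k, v in paths.items()}, "ground_truth": truth}
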