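"""Assembly of per-site descriptors into the 6-feature ML table.

The model inputs are exactly the six mechanism-driven descriptors:

======== ============== ============== =======================================
feature  reaction step  group          expected role
======== ============== ============== =======================================
CN       deprotonation  solvation      high CN promotes reactivity
VolE     deprotonation  electrostatics large spread increases reactivity
pctN     deprotonation  H-bonds        high % (N acceptor) reduces reactivity
pctNH    deprotonation  H-bonds        high % (N-H donor) reduces reactivity
dAconf   ring-closure   conformation   low values increase reactivity
RCS      ring-closure   electrostatics strong stabilisation favours reactivity
======== ============== ============== =======================================

Sites whose fragment never sampled a reactive-like conformation carry a
dA_conf sentinel; at assembly it resolves to ten times the dataset maximum
finite dA_conf, and RCS is then (re)computed with the table-wide maximum so
sentinel sites get RCS = 0 exactly.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "FEATURE_GROUPS",
    "SENTINEL_FACTOR",
    "assemble",
    "replicate_error",
    "feature_correlation",
]

FEATURES = ["CN", "VolE", "pctN", "pctNH", "dAconf", "RCS"]

#: chemically motivated feature groups used for grouped LOFO importance
FEATURE_GROUPS = {
    "Conf": ["dAconf"],
    "Solv": ["CN"],
    "HB": ["pctN", "pctNH"],
    "El": ["VolE", "RCS"],
}

SENTINEL_FACTOR = 10.0

LABEL_CODES = {"reactive": 1, "nonreactive": 0}


class IncompletePipelineError(ValueError):
    """A labeled site is missing a descriptor result."""


def assemble(records: list[dict]) -> pd.DataFrame:
    """Build the ML feature table from per-site descriptor records.

    Each record must carry ``protein_id``, ``residue``, ``label``
    (reactive/nonreactive/unknown), the four direct features (``CN``,
    ``VolE``, ``pctN``, ``pctNH``), ``dAconf`` (finite, or inf as the
    no-reactive-conformation sentinel) and ``rcs_delta_term`` (the
    Delta(E·mu) factor measured over reactant-like frames — already a
    percentage or a mean energy depending on the configured mode).

    Resolution is two-pass: (1) the dataset maximum of finite dA_conf is
    found and sentinel sites are set to ``SENTINEL_FACTOR`` times it;
    (2) RCS is computed with dA_max = the resolved table maximum, so
    sentinel sites end at RCS = 0. Unlabeled sites are excluded from the
    returned table. Passing an already-assembled table through changes
    nothing (idempotence).
    """
    needed = {"protein_id", "residue", "label", "CN", "VolE", "pctN", "pctNH",
              "dAconf", "rcs_delta_term"}
    rows = []
    for rec in records:
        missing = needed - set(rec)
        if missing - {"rcs_delta_term"}:
            raise IncompletePipelineError(
                f"site {rec.get('protein_id')}:{rec.get('residue')} missing {sorted(missing)}"
            )
        if "rcs_delta_term" not in rec:
            # already-assembled row: invert RCS only if dAconf known finite
            raise IncompletePipelineError("record lacks rcs_delta_term")
        rows.append(dict(rec))

    labeled = [r for r in rows if r["label"] in LABEL_CODES]
    if not labeled:
        raise ValueError("no labeled sites to assemble")

    dvals = np.array([r["dAconf"] for r in labeled], dtype=float)
    finite = dvals[np.isfinite(dvals)]
    if len(finite) == 0:
        raise ValueError("every site carries the conformational sentinel")
    sentinel_value = SENTINEL_FACTOR * float(finite.max())
    resolved = np.where(np.isfinite(dvals), dvals, sentinel_value)
    dAmax = float(resolved.max())

    out = []
    for r, dA, raw in zip(labeled, resolved, dvals):
        rcs = 0.0 if not np.isfinite(raw) else r["rcs_delta_term"] * (1.0 - dA / dAmax)
        out.append(
            {
                "protein_id": r["protein_id"],
                "residue": int(r["residue"]),
                "CN": float(r["CN"]),
                "VolE": float(r["VolE"]),
                "pctN": float(r["pctN"]),
                "pctNH": float(r["pctNH"]),
                "dAconf": float(dA),
                "RCS": float(rcs),
                "label": LABEL_CODES[r["label"]],
            }
        )
    table = pd.DataFrame(out)
    _validate(table)
    return table


def _validate(table: pd.DataFrame) -> None:
    if table[FEATURES].isna().any().any():
        raise ValueError("missing values after sentinel resolution")
    for col in ("pctN", "pctNH"):
        if ((table[col] < 0) | (table[col] > 100)).any():
            raise ValueError(f"{col} outside [0, 100]")
    if (table["dAconf"] < 0).any() or (table["VolE"] < 0).any():
        raise ValueError("negative dAconf or VolE")


def compute_records(ensemble, sites, refs, include_water: bool = False,
                    rcs_mode: str = "percent") -> list[dict]:
    """Run every descriptor for every site and return assemble-ready records.

    Convenience driver over the descriptor modules: CN from the water RDF,
    VolE on the shared dataset extent, the two N-based H-bond percentages,
    dA_conf from the R and R* local PCAs, and the RCS Delta(E·mu) term over
    reactant-like frames. Sentinels are left unresolved (that is
    :func:`assemble`'s job).
    """
    from . import conformation, electrostatics, hbond, solvation

    series = {id(s): electrostatics.field_series(ensemble, s) for s in sites}
    extent = electrostatics.dataset_extent(list(series.values()))
    records = []
    for site in sites:
        rdf = solvation.radial_distribution(ensemble, site)
        cn = solvation.coordination_number(rdf)
        vol = electrostatics.field_spread_volume(series[id(site)], extent=extent)
        prof_hb = hbond.classify_amide_hbonds(ensemble, site, include_water=include_water)
        profiles = {}
        for name, geom in (("R", refs.R_geometry), ("Rstar", refs.Rstar_geometry)):
            model = conformation.local_pca(ensemble, [site], geom)
            pc1 = model.project(ensemble.coords[:, site.fragment_atoms, :], 1)[:, 0]
            profiles[name] = conformation.free_energy_profile(pc1)
        dA = conformation.conf_free_energy_feature(profiles)
        mask = electrostatics.reactive_frame_mask(ensemble, site, refs.R_geometry)
        rcs = electrostatics.ring_closure_stabilization(
            series[id(site)], mask, refs, dAconf=0.0, dAmax=1.0, mode=rcs_mode
        )
        records.append(
            {
                "protein_id": site.protein_id,
                "residue": site.asn_residue,
                "label": site.label,
                "CN": cn,
                "VolE": vol["VolE"],
                "pctN": prof_hb.pct_N_acceptor,
                "pctNH": prof_hb.pct_N_donor,
                "pctO": prof_hb.pct_O_acceptor,
                "dAconf": dA,
                "rcs_delta_term": (
                    rcs.pct_favoring if rcs_mode == "percent" else rcs.mean_delta
                ),
            }
        )
    return records


def replicate_error(values) -> float:
    """Half the sample standard deviation across replicate-level estimates.

    The convention used for all descriptor error bars; undefined (None) for
    a single replicate.
    """
    v = np.asarray(list(values), dtype=float)
    if len(v) < 2:
        return None
    return 0.5 * float(np.std(v, ddof=1))


def feature_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """6x6 Pearson matrix of the features; zero-variance columns give NaN."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlations")
    sub = table[FEATURES]
    zero_var = sub.std(ddof=0) == 0
    corr = sub.corr(method="pearson")
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    np.fill_diagonal(corr.values, np.where(zero_var, np.nan, 1.0))
    return corr
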