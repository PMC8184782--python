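"""Desk-scale synthetic inputs with the statistical structure of the study.

Trajectory side: a toy two-domain protein in crystal-structure numbering —
a rigid "pseudokinase" body (residues placed inside 179–464), a rigid
four-helix-bundle stand-in, a brace helix, an activation-loop helix
(residues 343–352) that reorients per frame against a static adjacent helix
(residues 228–240), and a K219(NZ)/Q343(OE1) pseudo-atom pair toggling
between bonded (2.8 Å) and broken (6.0 Å) geometry with a configured
probability.  Per-frame loop-helix and interdomain angles are drawn from
reflected (wrapped-to-[0,180]) normal distributions, so the analysis
pipeline's estimates can be checked against known generating parameters.
Ten replicates of frames at fixed 10 ps spacing mirror the study design.

Histology side: FOV severity grids with controlled class proportions.

Nothing here is physically meaningful dynamics — it is the statistical
scaffolding the estimators assume, at a size that runs in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import helix_axis, principal_axis
from .lesion_score import SEVERITY_SCORES, FovGrid
from .trajectory_io import (
    AtomRecord,
    AtomTable,
    ConformationFrame,
    TrajectoryEnsemble,
    write_multimodel_pdb,
)

__all__ = [
    "TrajectoryGenParams",
    "GridGenParams",
    "CONSTRUCT_PRESETS",
    "build_ideal_helix",
    "generate_trajectory_ensemble",
    "generate_reference_frame",
    "generate_fov_grid",
]

# Ideal alpha-helix Cα trace parameters
HELIX_RISE = 1.5       # Å per residue
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Å

HBOND_FORMED_DISTANCE = 2.8  # Å, donor placed here when the bond is "on"
HBOND_BROKEN_DISTANCE = 6.0  # Å, otherwise


@dataclass(frozen=True)
class TrajectoryGenParams:
    """Generator settings; defaults mirror the study design at desk scale.

    Ten replicates with snapshots every 10 ps follow the simulation setup;
    1000 frames per replicate (10 ns equivalent) is the desk-scale stand-in
    for the 1 µs production runs.  Angle means/SDs and the H-bond probability
    are the recoverable "truth" of the generator; 0.14 is the wild-type
    occupancy scenario.
    """

    construct_name: str = "synthetic:wt"
    n_replicates: int = 10
    n_frames: int = 1000
    frame_spacing_ps: float = 10.0
    loop_angle_mean: float = 65.0    # degrees
    loop_angle_sd: float = 5.0
    domain_angle_mean: float = 60.0  # degrees
    domain_angle_sd: float = 10.0
    hbond_probability: float = 0.14
    coord_noise_sd: float = 0.1      # Å, isotropic per coordinate
    hinge_amplitude: float = 0.0     # degrees, extra 4HB wobble about a second axis
    angle_autocorr: float = 0.0      # AR(1) coefficient for angle series
    with_ubiquitin: bool = False     # extra chain-B moiety, excluded from selections
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_frames < 1:
            raise ValueError("need at least one replicate and one frame")
        if min(self.loop_angle_sd, self.domain_angle_sd, self.coord_noise_sd,
               self.hinge_amplitude) < 0:
            raise ValueError("spreads must be non-negative")
        if not 0.0 <= self.hbond_probability <= 1.0:
            raise ValueError("hbond_probability must lie in [0, 1]")
        if not -1.0 < self.angle_autocorr < 1.0:
            raise ValueError("angle_autocorr must lie in (-1, 1)")


#: Qualitative construct presets (synthetic stand-ins, not fitted values):
#: WT keeps the K219::Q343 bond ~14% of the time with the loop helix near its
#: crystal-like orientation; phosphorylation breaks the bond and reorients the
#: loop helix; the ubiquitylated+phosphorylated form additionally packs the
#: 4HB closer on average but with a wider spread.
CONSTRUCT_PRESETS: dict[str, TrajectoryGenParams] = {
    "WT": TrajectoryGenParams(construct_name="WT", hbond_probability=0.14,
                              loop_angle_mean=65.0, loop_angle_sd=5.0,
                              domain_angle_mean=60.0, domain_angle_sd=10.0),
    "S345phos": TrajectoryGenParams(construct_name="S345phos", hbond_probability=0.02,
                                    loop_angle_mean=80.0, loop_angle_sd=8.0,
                                    domain_angle_mean=75.0, domain_angle_sd=10.0),
    "K219ub_S345phos": TrajectoryGenParams(construct_name="K219ub_S345phos",
                                           hbond_probability=0.02,
                                           loop_angle_mean=78.0, loop_angle_sd=8.0,
                                           domain_angle_mean=55.0, domain_angle_sd=15.0,
                                           with_ubiquitin=True),
}


def build_ideal_helix(
    n_residues: int,
    start_residue_id: int = 1,
    chain_id: str = "A",
    residue_name: str = "ALA",
) -> tuple[np.ndarray, list[AtomRecord]]:
    """Ideal α-helix Cα trace along +z (1.5 Å rise, 100° twist, 2.3 Å radius).

    Returns the (n, 3) coordinates, centred on the helix midpoint, and the
    matching CA AtomRecords.
    """
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues")
    k = np.arange(n_residues)
    phi = np.radians(HELIX_TWIST) * k
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(phi),
        HELIX_RADIUS * np.sin(phi),
        HELIX_RISE * k,
    ])
    coords -= coords.mean(axis=0)
    records = [
        AtomRecord("CA", residue_name, start_residue_id + int(i), chain_id, coords[i])
        for i in k
    ]
    return coords, records


def _rot_y(theta_deg: np.ndarray) -> np.ndarray:
    t = np.radians(np.atleast_1d(theta_deg))
    c, s = np.cos(t), np.sin(t)
    R = np.zeros((t.size, 3, 3))
    R[:, 0, 0] = c; R[:, 0, 2] = s
    R[:, 1, 1] = 1.0
    R[:, 2, 0] = -s; R[:, 2, 2] = c
    return R


def _rot_x(theta_deg: np.ndarray) -> np.ndarray:
    t = np.radians(np.atleast_1d(theta_deg))
    c, s = np.cos(t), np.sin(t)
    R = np.zeros((t.size, 3, 3))
    R[:, 0, 0] = 1.0
    R[:, 1, 1] = c; R[:, 1, 2] = -s
    R[:, 2, 1] = s; R[:, 2, 2] = c
    return R


def fold_to_axis_range(x: np.ndarray) -> np.ndarray:
    """Reflect angles into [0, 180] (wrapped-normal sampling by reflection)."""
    y = np.mod(np.asarray(x, dtype=float), 360.0)
    return np.where(y > 180.0, 360.0 - y, y)


@dataclass(frozen=True)
class _Template:
    """Static assembly of the toy protein plus index groups for per-frame motion."""

    table: AtomTable
    coords: np.ndarray
    loop_idx: np.ndarray
    fourhb_idx: np.ndarray
    donor_idx: int
    acceptor_idx: int
    loop_centroid: np.ndarray
    fourhb_centroid: np.ndarray
    acceptor_pos: np.ndarray


def _build_template(with_ubiquitin: bool) -> _Template:
    pieces: list[tuple[str, np.ndarray, list[AtomRecord]]] = []

    def helix(n, start, offset, chain="A", resname="ALA"):
        coords, recs = build_ideal_helix(n, start, chain, resname)
        coords = coords + np.asarray(offset, dtype=float)
        recs = [replace(r, coords=c) for r, c in zip(recs, coords)]
        return coords, recs

    # 4HB stand-in: two parallel helices, body centred at (-30, 0, 0)
    pieces.append(("4hb", *helix(30, 10, (-26.0, 0.0, 0.0))))
    pieces.append(("4hb", *helix(30, 45, (-34.0, 0.0, 0.0))))
    # brace helix, static
    pieces.append(("static", *helix(21, 140, (-15.0, 10.0, 0.0))))
    # pseudokinase body: two long helices about the origin
    pieces.append(("static", *helix(30, 185, (4.0, 0.0, 0.0))))
    # K219 donor pseudo-atom (position overwritten per frame)
    donor_rec = AtomRecord("NZ", "LYS", 219, "A", np.array([22.8, 0.0, 0.0]))
    pieces.append(("donor", donor_rec.coords[None, :], [donor_rec]))
    # adjacent helix (contains T235), static part of the pseudokinase body
    pieces.append(("adjacent", *helix(13, 228, (12.0, 0.0, 0.0))))
    # activation-loop helix, reoriented per frame about its centroid
    loop_coords, loop_recs = helix(10, 343, (12.0, 8.0, 0.0))
    loop_recs[0] = replace(loop_recs[0], residue_name="GLN")
    pieces.append(("loop", loop_coords, loop_recs))
    # Q343 acceptor pseudo-atom, fixed
    acceptor_rec = AtomRecord("OE1", "GLN", 343, "A", np.array([20.0, 0.0, 0.0]))
    pieces.append(("acceptor", acceptor_rec.coords[None, :], [acceptor_rec]))
    # long C-lobe helices keep the pseudokinase principal axis firmly on z,
    # so the moving loop helix barely tilts the domain-axis estimate
    pieces.append(("static", *helix(40, 380, (-4.0, 0.0, 0.0))))
    pieces.append(("static", *helix(40, 425, (0.0, -8.0, 0.0))))
    if with_ubiquitin:
        # ubiquitin moiety stand-in on its own chain, excluded from selections
        pieces.append(("static", *helix(10, 1, (0.0, -20.0, 0.0), chain="B", resname="UBQ")))

    names, resnames, resids, chains, coords_list = [], [], [], [], []
    groups: dict[str, list[int]] = {"4hb": [], "loop": [], "adjacent": [],
                                    "donor": [], "acceptor": []}
    i = 0
    for tag, coords, recs in pieces:
        for rec in recs:
            names.append(rec.atom_name)
            resnames.append(rec.residue_name)
            resids.append(rec.residue_id)
            chains.append(rec.chain_id)
            coords_list.append(rec.coords)
            if tag in groups:
                groups[tag].append(i)
            i += 1

    table = AtomTable(tuple(names), tuple(resnames), tuple(resids), tuple(chains))
    coords = np.array(coords_list)
    fourhb_idx = np.array(groups["4hb"], dtype=int)
    loop_idx = np.array(groups["loop"], dtype=int)
    adjacent_idx = np.array(groups["adjacent"], dtype=int)

    # Rotate each orientable piece until its *measured* axis (the estimator
    # the metrics use: helix_axis for the helices, raw principal axis for the
    # 4HB domain) is exactly +z, so configured angles hold by construction.
    for idx, estimator in ((loop_idx, helix_axis), (adjacent_idx, helix_axis),
                           (fourhb_idx, principal_axis)):
        centroid = coords[idx].mean(axis=0)
        axis = estimator(coords[idx])
        rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
        coords[idx] = (coords[idx] - centroid) @ rot.as_matrix().T + centroid
    return _Template(
        table=table,
        coords=coords,
        loop_idx=loop_idx,
        fourhb_idx=fourhb_idx,
        donor_idx=groups["donor"][0],
        acceptor_idx=groups["acceptor"][0],
        loop_centroid=coords[loop_idx].mean(axis=0),
        fourhb_centroid=coords[fourhb_idx].mean(axis=0),
        acceptor_pos=coords[groups["acceptor"][0]].copy(),
    )


def _sample_angles(rng: np.random.Generator, n: int, mean: float, sd: float,
                   phi: float) -> np.ndarray:
    """Reflected-normal angle series, optionally AR(1)-correlated."""
    if sd == 0:
        return np.full(n, float(mean))
    if phi == 0:
        raw = rng.normal(mean, sd, size=n)
    else:
        eps = rng.normal(0.0, 1.0, size=n)
        x = np.empty(n)
        x[0] = sd * eps[0]
        innov_sd = sd * math.sqrt(1.0 - phi * phi)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov_sd * eps[t]
        raw = mean + x
    return fold_to_axis_range(raw)


def _assemble_replicate(template: _Template, params: TrajectoryGenParams,
                        rng: np.random.Generator) -> list[ConformationFrame]:
    n = params.n_frames
    theta_loop = _sample_angles(rng, n, params.loop_angle_mean,
                                params.loop_angle_sd, params.angle_autocorr)
    theta_dom = _sample_angles(rng, n, params.domain_angle_mean,
                               params.domain_angle_sd, params.angle_autocorr)
    hinge = (rng.normal(0.0, params.hinge_amplitude, size=n)
             if params.hinge_amplitude > 0 else np.zeros(n))
    bonded = rng.random(n) < params.hbond_probability

    coords = np.broadcast_to(template.coords, (n,) + template.coords.shape).copy()

    # activation-loop helix: rotate about y through its centroid
    Rl = _rot_y(theta_loop)
    loop0 = template.coords[template.loop_idx] - template.loop_centroid
    coords[:, template.loop_idx] = (
        np.einsum("fij,aj->fai", Rl, loop0) + template.loop_centroid
    )
    # 4HB body: domain angle about y, then hinge wobble about x
    Rd = np.einsum("fij,fjk->fik", _rot_x(hinge), _rot_y(theta_dom))
    body0 = template.coords[template.fourhb_idx] - template.fourhb_centroid
    coords[:, template.fourhb_idx] = (
        np.einsum("fij,aj->fai", Rd, body0) + template.fourhb_centroid
    )
    # H-bond pair: exact placement, exempt from coordinate noise
    dist = np.where(bonded, HBOND_FORMED_DISTANCE, HBOND_BROKEN_DISTANCE)
    coords[:, template.donor_idx] = template.acceptor_pos
    coords[:, template.donor_idx, 0] += dist
    coords[:, template.acceptor_idx] = template.acceptor_pos

    if params.coord_noise_sd > 0:
        noise = rng.normal(0.0, params.coord_noise_sd, size=coords.shape)
        noise[:, template.donor_idx] = 0.0
        noise[:, template.acceptor_idx] = 0.0
        coords += noise

    return [
        ConformationFrame(template.table, coords[f], frame_index=f,
                          time_ps=f * params.frame_spacing_ps)
        for f in range(n)
    ]


def generate_trajectory_ensemble(
    params: TrajectoryGenParams,
    out_dir: str | Path | None = None,
) -> TrajectoryEnsemble:
    """Seeded toy ensemble; optionally written as one multi-model PDB per replicate.

    The same seed and parameters always produce byte-identical files.  When
    *out_dir* is given, a ``manifest.csv`` (construct, replicate, file, seed)
    is written next to the PDB files.
    """
    template = _build_template(params.with_ubiquitin)
    root = np.random.SeedSequence(params.seed)
    replicates = [
        _assemble_replicate(template, params, np.random.default_rng(child))
        for child in root.spawn(params.n_replicates)
    ]
    ensemble = TrajectoryEnsemble(params.construct_name, replicates,
                                  params.frame_spacing_ps)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = params.construct_name.replace(":", "_")
        rows = []
        for r, rep in enumerate(ensemble.replicates):
            fname = f"{stem}_rep{r:02d}.pdb"
            write_multimodel_pdb(out_dir / fname, rep)
            rows.append({"construct": params.construct_name, "replicate": r,
                         "file": fname, "seed": params.seed})
        pd.DataFrame(rows).to_csv(out_dir / f"{stem}_manifest.csv", index=False)
    return ensemble


def generate_reference_frame(params: TrajectoryGenParams) -> ConformationFrame:
    """Noise-free structure at the configured mean angles with the bond formed.

    Stands in for the crystal structure: the single-frame reference against
    which the dashed histogram lines and domain-axis signs are computed.
    """
    template = _build_template(params.with_ubiquitin)
    frozen = replace(params, n_frames=1, coord_noise_sd=0.0, hinge_amplitude=0.0,
                     loop_angle_sd=0.0, domain_angle_sd=0.0, hbond_probability=1.0)
    rng = np.random.default_rng(0)  # unused: all spreads are zero
    return _assemble_replicate(template, frozen, rng)[0]


# --- FOV severity grids ----------------------------------------------------

@dataclass(frozen=True)
class GridGenParams:
    """Severity-grid generator settings.

    ``target_proportions`` maps severity class → target percent (summing to
    100).  Whole-FOV counts are allocated deterministically by flooring; the
    remainder FOVs are assigned by a seeded draw weighted by the fractional
    parts, so small grids round reproducibly instead of erroring.
    """

    n_fov: int
    target_proportions: dict[int, float]
    seed: int = 0
    specimen_id: str = "synthetic"
    genotype: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.n_fov < 1:
            raise ValueError("need at least one FOV")
        props = {int(k): float(v) for k, v in self.target_proportions.items()}
        if any(k not in SEVERITY_SCORES for k in props):
            raise ValueError("severity classes must be in 0..4")
        if any(v < 0 for v in props.values()):
            raise ValueError("proportions must be non-negative")
        if abs(sum(props.values()) - 100.0) > 1e-9:
            raise ValueError("proportions must sum to 100")
        object.__setattr__(self, "target_proportions", props)


def generate_fov_grid(params: GridGenParams) -> FovGrid:
    """Grid with class counts as close to the target proportions as n_fov allows."""
    rng = np.random.default_rng(params.seed)
    classes = sorted(params.target_proportions)
    exact = np.array([params.n_fov * params.target_proportions[c] / 100.0
                      for c in classes])
    base = np.floor(exact + 1e-9).astype(int)
    frac = exact - base
    frac[frac < 1e-9] = 0.0
    remainder = params.n_fov - int(base.sum())
    counts = dict(zip(classes, base))
    if remainder > 0:
        eligible = [c for c, f in zip(classes, frac) if f > 0]
        weights = np.array([f for f in frac if f > 0])
        if len(eligible) < remainder:  # float-rounding corner: widen the pool
            eligible = classes
            weights = np.maximum(frac, 1e-12)
        picked = rng.choice(eligible, size=remainder, replace=False,
                            p=weights / weights.sum())
        for c in np.atleast_1d(picked):
            counts[int(c)] += 1
    scores: list[int] = []
    for c in classes:
        scores.extend([c] * counts[c])
    scores = list(rng.permutation(scores))
    return FovGrid(params.specimen_id, tuple(int(s) for s in scores),
                   params.genotype, params.treatment)
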