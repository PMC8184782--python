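"""Reading and writing conformational snapshots and run configuration.

Trajectory ensembles are exchanged as multi-model PDB files (PDB v3.3
fixed-width columns, one ``MODEL``/``ENDMDL`` block per snapshot, one file
per replicate).  Residue numbering is taken verbatim from the input file —
the key MLKL residues (K219, Q343, S345) are referred to in crystal-structure
numbering throughout, so no renumbering ever happens.

Only ``ATOM`` records are read by default; ``HETATM`` records can be opted in
for pseudo-atoms named as hydrogen-bond partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "AtomTable",
    "ConformationFrame",
    "TrajectoryEnsemble",
    "DomainAnnotation",
    "PdbParseError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atoms",
    "select_atom_indices",
    "load_config",
    "DEFAULT_ANNOTATION",
    "DEFAULT_PARAMETERS",
]


class PdbParseError(ValueError):
    """Raised when a PDB file violates the fixed-width format or frame layout."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one snapshot, in file order and file numbering."""

    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    coords: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.atom_name}: coords must be a finite 3-vector")
        if self.residue_id < 1:
            raise ValueError(f"atom {self.atom_name}: residue_id must be >= 1")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class AtomTable:
    """Per-atom identity shared by every frame of a replicate.

    Separating identity from coordinates keeps a 10-replicate, thousand-frame
    ensemble cheap: frames share one table and carry only an (n, 3) array.
    """

    atom_names: tuple[str, ...]
    residue_names: tuple[str, ...]
    residue_ids: tuple[int, ...]
    chain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        if not (len(self.residue_names) == len(self.residue_ids) == len(self.chain_ids) == n):
            raise ValueError("atom table columns must have equal length")
        if any(r < 1 for r in self.residue_ids):
            raise ValueError("residue ids must be >= 1")

    def __len__(self) -> int:
        return len(self.atom_names)

    def signature(self) -> tuple:
        """Hashable atom-order fingerprint used for cross-frame consistency checks."""
        return (self.atom_names, self.residue_ids, self.chain_ids)


@dataclass(frozen=True)
class ConformationFrame:
    """A single snapshot: an atom table plus one coordinate set."""

    table: AtomTable
    coords: np.ndarray  # (n_atoms, 3), Å
    frame_index: int = 0
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape != (len(self.table), 3):
            raise ValueError(
                f"frame {self.frame_index}: coords shape {coords.shape} does not "
                f"match atom table of {len(self.table)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"frame {self.frame_index}: non-finite coordinates")
        if self.frame_index < 0 or self.time_ps < 0:
            raise ValueError("frame_index and time_ps must be non-negative")
        object.__setattr__(self, "coords", coords)

    @property
    def atoms(self) -> list[AtomRecord]:
        t = self.table
        return [
            AtomRecord(t.atom_names[i], t.residue_names[i], t.residue_ids[i],
                       t.chain_ids[i], self.coords[i])
            for i in range(len(t))
        ]

    def transformed(self, coords: np.ndarray) -> "ConformationFrame":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class TrajectoryEnsemble:
    """Replicate snapshot series for one construct (WT, S345phos, ...)."""

    construct: str
    replicates: list[list[ConformationFrame]]
    frame_spacing_ps: float = 10.0

    def __post_init__(self) -> None:
        if not self.replicates or any(not rep for rep in self.replicates):
            raise ValueError("ensemble needs at least one non-empty replicate")
        sig = self.replicates[0][0].table.signature()
        for r, rep in enumerate(self.replicates):
            for frame in rep:
                if frame.table.signature() != sig:
                    raise ValueError(
                        f"replicate {r}, frame {frame.frame_index}: atom ordering "
                        "differs from the first replicate"
                    )
            times = np.array([f.time_ps for f in rep])
            if len(times) > 1 and not np.all(np.diff(times) > 0):
                raise ValueError(f"replicate {r}: time stamps not strictly increasing")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def n_frames_total(self) -> int:
        return sum(len(rep) for rep in self.replicates)

    def iter_frames(self) -> Iterator[tuple[int, ConformationFrame]]:
        for r, rep in enumerate(self.replicates):
            for frame in rep:
                yield r, frame


@dataclass(frozen=True)
class DomainAnnotation:
    """Residue intervals (1-based, inclusive) and key atoms of the MLKL switch.

    Defaults: the pseudokinase domain is mouse MLKL residues 179–464; the
    hydrogen-bond pair is the pseudoactive-site K219(NZ) → Q343(OE1) contact.
    The activation-loop-helix and adjacent-helix boundaries are implementer
    assumptions (no published definition exists) and should be overridden when
    a better assignment is available.
    """

    fourhb_range: tuple[int, int] = (1, 130)
    brace_range: tuple[int, int] = (131, 178)
    pseudokinase_range: tuple[int, int] = (179, 464)
    loop_helix_range: tuple[int, int] = (343, 352)
    adjacent_helix_range: tuple[int, int] = (228, 240)
    hbond_donor: tuple[int, str] = (219, "NZ")
    hbond_acceptor: tuple[int, str] = (343, "OE1")
    chain_id: str = "A"

    def __post_init__(self) -> None:
        for name in ("fourhb_range", "brace_range", "pseudokinase_range",
                     "loop_helix_range", "adjacent_helix_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name}: malformed interval {lo}-{hi}")


DEFAULT_ANNOTATION = DomainAnnotation()

#: Pipeline-level defaults applied by :func:`load_config` for absent keys.
DEFAULT_PARAMETERS: dict = {
    "bin_width": 2.0,            # degrees, pooled angle histograms
    "n_permutations": 1_000_000,
    "exhaustive_cap": 1_000_000,
    "frame_spacing_ps": 10.0,
    "hbond_max_heavy_distance": 3.5,  # Å
    "hbond_min_dha_angle": 135.0,     # degrees, only with explicit hydrogens
    "seed": None,
}


# --- multi-model PDB -------------------------------------------------------
#
# Fixed columns per PDB v3.3:
#   1-6 record, 7-11 serial, 13-16 name, 18-20 resName, 22 chainID,
#   23-26 resSeq, 31-38 x, 39-46 y, 47-54 z.

def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, str, int, np.ndarray]:
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_id = int(line[22:26])
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"line {lineno}: unparsable ATOM record: {line.rstrip()!r}") from exc
    if not name:
        raise PdbParseError(f"line {lineno}: blank atom name")
    return name, res_name, chain, res_id, xyz


def read_multimodel_pdb(
    path: str | Path,
    frame_spacing_ps: float = 10.0,
    include_hetatm: bool = False,
) -> list[ConformationFrame]:
    """Read one replicate: one :class:`ConformationFrame` per ``MODEL`` block.

    A file without ``MODEL`` records yields a single frame.  Atom count and
    order must be identical across models; the first offending model is named
    in the error.
    """
    path = Path(path)
    record_types = ("ATOM",) + (("HETATM",) if include_hetatm else ())
    models: list[list[tuple]] = []
    current: list[tuple] | None = None
    saw_model = False
    skipped_hetatm = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                if current:
                    models.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                    current = None
            elif rec in record_types:
                if current is None:
                    current = []
                current.append(_parse_atom_line(line, lineno))
            elif rec == "HETATM":
                skipped_hetatm += 1
    if current:
        models.append(current)
    if skipped_hetatm:
        logger.info("%s: skipped %d HETATM records", path.name, skipped_hetatm)
    if not models:
        raise PdbParseError(f"{path}: no ATOM records found")

    first = models[0]
    key = [(a[0], a[3], a[2]) for a in first]
    for m, model in enumerate(models[1:], start=2):
        if [(a[0], a[3], a[2]) for a in model] != key:
            raise PdbParseError(
                f"{path}: model {m} has a different atom count or order than model 1"
            )

    table = AtomTable(
        atom_names=tuple(a[0] for a in first),
        residue_names=tuple(a[1] for a in first),
        residue_ids=tuple(a[3] for a in first),
        chain_ids=tuple(a[2] for a in first),
    )
    frames = [
        ConformationFrame(
            table=table,
            coords=np.array([a[4] for a in model]),
            frame_index=i,
            time_ps=i * frame_spacing_ps,
        )
        for i, model in enumerate(models)
    ]
    if saw_model and len(frames) == 1:
        logger.debug("%s: single MODEL block", path.name)
    return frames


def _format_atom_line(serial: int, name: str, res_name: str, chain: str,
                      res_id: int, xyz: np.ndarray) -> str:
    # Names shorter than 4 characters start in column 14, per convention.
    padded = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {padded:<4s} {res_name:<3s} {chain:1s}{res_id:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
    )


def write_multimodel_pdb(path: str | Path, frames: Sequence[ConformationFrame]) -> None:
    """Write frames as MODEL/ENDMDL blocks at PDB coordinate precision (3 dp)."""
    if not frames:
        raise ValueError("no frames to write")
    sig = frames[0].table.signature()
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            if frame.table.signature() != sig:
                raise ValueError(f"frame {m - 1}: atom ordering differs from frame 0")
            fh.write(f"MODEL     {m:4d}\n")
            t = frame.table
            for i in range(len(t)):
                fh.write(_format_atom_line(i + 1, t.atom_names[i], t.residue_names[i],
                                           t.chain_ids[i], t.residue_ids[i],
                                           frame.coords[i]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# --- selections ------------------------------------------------------------

def select_atom_indices(
    table: AtomTable,
    residue_range: tuple[int, int],
    atom_name: str,
    chain_id: str | None = None,
) -> np.ndarray:
    """Indices of atoms named *atom_name* in the inclusive residue interval."""
    lo, hi = residue_range
    if hi < lo:
        raise ValueError(f"malformed interval {lo}-{hi}")
    idx = [
        i for i in range(len(table))
        if lo <= table.residue_ids[i] <= hi
        and table.atom_names[i] == atom_name
        and (chain_id is None or table.chain_ids[i] == chain_id)
    ]
    if not idx:
        logger.debug("empty selection: residues %d-%d atom %s chain %s",
                     lo, hi, atom_name, chain_id)
    return np.array(idx, dtype=int)


def select_atoms(
    frame: ConformationFrame,
    residue_range: tuple[int, int],
    atom_name: str,
    chain_id: str | None = None,
) -> np.ndarray:
    """Coordinates (k, 3) of matching atoms in residue order; may be empty."""
    idx = select_atom_indices(frame.table, residue_range, atom_name, chain_id)
    return frame.coords[idx]


# --- configuration ---------------------------------------------------------

_RANGE_KEYS = ("fourhb_range", "brace_range", "pseudokinase_range",
               "loop_helix_range", "adjacent_helix_range")


def _parse_interval(value, key: str) -> tuple[int, int]:
    if isinstance(value, str):
        parts = value.replace("-", " ").split()
        value = [int(p) for p in parts]
    if not (isinstance(value, (list, tuple)) and len(value) == 2):
        raise ValueError(f"{key}: expected [lo, hi], got {value!r}")
    lo, hi = int(value[0]), int(value[1])
    if hi < lo or lo < 1:
        raise ValueError(f"{key}: malformed interval {lo}-{hi}")
    return lo, hi


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> tuple[DomainAnnotation, dict]:
    """Load annotation + pipeline parameters from a YAML key/value file.

    Absent keys fall back to documented defaults (each applied default is
    logged once).  ``overrides`` merges on top of the file, which makes CLI
    flags trivial to apply.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key/value mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    ann_kwargs: dict = {}
    for key in _RANGE_KEYS:
        if key in raw:
            ann_kwargs[key] = _parse_interval(raw.pop(key), key)
        else:
            logger.info("config: %s absent, using default %s",
                        key, getattr(DEFAULT_ANNOTATION, key))
    for key, default in (("hbond_donor", DEFAULT_ANNOTATION.hbond_donor),
                         ("hbond_acceptor", DEFAULT_ANNOTATION.hbond_acceptor)):
        if key in raw:
            val = raw.pop(key)
            if isinstance(val, dict):
                ann_kwargs[key] = (int(val["residue"]), str(val["atom"]))
            else:
                ann_kwargs[key] = (int(val[0]), str(val[1]))
        else:
            logger.info("config: %s absent, using default %s", key, default)
    if "chain_id" in raw:
        ann_kwargs["chain_id"] = str(raw.pop("chain_id"))

    annotation = DomainAnnotation(**ann_kwargs)

    lh, ah = annotation.loop_helix_range, annotation.adjacent_helix_range
    if max(lh[0], ah[0]) <= min(lh[1], ah[1]):
        logger.warning("config: loop helix %s overlaps adjacent helix %s", lh, ah)

    params = dict(DEFAULT_PARAMETERS)
    for key in list(raw):
        if key in params:
            params[key] = raw.pop(key)
    params.update(raw)  # pass through extra keys (e.g. replicate globs)
    return annotation, params
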