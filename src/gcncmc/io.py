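"""File formats: parameter side-car files, PDB, XYZ, move logs, reports.

PDB structures are read and written through biotite; molecules are grouped
by residue id and matched to templates through the residue names declared
in the parameter file.  Trajectories are plain XYZ; move logs are
tab-separated tables (one :class:`~gcncmc.grand_moves.MoveRecord` per
line); summaries are JSON.  Column specifications live in docs/formats.md.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigurationError, ParseError
from .model import MoleculeTemplate, ParticleSystem, Site


# ---------------------------------------------------------------------------
# parameter side-car files
# ---------------------------------------------------------------------------

def read_parameter_file(path) -> dict[str, MoleculeTemplate]:
    """Parse a key-value template parameter file (see docs/formats.md).

    Returns a mapping of template name -> :class:`MoleculeTemplate`; the PDB
    residue names each template answers to are attached as ``resnames``.
    """
    templates: dict[str, MoleculeTemplate] = {}
    name = None
    sites: list[Site] = []
    coords: list[list[float]] = []
    primary = 0
    resnames: list[str] = []

    def finish(lineno):
        nonlocal name, sites, coords, primary, resnames
        if name is None:
            return
        if not sites:
            raise ParseError(f"line {lineno}: template {name!r} has no sites")
        if len(sites) == 1:
            tpl = MoleculeTemplate(name=name, sites=tuple(sites),
                                   reference_coords=np.asarray(coords),
                                   primary_index=primary)
        else:
            tpl = MoleculeTemplate.rigid(name, sites, np.asarray(coords),
                                         primary_index=primary)
        object.__setattr__(tpl, "resnames", tuple(resnames))  # frozen dataclass
        templates[name] = tpl
        name, sites, coords, primary, resnames = None, [], [], 0, []

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        key = fields[0]
        try:
            if key == "version":
                continue
            elif key == "template":
                finish(lineno)
                name = fields[1]
            elif key == "resname":
                resnames = fields[1:]
            elif key == "primary":
                label = fields[1]
                labels = [s.label for s in sites]
                # may refer to a site parsed later; resolve as sites arrive
                primary = labels.index(label) if label in labels else ("label", label)
            elif key == "site":
                label = fields[1]
                mass, charge, eps, sigma, x, y, z = map(float, fields[2:9])
                sites.append(Site(label, mass, charge, eps, sigma))
                coords.append([x, y, z])
                if isinstance(primary, tuple) and primary[1] == label:
                    primary = len(sites) - 1
            elif key == "end":
                if isinstance(primary, tuple):
                    raise ParseError(f"unknown primary site {primary[1]!r}")
                finish(lineno)
            else:
                raise ParseError(f"unknown keyword {key!r}")
        except (IndexError, ValueError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    finish(-1)
    return templates


def default_water_template() -> MoleculeTemplate:
    """The rigid 3-site water template shipped with the package."""
    with resources.as_file(resources.files("gcncmc.data") / "water_tip3p.params") as p:
        return read_parameter_file(p)["water"]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _element_of(label: str) -> str:
    return label[0].upper()


def write_pdb(path, system: ParticleSystem, include_ghosts: bool = False,
              occupancy_by_molecule: dict[int, float] | None = None) -> None:
    """Write the system as a PDB file (fixed-column, via biotite).

    Ghosts are omitted unless ``include_ghosts``; ``occupancy_by_molecule``
    values, when given, are written into the B-factor column.
    """
    rows = []
    for mol_id, mol in enumerate(system.molecules):
        if not (mol.real or include_ghosts):
            continue
        sl = system.mol_slice(mol_id)
        for k, site in enumerate(mol.template.sites):
            rows.append((mol_id, mol.template.name, site.label,
                         system.positions[sl][k]))
    atoms = struc.AtomArray(len(rows))
    atoms.coord = np.array([r[3] for r in rows]).reshape(-1, 3)
    atoms.res_id = np.array([r[0] + 1 for r in rows])
    atoms.res_name = np.array([r[1][:3].upper() for r in rows])
    atoms.atom_name = np.array([r[2] for r in rows])
    atoms.element = np.array([_element_of(r[2]) for r in rows])
    atoms.hetero = np.ones(len(rows), dtype=bool)
    atoms.set_annotation("occupancy", np.ones(len(rows)))
    bfac = np.zeros(len(rows))
    if occupancy_by_molecule:
        for i, r in enumerate(rows):
            bfac[i] = occupancy_by_molecule.get(r[0], 0.0)
    atoms.set_annotation("b_factor", bfac)
    atoms.box = np.diag(system.box)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb(path, templates: dict[str, MoleculeTemplate], cutoff: float,
             switch_start: float | None = None, box=None,
             temperature: float = 298.0) -> ParticleSystem:
    """Load a PDB file into a :class:`ParticleSystem`.

    Molecules are grouped by residue; each residue name must be claimed by a
    template (via its own name or its ``resname`` declarations).  The box is
    taken from CRYST1 when present, else from ``box``.
    """
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:
        raise ParseError(f"could not parse PDB file {path}: {exc}") from exc

    if atoms.box is not None:
        box_edges = np.diag(atoms.box)
    elif box is not None:
        box_edges = np.asarray(box, dtype=float)
    else:
        raise ConfigurationError(
            f"{path} has no CRYST1 record; a box must be supplied")

    by_res: dict[str, MoleculeTemplate] = {}
    for tpl in templates.values():
        by_res[tpl.name.upper()[:3]] = tpl
        for rn in getattr(tpl, "resnames", ()):
            by_res[rn.upper()] = tpl

    system = ParticleSystem(box_edges, cutoff=cutoff, switch_start=switch_start,
                            temperature=temperature)
    # group consecutive atoms by (chain, res_id)
    chain = atoms.chain_id if atoms.chain_id is not None else np.full(len(atoms), "A")
    keys = list(zip(chain, atoms.res_id))
    start = 0
    for i in range(1, len(atoms) + 1):
        if i == len(atoms) or keys[i] != keys[start]:
            res_name = str(atoms.res_name[start]).upper()
            tpl = by_res.get(res_name)
            if tpl is None:
                raise ParseError(f"residue {res_name!r} matches no template")
            n = i - start
            if n != tpl.n_sites:
                raise ParseError(
                    f"residue {res_name!r} has {n} atoms, template "
                    f"{tpl.name!r} expects {tpl.n_sites}")
            system.add_molecule(tpl, positions=atoms.coord[start:i])
            start = i
    return system


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def append_xyz_frame(fh, labels, coords, comment="") -> None:
    coords = np.asarray(coords).reshape(-1, 3)
    fh.write(f"{len(coords)}\n{comment}\n")
    for lab, (x, y, z) in zip(labels, coords):
        fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_frames(path):
    """Yield (labels, coords, comment) per frame of a plain XYZ trajectory."""
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected atom count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"truncated XYZ frame at line {i + 1}")
        labels = [l.split()[0] for l in block]
        coords = np.array([[float(v) for v in l.split()[1:4]] for l in block])
        yield labels, coords, comment
        i += 2 + n


# ---------------------------------------------------------------------------
# move logs and reports
# ---------------------------------------------------------------------------

def move_records_dataframe(records) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "move": i,
            "kind": r.kind,
            "method": r.method,
            "accepted": int(r.accepted),
            "work_kcal_mol": r.work,
            "probability": r.probability,
            "n_before": r.n_before,
            "n0": r.n0 if r.n0 is not None else "",
            "nT": r.nT if r.nT is not None else "",
            "auto_rejected": int(r.auto_rejected),
            "auto_reject_reason": r.auto_reject_reason or "",
            "force_evaluations": r.force_evaluations,
        })
    return pd.DataFrame(rows)


def write_move_log(path, records) -> None:
    """Tab-separated move log, one record per line."""
    move_records_dataframe(records).to_csv(path, sep="\t", index=False)


def write_summary(path, stats, meta: dict | None = None) -> None:
    """Summary JSON report; ``meta`` (seed, config, ...) lands in a header."""
    from . import __version__
    payload = {"gcncmc_version": __version__}
    if meta:
        payload.update(meta)
    payload.update(stats.summary())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_cluster_pdb(path, report) -> None:
    """Cluster representatives as a PDB: one pseudo-water oxygen per
    hydration site, occupancy fraction in the B-factor column."""
    sites = report.sites
    atoms = struc.AtomArray(len(sites))
    atoms.coord = np.array([s.position for s in sites]).reshape(-1, 3)
    atoms.res_id = np.arange(1, len(sites) + 1)
    atoms.res_name = np.array(["HOH"] * len(sites))
    atoms.atom_name = np.array(["O"] * len(sites))
    atoms.element = np.array(["O"] * len(sites))
    atoms.hetero = np.ones(len(sites), dtype=bool)
    atoms.set_annotation("occupancy", np.ones(len(sites)))
    atoms.set_annotation("b_factor", np.array([s.occupancy for s in sites]))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def write_work_trace(path, record) -> None:
    """Per-move (λ, cumulative W) trace for free-energy post-analysis."""
    du = record.perturbation_du
    if du is None:
        raise ConfigurationError("record has no perturbation trace")
    lam = np.linspace(0.0, 1.0, len(du) + 1)
    cum = np.concatenate([[0.0], np.cumsum(du)])
    pd.DataFrame({"lambda": lam, "cumulative_work_kcal_mol": cum}).to_csv(
        path, sep="\t", index=False)
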