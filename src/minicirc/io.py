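"""Readers/writers for MD text formats (LAMMPS data-file and dump dialects).

The data writer emits the standard sections (counts header, Masses, Atoms,
Bonds, Angles, Dihedrals) with atoms as ``id mol type charge x y z`` and a
sidecar JSON mapping type numbers back to site/strand classes and term labels,
plus enough metadata (sequence, radius, closure term ids) to round-trip a
model.  The dump reader consumes ``ITEM: ATOMS id type x y z`` frames.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import TopologyError, TrajectoryError
from .geometry import CLASS_ORDER, BondedTerm, HelixParameters, MinicircleModel
from .poloidal import Conformation, Trajectory

#: nominal site masses, amu (deoxyribose, phosphate, average nucleobase)
SITE_MASSES = {"S": 83.11, "P": 94.97, "B": 130.9}
SITE_CHARGES = {"S": 0.0, "P": -1.0, "B": 0.0}


def _class_key(site: str, strand: int) -> str:
    return f"{site}{strand}"


def _type_tables(model: MinicircleModel) -> dict:
    atom_types = {_class_key(s, st): i + 1 for i, (s, st) in enumerate(CLASS_ORDER)}

    def labels(terms: list[BondedTerm]) -> dict[str, int]:
        seen: dict[str, int] = {}
        for t in terms:
            if t.label not in seen:
                seen[t.label] = len(seen) + 1
        return seen

    return {
        "atom_types": atom_types,
        "bond_types": labels(model.bonds),
        "angle_types": labels(model.angles),
        "dihedral_types": labels(model.dihedrals),
    }


def write_md_data(model: MinicircleModel, path: str | Path,
                  allow_open: bool = False) -> Path:
    """Write a LAMMPS-dialect data file plus a ``<path>.json`` sidecar map.

    Refuses topologically open models unless ``allow_open`` is set, and
    validates section/header consistency before writing.
    """
    model.validate()
    if not model.is_closed and not allow_open:
        raise TopologyError(
            "model is not topologically closed; pass allow_open=True to write anyway")
    path = Path(path)
    tables = _type_tables(model)

    lines = ["minicirc coarse-grained DNA data file (nm units)", ""]
    lines.append(f"{model.n_atoms} atoms")
    lines.append(f"{len(model.bonds)} bonds")
    lines.append(f"{len(model.angles)} angles")
    lines.append(f"{len(model.dihedrals)} dihedrals")
    lines.append("")
    lines.append(f"{len(tables['atom_types'])} atom types")
    lines.append(f"{len(tables['bond_types'])} bond types")
    lines.append(f"{len(tables['angle_types'])} angle types")
    lines.append(f"{len(tables['dihedral_types'])} dihedral types")
    lines.append("")
    span = float(np.abs(model.positions).max()) + 1.0
    for ax in ("x", "y", "z"):
        lines.append(f"{-span:.6f} {span:.6f} {ax}lo {ax}hi")
    lines.append("")

    lines.append("Masses")
    lines.append("")
    for key, num in tables["atom_types"].items():
        lines.append(f"{num} {SITE_MASSES[key[0]]:.4f}")
    lines.append("")

    lines.append("Atoms")
    lines.append("")
    for i, pos in enumerate(model.positions):
        site, strand = CLASS_ORDER[i % 6]
        type_num = tables["atom_types"][_class_key(site, strand)]
        lines.append(
            f"{i + 1} 1 {type_num} {SITE_CHARGES[site]:.1f} "
            f"{pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}")
    lines.append("")

    for section, terms, table in (
        ("Bonds", model.bonds, tables["bond_types"]),
        ("Angles", model.angles, tables["angle_types"]),
        ("Dihedrals", model.dihedrals, tables["dihedral_types"]),
    ):
        if not terms:
            continue
        lines.append(section)
        lines.append("")
        for j, term in enumerate(terms):
            atoms = " ".join(str(a + 1) for a in term.atoms)
            lines.append(f"{j + 1} {table[term.label]} {atoms}")
        lines.append("")

    path.write_text("\n".join(lines) + "\n")

    sidecar = {
        **tables,
        "sequence": model.sequence,
        "radius_nm": model.radius_nm,
        "metadata": {k: v for k, v in model.metadata.items()
                     if isinstance(v, (int, float, str, bool))},
        "helix_parameters": model.params.to_dict() if model.params else None,
        "closure": {
            "bonds": [j for j, t in enumerate(model.bonds) if t.closure],
            "angles": [j for j, t in enumerate(model.angles) if t.closure],
            "dihedrals": [j for j, t in enumerate(model.dihedrals) if t.closure],
        },
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_md_data(path: str | Path) -> MinicircleModel:
    """Read a data file written by :func:`write_md_data` (requires the sidecar)."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    text = path.read_text().splitlines()

    counts: dict[str, int] = {}
    sections: dict[str, list[str]] = {}
    current = None
    body: list[str] = []
    for line in text:
        stripped = line.strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) == 2 and parts[1] in ("atoms", "bonds", "angles", "dihedrals"):
            counts[parts[1]] = int(parts[0])
            continue
        if stripped in ("Masses", "Atoms", "Bonds", "Angles", "Dihedrals"):
            if current:
                sections[current] = body
            current, body = stripped, []
            continue
        if current:
            body.append(stripped)
    if current:
        sections[current] = body

    for name, key in (("Atoms", "atoms"), ("Bonds", "bonds"),
                      ("Angles", "angles"), ("Dihedrals", "dihedrals")):
        got = len(sections.get(name, []))
        if got != counts.get(key, 0):
            raise TrajectoryError(
                f"{name} section has {got} rows, header says {counts.get(key, 0)}")

    n_atoms = counts["atoms"]
    positions = np.empty((n_atoms, 3), dtype=float)
    for row in sections["Atoms"]:
        f = row.split()
        positions[int(f[0]) - 1] = [float(f[4]), float(f[5]), float(f[6])]

    inv = {table_name: {v: k for k, v in sidecar[table_name].items()}
           for table_name in ("bond_types", "angle_types", "dihedral_types")}

    def parse(section: str, table: str, closure_ids: list[int]) -> list[BondedTerm]:
        out = []
        for j, row in enumerate(sections.get(section, [])):
            f = row.split()
            label = inv[table][int(f[1])]
            atoms = tuple(int(a) - 1 for a in f[2:])
            out.append(BondedTerm(atoms, label, closure=j in set(closure_ids)))
        return out

    closure = sidecar.get("closure", {"bonds": [], "angles": [], "dihedrals": []})
    params = (HelixParameters.from_dict(sidecar["helix_parameters"])
              if sidecar.get("helix_parameters") else None)
    model = MinicircleModel(
        sequence=sidecar["sequence"],
        positions=positions,
        bonds=parse("Bonds", "bond_types", closure["bonds"]),
        angles=parse("Angles", "angle_types", closure["angles"]),
        dihedrals=parse("Dihedrals", "dihedral_types", closure["dihedrals"]),
        params=params,
        metadata=dict(sidecar.get("metadata", {})),
        radius_nm=float(sidecar.get("radius_nm") or 0.0),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# dump trajectories
# ---------------------------------------------------------------------------

def write_dump_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write frames in the LAMMPS dump text dialect (id type x y z)."""
    path = Path(path)
    n = traj.frames[0].positions.shape[0]
    span = max(float(np.abs(f.positions).max()) for f in traj.frames) + 1.0
    out = []
    for step, frame in enumerate(traj.frames):
        out.append("ITEM: TIMESTEP")
        out.append(str(step))
        out.append("ITEM: NUMBER OF ATOMS")
        out.append(str(n))
        out.append("ITEM: BOX BOUNDS pp pp pp")
        out.extend([f"{-span:.6f} {span:.6f}"] * 3)
        out.append("ITEM: ATOMS id type x y z")
        for i, pos in enumerate(frame.positions):
            type_num = (i % 6) + 1
            out.append(f"{i + 1} {type_num} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}")
    path.write_text("\n".join(out) + "\n")
    return path


def read_dump_trajectory(path: str | Path,
                         atom_map: dict[int, str] | None = None) -> Trajectory:
    """Read a dump file into a Trajectory (atoms re-sorted by id).

    ``atom_map`` maps dump type numbers to class keys like "S1"; when given,
    every type must be mapped and must match the bp-major class layout implied
    by the atom id.  Frames with inconsistent atom counts, duplicate ids, or
    missing atoms raise :class:`TrajectoryError`.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Conformation] = []
    i = 0
    n_expected: int | None = None
    class_keys = [f"{s}{st}" for s, st in CLASS_ORDER]

    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise TrajectoryError(f"expected TIMESTEP item at line {i + 1}")
        timestep = float(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise TrajectoryError(f"expected NUMBER OF ATOMS at line {i + 3}")
        n = int(lines[i + 3])
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryError(
                f"atom count changed from {n_expected} to {n} at timestep {timestep}")
        i += 4
        while i < len(lines) and not lines[i].startswith("ITEM: ATOMS"):
            i += 1
        if i >= len(lines):
            raise TrajectoryError("truncated frame: no ATOMS item")
        header = lines[i].split()[2:]
        try:
            col = {name: header.index(name) for name in ("id", "type", "x", "y", "z")}
        except ValueError as exc:
            raise TrajectoryError(f"dump missing required column: {exc}") from exc
        i += 1
        rows = lines[i:i + n]
        if len(rows) < n or any(r.startswith("ITEM:") for r in rows):
            raise TrajectoryError(f"frame at timestep {timestep} is missing atoms")
        i += n

        positions = np.empty((n, 3), dtype=float)
        seen = np.zeros(n, dtype=bool)
        for row in rows:
            f = row.split()
            idx = int(f[col["id"]]) - 1
            if not (0 <= idx < n) or seen[idx]:
                raise TrajectoryError(
                    f"bad or duplicate atom id {idx + 1} at timestep {timestep}")
            seen[idx] = True
            type_num = int(f[col["type"]])
            if atom_map is not None:
                if type_num not in atom_map:
                    raise TrajectoryError(f"unmapped atom type {type_num}")
                if atom_map[type_num] != class_keys[idx % 6]:
                    raise TrajectoryError(
                        f"atom id {idx + 1} has type {type_num} "
                        f"({atom_map[type_num]}), expected {class_keys[idx % 6]}")
            positions[idx] = [float(f[col["x"]]), float(f[col["y"]]), float(f[col["z"]])]
        if not seen.all():
            raise TrajectoryError(f"frame at timestep {timestep} is missing atoms")
        frames.append(Conformation(positions=positions, time=timestep))

    if not frames:
        raise TrajectoryError("empty dump file")
    return Trajectory(frames=frames, metadata={"source": str(path)})


def read_sequence(path_or_text: str | Path) -> str:
    """Read a sequence from FASTA, a plain-text file, or a literal string."""
    candidate = Path(str(path_or_text))
    try:
        exists = candidate.is_file()
    except OSError:
        exists = False
    if exists:
        text = candidate.read_text()
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        seq_lines = [ln for ln in lines if not ln.startswith((">", ";"))]
        return "".join(seq_lines).upper()
    return str(path_or_text).strip().upper()
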