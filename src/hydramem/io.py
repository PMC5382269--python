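"""Readers and writers: GRO configurations, annotation sidecars, curves.

GRO files carry no chemistry beyond atom and residue names, so hydrogen-bond
roles, partial charges and Lennard-Jones parameters live in a sidecar TSV
keyed on (resname, atomname).  Coordinates are written with six decimals so
that frames round-trip to 1e-6 nm; the fixed-width name/number fields follow
the standard GRO layout and files written by GROMACS (three decimals) parse
identically.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .frame import AtomRecord, Curve, Frame, FrameError

log = logging.getLogger("hydramem")

ANNOTATION_COLUMNS = [
    "resname",
    "atomname",
    "molecule_class",
    "leaflet_rule",
    "hb_role",
    "bonded_heavy",
    "charge_e",
    "sigma_nm",
    "epsilon_kJmol",
]


class GroParseError(FrameError):
    """GRO parsing failure; message names the offending line number."""


def _parse_atom_line(line: str, lineno: int):
    if len(line) < 20:
        raise GroParseError(f"line {lineno}: atom line too short")
    try:
        resid = int(line[0:5])
    except ValueError as exc:
        raise GroParseError(f"line {lineno}: bad residue number") from exc
    resname = line[5:10].strip()
    atomname = line[10:15].strip()
    rest = line[20:].split()
    if len(rest) < 3:
        raise GroParseError(f"line {lineno}: fewer than 3 coordinates")
    try:
        xyz = [float(v) for v in rest[:3]]
    except ValueError as exc:
        raise GroParseError(f"line {lineno}: non-numeric coordinate") from exc
    return resid, resname, atomname, xyz


def iter_gro_frames(path) -> Iterator[Frame]:
    """Iterate frames of a (possibly concatenated multi-frame) GRO file."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_id = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():  # tolerate blank separator lines
            i += 1
            continue
        title_line = i
        if i + 1 >= n_lines:
            raise GroParseError(f"line {title_line + 1}: truncated file after title")
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError as exc:
            raise GroParseError(
                f"line {i + 2}: malformed atom count {lines[i + 1]!r}"
            ) from exc
        if n_atoms < 0:
            raise GroParseError(f"line {i + 2}: negative atom count")
        first_atom = i + 2
        box_line = first_atom + n_atoms
        if box_line >= n_lines:
            raise GroParseError(
                f"line {n_lines}: truncated file, expected {n_atoms} atom lines "
                f"plus a box line"
            )
        positions = np.empty((n_atoms, 3))
        atoms: list[AtomRecord] = []
        for k in range(n_atoms):
            lineno = first_atom + k + 1
            resid, resname, atomname, xyz = _parse_atom_line(
                lines[first_atom + k], lineno
            )
            positions[k] = xyz
            atoms.append(
                AtomRecord(molecule_id=resid, atom_name=atomname, resname=resname)
            )
        box_fields = lines[box_line].split()
        try:
            box_vals = [float(v) for v in box_fields]
        except ValueError as exc:
            raise GroParseError(f"line {box_line + 1}: non-numeric box entry") from exc
        if len(box_vals) == 3:
            box = np.asarray(box_vals)
        elif len(box_vals) == 9:
            if any(abs(v) > 1e-12 for v in box_vals[3:]):
                raise GroParseError(
                    f"line {box_line + 1}: triclinic box not supported "
                    "(off-diagonal components present)"
                )
            box = np.asarray(box_vals[:3])
        else:
            raise GroParseError(
                f"line {box_line + 1}: box line must have 3 or 9 numbers"
            )
        if np.any(box <= 0):
            raise GroParseError(f"line {box_line + 1}: box lengths must be positive")
        yield Frame(positions=positions, box=box, atoms=atoms, frame_id=frame_id)
        frame_id += 1
        i = box_line + 1


def read_gro_frame(path) -> Frame:
    """Read the first (usually only) frame of a GRO file."""
    for frame in iter_gro_frames(path):
        return frame
    raise GroParseError(f"{path}: file contains no frames")


def read_gro_frames(path) -> list:
    return list(iter_gro_frames(path))


def write_gro(path, frames, title: str = "hydramem configuration") -> None:
    """Write one frame or a sequence of frames as (concatenated) GRO text."""
    if isinstance(frames, Frame):
        frames = [frames]
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            fh.write(f"{title}, frame {frame.frame_id}\n")
            fh.write(f"{frame.n_atoms:5d}\n")
            for k, atom in enumerate(frame.atoms):
                resid = atom.molecule_id % 100000
                x, y, z = frame.positions[k]
                fh.write(
                    f"{resid:5d}{atom.resname:<5.5s}{atom.atom_name:>5.5s}"
                    f"{(k + 1) % 100000:5d}{x:11.6f}{y:11.6f}{z:11.6f}\n"
                )
            fh.write(
                f"{frame.box[0]:11.6f}{frame.box[1]:11.6f}{frame.box[2]:11.6f}\n"
            )


# ---------------------------------------------------------------------------
# annotation sidecar
# ---------------------------------------------------------------------------

def read_annotation_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    return table


def write_annotation_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def _parse_roles(cell: str) -> frozenset:
    cell = cell.strip()
    if not cell or cell == "none":
        return frozenset()
    return frozenset(p.strip() for p in cell.replace("+", ",").split(",") if p.strip())


def merge_annotations(frame: Frame, table) -> Frame:
    """Return a copy of ``frame`` with sidecar annotations merged in.

    ``table`` is a path or a DataFrame with :data:`ANNOTATION_COLUMNS`.
    Leaflet labels for lipids are assigned by the sign of the molecule's
    midplane-relative z (``leaflet_rule`` = ``by_z``).
    """
    if not isinstance(table, pd.DataFrame):
        table = read_annotation_table(table)
    lookup = {}
    for _, row in table.iterrows():
        lookup[(row["resname"], row["atomname"])] = row

    out = frame.copy()
    unmatched = []
    for i, atom in enumerate(out.atoms):
        row = lookup.get((atom.resname, atom.atom_name))
        if row is None:
            unmatched.append(f"{atom.resname}/{atom.atom_name} (atom {i})")
            continue
        atom.molecule_class = row["molecule_class"]
        atom.hb_role = _parse_roles(row["hb_role"])
        offset = int(row["bonded_heavy"]) if str(row["bonded_heavy"]).strip() else 0
        atom.bonded_heavy = i + offset if "hydrogen" in atom.hb_role else -1
        atom.charge = float(row["charge_e"]) if str(row["charge_e"]).strip() else 0.0
        atom.lj_sigma = float(row["sigma_nm"]) if str(row["sigma_nm"]).strip() else 0.0
        atom.lj_epsilon = (
            float(row["epsilon_kJmol"]) if str(row["epsilon_kJmol"]).strip() else 0.0
        )
    if unmatched:
        shown = ", ".join(unmatched[:10])
        raise ValueError(
            f"{len(unmatched)} atoms lack annotation rows; first: {shown}"
        )
    _validate_hydrogens(out)
    _assign_leaflets(out)
    return out


def _validate_hydrogens(frame: Frame) -> None:
    n = frame.n_atoms
    for i, atom in enumerate(frame.atoms):
        if "hydrogen" in atom.hb_role:
            j = atom.bonded_heavy
            if not (0 <= j < n) or "hydrogen" in frame.atoms[j].hb_role:
                raise FrameError(
                    f"hydrogen atom {i} has invalid bonded_heavy index {j}"
                )
        elif atom.hb_role & {"donor", "acceptor"} and atom.atom_name.startswith("H"):
            log.warning("atom %d named %s marked donor/acceptor", i, atom.atom_name)


def _assign_leaflets(frame: Frame) -> None:
    z = frame.z_relative()
    by_mol: dict[int, list[int]] = {}
    for i, atom in enumerate(frame.atoms):
        if atom.molecule_class == "lipid":
            by_mol.setdefault(atom.molecule_id, []).append(i)
    for idx in by_mol.values():
        leaflet = "upper" if float(np.mean(z[idx])) >= 0 else "lower"
        for i in idx:
            frame.atoms[i].leaflet = leaflet


# ---------------------------------------------------------------------------
# columnar curves
# ---------------------------------------------------------------------------

def read_curve(path, x_unit: str = "", y_unit: str = "") -> Curve:
    """Read a 2- or 3-column whitespace/comma-separated curve.

    Lines starting with ``#`` or ``@`` (XVG headers) are skipped.  The third
    column, when present, is taken as the y error.
    """
    rows = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#@":
                continue
            parts = stripped.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value at data row "
                    f"{len(rows) + 1} (line {lineno})"
                ) from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = len(rows[0])
    if ncol < 2 or any(len(r) != ncol for r in rows):
        raise ValueError(f"{path}: need a constant number (>=2) of columns")
    arr = np.asarray(rows)
    y_err = arr[:, 2] if ncol >= 3 else None
    return Curve(x=arr[:, 0], y=arr[:, 1], y_err=y_err, x_unit=x_unit, y_unit=y_unit)


def write_curve(path, curve: Curve) -> None:
    header = f"# {curve.x_unit or 'x'}\t{curve.y_unit or 'y'}"
    cols = [curve.x, curve.y]
    if curve.y_err is not None:
        header += "\ty_err"
        cols.append(curve.y_err)
    with Path(path).open("w") as fh:
        fh.write(header + "\n")
        for row in zip(*cols):
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
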