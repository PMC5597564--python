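"""PDBQT reading/writing and run-result serialization.

The PDBQT dialect follows AutoDock 4's fixed-width layout: ATOM/HETATM
records with coordinates in columns 31-54, the partial charge in columns
67-76 and the AutoDock atom type in columns 78-79; ligand files additionally
carry the rotatable-bond tree as ROOT/ENDROOT and nested BRANCH/ENDBRANCH
blocks plus a TORSDOF record.  Parsing is tolerant of trailing whitespace
and loudly intolerant of shifted columns.  Water residues (HOH/WAT) are
dropped from receptors on read.

PDBQT carries no bond table, so ligand covalent bonds are perceived by
distance (heavy-atom pairs closer than 1.9 Å, hydrogen pairs 1.3 Å) and the
BRANCH axes are added explicitly.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from .pose import Atom, LigandTopology, ReceptorModel, TorsionNode
from .search import RunSummary

__all__ = [
    "read_receptor_pdbqt",
    "read_ligand_pdbqt",
    "write_receptor_pdbqt",
    "write_ligand_pdbqt",
    "write_results",
    "PdbqtError",
]

logger = logging.getLogger(__name__)

_WATER_RESIDUES = {"HOH", "WAT"}
_HEAVY_BOND_CUTOFF = 1.9  # Å
_H_BOND_CUTOFF = 1.3  # Å


class PdbqtError(ValueError):
    """Malformed PDBQT content; the message names the offending line."""


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, int]:
    """Parse one ATOM/HETATM record -> (atom with file-order id 0 placeholder,
    residue name, serial)."""
    if len(line.rstrip("\n")) < 79:
        raise PdbqtError(f"line {lineno}: ATOM record too short for PDBQT columns")
    try:
        serial = int(line[6:11])
        res_name = line[17:20].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        charge = float(line[66:76])
        type_code = line[77:79].strip()
    except ValueError as exc:
        raise PdbqtError(f"line {lineno}: malformed fixed-width field ({exc})") from exc
    if not type_code:
        raise PdbqtError(f"line {lineno}: missing atom type code")
    element = "H" if type_code in ("H", "HD", "HS") else type_code[0]
    atom = Atom(id=0, element=element, type_code=type_code, coords=(x, y, z),
                charge=charge)
    return atom, res_name, serial


def _format_atom_line(
    atom: Atom, serial: int, res_name: str, record: str = "ATOM"
) -> str:
    name = (atom.element + str(serial))[:4]
    x, y, z = atom.coords
    return (
        f"{record:<6}{serial:>5} {name:<4} {res_name:<3} A{1:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}{atom.charge:10.4f} "
        f"{atom.type_code:<2}"
    )


def read_receptor_pdbqt(
    path: str | Path,
    known_types: set[str] | None = "auto",  # type: ignore[assignment]
    box_half_extent: float = 6.0,
) -> ReceptorModel:
    """Read a rigid receptor.  Waters are dropped (count logged); atom
    types missing from the force-field table (or from ``known_types`` when
    given; ``None`` disables the check) are rejected with their line
    numbers.  The search box defaults to the atoms' bounding box center
    with the given half-extent.
    """
    if known_types == "auto":
        from .scoring import load_atom_type_table

        known_types = set(load_atom_type_table())
    path = Path(path)
    atoms: list[Atom] = []
    n_water = 0
    bad_types: list[tuple[int, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        atom, res_name, _serial = _parse_atom_line(line, lineno)
        if res_name.upper() in _WATER_RESIDUES:
            n_water += 1
            continue
        if known_types is not None and atom.type_code not in known_types:
            bad_types.append((lineno, atom.type_code))
            continue
        atoms.append(
            Atom(len(atoms), atom.element, atom.type_code, atom.coords, atom.charge)
        )
    if bad_types:
        listing = ", ".join(f"line {ln}: {tc!r}" for ln, tc in bad_types)
        raise PdbqtError(f"{path.name}: unknown atom types ({listing})")
    if n_water:
        logger.info("%s: dropped %d water atoms", path.name, n_water)
    if not atoms:
        raise PdbqtError(f"{path.name}: no atoms")
    coords = np.array([a.coords for a in atoms])
    center = 0.5 * (coords.min(axis=0) + coords.max(axis=0))
    h = float(box_half_extent)
    return ReceptorModel(
        atoms=tuple(atoms),
        bounding_box=(tuple(center), (h, h, h)),
        name=path.stem,
    )


def _perceive_bonds(atoms: list[Atom]) -> list[tuple[int, int]]:
    coords = np.array([a.coords for a in atoms])
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            cutoff = (
                _H_BOND_CUTOFF
                if atoms[i].is_hydrogen or atoms[j].is_hydrogen
                else _HEAVY_BOND_CUTOFF
            )
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                bonds.append((i, j))
    return bonds


def read_ligand_pdbqt(path: str | Path) -> LigandTopology:
    """Read a flexible ligand: atoms plus the ROOT/BRANCH torsion tree.

    ``n_torsions`` equals the number of BRANCH records; the TORSDOF record,
    when present, is stored separately as the torsional-penalty count.
    """
    path = Path(path)
    atoms: list[Atom] = []
    serial_to_idx: dict[int, int] = {}
    root_atoms: list[int] = []
    # open branches carry (declaration index, serial_a, serial_b, moved)
    branch_stack: list[tuple[int, int, int, list[int]]] = []
    branches: dict[int, tuple[int, int, list[int]]] = {}
    torsdof: int | None = None
    in_root = False
    seen_root = False

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tag = line.split()[0] if line.split() else ""
        if tag in ("ATOM", "HETATM"):
            atom, _res, serial = _parse_atom_line(line, lineno)
            idx = len(atoms)
            atoms.append(
                Atom(idx, atom.element, atom.type_code, atom.coords, atom.charge)
            )
            serial_to_idx[serial] = idx
            if in_root:
                root_atoms.append(idx)
            for _k, _a, _b, moved in branch_stack:
                moved.append(idx)
        elif tag == "ROOT":
            if seen_root:
                raise PdbqtError(f"line {lineno}: multiple ROOT blocks")
            in_root, seen_root = True, True
        elif tag == "ENDROOT":
            if not in_root:
                raise PdbqtError(f"line {lineno}: ENDROOT without ROOT")
            in_root = False
        elif tag == "BRANCH":
            try:
                _, sa, sb = line.split()
                branch_stack.append((len(branches) + len(branch_stack),
                                     int(sa), int(sb), []))
            except ValueError as exc:
                raise PdbqtError(f"line {lineno}: malformed BRANCH") from exc
        elif tag == "ENDBRANCH":
            if not branch_stack:
                raise PdbqtError(f"line {lineno}: ENDBRANCH without BRANCH")
            k, sa, sb, moved = branch_stack.pop()
            branches[k] = (sa, sb, moved)
        elif tag == "TORSDOF":
            torsdof = int(line.split()[1])
    if branch_stack:
        raise PdbqtError(f"{path.name}: unbalanced BRANCH/ENDBRANCH")
    if not seen_root:
        raise PdbqtError(f"{path.name}: ligand file needs exactly one ROOT block")
    if not root_atoms:
        raise PdbqtError(f"{path.name}: empty ROOT block")

    # emit torsion nodes in declaration (depth-first tree) order
    nodes = []
    for sa, sb, moved in (branches[k] for k in sorted(branches)):
        try:
            a, b = serial_to_idx[sa], serial_to_idx[sb]
        except KeyError as exc:
            raise PdbqtError(f"{path.name}: BRANCH references unknown serial {exc}")
        nodes.append(
            TorsionNode(a, b, frozenset(m for m in moved if m != b))
        )

    bonds = set(map(tuple, map(sorted, _perceive_bonds(atoms))))
    for node in nodes:
        bonds.add(tuple(sorted((node.axis_a, node.axis_b))))
    return LigandTopology(
        atoms=tuple(atoms),
        bonds=tuple(sorted(bonds)),
        torsion_nodes=tuple(nodes),
        root_atoms=tuple(root_atoms),
        torsdof=torsdof,
        name=path.stem,
    )


def write_receptor_pdbqt(receptor: ReceptorModel, path: str | Path) -> None:
    lines = [
        _format_atom_line(a, i + 1, "REC") for i, a in enumerate(receptor.atoms)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_ligand_pdbqt(
    topo: LigandTopology,
    path: str | Path,
    coords: np.ndarray | None = None,
    remarks: list[str] | None = None,
) -> None:
    """Write a ligand with its torsion tree (optionally at given pose
    coordinates).  Branches are emitted in declaration order, nested by
    moved-set containment."""
    coords = topo.template_coords if coords is None else np.asarray(coords)
    atoms = [
        Atom(a.id, a.element, a.type_code, tuple(coords[a.id]), a.charge)
        for a in topo.atoms
    ]
    lines: list[str] = [f"REMARK  {r}" for r in (remarks or [])]

    def atom_line(idx: int) -> str:
        return _format_atom_line(atoms[idx], idx + 1, "LIG")

    children: dict[int | None, list[int]] = {}  # parent node index -> node indices
    owners: list[int | None] = []
    for k, node in enumerate(topo.torsion_nodes):
        parent = None
        best_size = None
        for j, other in enumerate(topo.torsion_nodes):
            if j == k:
                continue
            if node.axis_b in other.moved or node.axis_a in other.moved:
                if best_size is None or len(other.moved) < best_size:
                    parent, best_size = j, len(other.moved)
        owners.append(parent)
        children.setdefault(parent, []).append(k)

    emitted: set[int] = set()

    def emit_branch(k: int) -> None:
        node = topo.torsion_nodes[k]
        own = {node.axis_b} | set(node.moved)
        for c in children.get(k, []):
            own -= topo.torsion_nodes[c].moved | {topo.torsion_nodes[c].axis_b}
        lines.append(f"BRANCH {node.axis_a + 1} {node.axis_b + 1}")
        for idx in sorted(own):
            if idx not in emitted:
                lines.append(atom_line(idx))
                emitted.add(idx)
        for c in children.get(k, []):
            emit_branch(c)
        lines.append(f"ENDBRANCH {node.axis_a + 1} {node.axis_b + 1}")

    lines.append("ROOT")
    for idx in topo.root_atoms:
        lines.append(atom_line(idx))
        emitted.add(idx)
    lines.append("ENDROOT")
    for k in children.get(None, []):
        emit_branch(k)
    lines.append(f"TORSDOF {topo.torsdof if topo.torsdof is not None else topo.n_torsions}")
    Path(path).write_text("\n".join(lines) + "\n")


def _config_hash(summary: RunSummary) -> str:
    payload = f"{summary.algorithm}:{summary.seed}:{len(summary.trace)}"
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_results(
    summary: RunSummary,
    out_dir: str | Path,
    topo: LigandTopology | None = None,
    run_id: str = "run",
) -> None:
    """Persist one run: best pose as PDBQT (when the topology is available)
    with REMARK lines carrying energy/RMSD/seed/config hash, plus a
    machine-readable TSV row table.  Deterministic and byte-stable for the
    same summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rmsd_txt = "" if summary.best_rmsd is None else f"{summary.best_rmsd:.4f}"
    if topo is not None:
        from .pose import Genome, decode

        coords = decode(Genome.from_vector(summary.best_genome), topo)
        write_ligand_pdbqt(
            topo,
            out / f"{run_id}_best_pose.pdbqt",
            coords=coords,
            remarks=[
                f"ENERGY {summary.best_energy:.6f}",
                f"RMSD {rmsd_txt or 'NA'}",
                f"SEED {summary.seed}",
                f"CONFIG_HASH {_config_hash(summary)}",
            ],
        )
    table = out / f"{run_id}_runs.tsv"
    header = "run_id\talgorithm\tseed\tfinal_energy\trmsd\tevaluations\n"
    row = (
        f"{run_id}\t{summary.algorithm}\t{summary.seed}\t"
        f"{summary.best_energy:.6f}\t{rmsd_txt or 'NA'}\t{summary.n_evaluations}\n"
    )
    table.write_text(header + row)
    trace = out / f"{run_id}_trace.tsv"
    trace.write_text(
        "n_evaluations\tbest_energy\n"
        + "".join(f"{n}\t{e:.6f}\n" for n, e in summary.trace)
    )
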