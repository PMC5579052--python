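"""Minimal XYZ geometry reader/writer.

Standard XYZ: atom count, comment line, then ``element x y z`` in Å.
"""

from __future__ import annotations

from pathlib import Path

Atom = tuple[str, float, float, float]


def read_xyz(path: str | Path) -> list[Atom]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: first line must be the atom count") from exc
    body = lines[2 : 2 + natoms]
    if len(body) < natoms:
        raise ValueError(f"{path}: expected {natoms} atom lines, found {len(body)}")
    atoms: list[Atom] = []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {ln!r}")
        atoms.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
    return atoms


def write_xyz(path: str | Path, atoms: list[Atom], comment: str = "") -> None:
    lines = [str(len(atoms)), comment]
    for el, x, y, z in atoms:
        lines.append(f"{el} {x!r} {y!r} {z!r}")
    Path(path).write_text("\n".join(lines) + "\n")
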