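"""Plain-text edge-list serialisation of spring networks.

Format (whitespace separated, '#' starts a comment):

    #v <index> <x> <y> [fixed]          mass positions (structured comments)
    <i> <j> <stiffness> <natural_length> <P|L> [creep_rate]

0-based indices; layer P = elastic, L = plastic (deformable).  Files written
by :func:`write_edge_list` round-trip exactly (floats via repr).  A separate
two-column-plus-weight format ``i j J`` carries spin-glass coupling lists.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import EdgeListError
from .model import SpringNetwork

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_coupling_list",
    "write_coupling_list",
]


def write_edge_list(network: SpringNetwork, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# natind edge list: i j stiffness natural_length layer [creep_rate]\n")
        for idx in range(network.n_masses):
            x, y = (float(v) for v in network.positions[idx])
            fixed = "" if network.mobile[idx] else " fixed"
            fh.write(f"#v {idx} {x!r} {y!r}{fixed}\n")
        for s in range(network.n_springs):
            layer = "L" if network.plastic[s] else "P"
            fh.write(
                f"{network.edge_i[s]} {network.edge_j[s]} "
                f"{float(network.stiffness[s])!r} {float(network.natural_length[s])!r} "
                f"{layer} {float(network.creep_rate[s])!r}\n"
            )


def _fail(path, lineno: int, msg: str):
    raise EdgeListError(f"{path}:{lineno}: {msg}")


def read_edge_list(path) -> SpringNetwork:
    path = Path(path)
    verts: dict[int, tuple[float, float, bool]] = {}
    ei, ej, ks, ls, plastic, creep = [], [], [], [], [], []
    seen: set[tuple[int, int, bool]] = set()
    max_idx = -1
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("v "):
                    parts = body.split()
                    if len(parts) not in (4, 5):
                        _fail(path, lineno, f"malformed vertex line: {line!r}")
                    try:
                        idx = int(parts[1])
                        x, y = float(parts[2]), float(parts[3])
                    except ValueError:
                        _fail(path, lineno, f"non-numeric vertex fields: {line!r}")
                    mobile = not (len(parts) == 5 and parts[4] == "fixed")
                    verts[idx] = (x, y, mobile)
                    max_idx = max(max_idx, idx)
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                _fail(path, lineno, f"expected 5 or 6 fields, got {len(parts)}")
            try:
                i, j = int(parts[0]), int(parts[1])
                k, l = float(parts[2]), float(parts[3])
            except ValueError:
                _fail(path, lineno, f"non-numeric edge fields: {line!r}")
            layer = parts[4]
            if layer not in ("P", "L"):
                _fail(path, lineno, f"layer must be P or L, got {layer!r}")
            cr = 1.0
            if len(parts) == 6:
                try:
                    cr = float(parts[5])
                except ValueError:
                    _fail(path, lineno, f"non-numeric creep_rate: {parts[5]!r}")
            if i == j:
                _fail(path, lineno, f"self-spring ({i}, {j})")
            if i < 0 or j < 0:
                _fail(path, lineno, "negative mass index")
            if k <= 0:
                _fail(path, lineno, f"stiffness must be > 0, got {k}")
            if l < 0:
                _fail(path, lineno, f"natural_length must be >= 0, got {l}")
            key = (min(i, j), max(i, j), layer == "L")
            if key in seen:
                _fail(path, lineno, f"duplicate pair ({i}, {j}) within layer {layer}")
            seen.add(key)
            ei.append(i)
            ej.append(j)
            ks.append(k)
            ls.append(l)
            plastic.append(layer == "L")
            creep.append(cr)
            max_idx = max(max_idx, i, j)

    if max_idx < 0:
        raise EdgeListError(f"{path}: no masses or springs found")
    n = max_idx + 1
    for idx in verts:
        if idx >= n:
            n = idx + 1
    positions = np.zeros((n, 2))
    mobile = np.ones(n, dtype=np.bool_)
    for idx, (x, y, mob) in verts.items():
        positions[idx] = (x, y)
        mobile[idx] = mob
    return SpringNetwork.from_arrays(
        positions,
        np.asarray(ei, np.int64),
        np.asarray(ej, np.int64),
        np.asarray(ks, float),
        np.asarray(ls, float),
        np.asarray(plastic, np.bool_),
        np.asarray(creep, float),
        mobile=mobile,
    )


def write_coupling_list(couplings: np.ndarray, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# natind coupling list: i j J\n")
        for i, j, J in np.asarray(couplings, dtype=float):
            fh.write(f"{int(i)} {int(j)} {float(J)!r}\n")


def read_coupling_list(path) -> np.ndarray:
    path = Path(path)
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                _fail(path, lineno, f"expected 3 fields, got {len(parts)}")
            try:
                i, j, J = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                _fail(path, lineno, f"non-numeric coupling fields: {line!r}")
            if i == j:
                _fail(path, lineno, f"self-coupling ({i}, {j})")
            rows.append((i, j, J))
    return np.asarray(rows, dtype=float).reshape(-1, 3)
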