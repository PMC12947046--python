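"""Domain types and data handling for conformer-ensemble ranking.

A :class:`Structure` is one molecular configuration (atomic numbers plus
Cartesian coordinates in Angstrom, with named scalar properties); a
:class:`ConformerGroup` collects every configuration that shares a parent
molecule identifier (e.g. an InChIKey) and is the unit over which
rankings are defined. Train/test splitting happens at the molecule level
so that no configuration of a test molecule is ever seen in training, and
pairwise training examples are always drawn within a group.

Files are read and written in XYZ / extended-XYZ dialects. The extended
comment line carries ``key=value`` fields (``structure_id``, ``group_id``
and one key per scalar property); plain XYZ is accepted together with a
sidecar delimited table keyed by ``structure_id``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "Structure",
    "ConformerGroup",
    "PairExample",
    "SplitResult",
    "SYMBOL_TO_Z",
    "Z_TO_SYMBOL",
    "read_structures",
    "write_structures",
    "group_structures",
    "split_by_molecule",
    "filter_and_cap_groups",
    "make_pairs",
]

# Periodic table, H..Og. Index 0 unused.
_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og"
).split()
SYMBOL_TO_Z: Dict[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL: Dict[int, str] = {i + 1: s for i, s in enumerate(_SYMBOLS)}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass
class Structure:
    """One molecular configuration."""

    structure_id: str
    group_id: str
    atomic_numbers: np.ndarray  # (n,) int
    positions: np.ndarray       # (n, 3) float, Angstrom
    properties: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be n x 3, got {self.positions.shape}")
        if len(self.atomic_numbers) != len(self.positions):
            raise ValueError(
                f"{len(self.atomic_numbers)} atomic numbers but "
                f"{len(self.positions)} coordinate rows"
            )
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be >= 1")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinate")
        if self.n_atoms > 1:
            d = self.distance_matrix()
            off = d[~np.eye(self.n_atoms, dtype=bool)]
            if np.any(off <= 0.0):
                raise ValueError("coincident atoms: zero interatomic distance")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def distance_matrix(self) -> np.ndarray:
        """Dense pairwise Euclidean distances in Angstrom (zero diagonal)."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff * diff).sum(axis=-1))


@dataclass
class ConformerGroup:
    """All configurations sharing one parent-molecule identifier."""

    group_id: str
    structures: List[Structure]

    def __post_init__(self) -> None:
        for s in self.structures:
            if s.group_id != self.group_id:
                raise ValueError(
                    f"structure {s.structure_id} has group {s.group_id!r}, "
                    f"expected {self.group_id!r}"
                )

    def __len__(self) -> int:
        return len(self.structures)

    def property_values(self, name: str) -> np.ndarray:
        vals = []
        for s in self.structures:
            if name not in s.properties:
                raise KeyError(
                    f"structure {s.structure_id} lacks property {name!r}"
                )
            vals.append(s.properties[name])
        return np.asarray(vals, dtype=np.float64)


@dataclass
class PairExample:
    """An ordered within-group pair with its comparison label.

    ``label`` is (1, 0) when a's property exceeds b's, (0, 1) when it is
    smaller, and (0.5, 0.5) on a tie; ``target_diff`` is t_a - t_b in the
    property's units.
    """

    a: Structure
    b: Structure
    label: Tuple[float, float]
    target_diff: float

    def __post_init__(self) -> None:
        if self.a.group_id != self.b.group_id:
            raise ValueError("pair members must share a group")
        if not math.isclose(self.label[0] + self.label[1], 1.0):
            raise ValueError("label components must sum to 1")


@dataclass
class SplitResult:
    """A molecule-level train/test partition of group identifiers."""

    train_groups: List[str]
    test_groups: List[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_groups) & set(self.test_groups):
            raise ValueError("train and test groups overlap")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> Dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(comment)}


def read_structures(
    path: Union[str, Path],
    format: str = "extxyz",
    property_table: Optional[Union[str, Path]] = None,
) -> List[Structure]:
    """Read all frames of an XYZ / extended-XYZ file.

    For ``format="extxyz"`` the comment line of each frame must contain
    ``key=value`` fields including ``group_id``; every numeric field other
    than ``structure_id``/``group_id`` becomes a property. For plain
    ``format="xyz"`` a sidecar ``property_table`` (CSV/TSV with a header
    and ``structure_id``, ``group_id`` columns) supplies the metadata,
    matched by frame order against the table's row order.
    """
    path = Path(path)
    if format not in ("xyz", "extxyz"):
        raise ValueError(f"unknown format {format!r}")
    lines = path.read_text().splitlines()
    frames: List[Tuple[int, str, List[str]]] = []  # (frame idx, comment, atom lines)
    i, frame_idx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(
                f"frame {frame_idx}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + natoms >= len(lines) + 1 and i + 1 + natoms > len(lines):
            raise ParseError(f"frame {frame_idx}: truncated (needs {natoms} atoms)")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        atom_lines = lines[i + 2: i + 2 + natoms]
        if len(atom_lines) != natoms:
            raise ParseError(f"frame {frame_idx}: truncated (needs {natoms} atoms)")
        frames.append((frame_idx, comment, atom_lines))
        i += 2 + natoms
        frame_idx += 1

    sidecar: Optional[pd.DataFrame] = None
    if format == "xyz":
        if property_table is None:
            raise ValueError("plain XYZ requires a sidecar property table")
        sidecar = pd.read_csv(property_table, sep=None, engine="python")
        for col in ("structure_id", "group_id"):
            if col not in sidecar.columns:
                raise ParseError(f"property table lacks column {col!r}")
        if len(sidecar) != len(frames):
            raise ParseError(
                f"property table has {len(sidecar)} rows for {len(frames)} frames"
            )

    structures: List[Structure] = []
    for k, (idx, comment, atom_lines) in enumerate(frames):
        zs, xyz = [], []
        for ln in atom_lines:
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"frame {idx}: malformed atom line {ln!r}")
            sym = parts[0]
            if sym.isdigit():
                z = int(sym)
                if z < 1 or z > len(_SYMBOLS):
                    raise ParseError(f"frame {idx}: invalid atomic number {z}")
            elif sym in SYMBOL_TO_Z:
                z = SYMBOL_TO_Z[sym]
            else:
                raise ParseError(f"frame {idx}: unknown element symbol {sym!r}")
            try:
                coords = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"frame {idx}: bad coordinate in {ln!r}") from exc
            if not all(math.isfinite(c) for c in coords):
                raise ParseError(f"frame {idx}: non-finite coordinate in {ln!r}")
            zs.append(z)
            xyz.append(coords)

        if format == "extxyz":
            meta = _parse_comment(comment)
            if "group_id" not in meta:
                raise ParseError(f"frame {idx}: comment line lacks group_id")
            structure_id = meta.pop("structure_id", f"frame{idx}")
            group_id = meta.pop("group_id")
            props: Dict[str, float] = {}
            for key, val in meta.items():
                try:
                    props[key] = float(val)
                except ValueError:
                    continue  # non-numeric metadata is ignored
        else:
            row = sidecar.iloc[k]
            structure_id = str(row["structure_id"])
            group_id = str(row["group_id"])
            props = {
                c: float(row[c]) for c in sidecar.columns
                if c not in ("structure_id", "group_id")
                and pd.api.types.is_numeric_dtype(sidecar[c])
            }
        try:
            structures.append(Structure(structure_id, group_id,
                                        np.array(zs), np.array(xyz), props))
        except ValueError as exc:
            raise ParseError(f"frame {idx}: {exc}") from exc
    return structures


def write_structures(structures: Sequence[Structure],
                     path: Union[str, Path]) -> None:
    """Write structures as extended XYZ (round-trips with read_structures)."""
    out_lines: List[str] = []
    for s in structures:
        out_lines.append(str(s.n_atoms))
        fields = [f"structure_id={s.structure_id}", f"group_id={s.group_id}"]
        fields += [f"{k}={v:.12g}" for k, v in sorted(s.properties.items())]
        out_lines.append(" ".join(fields))
        for z, (x, y, zc) in zip(s.atomic_numbers, s.positions):
            out_lines.append(
                f"{Z_TO_SYMBOL[int(z)]} {x:.8f} {y:.8f} {zc:.8f}"
            )
    Path(path).write_text("\n".join(out_lines) + "\n")


# ---------------------------------------------------------------------------
# Grouping, splitting, filtering
# ---------------------------------------------------------------------------

def group_structures(structures: Iterable[Structure]) -> List[ConformerGroup]:
    """Partition structures into groups by ``group_id`` (order-preserving)."""
    by_id: Dict[str, List[Structure]] = {}
    order: List[str] = []
    for s in structures:
        if s.group_id not in by_id:
            by_id[s.group_id] = []
            order.append(s.group_id)
        by_id[s.group_id].append(s)
    return [ConformerGroup(gid, by_id[gid]) for gid in order]


def split_by_molecule(groups: Sequence[ConformerGroup],
                      test_fraction: float, seed: int) -> SplitResult:
    """Molecule-level split: every group falls entirely on one side.

    The test set holds ``round(test_fraction * n_groups)`` groups (at
    least one) chosen by a seeded uniform shuffle.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to split")
    ids = [g.group_id for g in groups]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = max(1, round(test_fraction * len(ids)))
    test = sorted(ids[i] for i in perm[:n_test])
    train = sorted(ids[i] for i in perm[n_test:])
    return SplitResult(train_groups=train, test_groups=test, seed=seed)


def filter_and_cap_groups(groups: Sequence[ConformerGroup],
                          min_exclusive: int = 5, cap: int = 11,
                          seed: int = 0) -> List[ConformerGroup]:
    """Keep groups with more than ``min_exclusive`` members and subsample
    larger ones to at most ``cap`` members (seeded, without replacement).

    Mirrors the ensemble-screening protocol of keeping only molecules
    with >5 configurations and drawing up to 11 per molecule.
    """
    if min_exclusive < 1:
        raise ValueError("min_exclusive must be >= 1")
    if cap < 2:
        raise ValueError("cap must be >= 2")
    rng = np.random.default_rng(seed)
    out: List[ConformerGroup] = []
    for g in groups:
        if len(g) <= min_exclusive:
            continue
        if len(g) > cap:
            idx = np.sort(rng.choice(len(g), size=cap, replace=False))
            out.append(ConformerGroup(g.group_id, [g.structures[i] for i in idx]))
        else:
            out.append(g)
    return out


def make_pairs(group: ConformerGroup, property_name: str,
               budget: Optional[int] = None, seed: int = 0,
               tie_tolerance: float = 0.0) -> List[PairExample]:
    """Draw up to ``budget`` distinct unordered pairs from one group.

    Each pair is emitted once in a seeded random orientation (the Siamese
    head is exactly antisymmetric, so both orders carry the same
    information). The label is (1,0) if t_a > t_b, (0,1) if t_a < t_b and
    (0.5, 0.5) on a tie, judged with absolute tolerance ``tie_tolerance``.
    """
    n = len(group)
    if n < 2:
        raise ValueError(f"group {group.group_id} has fewer than 2 members")
    for s in group.structures:
        if property_name not in s.properties:
            raise KeyError(
                f"structure {s.structure_id} lacks property {property_name!r}"
            )
    all_pairs = list(combinations(range(n), 2))
    rng = np.random.default_rng(seed)
    if budget is not None and budget < len(all_pairs):
        idx = rng.choice(len(all_pairs), size=budget, replace=False)
        chosen = [all_pairs[i] for i in sorted(idx)]
    else:
        chosen = all_pairs
    flips = rng.random(len(chosen)) < 0.5
    out: List[PairExample] = []
    for (i, j), flip in zip(chosen, flips):
        if flip:
            i, j = j, i
        a, b = group.structures[i], group.structures[j]
        ta, tb = a.properties[property_name], b.properties[property_name]
        diff = ta - tb
        if abs(diff) <= tie_tolerance:
            label = (0.5, 0.5)
        elif diff > 0:
            label = (1.0, 0.0)
        else:
            label = (0.0, 1.0)
        out.append(PairExample(a=a, b=b, label=label, target_diff=diff))
    return out
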