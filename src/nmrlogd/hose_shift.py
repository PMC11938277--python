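"""Built-in HOSE-code ¹H chemical-shift predictor.

A HOSE code (Hierarchically Ordered Spherical Environment) is a canonical
string describing the bonded neighbourhood of an atom shell by shell.
Prediction works by nearest-environment lookup: hydrogens whose anchor
heavy atoms share a HOSE code up to some sphere depth are assigned the
mean shift observed for that code in a training table, falling back to
shallower spheres (and ultimately to the table's global mean) when the
deep environment is unseen.

The encoding here is this package's own canonical scheme — breadth-first
shells from the anchor heavy atom, substituent branches sorted by
(element priority C > O > N > halogens > others, bond symbol, recursive
sub-code), ring closures marked with ``&`` — chosen so that two hydrogens
with graph-identical environments up to ``max_spheres`` always receive
identical codes, and so that truncating a deep code to *s* spheres equals
encoding directly with ``max_spheres = s``.  String compatibility with any
external HOSE dialect is a non-goal.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import SOURCE_HOSE, DataError, ShiftList, compound_id

logger = logging.getLogger("nmrlogd")

_ELEMENT_PRIORITY = {"C": 0, "O": 1, "N": 2, "F": 3, "Cl": 4, "Br": 5, "I": 6}
_RING_CLOSURE = "&"
_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "%",
    Chem.BondType.AROMATIC: "*",
}

DEFAULT_MAX_SPHERES = 6


def _atom_token(atom: Chem.Atom) -> str:
    tok = atom.GetSymbol()
    nh = atom.GetTotalNumHs(includeNeighbors=True)
    if nh:
        tok += f"H{nh}"
    chg = atom.GetFormalCharge()
    if chg:
        tok += f"{chg:+d}"
    return tok


def _element_rank(symbol: str) -> int:
    if symbol == _RING_CLOSURE:
        return 99
    return _ELEMENT_PRIORITY.get(symbol, 50)


def _bfs_distances(mol: Chem.Mol, start: int) -> list[int]:
    dist = [-1] * mol.GetNumAtoms()
    dist[start] = 0
    q = deque([start])
    while q:
        i = q.popleft()
        for nbr in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nbr.GetIdx()
            if dist[j] < 0:
                dist[j] = dist[i] + 1
                q.append(j)
    return dist


def _expand(mol: Chem.Mol, atom_idx: int, parent_idx: int, depth: int,
            dist: list[int]) -> tuple[str, ...]:
    """Per-sphere strings for the branch rooted just below ``atom_idx``.

    Only edges that strictly increase the BFS distance from the anchor are
    followed; backward or lateral edges are ring closures, emitted as a
    ``&`` token and not expanded further.
    """
    if depth == 0:
        return ()
    atom = mol.GetAtomWithIdx(atom_idx)
    entries: list[tuple[int, str, tuple[str, ...]]] = []
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        j = nbr.GetIdx()
        if j == parent_idx:
            continue
        bsym = _BOND_SYMBOL.get(bond.GetBondType(), "?")
        if dist[j] <= dist[atom_idx]:
            entries.append((_element_rank(_RING_CLOSURE), bsym + _RING_CLOSURE, ()))
        else:
            sub = _expand(mol, j, atom_idx, depth - 1, dist)
            entries.append((_element_rank(nbr.GetSymbol()), bsym + _atom_token(nbr), sub))
    # Sorting by the full-depth key keeps truncated codes consistent with
    # shallow encodings: ties within the truncated depth are, by
    # construction, string-identical there.
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    spheres = ["".join(tok for _, tok, _ in entries)]
    for d in range(depth - 1):
        spheres.append(",".join(sub[d] if d < len(sub) else "" for _, _, sub in entries))
    return tuple(spheres)


def encode_hose(mol: Chem.Mol, hydrogen_anchor: int,
                max_spheres: int = DEFAULT_MAX_SPHERES) -> str:
    """Canonical spherical-environment code for the hydrogens on one anchor.

    ``hydrogen_anchor`` is the index of a heavy atom bearing at least one
    hydrogen.  Spheres are separated by ``/``; ``truncate_hose`` recovers
    any shallower encoding from a deeper one.
    """
    if max_spheres < 1:
        raise ValueError("max_spheres must be >= 1")
    atom = mol.GetAtomWithIdx(int(hydrogen_anchor))
    if atom.GetTotalNumHs(includeNeighbors=True) < 1:
        raise DataError(
            f"anchor atom {hydrogen_anchor} ({atom.GetSymbol()}) bears no hydrogen")
    dist = _bfs_distances(mol, int(hydrogen_anchor))
    spheres = _expand(mol, int(hydrogen_anchor), -1, max_spheres, dist)
    return _atom_token(atom) + "|" + "/".join(spheres)


def truncate_hose(code: str, spheres: int) -> str:
    root, _, rest = code.partition("|")
    return root + "|" + "/".join(rest.split("/")[:spheres])


@dataclass
class ShiftTable:
    """HOSE code → (aggregated shift, support count) lookup, per sphere depth.

    Aggregation is the unweighted mean by default; ``aggregate="median"``
    is available as an alternative robust summary.
    """

    max_spheres: int = DEFAULT_MAX_SPHERES
    aggregate: str = "mean"
    # depth -> code -> list of observed shifts
    _obs: dict[int, dict[str, list[float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aggregate not in ("mean", "median"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")

    def _summary(self, values: list[float]) -> float:
        return float(np.median(values)) if self.aggregate == "median" else \
            float(np.mean(values))

    def add(self, depth: int, code: str, shift: float) -> None:
        self._obs.setdefault(depth, {}).setdefault(code, []).append(float(shift))

    def lookup(self, depth: int, code: str) -> float | None:
        values = self._obs.get(depth, {}).get(code)
        return self._summary(values) if values else None

    def mean_and_count(self, depth: int, code: str) -> tuple[float, int] | None:
        values = self._obs.get(depth, {}).get(code)
        return (self._summary(values), len(values)) if values else None

    @property
    def n_codes(self) -> int:
        return sum(len(v) for v in self._obs.values())

    def is_empty(self) -> bool:
        return self.n_codes == 0

    def global_mean(self) -> float:
        depth1 = self._obs.get(1, {})
        values = [v for obs in depth1.values() for v in obs]
        if not values:
            raise DataError("empty shift table has no global mean")
        return self._summary(values)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"spheres": d, "hose_code": code,
             "mean_shift_ppm": self._summary(obs), "count": len(obs)}
            for d, codes in sorted(self._obs.items())
            for code, obs in sorted(codes.items())
        ]
        return pd.DataFrame(rows, columns=["spheres", "hose_code", "mean_shift_ppm", "count"])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "ShiftTable":
        """Load a serialized table; per-code observations collapse to their
        stored summary value (repeated ``count`` times to preserve weights)."""
        df = pd.read_csv(path)
        table = cls(max_spheres=int(df["spheres"].max()) if len(df) else DEFAULT_MAX_SPHERES)
        for row in df.itertuples(index=False):
            table._obs.setdefault(int(row.spheres), {})[str(row.hose_code)] = \
                [float(row.mean_shift_ppm)] * int(row.count)
        return table


def build_table(training: list[tuple[Chem.Mol, ShiftList]],
                max_spheres: int = DEFAULT_MAX_SPHERES) -> ShiftTable:
    """Aggregate mapped per-hydrogen shifts into a HOSE lookup table.

    Every shift must carry an anchor heavy-atom index (``h_indices``); each
    observation is registered at every sphere depth 1..max_spheres so that
    prediction can fall back sphere by sphere.
    """
    unmapped = [compound_id(m) or sl.compound_id for m, sl in training if sl.h_indices is None]
    if unmapped:
        raise DataError(f"shift lists without atom mapping: {unmapped}")
    table = ShiftTable(max_spheres=max_spheres)
    for mol, sl in training:
        for shift, anchor in zip(sl.shifts, sl.h_indices):
            deep = encode_hose(mol, anchor, max_spheres)
            for depth in range(1, max_spheres + 1):
                table.add(depth, truncate_hose(deep, depth), shift)
    if table.is_empty():
        logger.warning("build_table: empty training set, empty table")
    return table


def predict_shifts_detailed(mol: Chem.Mol, table: ShiftTable,
                            max_spheres: int = DEFAULT_MAX_SPHERES
                            ) -> tuple[ShiftList, int]:
    """Predict per-hydrogen shifts; also return the global-mean fallback count.

    For each hydrogen-bearing heavy atom the deepest matching sphere code is
    used; chemically equivalent protons therefore receive identical shifts.
    """
    if table.is_empty():
        raise DataError("cannot predict from an empty shift table")
    shifts: list[float] = []
    h_indices: list[int] = []
    n_fallback = 0
    depth_cap = min(max_spheres, table.max_spheres)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        nh = atom.GetTotalNumHs(includeNeighbors=True)
        if nh == 0:
            continue
        deep = encode_hose(mol, atom.GetIdx(), depth_cap)
        value = None
        for depth in range(depth_cap, 0, -1):
            value = table.lookup(depth, truncate_hose(deep, depth))
            if value is not None:
                break
        if value is None:
            value = table.global_mean()
            n_fallback += nh
        shifts.extend([value] * nh)
        h_indices.extend([atom.GetIdx()] * nh)
    if n_fallback:
        logger.info("predict_shifts(%s): %d proton(s) fell back to the table "
                    "global mean", compound_id(mol), n_fallback)
    sl = ShiftList(compound_id=compound_id(mol), shifts=np.array(shifts),
                   h_indices=h_indices, source=SOURCE_HOSE)
    return sl, n_fallback


def predict_shifts(mol: Chem.Mol, table: ShiftTable,
                   max_spheres: int = DEFAULT_MAX_SPHERES) -> ShiftList:
    return predict_shifts_detailed(mol, table, max_spheres)[0]
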