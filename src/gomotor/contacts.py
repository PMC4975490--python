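"""Native, exclusive, interface and phosphate-mediated contact maps.

A native contact is a residue pair whose C-alpha distance in the reference
conformation is below the cutoff (default 0.8 nm) with sequence separation
(j - i) > 3 within a chain.  Contact maps are tagged by the Hamiltonian term
they feed (preMH, preConv, postConv, preConvMH, postConvMH, actin, Pi) and
serialize to TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import CAlphaStructure

VALID_TAGS = {"preMH", "preConv", "postConv", "preConvMH", "postConvMH",
              "actin", "Pi", "toy"}


@dataclass
class ContactMap:
    """Tagged set of native pairs (i < j, 1-based) with native distances r0 (nm)."""

    i: np.ndarray
    j: np.ndarray
    r0: np.ndarray
    tag: str
    cutoff: float = 0.8
    min_seq_sep: int = 3

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.r0 = np.asarray(self.r0, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.r0)):
            raise ValueError("i, j, r0 must have equal length")
        if len(self.i):
            if np.any(self.i >= self.j):
                raise ValueError("entries must satisfy i < j")
            if np.any(self.r0 >= self.cutoff):
                raise ValueError("r0 must be below the cutoff")
            pairs = self.pair_set()
            if len(pairs) != len(self.i):
                raise ValueError("duplicate (i, j) pair in contact map")
        # canonical ordering makes maps comparable and serialization stable
        order = np.lexsort((self.j, self.i))
        self.i, self.j, self.r0 = self.i[order], self.j[order], self.r0[order]

    def __len__(self) -> int:
        return len(self.i)

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"i": self.i, "j": self.j,
                             "r0_nm": self.r0, "tag": self.tag})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, cutoff: float = 0.8, min_seq_sep: int = 3) -> "ContactMap":
        df = pd.read_csv(path, sep="\t")
        tag = str(df["tag"].iloc[0]) if len(df) else "toy"
        return cls(df["i"].to_numpy(), df["j"].to_numpy(),
                   df["r0_nm"].to_numpy(), tag, cutoff, min_seq_sep)

    def dense(self, n: int) -> np.ndarray:
        """Symmetric boolean N x N matrix for contact-map plots."""
        m = np.zeros((n, n), dtype=bool)
        m[self.i - 1, self.j - 1] = True
        m[self.j - 1, self.i - 1] = True
        return m


def native_contacts(structure: CAlphaStructure, group, cutoff: float = 0.8,
                    min_seq_sep: int = 3, tag: str = "toy") -> ContactMap:
    """All pairs within ``group`` closer than ``cutoff`` with (j - i) > min_seq_sep."""
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        raise ValueError("empty group")
    xyz = structure.coords_of(group)
    d = cdist(xyz, xyz)
    gi = group[:, None]
    gj = group[None, :]
    mask = (d < cutoff) & (gj - gi > min_seq_sep)
    a, b = np.nonzero(mask)
    return ContactMap(gi[a, 0], gj[0, b], d[a, b], tag, cutoff, min_seq_sep)


def interface_contacts(structure: CAlphaStructure, groupA, groupB,
                       cutoff: float = 0.8, min_seq_sep: int = 3,
                       tag: str = "toy") -> ContactMap:
    """Cross contacts with one endpoint in each group.

    The (j - i) > min_seq_sep filter applies only to pairs on the same chain
    (the native-contact definition is global along a chain); pairs on
    different chains (e.g. myosin vs actin) are never filtered.  Pass
    ``min_seq_sep=0`` for the unfiltered cross-product.
    """
    groupA = np.asarray(groupA, dtype=int)
    groupB = np.asarray(groupB, dtype=int)
    if groupA.size == 0 or groupB.size == 0:
        raise ValueError("empty group")
    if np.intersect1d(groupA, groupB).size:
        raise ValueError("groups overlap")
    d = cdist(structure.coords_of(groupA), structure.coords_of(groupB))
    same_chain = (structure.chain_ids[groupA - 1][:, None]
                  == structure.chain_ids[groupB - 1][None, :])
    sep = np.abs(groupB[None, :] - groupA[:, None])
    mask = (d < cutoff) & (~same_chain | (sep > min_seq_sep))
    a, b = np.nonzero(mask)
    i = np.minimum(groupA[a], groupB[b])
    j = np.maximum(groupA[a], groupB[b])
    return ContactMap(i, j, d[a, b], tag, cutoff, min_seq_sep)


def exclusive_contacts(A: ContactMap, B: ContactMap, tag=None) -> ContactMap:
    """Entries of A whose (i, j) pair is absent from B (Fig-2B-style exclusive
    converter-MH contacts); r0 taken from A."""
    other = B.pair_set()
    keep = np.array([(ii, jj) not in other
                     for ii, jj in zip(A.i, A.j)], dtype=bool)
    if len(A) == 0:
        keep = np.zeros(0, dtype=bool)
    return ContactMap(A.i[keep], A.j[keep], A.r0[keep],
                      tag or A.tag, A.cutoff, A.min_seq_sep)


def shared_contacts(A: ContactMap, B: ContactMap, tag=None) -> ContactMap:
    """Entries of A whose pair also occurs in B (r0 from A)."""
    other = B.pair_set()
    keep = np.array([(ii, jj) in other for ii, jj in zip(A.i, A.j)], dtype=bool)
    if len(A) == 0:
        keep = np.zeros(0, dtype=bool)
    return ContactMap(A.i[keep], A.j[keep], A.r0[keep],
                      tag or A.tag, A.cutoff, A.min_seq_sep)


def pi_mediated_contacts(structure: CAlphaStructure, native: ContactMap,
                         lig_cutoff: float = 0.8, mode: str = "both"):
    """Identify the phosphate-coordinating residue set and the native-contact
    subset to remove on Pi release.

    A residue coordinates Pi if its C-alpha lies within ``lig_cutoff`` of any
    phosphate ligand atom.  With ``mode="both"`` (default) the removal subset
    is the native entries with *both* endpoints coordinating — the literal
    reading of a contact bridged through the ligand; ``mode="any"`` removes
    every native contact touching one coordinating residue.

    Returns ``(coordinating_beads, removal_map)``.
    """
    phos = structure.phosphate_atoms()
    if phos.shape[0] == 0:
        raise ValueError("structure has no phosphate ligand")
    if mode not in ("both", "any"):
        raise ValueError("mode must be 'both' or 'any'")
    d = cdist(structure.coords, phos)
    coord_beads = np.nonzero((d < lig_cutoff).any(axis=1))[0] + 1
    cs = set(coord_beads.tolist())
    if mode == "both":
        keep = np.array([ii in cs and jj in cs
                         for ii, jj in zip(native.i, native.j)], dtype=bool)
    else:
        keep = np.array([ii in cs or jj in cs
                         for ii, jj in zip(native.i, native.j)], dtype=bool)
    if len(native) == 0:
        keep = np.zeros(0, dtype=bool)
    subset = ContactMap(native.i[keep], native.j[keep], native.r0[keep],
                        "Pi", native.cutoff, native.min_seq_sep)
    return coord_beads, subset


def remove_contacts(cmap: ContactMap, subset: ContactMap) -> ContactMap:
    """Set difference ``cmap`` minus ``subset`` (subset must be contained)."""
    pairs = cmap.pair_set()
    missing = [p for p in subset.pair_set() if p not in pairs]
    if missing:
        raise ValueError(f"subset entries absent from map: {sorted(missing)[:5]}")
    drop = subset.pair_set()
    keep = np.array([(ii, jj) not in drop
                     for ii, jj in zip(cmap.i, cmap.j)], dtype=bool)
    if len(cmap) == 0:
        keep = np.zeros(0, dtype=bool)
    return ContactMap(cmap.i[keep], cmap.j[keep], cmap.r0[keep],
                      cmap.tag, cmap.cutoff, cmap.min_seq_sep)
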