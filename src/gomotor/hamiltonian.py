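"""Assembly and evaluation of the six-term multi-basin energy function.

The full Hamiltonian is the additive sum

    H = H_preMH + H_preConv + H_postConv + H_preConv-MH + H_postConv-MH + H_MH-Actin

where each intra-domain term carries harmonic bonds/angles, 1,3-cosine
dihedrals and 10-12 native contacts measured from its reference
conformation, the cross terms carry native contacts only, and every
non-native pair feels the (sigma/r)^12 repulsion exactly once.  Scenario
logic switches individual terms on or off; phosphate release removes the
Pi-mediated subset from the preMH contact list.

Energies are reported in units of the contact depth eps_h.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .contacts import ContactMap, remove_contacts
from .structure import CAlphaStructure, DomainPartition

TERM_TAGS = ("preMH", "preConv", "postConv", "preConvMH", "postConvMH", "MHActin")


@dataclass
class ForceFieldParams:
    """Force-field constants in their conventional units.

    k_bond in kcal/(mol A^2), k_angle in kcal/(mol rad^2), dihedral
    amplitudes and contact depths in kcal/mol, sigma in nm.  ``reduced()``
    converts to internal units (nm, eps_h, m = 1).
    """

    k_bond: float = 20.0
    k_angle: float = 20.0
    k_phi1: float = 1.0
    k_phi3: float = 0.5
    eps_h: float = 1.0
    eps_l: float = 1.0
    sigma: float = 0.4
    mass: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_bond", "k_angle", "k_phi1", "k_phi3",
                     "eps_h", "eps_l", "sigma", "mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def reduced(self) -> dict:
        e = self.eps_h
        return {
            "k_bond": self.k_bond * 100.0 / e,   # per A^2 -> per nm^2
            "k_angle": self.k_angle / e,
            "k_phi1": self.k_phi1 / e,
            "k_phi3": self.k_phi3 / e,
            "eps_l": self.eps_l / e,
            "sigma": self.sigma,
            "mass": self.mass,
        }


# ---------------------------------------------------------------------------
# native internal coordinates
# ---------------------------------------------------------------------------

def angle_between(p1, p2, p3) -> float:
    u = np.asarray(p1, float) - p2
    w = np.asarray(p3, float) - p2
    c = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral in (-pi, pi]; 0 for a degenerate (collinear) frame."""
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    b3 = np.asarray(p4, float) - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.dot(n1, n1) < 1e-16 or np.dot(n2, n2) < 1e-16 or nb2 < 1e-12:
        return 0.0
    return float(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))


@dataclass
class BondedTopology:
    """Native bonds, angles and dihedrals of one consecutive bead group."""

    bonds: np.ndarray          # (nb, 2) 1-based
    bond_r0: np.ndarray        # nm
    angles: np.ndarray         # (na, 3)
    theta0: np.ndarray         # rad
    dihedrals: np.ndarray      # (nd, 4)
    phi0: np.ndarray           # rad

    def __len__(self) -> int:
        return len(self.bonds) + len(self.angles) + len(self.dihedrals)


def build_bonded(structure: CAlphaStructure, group) -> BondedTopology:
    """Measure native bonded geometry over a contiguous bead range.

    For N beads this yields N-1 bonds, N-2 angles and N-3 dihedrals.
    """
    group = np.asarray(group, dtype=int)
    group.sort()
    if group.size == 0:
        raise ValueError("empty group")
    if not np.array_equal(group, np.arange(group[0], group[-1] + 1)):
        raise ValueError("group must be a contiguous index range")
    xyz = structure.coords_of(group)
    n = len(group)
    bonds = np.column_stack([group[:-1], group[1:]]) if n > 1 \
        else np.zeros((0, 2), dtype=int)
    bond_r0 = np.linalg.norm(np.diff(xyz, axis=0), axis=1) if n > 1 \
        else np.zeros(0)
    angles = np.column_stack([group[:-2], group[1:-1], group[2:]]) if n > 2 \
        else np.zeros((0, 3), dtype=int)
    theta0 = np.array([angle_between(xyz[k], xyz[k + 1], xyz[k + 2])
                       for k in range(n - 2)])
    dihedrals = np.column_stack([group[:-3], group[1:-2], group[2:-1], group[3:]]) \
        if n > 3 else np.zeros((0, 4), dtype=int)
    phi0 = np.array([dihedral_angle(xyz[k], xyz[k + 1], xyz[k + 2], xyz[k + 3])
                     for k in range(n - 3)])
    return BondedTopology(bonds, bond_r0, angles, theta0, dihedrals, phi0)


@dataclass
class TermSet:
    """Flat term arrays of one Hamiltonian term (1-based bead indices)."""

    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), int))
    phi0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dih_k1: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dih_k3: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pairs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    pair_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pair_eps: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def from_bonded(cls, topo: BondedTopology, red: dict) -> "TermSet":
        nb, na, nd = len(topo.bonds), len(topo.angles), len(topo.dihedrals)
        return cls(
            bonds=topo.bonds, bond_r0=topo.bond_r0,
            bond_k=np.full(nb, red["k_bond"]),
            angles=topo.angles, theta0=topo.theta0,
            angle_k=np.full(na, red["k_angle"]),
            dihedrals=topo.dihedrals, phi0=topo.phi0,
            dih_k1=np.full(nd, red["k_phi1"]),
            dih_k3=np.full(nd, red["k_phi3"]),
        )

    def with_contacts(self, cmap: ContactMap, eps: float = 1.0) -> "TermSet":
        return replace(
            self,
            pairs=np.column_stack([cmap.i, cmap.j]) if len(cmap)
            else np.zeros((0, 2), int),
            pair_r0=cmap.r0, pair_eps=np.full(len(cmap), eps),
        )

    def n_terms(self) -> int:
        return (len(self.bonds) + len(self.angles) + len(self.dihedrals)
                + len(self.pairs))


class EnergyModel:
    """Assembled multi-basin model: term sets, toggles, frozen beads, forces.

    Use :func:`assemble` to construct one.  ``set_toggles`` re-activates a
    different term subset (rebuilding the repulsive exclusion list);
    ``set_external_force`` attaches a constant pulling force in reduced
    units (see :mod:`gomotor.dynamics` for the kJ/mol/nm entry point).
    """

    def __init__(self, n_beads: int, chain_ids: np.ndarray,
                 term_sets: dict[str, TermSet], active: set[str],
                 params: ForceFieldParams, frozen=None,
                 pi_removed: bool = False, pi_subset_size: int = 0,
                 dedup_shared_converter: bool = False):
        self.n_beads = n_beads
        self.chain_ids = np.asarray(chain_ids)
        self.term_sets = term_sets
        self.params = params
        self.pi_removed = pi_removed
        self.pi_subset_size = pi_subset_size
        self.dedup_shared_converter = dedup_shared_converter
        self.frozen = np.zeros(n_beads, dtype=bool) if frozen is None \
            else np.asarray(frozen, dtype=bool).copy()
        self.external = np.zeros((n_beads, 3))
        self.set_toggles(active)

    # -- configuration ----------------------------------------------------

    def set_toggles(self, active) -> None:
        active = set(active)
        unknown = active - set(TERM_TAGS)
        if unknown:
            raise ValueError(f"unknown toggles: {sorted(unknown)}")
        missing = [t for t in active if t not in self.term_sets]
        if missing:
            raise ValueError(f"toggled-on term(s) without a map: {sorted(missing)}")
        self.active = active
        self._build_repulsion()

    def set_external_force(self, fext: np.ndarray | None) -> None:
        if fext is None:
            self.external = np.zeros((self.n_beads, 3))
        else:
            fext = np.asarray(fext, dtype=float)
            if fext.shape != (self.n_beads, 3):
                raise ValueError("external force must be (N, 3)")
            self.external = fext.copy()

    def active_term_sets(self) -> dict[str, TermSet]:
        out = {t: self.term_sets[t] for t in sorted(self.active)}
        if "linker" in self.term_sets:
            out["linker"] = self.term_sets["linker"]
        if self.dedup_shared_converter and "preConv" in out and "postConv" in out:
            out["postConv"] = self._dedup(out["postConv"], out["preConv"])
        if self.dedup_shared_converter and "preConvMH" in out and "postConvMH" in out:
            out["postConvMH"] = self._dedup(out["postConvMH"], out["preConvMH"])
        return out

    @staticmethod
    def _dedup(ts: TermSet, against: TermSet) -> TermSet:
        ref = {tuple(p) for p in against.pairs.tolist()}
        keep = np.array([tuple(p) not in ref for p in ts.pairs.tolist()],
                        dtype=bool) if len(ts.pairs) else np.zeros(0, bool)
        return replace(ts, pairs=ts.pairs[keep], pair_r0=ts.pair_r0[keep],
                       pair_eps=ts.pair_eps[keep])

    # -- repulsion bookkeeping --------------------------------------------

    def _build_repulsion(self) -> None:
        """All-pairs (sigma/r)^12 list: every pair except bonded neighbours
        (|i-j| <= 3 within a chain), pairs native in ANY active map, and
        frozen-frozen pairs (the filament has no internal terms)."""
        n = self.n_beads
        iu, ju = np.triu_indices(n, k=1)
        same_chain = self.chain_ids[iu] == self.chain_ids[ju]
        mask = ~(same_chain & (ju - iu <= 3))
        mask &= ~(self.frozen[iu] & self.frozen[ju])
        native = np.zeros((n, n), dtype=bool)
        for ts in self.active_term_sets().values():
            for idx in (ts.pairs.reshape(-1, 2), ts.bonds.reshape(-1, 2)):
                if len(idx):
                    native[idx[:, 0] - 1, idx[:, 1] - 1] = True
                    native[idx[:, 1] - 1, idx[:, 0] - 1] = True
        mask &= ~native[iu, ju]
        self.repulsive_pairs = np.column_stack([iu[mask] + 1, ju[mask] + 1])

    # -- packing for the kernels ------------------------------------------

    def pack(self):
        """Merge active term sets into flat 0-based arrays for the kernels."""
        sets = list(self.active_term_sets().values())

        def cat(parts, width=None, dtype=float):
            parts = [p for p in parts if len(p)]
            if not parts:
                if width:
                    return np.zeros((0, width), dtype=np.int64)
                return np.zeros(0, dtype=dtype)
            return np.concatenate(parts).astype(
                np.int64 if width else dtype).reshape(-1, width) \
                if width else np.concatenate(parts).astype(dtype)

        bonds = cat([t.bonds for t in sets], width=2) - 1
        angles = cat([t.angles for t in sets], width=3) - 1
        dihedrals = cat([t.dihedrals for t in sets], width=4) - 1
        pairs = cat([t.pairs for t in sets], width=2) - 1
        red = self.params.reduced()
        packed_ints = (
            np.ascontiguousarray(bonds), np.ascontiguousarray(angles),
            np.ascontiguousarray(dihedrals), np.ascontiguousarray(pairs),
            np.ascontiguousarray(self.repulsive_pairs.astype(np.int64) - 1),
        )
        packed_floats = (
            cat([t.bond_r0 for t in sets]), cat([t.bond_k for t in sets]),
            cat([t.theta0 for t in sets]), cat([t.angle_k for t in sets]),
            cat([t.phi0 for t in sets]), cat([t.dih_k1 for t in sets]),
            cat([t.dih_k3 for t in sets]),
            cat([t.pair_r0 for t in sets]), cat([t.pair_eps for t in sets]),
            np.array([red["eps_l"]]), np.array([red["sigma"]]),
        )
        return packed_ints, packed_floats

    def free_mask(self) -> np.ndarray:
        return (~self.frozen).astype(float)


def _junction_terms(pre: CAlphaStructure, post: CAlphaStructure,
                    mh_last: int, conv_first: int, red: dict, mode: str):
    """Bond (always) and optional basin-assigned angles/dihedrals spanning
    the MH->converter junction."""
    r0 = float(np.linalg.norm(pre.coords[conv_first - 1] - pre.coords[mh_last - 1]))
    linker = TermSet(bonds=np.array([[mh_last, conv_first]]),
                     bond_r0=np.array([r0]),
                     bond_k=np.array([red["k_bond"]]))
    extra: dict[str, TermSet] = {}
    if mode == "basin":
        for tag, st in (("preConv", pre), ("postConv", post)):
            quads, angs = [], []
            for start in range(mh_last - 2, mh_last + 1):
                q = [start, start + 1, start + 2, start + 3]
                if q[0] >= 1 and q[-1] <= st.n_beads and q[0] <= mh_last < q[-1]:
                    quads.append(q)
            for start in range(mh_last - 1, mh_last + 1):
                a = [start, start + 1, start + 2]
                if a[0] >= 1 and a[-1] <= st.n_beads and a[0] <= mh_last < a[-1]:
                    angs.append(a)
            xyz = st.coords
            extra[tag] = TermSet(
                angles=np.array(angs, int).reshape(-1, 3),
                theta0=np.array([angle_between(*(xyz[k - 1] for k in a))
                                 for a in angs]),
                angle_k=np.full(len(angs), red["k_angle"]),
                dihedrals=np.array(quads, int).reshape(-1, 4),
                phi0=np.array([dihedral_angle(*(xyz[k - 1] for k in q))
                               for q in quads]),
                dih_k1=np.full(len(quads), red["k_phi1"]),
                dih_k3=np.full(len(quads), red["k_phi3"]),
            )
    return linker, extra


def _merge_termsets(a: TermSet, b: TermSet) -> TermSet:
    return TermSet(
        bonds=np.vstack([a.bonds.reshape(-1, 2), b.bonds.reshape(-1, 2)]),
        bond_r0=np.concatenate([a.bond_r0, b.bond_r0]),
        bond_k=np.concatenate([a.bond_k, b.bond_k]),
        angles=np.vstack([a.angles.reshape(-1, 3), b.angles.reshape(-1, 3)]),
        theta0=np.concatenate([a.theta0, b.theta0]),
        angle_k=np.concatenate([a.angle_k, b.angle_k]),
        dihedrals=np.vstack([a.dihedrals.reshape(-1, 4), b.dihedrals.reshape(-1, 4)]),
        phi0=np.concatenate([a.phi0, b.phi0]),
        dih_k1=np.concatenate([a.dih_k1, b.dih_k1]),
        dih_k3=np.concatenate([a.dih_k3, b.dih_k3]),
        pairs=np.vstack([a.pairs.reshape(-1, 2), b.pairs.reshape(-1, 2)]),
        pair_r0=np.concatenate([a.pair_r0, b.pair_r0]),
        pair_eps=np.concatenate([a.pair_eps, b.pair_eps]),
    )


def assemble(pre: CAlphaStructure, post: CAlphaStructure,
             partition: DomainPartition, maps: dict[str, ContactMap],
             params: ForceFieldParams | None = None,
             toggles=("preMH", "preConv", "preConvMH"),
             pi_subset: ContactMap | None = None, pi_removed: bool = False,
             junction_bonded: str = "bond_only",
             dedup_shared_converter: bool = False) -> EnergyModel:
    """Build the multi-basin model from two conformations and contact maps.

    ``maps`` uses the term tags as keys ("preMH", "preConv", "postConv",
    "preConvMH", "postConvMH", "MHActin"); only maps for toggled-on terms
    are required.  With ``pi_removed`` the ``pi_subset`` entries are removed
    from the preMH contact list (phosphate release).  The frozen set is the
    partition's ``actin`` group, if present.
    """
    params = params or ForceFieldParams()
    red = params.reduced()
    partition.validate(pre.n_beads)
    toggles = set(toggles)
    mh = partition["MH"]
    conv = partition["converter"]

    term_sets: dict[str, TermSet] = {}
    if "preMH" in toggles:
        cmap = maps["preMH"] if "preMH" in maps else None
        if cmap is None:
            raise ValueError("toggled-on term preMH has no contact map")
        if pi_removed:
            if pi_subset is None:
                raise ValueError("pi_removed requires a pi_subset")
            cmap = remove_contacts(cmap, pi_subset)
        term_sets["preMH"] = TermSet.from_bonded(
            build_bonded(pre, mh), red).with_contacts(cmap)
    for tag, st in (("preConv", pre), ("postConv", post)):
        if tag in toggles:
            if tag not in maps:
                raise ValueError(f"toggled-on term {tag} has no contact map")
            term_sets[tag] = TermSet.from_bonded(
                build_bonded(st, conv), red).with_contacts(maps[tag])
    for tag in ("preConvMH", "postConvMH", "MHActin"):
        if tag in toggles:
            if tag not in maps:
                raise ValueError(f"toggled-on term {tag} has no contact map")
            term_sets[tag] = TermSet().with_contacts(maps[tag])

    # chain connectivity across the MH -> converter junction
    if conv.size and mh.size and conv.min() == mh.max() + 1:
        linker, extra = _junction_terms(pre, post, int(mh.max()),
                                        int(conv.min()), red, junction_bonded)
        term_sets["linker"] = linker
        for tag, ts in extra.items():
            if tag in term_sets:
                term_sets[tag] = _merge_termsets(term_sets[tag], ts)

    frozen = np.zeros(pre.n_beads, dtype=bool)
    if "actin" in partition and partition["actin"].size:
        frozen[partition["actin"] - 1] = True

    return EnergyModel(
        n_beads=pre.n_beads, chain_ids=pre.chain_ids, term_sets=term_sets,
        active=toggles, params=params, frozen=frozen, pi_removed=pi_removed,
        pi_subset_size=len(pi_subset) if pi_subset is not None else 0,
        dedup_shared_converter=dedup_shared_converter)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def potential_energy(model: EnergyModel, coords: np.ndarray):
    """Total potential energy (eps_h units) and a per-term breakdown."""
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.shape != (model.n_beads, 3):
        raise ValueError("coords shape mismatch")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    red = model.params.reduced()
    empty_rep = np.zeros((0, 2), dtype=np.int64)
    scratch = np.zeros_like(coords)
    breakdown: dict[str, float] = {}
    total = 0.0
    for tag, ts in model.active_term_sets().items():
        eb, ea, ed, ep, _ = _kernels._ef_terms(
            coords,
            np.ascontiguousarray(ts.bonds.reshape(-1, 2).astype(np.int64) - 1),
            ts.bond_r0.astype(float), ts.bond_k.astype(float),
            np.ascontiguousarray(ts.angles.reshape(-1, 3).astype(np.int64) - 1),
            ts.theta0.astype(float), ts.angle_k.astype(float),
            np.ascontiguousarray(ts.dihedrals.reshape(-1, 4).astype(np.int64) - 1),
            ts.phi0.astype(float), ts.dih_k1.astype(float), ts.dih_k3.astype(float),
            np.ascontiguousarray(ts.pairs.reshape(-1, 2).astype(np.int64) - 1),
            ts.pair_r0.astype(float), ts.pair_eps.astype(float),
            empty_rep, red["eps_l"], red["sigma"], scratch)
        breakdown[tag] = eb + ea + ed + ep
        total += breakdown[tag]
    scratch[:] = 0.0
    _, _, _, _, er = _kernels._ef_terms(
        coords, *(np.zeros((0, 2), np.int64), np.zeros(0), np.zeros(0)),
        np.zeros((0, 3), np.int64), np.zeros(0), np.zeros(0),
        np.zeros((0, 4), np.int64), np.zeros(0), np.zeros(0), np.zeros(0),
        np.zeros((0, 2), np.int64), np.zeros(0), np.zeros(0),
        np.ascontiguousarray(model.repulsive_pairs.astype(np.int64) - 1),
        red["eps_l"], red["sigma"], scratch)
    breakdown["repulsion"] = er
    total += er
    return total, breakdown


def forces(model: EnergyModel, coords: np.ndarray) -> np.ndarray:
    """Analytic forces, -dH/dr, with frozen beads zeroed and the external
    constant force added to its targets (eps_h / nm)."""
    coords = np.ascontiguousarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    packed_ints, packed_floats = model.pack()
    out = np.zeros_like(coords)
    _kernels._compute_forces(coords, packed_ints, packed_floats,
                             model.external, model.free_mask(), out)
    return out


# ---------------------------------------------------------------------------
# plain-text topology serialization
# ---------------------------------------------------------------------------

def write_topology(model: EnergyModel, path) -> None:
    """Plain-text topology: a JSON header (params, toggles, frozen) followed
    by one section per term set."""
    header = {
        "params": {k: getattr(model.params, k) for k in
                   ("k_bond", "k_angle", "k_phi1", "k_phi3",
                    "eps_h", "eps_l", "sigma", "mass")},
        "active": sorted(model.active),
        "pi_removed": model.pi_removed,
        "n_beads": model.n_beads,
        "chain_ids": self_chain_list(model),
        "frozen": (np.nonzero(model.frozen)[0] + 1).tolist(),
        "dedup_shared_converter": model.dedup_shared_converter,
    }
    buf = io.StringIO()
    buf.write("#HEADER " + json.dumps(header) + "\n")
    for tag in sorted(model.term_sets):
        ts = model.term_sets[tag]
        buf.write(f"[term {tag}]\n")
        for (i, j), r0, k in zip(ts.bonds.reshape(-1, 2), ts.bond_r0, ts.bond_k):
            buf.write(f"bond {i} {j} {r0:.17g} {k:.17g}\n")
        for (i, j, k_), t0, ka in zip(ts.angles.reshape(-1, 3), ts.theta0, ts.angle_k):
            buf.write(f"angle {i} {j} {k_} {t0:.17g} {ka:.17g}\n")
        for (a, b, c, d), p0, k1, k3 in zip(ts.dihedrals.reshape(-1, 4),
                                            ts.phi0, ts.dih_k1, ts.dih_k3):
            buf.write(f"dihedral {a} {b} {c} {d} {p0:.17g} {k1:.17g} {k3:.17g}\n")
        for (i, j), r0, e in zip(ts.pairs.reshape(-1, 2), ts.pair_r0, ts.pair_eps):
            buf.write(f"pair {i} {j} {r0:.17g} {e:.17g}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def self_chain_list(model: EnergyModel) -> list[str]:
    return [str(c) for c in model.chain_ids]


def read_topology(path) -> EnergyModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#HEADER "):
        raise ValueError("missing topology header")
    header = json.loads(lines[0][len("#HEADER "):])
    params = ForceFieldParams(**header["params"])
    term_sets: dict[str, TermSet] = {}
    tag = None
    acc: dict[str, list] = {}

    def flush():
        if tag is None:
            return
        term_sets[tag] = TermSet(
            bonds=np.array(acc["bond_idx"], int).reshape(-1, 2),
            bond_r0=np.array(acc["bond_r0"]), bond_k=np.array(acc["bond_k"]),
            angles=np.array(acc["ang_idx"], int).reshape(-1, 3),
            theta0=np.array(acc["theta0"]), angle_k=np.array(acc["angle_k"]),
            dihedrals=np.array(acc["dih_idx"], int).reshape(-1, 4),
            phi0=np.array(acc["phi0"]),
            dih_k1=np.array(acc["dih_k1"]), dih_k3=np.array(acc["dih_k3"]),
            pairs=np.array(acc["pair_idx"], int).reshape(-1, 2),
            pair_r0=np.array(acc["pair_r0"]), pair_eps=np.array(acc["pair_eps"]),
        )

    for line in lines[1:]:
        line = line.strip()
        if not line:
            continue
        if line.startswith("[term "):
            flush()
            tag = line[len("[term "):-1]
            acc = {k: [] for k in ("bond_idx", "bond_r0", "bond_k", "ang_idx",
                                   "theta0", "angle_k", "dih_idx", "phi0",
                                   "dih_k1", "dih_k3", "pair_idx", "pair_r0",
                                   "pair_eps")}
            continue
        parts = line.split()
        kind = parts[0]
        vals = [float(v) for v in parts[1:]]
        if kind == "bond":
            acc["bond_idx"].append([int(vals[0]), int(vals[1])])
            acc["bond_r0"].append(vals[2])
            acc["bond_k"].append(vals[3])
        elif kind == "angle":
            acc["ang_idx"].append([int(v) for v in vals[:3]])
            acc["theta0"].append(vals[3])
            acc["angle_k"].append(vals[4])
        elif kind == "dihedral":
            acc["dih_idx"].append([int(v) for v in vals[:4]])
            acc["phi0"].append(vals[4])
            acc["dih_k1"].append(vals[5])
            acc["dih_k3"].append(vals[6])
        elif kind == "pair":
            acc["pair_idx"].append([int(vals[0]), int(vals[1])])
            acc["pair_r0"].append(vals[2])
            acc["pair_eps"].append(vals[3])
    flush()

    frozen = np.zeros(header["n_beads"], dtype=bool)
    if header["frozen"]:
        frozen[np.array(header["frozen"], int) - 1] = True
    return EnergyModel(
        n_beads=header["n_beads"], chain_ids=np.array(header["chain_ids"]),
        term_sets=term_sets, active=set(header["active"]), params=params,
        frozen=frozen, pi_removed=header["pi_removed"],
        dedup_shared_converter=header.get("dedup_shared_converter", False))
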