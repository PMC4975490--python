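"""Scenario orchestration: wire toggles, run, analyse, write provenance.

The mechanochemical-cycle scenarios map onto term toggles of the six-term
Hamiltonian:

========================  ====================================================
scenario                  active terms
========================  ====================================================
leading                   preMH, preConv, preConvMH, MHActin
trailing                  preMH, postConv, postConvMH, MHActin
powerstroke_with_pi       all six
powerstroke_without_pi    all six, Pi-mediated subset removed from preMH
strain_scan               trailing terms + constant pulling force on the
                          converter along the actin axis (0/3/5 kJ/mol/nm)
toy_demo                  leading + trailing on the synthetic toy motor
========================  ====================================================

Inputs are either the synthetic toy motor (default) or user-supplied
PDB files plus a residue-range partition; all numeric knobs live in a single
YAML/JSON config.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import (DistributionSummary, basin_populations,
                       group_distance_series, rmsd_distribution)
from .contacts import (interface_contacts, native_contacts,
                       pi_mediated_contacts)
from .dynamics import (ExternalForce, LangevinConfig, Trajectory, actin_axis,
                       langevin_run)
from .hamiltonian import ForceFieldParams, assemble, write_topology
from .structure import (CAlphaStructure, DomainPartition, fitted_rmsd,
                        map_actin, partition_from_ranges, read_calpha,
                        write_xyz)
from .synthetic import (ToyMotorSpec, default_pocket, make_toy_filament,
                        make_toy_ligand, make_toy_motor)

SCENARIOS = ("leading", "trailing", "powerstroke_with_pi",
             "powerstroke_without_pi", "strain_scan", "toy_demo")

TOGGLES = {
    "leading": ("preMH", "preConv", "preConvMH", "MHActin"),
    "trailing": ("preMH", "postConv", "postConvMH", "MHActin"),
    "powerstroke_with_pi": ("preMH", "preConv", "postConv", "preConvMH",
                            "postConvMH", "MHActin"),
    "powerstroke_without_pi": ("preMH", "preConv", "postConv", "preConvMH",
                               "postConvMH", "MHActin"),
    "strain_scan": ("preMH", "postConv", "postConvMH", "MHActin"),
}


class ConfigError(ValueError):
    """Scenario configuration problem (missing input, bad partition, ...)."""


@dataclass
class ScenarioConfig:
    """Declarative description of one simulation scenario.

    With ``toy=True`` (default) the structures come from the synthetic
    generator; otherwise ``pre_pdb``/``post_pdb`` paths plus
    ``partition_ranges`` (and, for actin, an aligned template with an
    explicit bead correspondence) are required.
    """

    scenario: str = "toy_demo"
    seed: int = 0
    outdir: str | None = None

    # --- structures
    toy: bool = True
    toy_spec: dict = field(default_factory=dict)          # ToyMotorSpec overrides
    filament_beads: int = 10
    filament_spacing: float = 0.55
    pre_pdb: str | None = None
    post_pdb: str | None = None
    actin_template_pdb: str | None = None
    actin_correspondence: list | None = None              # (motor, template) pairs
    actin_template_actin_beads: list | None = None
    partition_ranges: dict | None = None

    # --- model
    params: dict = field(default_factory=dict)            # ForceFieldParams overrides
    cutoff: float = 0.8
    min_seq_sep: int = 3
    pi_mode: str = "any"
    pi_lig_cutoff: float = 0.8
    junction_bonded: str = "bond_only"
    dedup_shared_converter: bool = False

    # --- sampling
    langevin: dict = field(default_factory=dict)          # LangevinConfig overrides
    n_sample: int | None = None                           # scenario default if None
    replicas: int = 1                                     # pooled independent runs
    strain_magnitudes: list = field(default_factory=lambda: [0.0, 3.0, 5.0])
    strain_per_bead: bool = True
    write_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; "
                              f"choose one of {SCENARIOS}")
        if not self.toy:
            missing = [n for n in ("pre_pdb", "post_pdb", "partition_ranges")
                       if getattr(self, n) is None]
            if missing:
                raise ConfigError(
                    f"file-based run needs {missing}; or set toy: true")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def force_field(self) -> ForceFieldParams:
        return ForceFieldParams(**self.params)

    def langevin_config(self, n_sample_default: int,
                        replica: int = 0) -> LangevinConfig:
        kw = dict(self.langevin)
        kw.setdefault("seed", self.seed)
        kw.setdefault("n_relax", 20_000)
        kw.setdefault("save_every", 500)
        kw.setdefault("n_sample", self.n_sample or n_sample_default)
        if replica:
            kw["seed"] = replica_seed(kw["seed"], replica)
        return LangevinConfig(**kw)


def replica_seed(seed: int, replica: int) -> int:
    """Derived seed for pooled replicas, kept below 2^31."""
    return (seed * 1_000_003 + replica) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------

@dataclass
class MotorSystem:
    """Everything needed to assemble and analyse one motor model."""

    pre: CAlphaStructure            # pre conformation, actin beads appended
    post: CAlphaStructure           # post conformation (myosin beads only)
    partition: DomainPartition
    maps: dict
    pi_subset: object               # ContactMap or None
    axis: np.ndarray | None         # actin axis, if actin present

    def trailing_coords(self) -> np.ndarray:
        """Composite trailing-head start: pre body with the converter taken
        from the post conformation (superposed over the MH anchor)."""
        conv = self.partition["converter"]
        mh = self.partition["MH"]
        from .structure import apply_transform, kabsch_superpose
        R, t, _ = kabsch_superpose(self.post.coords_of(mh),
                                   self.pre.coords_of(mh))
        coords = self.pre.coords.copy()
        coords[conv - 1] = apply_transform(self.post.coords_of(conv), R, t)
        return coords

    def post_reference_rmsd(self) -> float:
        """Converter RMSD (after MH fit) of the post pose vs the pre
        reference — sets the midpoint threshold between the two basins."""
        frame = self.trailing_coords()
        return fitted_rmsd(frame, self.pre, self.partition["MH"],
                           self.partition["converter"])


def _with_actin(st: CAlphaStructure, fil: CAlphaStructure) -> CAlphaStructure:
    return CAlphaStructure(
        coords=np.vstack([st.coords, fil.coords]),
        chain_ids=np.concatenate([st.chain_ids, fil.chain_ids]),
        res_numbers=np.concatenate([st.res_numbers, fil.res_numbers]),
        res_names=np.concatenate([st.res_names, fil.res_names]),
        ligands=list(st.ligands),
    )


def build_toy_system(spec: ToyMotorSpec | None = None, with_actin: bool = True,
                     filament_beads: int = 10, filament_spacing: float = 0.55,
                     cutoff: float = 0.8, min_seq_sep: int = 3,
                     pi_mode: str = "any", pi_lig_cutoff: float = 0.8) -> MotorSystem:
    """Assemble the toy motor with filament, contact maps and Pi subset.

    The filament is laid under the slab with its bead order chosen so that
    the actin axis (toward increasing bead index) points away from the
    converter docks — the forward-strain direction of the trailing head.
    """
    spec = spec or ToyMotorSpec()
    pre, post, partition = make_toy_motor(spec)
    axis = None
    if with_actin:
        n_my = pre.n_beads
        fil = make_toy_filament(filament_beads, filament_spacing,
                                axis=(-1.0, 0.0, 0.0),
                                origin=(5.0, 0.235, -0.62))
        pre = _with_actin(pre, fil)
        actin = np.arange(n_my + 1, n_my + filament_beads + 1)
        groups = dict(partition.groups)
        groups["actin"] = actin
        partition = DomainPartition(groups)
        partition.validate(pre.n_beads)
        axis = actin_axis(pre.coords[n_my:])
    mh, conv = partition["MH"], partition["converter"]
    maps = {
        "preMH": native_contacts(pre, mh, cutoff, min_seq_sep, tag="preMH"),
        "preConv": native_contacts(pre, conv, cutoff, min_seq_sep, tag="preConv"),
        "postConv": native_contacts(post, conv, cutoff, min_seq_sep, tag="postConv"),
        "preConvMH": interface_contacts(pre, conv, mh, cutoff, min_seq_sep,
                                        tag="preConvMH"),
        "postConvMH": interface_contacts(post, conv, mh, cutoff, min_seq_sep,
                                         tag="postConvMH"),
    }
    if with_actin:
        maps["MHActin"] = interface_contacts(pre, mh, partition["actin"],
                                             cutoff, min_seq_sep, tag="actin")
    lig = make_toy_ligand(pre, default_pocket(spec))
    _, pi_subset = pi_mediated_contacts(lig, maps["preMH"],
                                        lig_cutoff=pi_lig_cutoff, mode=pi_mode)
    return MotorSystem(pre, post, partition, maps, pi_subset, axis)


def build_file_system(config: ScenarioConfig) -> MotorSystem:
    """Assemble a motor model from PDB files per the config."""
    try:
        pre = read_calpha(Path(config.pre_pdb).read_text())
        post = read_calpha(Path(config.post_pdb).read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"missing structure file: {exc.filename}") from exc
    partition = partition_from_ranges(pre, config.partition_ranges)
    axis = None
    if config.actin_template_pdb is not None:
        if not (config.actin_correspondence and config.actin_template_actin_beads):
            raise ConfigError("actin template needs actin_correspondence and "
                              "actin_template_actin_beads")
        template = read_calpha(Path(config.actin_template_pdb).read_text())
        actin_xyz = map_actin(pre, template, config.actin_correspondence,
                              config.actin_template_actin_beads)
        n_my = pre.n_beads
        fil = CAlphaStructure(
            coords=actin_xyz,
            chain_ids=np.full(len(actin_xyz), "F"),
            res_numbers=np.arange(1, len(actin_xyz) + 1),
            res_names=np.full(len(actin_xyz), "ACT"))
        pre = _with_actin(pre, fil)
        groups = dict(partition.groups)
        groups["actin"] = np.arange(n_my + 1, pre.n_beads + 1)
        partition = DomainPartition(groups)
        partition.validate(pre.n_beads)
        axis = actin_axis(actin_xyz)
    mh, conv = partition["MH"], partition["converter"]
    c, s = config.cutoff, config.min_seq_sep
    maps = {
        "preMH": native_contacts(pre, mh, c, s, tag="preMH"),
        "preConv": native_contacts(pre, conv, c, s, tag="preConv"),
        "postConv": native_contacts(post, conv, c, s, tag="postConv"),
        "preConvMH": interface_contacts(pre, conv, mh, c, s, tag="preConvMH"),
        "postConvMH": interface_contacts(post, conv, mh, c, s, tag="postConvMH"),
    }
    if "actin" in partition and partition["actin"].size:
        maps["MHActin"] = interface_contacts(pre, mh, partition["actin"],
                                             c, s, tag="actin")
    pi_subset = None
    if pre.phosphate_atoms().shape[0]:
        _, pi_subset = pi_mediated_contacts(pre, maps["preMH"],
                                            lig_cutoff=config.pi_lig_cutoff,
                                            mode=config.pi_mode)
    return MotorSystem(pre, post, partition, maps, pi_subset, axis)


def build_system(config: ScenarioConfig) -> MotorSystem:
    if config.toy:
        return build_toy_system(
            ToyMotorSpec(**config.toy_spec),
            filament_beads=config.filament_beads,
            filament_spacing=config.filament_spacing,
            cutoff=config.cutoff, min_seq_sep=config.min_seq_sep,
            pi_mode=config.pi_mode, pi_lig_cutoff=config.pi_lig_cutoff)
    return build_file_system(config)


# ---------------------------------------------------------------------------
# scenario runners
# ---------------------------------------------------------------------------

def _assemble(system: MotorSystem, config: ScenarioConfig, toggles,
              pi_removed: bool = False):
    if pi_removed and system.pi_subset is None:
        raise ConfigError("Pi-removal scenario needs a phosphate ligand "
                          "(none found in the pre structure)")
    return assemble(system.pre, system.post, system.partition, system.maps,
                    params=config.force_field(), toggles=toggles,
                    pi_subset=system.pi_subset, pi_removed=pi_removed,
                    junction_bonded=config.junction_bonded,
                    dedup_shared_converter=config.dedup_shared_converter)


def _head_summaries(traj: Trajectory, system: MotorSystem) -> dict:
    """Fig 3-style observables for a leading/trailing trajectory."""
    p = system.partition
    ref = system.pre
    out = {
        "small_subunit_rmsd": rmsd_distribution(traj, ref, p["MH_big"], p["MH_small"]),
        "converter_rmsd": rmsd_distribution(traj, ref, p["MH"], p["converter"]),
        "d_swI_ploop": group_distance_series(traj, p["P_loop"], p["switch_I"]),
        "d_swII_ploop": group_distance_series(traj, p["P_loop"], p["switch_II"]),
        "d_swI_swII": group_distance_series(traj, p["switch_I"], p["switch_II"]),
    }
    for motif in ("P_loop", "switch_I", "switch_II"):
        out[f"rmsd_{motif}"] = rmsd_distribution(traj, ref, p["MH_big"], p[motif])
    return out


def _summary_json(summaries: dict) -> dict:
    out = {}
    for key, val in summaries.items():
        if isinstance(val, DistributionSummary):
            out[key] = val.to_dict()
        elif isinstance(val, dict):
            out[key] = _summary_json(val)
        else:
            out[key] = val
    return out


def run_scenario(config: ScenarioConfig) -> dict:
    """Run one scenario end-to-end; returns a result bundle.

    The bundle maps scenario-specific keys to trajectories and
    :class:`DistributionSummary` objects, plus ``provenance``.  With
    ``config.outdir`` set, summaries (JSON), per-frame observables (TSV),
    provenance and — optionally — XYZ trajectories are written there.
    """
    t_start = time.time()
    system = build_system(config)
    bundle: dict = {"scenario": config.scenario}
    scenario = config.scenario

    if scenario in ("leading", "trailing"):
        model = _assemble(system, config, TOGGLES[scenario])
        init = system.pre.coords if scenario == "leading" \
            else system.trailing_coords()
        traj = langevin_run(model, init, config.langevin_config(1_000_000))
        bundle["trajectory"] = traj
        bundle["summaries"] = _head_summaries(traj, system)

    elif scenario == "toy_demo":
        cfg = config.langevin_config(1_000_000)
        for head, tg in (("leading", TOGGLES["leading"]),
                         ("trailing", TOGGLES["trailing"])):
            model = _assemble(system, config, tg)
            init = system.pre.coords if head == "leading" \
                else system.trailing_coords()
            traj = langevin_run(model, init, cfg)
            bundle[head] = {"trajectory": traj,
                            "summaries": _head_summaries(traj, system)}
        lead = bundle["leading"]["summaries"]["converter_rmsd"].modes[0]
        trail = bundle["trailing"]["summaries"]["converter_rmsd"].modes[0]
        bundle["converter_rmsd_modes"] = {"leading": float(lead),
                                          "trailing": float(trail)}

    elif scenario in ("powerstroke_with_pi", "powerstroke_without_pi"):
        pi_removed = scenario == "powerstroke_without_pi"
        model = _assemble(system, config, TOGGLES[scenario], pi_removed)
        threshold = 0.5 * system.post_reference_rmsd()
        samples, replica_fracs, trajs = [], [], []
        for rep in range(max(1, config.replicas)):
            traj = langevin_run(model, system.pre.coords,
                                config.langevin_config(2_000_000, rep))
            s = rmsd_distribution(traj, system.pre, system.partition["MH"],
                                  system.partition["converter"]).samples
            samples.append(s)
            replica_fracs.append(float((s < threshold).mean()))
            trajs.append(traj)
        summary = DistributionSummary(np.concatenate(samples),
                                      bin_width=0.01)
        from .analysis import estimate_modes
        if summary.samples.size >= 100:
            summary.modes = estimate_modes(summary, 2)
        try:
            frac_pre, frac_post = basin_populations(summary, threshold)
        except ValueError:
            # every sample on one side of the threshold (no transition seen)
            frac_pre = float((summary.samples < threshold).mean())
            frac_post = 1.0 - frac_pre
        bundle["trajectory"] = trajs[0]
        bundle["summaries"] = {"converter_rmsd": summary}
        bundle["basin_threshold_nm"] = threshold
        bundle["fraction_pre"] = frac_pre
        bundle["fraction_post"] = frac_post
        bundle["replica_fractions_pre"] = replica_fracs
        bundle["active_preMH_contacts"] = len(
            model.term_sets["preMH"].pairs)

    elif scenario == "strain_scan":
        if system.axis is None:
            raise ConfigError("strain_scan needs an actin filament "
                              "(the force direction is the actin axis)")
        model = _assemble(system, config, TOGGLES[scenario])
        init = system.trailing_coords()
        bundle["magnitudes"] = list(config.strain_magnitudes)
        bundle["trajectories"] = []
        bundle["summaries"] = {"d_small_big": []}
        from .analysis import DISTANCE_BIN_NM, estimate_modes
        for mag in config.strain_magnitudes:
            force = ExternalForce(group=system.partition["converter"],
                                  direction=system.axis, magnitude=float(mag),
                                  per_bead=config.strain_per_bead)
            samples = []
            for rep in range(max(1, config.replicas)):
                cfg = config.langevin_config(700_000, rep)
                traj = langevin_run(model, init, cfg, force=force)
                traj.provenance["strain_magnitude_kj_mol_nm"] = float(mag)
                samples.append(group_distance_series(
                    traj, system.partition["MH_small"],
                    system.partition["MH_big"]).samples)
            dist = DistributionSummary(np.concatenate(samples),
                                       bin_width=DISTANCE_BIN_NM)
            dist.modes = estimate_modes(dist, 1)
            bundle["trajectories"].append(traj)
            bundle["summaries"]["d_small_big"].append(dist)
        bundle["d_small_big_modes"] = [
            float(d.modes[0]) for d in bundle["summaries"]["d_small_big"]]

    bundle["provenance"] = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "wall_seconds": round(time.time() - t_start, 2),
    }
    if config.outdir is not None:
        _write_bundle(bundle, system, config)
    return bundle


def _iter_trajectories(bundle: dict):
    if "trajectory" in bundle:
        yield "trajectory", bundle["trajectory"]
    for head in ("leading", "trailing"):
        if head in bundle and "trajectory" in bundle[head]:
            yield head, bundle[head]["trajectory"]
    for k, traj in enumerate(bundle.get("trajectories", [])):
        yield f"strain_{k}", traj


def _write_bundle(bundle: dict, system: MotorSystem,
                  config: ScenarioConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for key in ("summaries", "converter_rmsd_modes", "basin_threshold_nm",
                "fraction_pre", "fraction_post", "active_preMH_contacts",
                "magnitudes", "d_small_big_modes"):
        if key in bundle:
            summaries[key] = _summary_json(bundle[key]) \
                if isinstance(bundle[key], dict) else bundle[key]
    for head in ("leading", "trailing"):
        if head in bundle:
            summaries[head] = _summary_json(bundle[head]["summaries"])
    if "summaries" in bundle and isinstance(bundle["summaries"], dict):
        ds = bundle["summaries"].get("d_small_big")
        if isinstance(ds, list):
            summaries["summaries"] = {"d_small_big": [d.to_dict() for d in ds]}
    (outdir / "summary.json").write_text(json.dumps(summaries, indent=2))
    (outdir / "provenance.json").write_text(
        json.dumps(bundle["provenance"], indent=2))
    for name, traj in _iter_trajectories(bundle):
        import pandas as pd
        pd.DataFrame({"time_tauL": traj.times,
                      "potential_eps": traj.potential,
                      "kinetic_eps": traj.kinetic}).to_csv(
            outdir / f"{name}_energies.tsv", sep="\t", index=False)
        if config.write_trajectories:
            write_xyz(outdir / f"{name}.xyz", traj.frames)
    for tag, cmap in system.maps.items():
        cmap.to_tsv(outdir / f"contacts_{tag}.tsv")
    if system.pi_subset is not None:
        system.pi_subset.to_tsv(outdir / "contacts_Pi_subset.tsv")


def write_model_topology(config: ScenarioConfig, path) -> None:
    """Assemble the scenario's model and serialize its topology file."""
    system = build_system(config)
    toggles = TOGGLES.get(config.scenario, TOGGLES["powerstroke_with_pi"])
    model = _assemble(system, config, toggles,
                      config.scenario == "powerstroke_without_pi")
    write_topology(model, path)
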