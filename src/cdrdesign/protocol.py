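"""The nested Monte Carlo design engine.

An outer loop repeatedly (1) picks a CDR at random according to
configured weights, (2) picks a donor conformation from the CDRSet via
one of the graft-source algorithms, (3) grafts it, (4) runs the inner
loop (optional rigid-body dock perturbation, profile-guided sequence
design over the packing shell, optional restrained backbone
minimization, inner Metropolis), and (5) applies the outer Metropolis
criterion on the acceptance energy (total energy, interface energy, or
a weighted combination).  The run's output is the lowest
acceptance-energy state observed.

Every source of randomness flows from the config seed through
``numpy.random.SeedSequence``, so identical seed + config + inputs give
identical outputs, including the serialized score file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import database as dbm
from . import design as dops
from . import grafting
from . import scoring
from .errors import ConfigError
from .model import CDR_REGIONS
from .scoring import AtomTable, ReferenceEnergy, interface_energy


@dataclass
class ProtocolConfig:
    """Run parameters for :func:`run_design`."""

    n_outer: int = 25
    n_inner: int = 1
    kT: float = 1.0
    acceptance_mode: str = "opt_E"       # opt_E | opt_dG | weighted
    acceptance_weight: float = 0.5       # w for weighted mode
    graft_algorithm: str = "even_cluster_mc"
    graft_design_cdrs: tuple = ()
    seq_design_cdrs: tuple = ()
    cdr_weights: dict = field(default_factory=dict)
    random_start: bool = False
    seed: int = 0
    n_struct: int = 1
    min_protocol: str = "none"           # none | greedy_min | relax_lite
    dock_cycle: bool = False
    antigen_present: bool = True
    prepare: bool = False                # restrained pre-minimization
    profile_rounds: int = 20
    pack_sweeps: int = 1
    seq_strategy: str = "profile"        # profile | conservative | none
    seq_strategy_by_cdr: dict = field(default_factory=dict)
    overrides: str | None = None
    # escalate to the restrained-minimizer fallback after a few CCD
    # attempts; the fallback closes hard (long-loop) grafts far faster
    # than repeated perturb-and-retry cycles
    graft: grafting.GraftConfig = field(
        default_factory=lambda: grafting.GraftConfig(max_cycles=2))

    def __post_init__(self):
        if self.n_outer < 0:
            raise ConfigError("n_outer must be >= 0")
        if self.acceptance_mode not in ("opt_E", "opt_dG", "weighted"):
            raise ConfigError(f"bad acceptance_mode {self.acceptance_mode!r}")
        weights = self.effective_weights()
        if self.graft_design_cdrs:
            if any(w < 0 for w in weights.values()):
                raise ConfigError("cdr weights must be non-negative")
            if sum(weights.values()) <= 0:
                raise ConfigError("cdr weights must not all be zero")
        if (self.graft_algorithm == "deterministic_graft"
                and len(self.graft_design_cdrs) > 1):
            raise ConfigError(
                "deterministic_graft supports a single graft-design CDR")

    def effective_weights(self) -> dict:
        return {cdr: float(self.cdr_weights.get(cdr, 1.0))
                for cdr in self.graft_design_cdrs}


@dataclass
class DesignRecord:
    """One output decoy: the best state of a single design trajectory."""

    complex: object
    acceptance_energy: float
    total_energy: float
    dG_interface: float | None
    graft_history: list
    sequence: dict
    sampled_counts: dict
    run_index: int = 0
    final_labels: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# elementary operations


def metropolis_accept(e_old: float, e_new: float, kT: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion; kT <= 0 degrades to greedy."""
    if not (np.isfinite(e_old) and np.isfinite(e_new)):
        return bool(e_new <= e_old)
    if e_new <= e_old:
        return True
    if kT <= 0:
        return False
    return bool(rng.random() < np.exp(-(e_new - e_old) / kT))


def choose_cdr(weights: dict, rng: np.random.Generator) -> str:
    """Categorical draw of a CDR proportional to its weight."""
    cdrs = sorted(weights)
    if not cdrs:
        raise ConfigError("no CDRs enabled for graft design")
    w = np.array([weights[c] for c in cdrs], float)
    if w.sum() <= 0:
        raise ConfigError("all CDR weights are zero")
    return cdrs[int(rng.choice(len(cdrs), p=w / w.sum()))]


def choose_graft_source(cdrset: dbm.CdrSet, cdr: str, algorithm: str,
                        rng: np.random.Generator, counter: int = 0):
    """Pick a donor entry by the configured sampling scheme.

    even_cluster_mc: uniform over clusters, then uniform within.
    gen_mc: uniform over all entries (frequency-weighted by database).
    even_length_cluster_mc: uniform over lengths, then clusters of that
    length, then entries.  deterministic_graft: sequential enumeration.
    """
    entries = cdrset.for_cdr(cdr)
    if not entries:
        raise ConfigError(f"empty CDRSet for {cdr}")
    if algorithm == "gen_mc":
        return entries[int(rng.integers(len(entries)))]
    if algorithm == "even_cluster_mc":
        clusters = cdrset.clusters(cdr)
        cid = sorted(clusters)[int(rng.integers(len(clusters)))]
        group = clusters[cid]
        return group[int(rng.integers(len(group)))]
    if algorithm == "even_length_cluster_mc":
        lengths = cdrset.lengths(cdr)
        length = sorted(lengths)[int(rng.integers(len(lengths)))]
        clusters: dict = {}
        for e in lengths[length]:
            clusters.setdefault(e.cluster_id, []).append(e)
        cid = sorted(clusters)[int(rng.integers(len(clusters)))]
        group = clusters[cid]
        return group[int(rng.integers(len(group)))]
    if algorithm == "deterministic_graft":
        return entries[counter % len(entries)]
    raise ConfigError(f"unknown graft algorithm {algorithm!r}")


# ----------------------------------------------------------------------
# restrained pre-minimization


def prepare_complex(complex_, energy: ReferenceEnergy | None = None,
                    restraint_weight: float = 10.0, max_iter: int = 150):
    """Coordinate-restrained minimization of the input structure.

    All-atom L-BFGS under the reference score plus harmonic restraints
    to the input coordinates (weight in energy units per A^2).  If the
    optimized structure drifts more than 1 A RMSD the move is reverted
    with a warning flag.  Returns ``(complex, rmsd_to_input)``.
    """
    from scipy.optimize import minimize as _minimize

    energy = energy or ReferenceEnergy()
    work = complex_.copy()
    table = AtomTable.from_complex(work)
    x0 = table.positions.copy()

    def fun(xflat):
        table.positions = xflat.reshape(-1, 3)
        e, grad = energy.energy_and_grad(table)
        diff = table.positions - x0
        e += restraint_weight * float(np.sum(diff ** 2))
        grad = grad + 2.0 * restraint_weight * diff
        return e, grad.ravel()

    e_start, _ = fun(x0.ravel())
    result = _minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter})
    xopt = result.x.reshape(-1, 3)
    e_end, _ = fun(result.x)
    rmsd = float(np.sqrt(np.mean(np.sum((xopt - x0) ** 2, axis=1))))
    if rmsd > 1.0 or e_end > e_start:
        return complex_.copy(), 0.0
    _write_positions(work, xopt)
    return work, rmsd


def _write_positions(complex_, positions: np.ndarray) -> None:
    i = 0
    for res in complex_.residues():
        for name in res.atoms:
            res.atoms[name] = positions[i].copy()
            i += 1


# ----------------------------------------------------------------------
# acceptance energy


def acceptance_energy(complex_, energy, config: ProtocolConfig) -> float:
    mode = config.acceptance_mode
    if not config.antigen_present or not complex_.antigen_chain_ids:
        mode = "opt_E"  # interface energy is meaningless without antigen
    total = energy.score(complex_)
    if mode == "opt_E":
        return float(total)
    dg = interface_energy(complex_, energy)
    if mode == "opt_dG":
        return float(dg)
    w = config.acceptance_weight
    return float((1.0 - w) * total + w * dg)


# ----------------------------------------------------------------------
# inner cycle


def _build_palettes(complex_, config: ProtocolConfig, profiles: dict,
                    rng: np.random.Generator) -> dict:
    """Per-position allowed-type sets for all seq-design CDRs."""
    palette: dict = {}
    for region in config.seq_design_cdrs:
        strategy = config.seq_strategy_by_cdr.get(region,
                                                  config.seq_strategy)
        if strategy == "none":
            continue
        residues = complex_.region_residues(region)
        if not residues:
            continue
        native_seq = "".join(r.aa for r in residues)
        labels = complex_.cdr_labels.get(region, {})
        profile = profiles.get(labels.get("cluster")) if profiles else None
        if (strategy == "profile" and profile is not None
                and profile.usable and profile.length == len(native_seq)):
            pal = dops.profile_palette(profile, native_seq,
                                       config.profile_rounds, rng)
        else:
            pal = dops.conservative_palette(native_seq)
        for res, allowed in zip(residues, pal.allowed):
            palette[(res.chain_id, res.number_label)] = allowed
    return palette


def _dock_perturb(complex_, energy, rng: np.random.Generator,
                  max_trans: float = 1.0, max_rot_deg: float = 3.0):
    """Small random rigid-body move of the antigen + greedy back-off.

    The perturbed pose is kept only if it does not worsen the score;
    otherwise the translation is halved twice before giving up.
    """
    from . import geometry as geo

    work = complex_.copy()
    ag = work.antigen_chain_ids
    if not ag:
        return complex_
    atoms = [xyz for cid in ag for res in work.chains[cid]
             for xyz in res.atoms.values()]
    center = np.mean(atoms, axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_rot_deg, max_rot_deg))
    rot, trans_rot = geo.rotation_about_axis(center, axis, angle)
    shift = rng.uniform(-max_trans, max_trans, size=3)
    e_before = energy.score(complex_)
    scale = 1.0
    for _ in range(3):
        cand = complex_.copy()
        for cid in ag:
            for res in cand.chains[cid]:
                for name, xyz in res.atoms.items():
                    moved = rot @ xyz + trans_rot + scale * shift
                    res.atoms[name] = moved
        if energy.score(cand) <= e_before:
            return cand
        scale *= 0.5
    return complex_


def _greedy_min(complex_, region: str, energy, centroids: dict,
                restraint_weight: float = 0.002, step: float = 2.0):
    """One pass of greedy torsion descent with cluster restraints.

    Works in the closure torsion space of the region (anchored on the
    N-side framework); a move is kept only when it lowers
    energy + circular-harmonic restraint while both junctions remain
    closed.
    """
    from . import geometry as geo

    labels = complex_.cdr_labels.get(region, {})
    centroid = centroids.get(labels.get("cluster")) if centroids else None
    work = complex_.copy()
    try:
        reg = grafting._RebuildRegion(work, region)
    except Exception:
        return complex_
    if not reg.junction_geometry().closed():
        return complex_

    def restraint():
        if centroid is None:
            return 0.0
        dev = 0.0
        cen = np.asarray(centroid.centroid_dihedrals.angles, float)
        for k in range(reg.length):
            dev += geo.angular_difference(reg.torsions[2 + k, 0],
                                          cen[k, 0]) ** 2
            dev += geo.angular_difference(reg.torsions[2 + k, 1],
                                          cen[k, 1]) ** 2
        return restraint_weight * dev

    def objective():
        reg.write_back()
        return energy.score(work) + restraint()

    current = objective()
    pairs = [(2 + k, t) for k in range(reg.length) for t in (0, 1)]
    for local, kind in pairs:
        for delta in (step, -step):
            reg.rotate_torsion(local, kind, delta)
            if reg.junction_geometry().closed():
                trial = objective()
                if trial < current:
                    current = trial
                    continue
            reg.rotate_torsion(local, kind, -delta)
            reg.write_back()
    return work


def run_inner_cycle(complex_, chosen_cdr: str, energy,
                    config: ProtocolConfig, profiles: dict,
                    centroids: dict, rng: np.random.Generator):
    """Inner optimization: dock -> pack/design -> minimize -> Metropolis.

    Runs ``n_inner`` cycles and returns the lowest acceptance-energy
    state seen (including the entry state).
    """
    current = complex_
    e_cur = acceptance_energy(current, energy, config)
    best, e_best = current, e_cur
    mask = None
    for _ in range(max(1, config.n_inner)):
        cand = current
        if config.dock_cycle and config.antigen_present:
            cand = _dock_perturb(cand, energy, rng)
        if config.seq_design_cdrs and config.seq_strategy != "none":
            if mask is None:
                mask = dops.build_design_mask(cand, config.seq_design_cdrs,
                                              config.overrides)
            palette = _build_palettes(cand, config, profiles, rng)
            shell = dops.packing_shell(cand, chosen_cdr)
            cand = dops.pack_and_design(cand, palette, mask, shell, energy,
                                        rng, sweeps=config.pack_sweeps)
        if config.min_protocol == "greedy_min":
            cand = _greedy_min(cand, chosen_cdr, energy, centroids)
        elif config.min_protocol == "relax_lite":
            cand = _relax_lite(cand, chosen_cdr, energy, config, profiles,
                               centroids, rng)
        e_new = acceptance_energy(cand, energy, config)
        if metropolis_accept(e_cur, e_new, config.kT, rng):
            current, e_cur = cand, e_new
        if e_new < e_best:
            best, e_best = cand, e_new
    return best, e_best


def _relax_lite(complex_, region, energy, config, profiles, centroids, rng):
    """Miniature relax: clash-weight ramp with pack + greedy minimize."""
    cand = complex_
    if not isinstance(energy, ReferenceEnergy):
        return _greedy_min(cand, region, energy, centroids)
    for scale in (0.2, 0.6, 1.0):
        ramped = ReferenceEnergy(
            clash_weight=energy.clash_weight * scale,
            contact_weight=energy.contact_weight,
            hbond_weight=energy.hbond_weight,
            reference_offsets=energy.reference_offsets)
        if config.seq_design_cdrs and config.seq_strategy != "none":
            mask = dops.build_design_mask(cand, config.seq_design_cdrs,
                                          config.overrides)
            palette = _build_palettes(cand, config, profiles, rng)
            shell = dops.packing_shell(cand, region)
            cand = dops.pack_and_design(cand, palette, mask, shell, ramped,
                                        rng, sweeps=1)
        cand = _greedy_min(cand, region, ramped, centroids)
    return cand


# ----------------------------------------------------------------------
# the outer loop


def run_design(complex_, cdrset: dbm.CdrSet, energy,
               config: ProtocolConfig, profiles: dict | None = None,
               centroids: dict | None = None) -> list:
    """Run ``config.n_struct`` independent seeded design trajectories.

    Each trajectory performs ``n_outer`` cycles of CDR choice, graft,
    inner optimization and outer Metropolis acceptance, and reports the
    lowest acceptance-energy state it observed as one
    :class:`DesignRecord`.  Grafts that fail closure are rejected and
    logged but still count as sampled.
    """
    profiles = profiles or {}
    centroids = centroids or {}
    if not config.antigen_present:
        complex_ = complex_.without_antigen()
    records = []
    for run_index in range(config.n_struct):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, run_index]))
        records.append(_run_single(complex_, cdrset, energy, config,
                                   profiles, centroids, rng, run_index))
    return records


def _run_single(complex_, cdrset, energy, config, profiles, centroids,
                rng, run_index) -> DesignRecord:
    if config.prepare:
        current, _ = prepare_complex(complex_, energy if isinstance(
            energy, ReferenceEnergy) else None)
    else:
        current = complex_.copy()
    history = []
    sampled = {cdr: {"attempts": 0, "lengths": {}, "clusters": {}}
               for cdr in config.graft_design_cdrs}
    det_counter = 0

    if config.random_start:
        for cdr in sorted(config.graft_design_cdrs):
            for _ in range(5):  # retry unclosable random starts
                entry = choose_graft_source(cdrset, cdr,
                                            config.graft_algorithm, rng,
                                            det_counter)
                result = grafting.graft_cdr(entry, current, cdr,
                                            config.graft, rng)
                if result.closed:
                    current = result.complex
                    break

    weights = config.effective_weights()
    e_cur = acceptance_energy(current, energy, config)
    best, e_best = current, e_cur

    for cycle in range(config.n_outer):
        if not config.graft_design_cdrs:
            break
        cdr = choose_cdr(weights, rng)
        entry = choose_graft_source(cdrset, cdr, config.graft_algorithm,
                                    rng, det_counter)
        det_counter += 1
        tally = sampled[cdr]
        tally["attempts"] += 1
        tally["lengths"][entry.length] = tally["lengths"].get(
            entry.length, 0) + 1
        tally["clusters"][entry.cluster_id] = tally["clusters"].get(
            entry.cluster_id, 0) + 1
        result = grafting.graft_cdr(entry, current, cdr, config.graft, rng)
        event = {"cycle": cycle, "cdr": cdr, "cluster": entry.cluster_id,
                 "length": entry.length, "source_pdb": entry.source_pdb,
                 "closed": result.closed, "fallback": result.used_fallback,
                 "accepted": False}
        if not result.closed:
            history.append(event)
            continue
        cand, e_new = run_inner_cycle(result.complex, cdr, energy, config,
                                      profiles, centroids, rng)
        if metropolis_accept(e_cur, e_new, config.kT, rng):
            current, e_cur = cand, e_new
            event["accepted"] = True
        if e_new < e_best:
            best, e_best = cand, e_new
        history.append(event)

    total = energy.score(best)
    dg = None
    if config.antigen_present and best.antigen_chain_ids:
        dg = interface_energy(best, energy)
    return DesignRecord(
        complex=best, acceptance_energy=float(e_best),
        total_energy=float(total), dG_interface=dg,
        graft_history=history,
        sequence={region: "".join(r.aa
                                  for r in best.region_residues(region))
                  for region in CDR_REGIONS if best.region_residues(region)},
        sampled_counts=sampled, run_index=run_index,
        final_labels={cdr: dict(best.cdr_labels.get(cdr, {}))
                      for cdr in config.graft_design_cdrs})


# ----------------------------------------------------------------------
# outputs


def score_table(records) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for rec in records:
        row = {"run": rec.run_index,
               "acceptance_energy": round(rec.acceptance_energy, 6),
               "total_energy": round(rec.total_energy, 6),
               "dG_interface": (None if rec.dG_interface is None
                                else round(rec.dG_interface, 6)),
               "grafts_attempted": sum(
                   c["attempts"] for c in rec.sampled_counts.values()),
               "grafts_accepted": sum(
                   1 for ev in rec.graft_history if ev["accepted"])}
        for cdr, labels in sorted(rec.final_labels.items()):
            row[f"{cdr}_cluster"] = labels.get("cluster", "")
            row[f"{cdr}_length"] = labels.get("length", "")
        for region, seq in sorted(rec.sequence.items()):
            row[f"seq_{region}"] = seq
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(records, config: ProtocolConfig, outdir,
                  write_pdbs: bool = True) -> None:
    """Decoy PDBs, TSV score file and a JSON run manifest."""
    import os

    from .model import write_pdb

    os.makedirs(outdir, exist_ok=True)
    table = score_table(records)
    table.to_csv(os.path.join(outdir, "scores.tsv"), sep="\t", index=False)
    manifest = {"config": _config_dict(config), "version": "cdrdesign-0.1.0",
                "n_records": len(records)}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if write_pdbs:
        for rec in records:
            path = os.path.join(outdir, f"decoy_{rec.run_index:04d}.pdb")
            with open(path, "w") as fh:
                fh.write(write_pdb(rec.complex))


def _config_dict(config: ProtocolConfig) -> dict:
    out = asdict(config)
    out["graft"] = asdict(config.graft)
    return out
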