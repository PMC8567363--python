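"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure of the study system without
running molecular dynamics or a docking engine:

* a Pro-trans marker-distance trajectory that switches between a compact mode
  (Gaussian centered 0.5 nm, sd 0.08 nm) and an extended mode (1.9 nm, sd
  0.3 nm) via a two-state Markov chain, truncated to the observed 0.3-2.5 nm
  range;
* a Pro-cis trajectory with a single extended mode (2.2 nm, sd 0.35 nm,
  truncated to 1-2.8 nm);
* coarse 3-D realizations of those series (one bead per residue plus the
  backbone pseudo-atoms needed for the omega dihedral);
* a seven-helix toy receptor with a transmembrane-helix annotation;
* per-sub-ensemble binding-energy tables with a controlled best-K_D ratio.

All generators are pure functions of (parameters, seed); hidden state labels
are returned alongside the data so downstream classifiers can be checked
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .conformers import Conformer, Trajectory, DEFAULT_FRAME_INTERVAL_PS
from .dissection import DistanceSeries, SubEnsembleLabel
from .exceptions import ConstructionError
from .screening import GAS_CONSTANT_KCAL, DEFAULT_TEMPERATURE_K, Receptor

__all__ = [
    "TrajectoryParams",
    "EnergyTableParams",
    "SyntheticReplica",
    "gen_distance_series",
    "gen_replica_set",
    "gen_toy_trajectory",
    "gen_toy_receptor",
    "gen_reference_pose",
    "gen_energy_table",
]

#: Residue sequence of the 9-residue peptide (disulfide ring 1-6, tail 7-9).
PEPTIDE_SEQUENCE = ["CYS", "TYR", "PHE", "GLN", "ASN", "CYS", "PRO", "ARG", "GLY"]


@dataclass
class TrajectoryParams:
    """Parameters of the synthetic marker-distance trajectory.

    Mode centers, widths and truncation bounds follow the observed distance
    distributions; the two-state Markov switch probabilities (per frame)
    give mean dwell times of ~100 frames and are not calibrated claims about
    the real kinetics.
    """

    state: str = "trans"                 # {"trans", "cis"}
    n_frames: int = 12_000               # ~120 ns at 10 ps/frame
    seed: int = 0
    compact_mean: float = 0.5            # nm
    compact_sd: float = 0.08
    extended_mean: float = 1.9
    extended_sd: float = 0.3
    cis_mean: float = 2.2
    cis_sd: float = 0.35
    trans_bounds: tuple[float, float] = (0.3, 2.5)
    cis_bounds: tuple[float, float] = (1.0, 2.8)
    switch_prob_ce: float = 0.01         # compact -> extended, per frame
    switch_prob_ec: float = 0.02         # extended -> compact, per frame
    n_replicas: int = 3
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS   # ps

    def __post_init__(self):
        if self.state not in ("trans", "cis"):
            raise ValueError("state must be 'trans' or 'cis'")
        for p in (self.switch_prob_ce, self.switch_prob_ec):
            if not 0 < p < 1:
                raise ValueError("switch probabilities must lie in (0, 1)")
        lo, hi = self.trans_bounds
        if not (lo < self.compact_mean < hi and lo < self.extended_mean < hi):
            raise ValueError("trans mode means must lie within trans_bounds")
        lo, hi = self.cis_bounds
        if not lo < self.cis_mean < hi:
            raise ValueError("cis mode mean must lie within cis_bounds")


def _trunc_draws(rng, mean, sd, bounds, n):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def gen_distance_series(params: TrajectoryParams
                        ) -> tuple[DistanceSeries, np.ndarray]:
    """Generate a marker-distance series plus its hidden state labels.

    Trans: a two-state Markov chain over {compact, extended} with truncated
    Gaussian emissions per state.  Cis: a single truncated Gaussian state.
    Returns ``(series, labels)`` with labels in {"compact", "extended"}.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    times = np.arange(n) * params.frame_interval
    if params.state == "cis":
        values = _trunc_draws(rng, params.cis_mean, params.cis_sd, params.cis_bounds, n)
        labels = np.full(n, "extended")
        return DistanceSeries(times, values), labels

    p_ce, p_ec = params.switch_prob_ce, params.switch_prob_ec
    stationary_compact = p_ec / (p_ce + p_ec)
    states = np.empty(n, dtype=int)   # 0 = compact, 1 = extended
    u = rng.random(n)
    states[0] = 0 if u[0] < stationary_compact else 1
    for i in range(1, n):
        if states[i - 1] == 0:
            states[i] = 1 if u[i] < p_ce else 0
        else:
            states[i] = 0 if u[i] < p_ec else 1
    compact_draws = _trunc_draws(rng, params.compact_mean, params.compact_sd,
                                 params.trans_bounds, n)
    extended_draws = _trunc_draws(rng, params.extended_mean, params.extended_sd,
                                  params.trans_bounds, n)
    values = np.where(states == 0, compact_draws, extended_draws)
    labels = np.where(states == 0, "compact", "extended")
    return DistanceSeries(times, values), labels


@dataclass
class SyntheticReplica:
    """One replica of the synthetic study design: state, series, ground truth."""

    state: str
    replica_id: int
    series: DistanceSeries
    hidden_labels: np.ndarray

    @property
    def true_sub_ensembles(self) -> np.ndarray:
        """Hidden labels mapped to sub-ensemble names."""
        if self.state == "cis":
            return np.where(self.hidden_labels == "compact",
                            SubEnsembleLabel.C_CIS.value, SubEnsembleLabel.E_CIS.value)
        return np.where(self.hidden_labels == "compact",
                        SubEnsembleLabel.C_TRANS.value, SubEnsembleLabel.E_TRANS.value)


def gen_replica_set(params: TrajectoryParams | None = None) -> list[SyntheticReplica]:
    """Generate the default replication design: n_replicas x {trans, cis}.

    With the default 3 replicas this emits 6 independent trajectories, one
    per (replica, isomer-state) combination, with per-replica derived seeds.
    """
    params = params or TrajectoryParams()
    replicas = []
    for rep in range(params.n_replicas):
        for state in ("trans", "cis"):
            child = int(np.random.SeedSequence(
                entropy=params.seed, spawn_key=(rep, 0 if state == "trans" else 1)
            ).generate_state(1)[0])
            p = replace(params, state=state, seed=child)
            series, labels = gen_distance_series(p)
            replicas.append(SyntheticReplica(state, rep, series, labels))
    return replicas


# --- coarse 3-D realization -------------------------------------------------

_RING_RADIUS = 0.38          # nm, hexagon of ring CA beads
_MARKER_OFFSET = 0.05        # nm, marker proton offset from its CA
_MIN_MARKER_DIST = 0.1       # nm, below this the beads would overlap
_MAX_MARKER_DIST = 10.0      # nm, beyond any physical tail extension


def _ring_positions() -> np.ndarray:
    ang = np.deg2rad(60.0 * np.arange(6))
    return np.column_stack([_RING_RADIUS * np.cos(ang),
                            _RING_RADIUS * np.sin(ang),
                            np.zeros(6)])


def _build_frame(distance: float, omega_deg: float, rng) -> tuple[list, np.ndarray]:
    """One coarse frame realizing the marker distance and omega dihedral."""
    ring = _ring_positions()           # CA of residues 1..6
    ca2, ca6 = ring[1], ring[5]
    e1 = ca6 / np.linalg.norm(ca6)     # radial, outward at residue 6
    et = np.array([-e1[1], e1[0], 0.0])  # tangent in the ring plane
    c6 = ca6 + 0.153 * e1
    n7 = c6 + 0.133 * (np.cos(np.deg2rad(40)) * e1 + np.sin(np.deg2rad(40)) * et)
    # place CA7 at the requested dihedral about the C6-N7 axis
    axis = n7 - c6
    axis /= np.linalg.norm(axis)
    v = (ca6 - c6) - np.dot(ca6 - c6, axis) * axis
    v /= np.linalg.norm(v)
    w = np.cross(axis, v)
    om = np.deg2rad(omega_deg)
    theta = np.deg2rad(70.0)           # polar angle of the CA7 bond off the axis
    ca7 = n7 + 0.146 * (np.cos(theta) * axis
                        + np.sin(theta) * (np.cos(om) * v + np.sin(om) * w))
    hh2 = ca2 + _MARKER_OFFSET * ca2 / np.linalg.norm(ca2)
    # tail direction: away from the ring through CA7, with a little jitter
    u = ca7 - hh2 + rng.normal(0.0, 0.05, 3)
    u /= np.linalg.norm(u)
    hh8 = hh2 + distance * u
    ca8 = hh8 + np.array([0.0, 0.0, _MARKER_OFFSET])
    ca9 = ca8 + 0.38 * u
    atoms = [
        ("CA", 1, "CYS", ring[0]), ("CA", 2, "TYR", ca2), ("HH", 2, "TYR", hh2),
        ("CA", 3, "PHE", ring[2]), ("CA", 4, "GLN", ring[3]), ("CA", 5, "ASN", ring[4]),
        ("CA", 6, "CYS", ca6), ("C", 6, "CYS", c6),
        ("N", 7, "PRO", n7), ("CA", 7, "PRO", ca7),
        ("CA", 8, "ARG", ca8), ("HH11", 8, "ARG", hh8),
        ("CA", 9, "GLY", ca9),
    ]
    names = [a[0] for a in atoms]
    return names, atoms


def gen_toy_trajectory(series: DistanceSeries, state: str, seed: int = 0,
                       omega_jitter_sd: float = 5.0) -> Trajectory:
    """Realize a distance series as a coarse 9-residue 3-D trajectory.

    Each frame carries one CA bead per residue, a marker pseudo-proton on
    residues 2 and 8 placed so their separation equals the series value to
    1e-6 nm, and the CA(6)/C(6)/N(7)/CA(7) backbone pseudo-atoms arranged to
    give an omega dihedral of 0 (cis) or 180 (trans) degrees with seeded
    jitter of ``omega_jitter_sd`` degrees.
    """
    if len(series) == 0:
        raise ValueError("empty distance series")
    if state not in ("cis", "trans"):
        raise ValueError("state must be 'cis' or 'trans'")
    bad = (series.values < _MIN_MARKER_DIST) | (series.values > _MAX_MARKER_DIST)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ConstructionError(
            f"marker distance {series.values[i]:.3f} nm at frame {i} is outside the "
            f"constructible range [{_MIN_MARKER_DIST}, {_MAX_MARKER_DIST}] nm"
        )
    rng = np.random.default_rng(seed)
    base_omega = 0.0 if state == "cis" else 180.0
    conformers = []
    for i, d in enumerate(series.values):
        omega = base_omega + float(np.clip(rng.normal(0.0, omega_jitter_sd), -15, 15))
        _, atoms = _build_frame(float(d), omega, rng)
        conformers.append(Conformer(
            id=i, time=float(series.times[i]),
            atom_names=np.array([a[0] for a in atoms]),
            res_ids=np.array([a[1] for a in atoms]),
            res_names=np.array([a[2] for a in atoms]),
            coords=np.array([a[3] for a in atoms]),
        ))
    return Trajectory(conformers, isomer_hint=state)


# --- toy receptor -----------------------------------------------------------

_N_HELICES = 7
_BEADS_PER_HELIX = 10
_HELIX_RING_RADIUS = 1.1     # nm, helix axes on a circle around the pocket
_BEAD_SPACING = 0.15         # nm, along the membrane normal


def gen_toy_receptor(seed: int = 0) -> Receptor:
    """A seven-helix coarse receptor enclosing a central pocket.

    Helix axes sit on a circle of radius 1.1 nm around the pocket; each helix
    is a column of 10 CA beads spaced 0.15 nm along z, annotated as helices
    1-7 with disjoint residue ranges.  A small seeded positional jitter makes
    distinct seeds produce distinct (but equivalent) receptors.
    """
    rng = np.random.default_rng(seed)
    names, res_ids, res_names, coords = [], [], [], []
    annotation = {}
    z = (np.arange(_BEADS_PER_HELIX) - (_BEADS_PER_HELIX - 1) / 2) * _BEAD_SPACING
    for h in range(_N_HELICES):
        ang = 2 * np.pi * h / _N_HELICES
        axis_xy = _HELIX_RING_RADIUS * np.array([np.cos(ang), np.sin(ang)])
        start = h * _BEADS_PER_HELIX + 1
        annotation[h + 1] = (start, start + _BEADS_PER_HELIX - 1)
        for k in range(_BEADS_PER_HELIX):
            names.append("CA")
            res_ids.append(start + k)
            res_names.append("ALA")
            coords.append([axis_xy[0], axis_xy[1], z[k]] + rng.normal(0, 0.01, 3))
    structure = Conformer(0, 0.0, np.array(names), np.array(res_ids),
                          np.array(res_names), np.array(coords))
    return Receptor(structure, annotation)


def gen_reference_pose(receptor: Receptor, approach: float = 0.4) -> Conformer:
    """A hand-placed ligand pose with the reference contact pattern.

    Residue 2 sits ``approach`` nm inside helix 3, residue 3 inside helix 4
    and the tail residue 8 inside helix 6; all other residues rest at the
    pocket center, out of contact range of every helix.  Used as the fixture
    reproducing the qualitative helix-contact pattern of the best
    extended-trans complex.
    """
    rec = receptor.structure

    def inner_point(helix_id):
        s, e = receptor.tmh_annotation[helix_id]
        mask = (rec.res_ids >= s) & (rec.res_ids <= e)
        beads = rec.coords[mask]
        mid = beads[len(beads) // 2]
        radial = np.array([mid[0], mid[1], 0.0])
        return mid - approach * radial / np.linalg.norm(radial)

    center = rec.coords.mean(axis=0)
    positions = {res: center.copy() for res in range(1, 10)}
    positions[2] = inner_point(3)
    positions[3] = inner_point(4)
    positions[8] = inner_point(6)
    # spread the idle residues slightly so atom positions are distinct
    for res in (1, 4, 5, 6, 7, 9):
        positions[res] = center + np.array([0.02 * res, -0.02 * res, 0.0])
    res_ids = np.arange(1, 10)
    return Conformer(
        0, 0.0,
        atom_names=np.full(9, "CA"), res_ids=res_ids,
        res_names=np.array(PEPTIDE_SEQUENCE),
        coords=np.array([positions[r] for r in res_ids]),
    )


# --- binding-energy tables --------------------------------------------------

@dataclass
class EnergyTableParams:
    """Parameters of the synthetic per-sub-ensemble binding-energy table.

    Energies are Gaussian per class; the extended-trans class mean is shifted
    by ``-RT ln(ratio)`` relative to the others so the expected best-K_D
    ratio between it and each other class is about ``ratio`` (the observed
    separation is two- to three-fold).
    """

    n_structures: int = 50
    n_repeats: int = 25
    n_runs: int = 1
    seed: int = 0
    base_mean: float = -6.0      # kcal/mol, C_TRANS / E_CIS class mean
    sd: float = 0.5              # kcal/mol, all classes
    ratio: float = 3.0           # target best-K_D fold separation
    temperature: float = DEFAULT_TEMPERATURE_K
    classes: tuple = (SubEnsembleLabel.C_TRANS, SubEnsembleLabel.E_TRANS,
                      SubEnsembleLabel.E_CIS)

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")

    def class_mean(self, label: SubEnsembleLabel) -> float:
        shift = -GAS_CONSTANT_KCAL * self.temperature * np.log(self.ratio)
        return self.base_mean + (shift if label is SubEnsembleLabel.E_TRANS else 0.0)


def gen_energy_table(params: EnergyTableParams | None = None) -> pd.DataFrame:
    """Generate a binding-energy table compatible with the energy-table reader.

    One row per (class, run, structure, repeat); with the defaults that is
    1250 rows per sub-ensemble and 3750 in total.
    """
    params = params or EnergyTableParams()
    rng = np.random.default_rng(params.seed)
    rows = []
    for run in range(params.n_runs):
        for label in params.classes:
            mean = params.class_mean(label)
            energies = rng.normal(mean, params.sd,
                                  params.n_structures * params.n_repeats)
            i = 0
            for conf in range(params.n_structures):
                for rep in range(params.n_repeats):
                    rows.append((label.value, run, conf, rep, energies[i],
                                 "negative_favorable"))
                    i += 1
    return pd.DataFrame(rows, columns=["sub_ensemble", "run_id", "conformer_id",
                                       "repeat_index", "energy_kcal_mol", "convention"])
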