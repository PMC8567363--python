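"""Ensemble screening: sample conformers per sub-ensemble, dock, convert to K_D.

The screening protocol draws ``n_structures`` random snapshots from each
sub-ensemble, submits each to a docking backend ``n_repeats`` times with
independent derived seeds, and converts every binding energy DG (kcal/mol,
negative = favorable) to a dissociation constant via

    K_D = exp(DG / (R T)),   R = 1.987204e-3 kcal / (mol K)

so that DG = -RT ln K_binding with K_binding = 1/K_D.  The default plan (50
structures x 25 repeats) yields 1250 complexes per sub-ensemble per run, and
the default 3 runs x 3 sub-ensembles give 9 screening experiments.

The docking backend is a contract — any callable
``dock(conformer, receptor, n_poses, seed) -> BindingScore`` — with two
implementations shipped: :class:`ToyDockBackend`, a seeded rigid-body
Monte-Carlo search over a capped 12-6 pair potential on one-bead-per-residue
models, and :func:`read_energy_table`, which ingests externally computed
energies instead of docking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .conformers import Conformer
from .dissection import LabeledTrajectory, SubEnsembleLabel
from .exceptions import AnnotationError, BackendError, EnergyTableError, InsufficientFramesError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "ScreeningPlan",
    "BindingScore",
    "ComplexRecord",
    "Receptor",
    "ToyDockBackend",
    "kd_from_binding_energy",
    "binding_energy_from_kd",
    "sample_structures",
    "toy_dock",
    "pair_potential_energy",
    "run_screening",
    "select_top_complexes",
    "read_energy_table",
    "records_to_frame",
    "write_energy_table",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987204e-3
DEFAULT_TEMPERATURE_K = 298.15


@dataclass
class ScreeningPlan:
    """Counts, temperature and master seed of one screening campaign."""

    n_structures: int = 50
    n_repeats: int = 25
    top_n: int = 5
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0
    n_runs: int = 3

    def __post_init__(self):
        for name in ("n_structures", "n_repeats", "top_n", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class BindingScore:
    """One docking result: best energy (kcal/mol, negative-favorable) and pose.

    Scores produced under a positive-favorable convention must be negated on
    ingest; ``convention_flag`` records the original convention.
    """

    energy: float
    rotation: np.ndarray | None = None     # 3x3, ligand about its centroid
    translation: np.ndarray | None = None  # nm
    convention_flag: str = "negative_favorable"

    def __post_init__(self):
        if not np.isfinite(self.energy):
            raise ValueError("binding energy must be finite")
        if self.convention_flag == "positive_favorable":
            self.energy = -self.energy
            self.convention_flag = "negative_favorable"
        elif self.convention_flag != "negative_favorable":
            raise ValueError(f"unknown energy convention {self.convention_flag!r}")


@dataclass(frozen=True)
class ComplexRecord:
    """One docked complex: provenance, energy and derived K_D."""

    sub_ensemble: SubEnsembleLabel
    run_id: int
    conformer_id: int
    repeat_index: int
    energy: float          # kcal/mol, negative-favorable
    kd: float              # mol/L


@dataclass
class Receptor:
    """Receptor structure with a transmembrane-helix annotation.

    ``tmh_annotation`` maps helix id (1..7 for a class-A GPCR) to an inclusive
    (start, end) residue-index range; ranges must be pairwise disjoint.
    """

    structure: Conformer
    tmh_annotation: dict[int, tuple[int, int]]

    def __post_init__(self):
        spans = sorted(self.tmh_annotation.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 >= s2:
                raise ValueError("helix residue ranges must be pairwise disjoint")
        present = set(self.structure.res_ids.tolist())
        for hid, (s, e) in self.tmh_annotation.items():
            if not any(r in present for r in range(s, e + 1)):
                raise AnnotationError(
                    f"helix {hid} range {s}-{e} references no receptor residue"
                )

    def helix_of_residue(self, res_id: int) -> int | None:
        for hid, (s, e) in self.tmh_annotation.items():
            if s <= res_id <= e:
                return hid
        return None


def kd_from_binding_energy(energy: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Dissociation constant (mol/L) from a negative-favorable binding energy.

    K_D = exp(DG/(RT)); DG = 0 gives K_D = 1 M, and more negative DG gives
    smaller K_D (tighter binding).
    """
    if not np.isfinite(energy):
        raise ValueError("binding energy must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(energy / (GAS_CONSTANT_KCAL * temperature)))


def binding_energy_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Inverse of :func:`kd_from_binding_energy`: DG = RT ln K_D."""
    if kd <= 0:
        raise ValueError("K_D must be positive")
    return float(GAS_CONSTANT_KCAL * temperature * np.log(kd))


def sample_structures(labeled: LabeledTrajectory, target: SubEnsembleLabel,
                      n: int, seed: int) -> list[Conformer]:
    """Draw ``n`` distinct frames of the target sub-ensemble, seed-reproducibly."""
    pool = labeled.frames_with_label(target)
    if len(pool) < n:
        raise InsufficientFramesError(
            f"sub-ensemble {target} has {len(pool)} frames, {n} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return [labeled.trajectory[pool[i]] for i in sorted(chosen)]


def pair_potential_energy(lig_coords: np.ndarray, rec_coords: np.ndarray,
                          epsilon: float, sigma: float) -> float:
    """Capped 12-6 well summed over all ligand-receptor bead pairs.

    Each pair contributes eps*[(sigma/r)^12 - 2 (sigma/r)^6], minimum -eps at
    r = sigma, capped at +10 eps to keep clashes finite.
    """
    r = cdist(lig_coords, rec_coords)
    sr6 = (sigma / np.maximum(r, 1e-9)) ** 6
    e = epsilon * (sr6 * sr6 - 2.0 * sr6)
    return float(np.minimum(e, 10.0 * epsilon).sum())


@dataclass
class ToyDockBackend:
    """Seeded rigid-body Monte-Carlo docking over a coarse pair potential.

    The ligand is kept internally rigid (the screening premise is that the
    preformed conformation is conserved on binding); one bead per residue (CA
    atoms if present, else all atoms) interacts with the receptor beads
    through the capped 12-6 well.  ``n_poses`` random placements around the
    receptor pocket centroid are scored and the best returned.
    """

    epsilon: float = 0.5    # kcal/mol, well depth per bead pair
    sigma: float = 0.55     # nm, well minimum distance
    n_poses: int = 200
    placement_sd: float = 0.3   # nm, translation scatter around the pocket centroid

    @staticmethod
    def _beads(conf: Conformer) -> np.ndarray:
        mask = conf.atom_names == "CA"
        return conf.coords[mask] if mask.any() else conf.coords

    def dock(self, conformer: Conformer, receptor: Receptor,
             n_poses: int | None = None, seed: int = 0) -> BindingScore:
        n_poses = self.n_poses if n_poses is None else n_poses
        if n_poses < 1:
            raise ValueError("n_poses must be >= 1")
        lig = self._beads(conformer)
        rec = self._beads(receptor.structure)
        if len(lig) == 0 or len(rec) == 0:
            raise ValueError("ligand and receptor must be non-empty")
        rng = np.random.default_rng(seed)
        pocket = rec.mean(axis=0)
        lig_center = lig.mean(axis=0)
        best_e, best_rot, best_t = np.inf, None, None
        for _ in range(n_poses):
            rot = Rotation.random(rng=rng).as_matrix()
            target = pocket + rng.normal(0.0, self.placement_sd, 3)
            placed = (lig - lig_center) @ rot.T + target
            e = pair_potential_energy(placed, rec, self.epsilon, self.sigma)
            if e < best_e:
                best_e, best_rot, best_t = e, rot, target - lig_center
        return BindingScore(energy=best_e, rotation=best_rot, translation=best_t)

    __call__ = dock


def toy_dock(conformer: Conformer, receptor: Receptor, n_poses: int = 200,
             seed: int = 0) -> BindingScore:
    """Functional form of :class:`ToyDockBackend` with default parameters."""
    return ToyDockBackend(n_poses=n_poses).dock(conformer, receptor, n_poses, seed)


def _child_seed(master: int, *key: int) -> int:
    # Counter-based derivation: identical (master, key) always maps to the
    # same child seed, so any subset of the campaign reruns identically.
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0])


_CLASS_ORDER = [SubEnsembleLabel.C_TRANS, SubEnsembleLabel.E_TRANS,
                SubEnsembleLabel.E_CIS, SubEnsembleLabel.C_CIS]


def run_screening(plan: ScreeningPlan, labeled: LabeledTrajectory, receptor: Receptor,
                  backend) -> list[ComplexRecord]:
    """Execute the full screening campaign.

    For every run and every sub-ensemble present in the labeled trajectory:
    sample ``plan.n_structures`` conformers and call the backend
    ``plan.n_repeats`` times per conformer with distinct derived seeds.
    Backend failures are collected per (conformer, repeat) and surfaced as a
    single :class:`BackendError` after the campaign.
    """
    counts = labeled.label_counts()
    present = [l for l in _CLASS_ORDER if counts.get(l, 0) > 0]
    for label in present:
        if counts[label] < plan.n_structures:
            raise InsufficientFramesError(
                f"sub-ensemble {label} has {counts[label]} frames, "
                f"{plan.n_structures} required"
            )
    records: list[ComplexRecord] = []
    failures: list[tuple] = []
    for run_id in range(plan.n_runs):
        for ci, label in enumerate(present):
            sample_seed = _child_seed(plan.seed, run_id, ci)
            conformers = sample_structures(labeled, label, plan.n_structures, sample_seed)
            for conf in conformers:
                for rep in range(plan.n_repeats):
                    dock_seed = _child_seed(plan.seed, run_id, ci, conf.id, rep)
                    try:
                        score = backend(conf, receptor, None, dock_seed)
                    except Exception as exc:  # noqa: BLE001 — per-call bookkeeping
                        failures.append((label, run_id, conf.id, rep, str(exc)))
                        continue
                    records.append(ComplexRecord(
                        sub_ensemble=label, run_id=run_id, conformer_id=conf.id,
                        repeat_index=rep, energy=score.energy,
                        kd=kd_from_binding_energy(score.energy, plan.temperature),
                    ))
    if failures:
        raise BackendError(
            f"{len(failures)} backend calls failed; first: {failures[0]}", failures
        )
    return records


def select_top_complexes(records: list[ComplexRecord], top_n: int) -> list[ComplexRecord]:
    """The ``top_n`` records with the most favorable (lowest) energies.

    Ties are broken by (conformer_id, repeat_index) ascending.  If ``top_n``
    exceeds the record count, all records are returned with a warning.
    """
    if not records:
        raise ValueError("no records to select from")
    if top_n > len(records):
        warnings.warn(f"top_n={top_n} exceeds {len(records)} records; returning all",
                      stacklevel=2)
    ordered = sorted(records, key=lambda r: (r.energy, r.conformer_id, r.repeat_index))
    return ordered[:top_n]


_TABLE_COLUMNS = ["sub_ensemble", "run_id", "conformer_id", "repeat_index",
                  "energy_kcal_mol", "convention"]


def read_energy_table(path: str, temperature: float = DEFAULT_TEMPERATURE_K
                      ) -> list[ComplexRecord]:
    """Ingest a TSV of externally computed binding energies.

    Required columns: sub_ensemble, run_id, conformer_id, repeat_index,
    energy_kcal_mol, convention.  Rows with ``convention=positive_favorable``
    are negated on ingest so the stored energy is always negative-favorable;
    K_D is derived at the given temperature.  Malformed rows raise
    :class:`EnergyTableError` naming the line number (header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise EnergyTableError(f"{path}: missing columns {missing}")

    def first_bad_line(mask) -> int:
        return int(np.flatnonzero(mask)[0]) + 2   # header is line 1

    valid_labels = {l.value for l in SubEnsembleLabel}
    bad = ~df["sub_ensemble"].isin(valid_labels)
    if bad.any():
        i = first_bad_line(bad.to_numpy())
        raise EnergyTableError(
            f"{path} line {i}: unknown sub-ensemble {df['sub_ensemble'].iloc[i - 2]!r}"
        )
    numeric = {}
    for col in ("run_id", "conformer_id", "repeat_index", "energy_kcal_mol"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna().to_numpy() | ~np.isfinite(converted.to_numpy(dtype=float))
        if bad.any():
            raise EnergyTableError(
                f"{path} line {first_bad_line(bad)}: unparseable numeric field {col!r}"
            )
        numeric[col] = converted.to_numpy()
    conv = df["convention"].to_numpy()
    bad = ~np.isin(conv, ["negative_favorable", "positive_favorable"])
    if bad.any():
        raise EnergyTableError(
            f"{path} line {first_bad_line(bad)}: unknown energy convention"
        )
    energies = np.where(conv == "positive_favorable",
                        -numeric["energy_kcal_mol"], numeric["energy_kcal_mol"])
    dup = df.duplicated(subset=["sub_ensemble", "run_id", "conformer_id",
                                "repeat_index"]).to_numpy()
    if dup.any():
        i = first_bad_line(dup)
        raise EnergyTableError(f"{path} line {i}: duplicate key "
                               f"{tuple(df.iloc[i - 2][:4])}")
    rt = GAS_CONSTANT_KCAL * temperature
    return [
        ComplexRecord(SubEnsembleLabel(lab), int(run), int(conf), int(rep),
                      float(e), float(np.exp(e / rt)))
        for lab, run, conf, rep, e in zip(
            df["sub_ensemble"], numeric["run_id"], numeric["conformer_id"],
            numeric["repeat_index"], energies)
    ]


def records_to_frame(records: list[ComplexRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "sub_ensemble": [str(r.sub_ensemble) for r in records],
        "run_id": [r.run_id for r in records],
        "conformer_id": [r.conformer_id for r in records],
        "repeat_index": [r.repeat_index for r in records],
        "energy_kcal_mol": [r.energy for r in records],
        "kd_mol_per_l": [r.kd for r in records],
    })


def write_energy_table(records: list[ComplexRecord], path: str) -> None:
    """Write records as a TSV round-trippable through :func:`read_energy_table`."""
    df = records_to_frame(records).drop(columns="kd_mol_per_l")
    df["convention"] = "negative_favorable"
    df.to_csv(path, sep="\t", index=False)
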