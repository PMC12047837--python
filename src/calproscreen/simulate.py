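"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure of one experimental input
(plate-reader OD600 growth curves, dimer coordinate models with a planted
metal site, dual-luciferase plates, diverged sequence families) and returns a
*truth record* holding everything needed to compute expected downstream
values without re-running the generator.

Randomness: every generator derives its own independent stream from the user
seed via ``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed
``k`` per generator (growth 0, structure 1, reporter 2, sequences 3,
stand-ins 4). Adding a call to one generator therefore never perturbs
another's output.

This module also provides two deliberately simplified stand-ins for
reference objects that live in external databases: a synthetic
calprotectin-like Zn-bound heterodimer and a synthetic icn/icn2-like
sequence pair. Both are labelled synthetic and are geometric/arithmetic
emulations, not the database entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

import pandas as pd

from .fasta import SequenceRecord
from .pdb import Atom, Structure
from .tables import BLANK, validate_growth_table, validate_reporter_table

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_STREAMS = {"growth": 0, "structure": 1, "reporter": 2, "sequences": 3, "standin": 4}


class SimulationError(ValueError):
    pass


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


def _q(x: float) -> float:
    """Quantize a coordinate to PDB precision (0.001 Å)."""
    return float(np.round(x, 3))


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimParams:
    """Logistic growth with Hill-type dose-dependent suppression.

    ``effect`` is the fraction of both carrying capacity and rate suppressed
    at saturating dose; the inhibition multiplier at dose c is
    ``s(c) = 1 − effect · c^hill / (c^hill + ic50^hill)``.
    """

    strain: str = "S_epidermidis_like"
    protein: str = "hCP"
    blank_od: float = 0.05        # OD600 of medium + protein, no bacteria
    K: float = 1.0                # carrying capacity, OD600
    r: float = 0.8                # growth rate, /h
    t_lag: float = 4.0            # inflection time, h
    ic50: float = 20.0            # µM
    hill: float = 2.0
    effect: float = 1.0           # 0 = inert protein, 1 = full suppression
    doses: tuple[float, ...] = (0.0, 12.5, 25.0, 50.0, 100.0)  # µM
    n_bio: int = 3
    n_tech: int = 3
    noise_sd: float = 0.01        # OD noise (additive sd, or CV in multiplicative mode)
    noise_mode: str = "additive"  # "additive" (plate-reader-like) or "multiplicative"
    t_end: float = 13.0           # h
    dt: float = 0.25              # h (15-minute plate-reader grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.r <= 0 or self.ic50 <= 0 or self.hill <= 0:
            raise SimulationError("K, r, ic50 and hill must be positive")
        if not 0 <= self.effect <= 1:
            raise SimulationError("effect must be in [0, 1]")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")
        if self.noise_mode not in ("additive", "multiplicative"):
            raise SimulationError(f"unknown noise_mode {self.noise_mode!r}")
        if 0.0 not in self.doses:
            raise SimulationError("doses must include the 0 µM control")

    def grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt)) + 1
        return np.round(np.linspace(0.0, self.t_end, n), 6)

    def inhibition_multiplier(self, dose: float) -> float:
        if dose == 0:
            return 1.0
        h = self.hill
        return 1.0 - self.effect * dose**h / (dose**h + self.ic50**h)

    def signal(self, t: np.ndarray, dose: float) -> np.ndarray:
        s = self.inhibition_multiplier(dose)
        if s == 0:
            return np.zeros_like(t)
        return s * self.K / (1.0 + np.exp(-s * self.r * (t - self.t_lag)))

    def signal_auc_closed_form(self, dose: float, t0: float = 0.0, t1: float | None = None) -> float:
        """Exact integral of the noiseless logistic signal over [t0, t1]."""
        if t1 is None:
            t1 = self.t_end
        s = self.inhibition_multiplier(dose)
        if s == 0:
            return 0.0
        a = s * self.r
        upper = np.logaddexp(0.0, a * (t1 - self.t_lag))
        lower = np.logaddexp(0.0, a * (t0 - self.t_lag))
        return float(self.K / self.r * (upper - lower))


def simulate_growth_plate(params: GrowthSimParams) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format OD600 plate with matching no-bacteria blanks.

    Returns ``(table, truth)``; truth stores the noiseless signal per dose
    and the true ΔAUC per dose from the closed-form logistic integral.
    """
    rng = _rng(params.seed, "growth")
    t = params.grid()
    rows = []
    well_idx = 0

    def _measure(clean: np.ndarray) -> np.ndarray:
        if not params.noise_sd:
            return clean + np.zeros_like(t)
        eps = rng.normal(0.0, params.noise_sd, size=t.shape)
        if params.noise_mode == "multiplicative":
            return clean * (1.0 + eps)
        return clean + eps

    for dose in params.doses:
        sig = params.signal(t, dose)
        for rep in range(1, params.n_bio + 1):
            for tech in range(1, params.n_tech + 1):
                well_idx += 1
                od = _measure(params.blank_od + sig)
                rows.extend(
                    {
                        "strain": params.strain,
                        "protein": params.protein,
                        "concentration": dose,
                        "replicate_bio": rep,
                        "replicate_tech": tech,
                        "well": f"W{well_idx:03d}",
                        "time": ti,
                        "od600": oi,
                    }
                    for ti, oi in zip(t, od)
                )
            # matching blanks: medium + protein at this dose, no bacteria;
            # each biological replicate (plate/day) carries its own blanks
            for tech in range(1, params.n_tech + 1):
                well_idx += 1
                od = _measure(np.full_like(t, params.blank_od))
                rows.extend(
                    {
                        "strain": BLANK,
                        "protein": params.protein,
                        "concentration": dose,
                        "replicate_bio": rep,
                        "replicate_tech": tech,
                        "well": f"W{well_idx:03d}",
                        "time": ti,
                        "od600": oi,
                    }
                    for ti, oi in zip(t, od)
                )
    table = validate_growth_table(pd.DataFrame(rows))
    control_auc = params.signal_auc_closed_form(0.0)
    truth = {
        "times": t.tolist(),
        "noiseless_signal": {str(d): params.signal(t, d).tolist() for d in params.doses},
        "inhibition_multiplier": {str(d): params.inhibition_multiplier(d) for d in params.doses},
        "control_auc": control_auc,
        "true_delta_auc": {
            str(d): params.signal_auc_closed_form(d) - control_auc
            for d in params.doses
        },
    }
    return table, truth


# ---------------------------------------------------------------------------
# structure fixtures
# ---------------------------------------------------------------------------

@dataclass
class StructureFixturePlan:
    """Idealized dimer fixture: a planted Zn site probed by the census.

    Residues carry only the atoms the analysis reads (Cα, plus NE2 when
    ``donor_mode="NE2"``); full backbone geometry would not change any tested
    quantity.
    """

    n_his: int = 7
    his_radii: tuple[float, ...] = (6.3, 6.3, 6.4, 6.4, 6.5, 6.5, 8.5)  # Å from Zn
    n_decoy: int = 20
    donor_mode: str = "CA"        # "CA" or "NE2"
    donor_distance: float = 2.1   # Å, NE2–Zn distance in NE2 mode
    transform: str | tuple = "random"  # or (rotation 3x3, translation 3)
    noise_sd: float = 0.0         # Å, per-atom Gaussian noise on the mobile copy
    axis_aligned: bool = False    # deterministic His directions (exact radii)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_his != len(self.his_radii):
            raise SimulationError("n_his must equal len(his_radii)")
        if any(r <= 0 for r in self.his_radii):
            raise SimulationError("his_radii must be positive")
        if self.donor_mode not in ("CA", "NE2"):
            raise SimulationError(f"unknown donor_mode {self.donor_mode!r}")


_AXES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _place_decoy(rng: np.random.Generator, taken: list[np.ndarray]) -> np.ndarray:
    for _ in range(100):
        p = _random_unit(rng) * rng.uniform(12.0, 25.0)
        if all(np.linalg.norm(p - q) >= 1.5 for q in taken):
            return p
    raise SimulationError("could not place a decoy without collision")


def simulate_structure_fixture(
    plan: StructureFixturePlan,
) -> tuple[Structure, Structure, dict]:
    """Build (reference, mobile, truth) for the superposition/census screen.

    The reference has a Zn ion at the origin, ``n_his`` histidine Cα at the
    planted radii and non-His decoy residues split over two chains; the
    mobile copy is the reference polymer under the planted (or random) rigid
    motion plus optional coordinate noise. Reference coordinates are
    quantized to PDB precision so file round-trips are exact.
    """
    rng = _rng(plan.seed, "structure")
    serial = 0
    atoms: list[Atom] = []
    taken: list[np.ndarray] = []

    def add(kind, name, resname, chain, resseq, xyz, element):
        nonlocal serial
        serial += 1
        atoms.append(
            Atom(
                record_kind=kind, serial=serial, name=name, altloc="",
                resname=resname, chain=chain, resseq=resseq, icode="",
                x=_q(xyz[0]), y=_q(xyz[1]), z=_q(xyz[2]), element=element,
            )
        )

    # chain A: histidines (+ half the decoys), chain B: remaining decoys
    resseq = 0
    for i, radius in enumerate(plan.his_radii):
        if plan.axis_aligned:
            d = _AXES[i % 6]
        else:
            d = _random_unit(rng)
        resseq += 1
        add("ATOM", "CA", "HIS", "A", resseq, d * radius, "C")
        taken.append(d * radius)
        if plan.donor_mode == "NE2":
            add("ATOM", "NE2", "HIS", "A", resseq, d * plan.donor_distance, "N")
    n_a = plan.n_decoy // 2
    for _ in range(n_a):
        p = _place_decoy(rng, taken)
        taken.append(p)
        resseq += 1
        add("ATOM", "CA", "ALA", "A", resseq, p, "C")
    resseq = 0
    for _ in range(plan.n_decoy - n_a):
        p = _place_decoy(rng, taken)
        taken.append(p)
        resseq += 1
        add("ATOM", "CA", "ALA", "B", resseq, p, "C")
    add("HETATM", "ZN", "ZN", "A", 901, np.zeros(3), "ZN")
    reference = Structure(id="fixture_ref", atoms=atoms)

    if plan.transform == "random":
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20.0, 20.0, size=3)
    elif plan.transform == "identity":
        R = np.eye(3)
        t = np.zeros(3)
    else:
        R = np.asarray(plan.transform[0], dtype=float)
        t = np.asarray(plan.transform[1], dtype=float)
    mobile = reference.subset(polymer_only=True).transformed(R, t)
    if plan.noise_sd > 0:
        noisy = []
        from dataclasses import replace as _replace

        for a in mobile.atoms:
            dx = rng.normal(0.0, plan.noise_sd, size=3)
            noisy.append(_replace(a, x=a.x + dx[0], y=a.y + dx[1], z=a.z + dx[2]))
        mobile = Structure(id=mobile.id, atoms=noisy)
    mobile.id = "fixture_mobile"

    truth = {
        "rotation": R.tolist(),
        "translation": t.tolist(),
        "his_radii": list(plan.his_radii),
        "expected_census_9A": int(sum(1 for r in plan.his_radii if r <= 9.0)),
        "planted_donors": (
            [["A", i + 1] for i in range(plan.n_his)]
            if plan.donor_mode == "NE2"
            else []
        ),
    }
    return reference, mobile, truth


# ---------------------------------------------------------------------------
# reporter plates
# ---------------------------------------------------------------------------

@dataclass
class ReporterSimParams:
    """Dual-luciferase plate with planted fold-activation per condition.

    ``fold_activation`` is the induced firefly signal per unit Renilla,
    relative to the per-complex baseline: vehicle wells carry fold 0 (pure
    background), and the expected pipeline output for a condition is
    ``fold(complex, treatment) / fold(reference)``.
    """

    complexes: tuple[str, ...] = ("hTLR4", "tlr4ba", "tlr4bb", "tlr4al")
    treatments: tuple[str, ...] = ("ENDOTOXIN", "S100A9")
    fold_activation: dict = field(
        default_factory=lambda: {
            ("hTLR4", "ENDOTOXIN"): 20.0,
            ("tlr4ba", "ENDOTOXIN"): 10.0,
            ("hTLR4", "S100A9"): 15.0,
        }
    )
    reference_complex: str = "hTLR4"
    reference_treatment: str = "ENDOTOXIN"
    baseline_ff: float = 5.0      # firefly per unit Renilla at fold 1
    baseline_rn: float = 1000.0   # median Renilla of transfected wells
    ff_background: float = 200.0  # complex-matched additive firefly background
    rn_background: float = 50.0   # instrument Renilla background
    rn_dispersion: float = 0.2    # lognormal sigma of transfection efficiency
    noise_cv: float = 0.05        # multiplicative measurement noise
    n_bio: int = 3                # biological replicates (the replicate column)
    n_tech: int = 3               # technical wells per biological replicate
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fold_activation.values()):
            raise SimulationError("fold activations must be >= 0")
        if self.baseline_ff <= 0 or self.baseline_rn <= 0:
            raise SimulationError("baselines must be positive")
        ref = (self.reference_complex, self.reference_treatment)
        if self.fold_activation.get(ref, 0.0) <= 0:
            raise SimulationError("reference condition must have positive fold")

    def fold(self, complex_: str, treatment: str) -> float:
        if treatment == "VEHICLE":
            return 0.0
        return float(self.fold_activation.get((complex_, treatment), 0.0))


def simulate_reporter_plate(params: ReporterSimParams) -> tuple[pd.DataFrame, dict]:
    """Simulate a reporter plate incl. vehicle and vector-only wells.

    Returns ``(table, truth)``; truth stores the planted folds and the
    expected normalized mean per (complex, treatment).
    """
    rng = _rng(params.seed, "reporter")
    complexes = list(params.complexes)
    treatments = list(params.treatments)
    if "VEHICLE" not in treatments:
        treatments.append("VEHICLE")
    bg_ff = {
        c: params.ff_background * (1.0 + 0.2 * rng.uniform(-1, 1))
        for c in complexes + ["VECTOR"]
    }
    rows = []
    for c in complexes + ["VECTOR"]:
        for trt in treatments:
            for bio in range(1, params.n_bio + 1):
                for _tech in range(params.n_tech):
                    eps = lambda: 1.0 + rng.normal(0.0, params.noise_cv)
                    if c == "VECTOR":
                        renilla = params.rn_background * eps()
                        firefly = bg_ff[c] * eps()
                    else:
                        L = rng.lognormal(np.log(params.baseline_rn), params.rn_dispersion)
                        renilla = L + params.rn_background * eps()
                        firefly = (
                            L * params.baseline_ff * params.fold(c, trt) * eps()
                            + bg_ff[c] * eps()
                        )
                    rows.append(
                        {
                            "complex": c,
                            "treatment": trt,
                            "replicate": bio,
                            "firefly": max(firefly, 0.0),
                            "renilla": max(renilla, 0.0),
                        }
                    )
    table = validate_reporter_table(pd.DataFrame(rows))
    ref_fold = params.fold(params.reference_complex, params.reference_treatment)
    truth = {
        "fold": {f"{c}|{t}": params.fold(c, t) for c in complexes for t in treatments},
        "expected_normalized": {
            f"{c}|{t}": params.fold(c, t) / ref_fold
            for c in complexes
            for t in treatments
        },
        "reference": [params.reference_complex, params.reference_treatment],
    }
    return table, truth


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------

@dataclass
class FamilySimParams:
    """Star-shaped family: descendants of one ancestor with planted counts."""

    length: int = 111
    substitutions: tuple[int, ...] = (5, 10, 20)  # per descendant vs ancestor
    alphabet: str = AMINO_ACIDS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k > self.length for k in self.substitutions):
            raise SimulationError("substitution count exceeds sequence length")
        if self.length < 1 or not self.substitutions:
            raise SimulationError("need positive length and >= 1 descendant")


def simulate_sequence_family(
    params: FamilySimParams,
) -> tuple[list[SequenceRecord], dict]:
    """Generate descendants with exact planted substitution counts.

    Each descendant differs from the shared ancestor at exactly its planted
    number of positions (substituted residues always differ from the
    ancestral one). Truth records the realized pairwise difference counts.
    """
    rng = _rng(params.seed, "sequences")
    alphabet = np.array(list(params.alphabet))
    ancestor = rng.choice(alphabet, size=params.length)
    seqs = []
    for i, k in enumerate(params.substitutions, start=1):
        child = ancestor.copy()
        positions = rng.choice(params.length, size=k, replace=False)
        for pos in positions:
            choices = [a for a in params.alphabet if a != child[pos]]
            child[pos] = rng.choice(choices)
        seqs.append(SequenceRecord(id=f"seq{i}", residues="".join(child)))
    pairwise = {}
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            diff = sum(
                1 for a, b in zip(seqs[i].residues, seqs[j].residues) if a != b
            )
            pairwise[f"{seqs[i].id}|{seqs[j].id}"] = diff
    truth = {
        "ancestor": "".join(ancestor),
        "planted_substitutions": list(params.substitutions),
        "pairwise_differences": pairwise,
    }
    return seqs, truth


# ---------------------------------------------------------------------------
# labelled synthetic stand-ins for external reference objects
# ---------------------------------------------------------------------------

def synthetic_calprotectin_reference(seed: int = 0) -> Structure:
    """Synthetic stand-in for a Zn-bound calprotectin heterodimer.

    Geometric emulation only (not a database entry): chain A plays the
    S100A8-like subunit contributing His17 and His27 to the metal site, chain
    C the S100A9-like subunit contributing His87, His91, His99 and His101.
    The six coordinating histidines have NE2 donors 2.2 Å from an octahedral
    Zn at the origin and Cα ~6.4 Å out; one further non-coordinating
    histidine (chain C, 95) sits with its Cα at 8.5 Å so that exactly seven
    His Cα fall within the 9 Å census radius. Decoy alanine residues give
    each chain a superposable Cα scaffold, and two Ca ions mimic the EF-hand
    calcium.
    """
    rng = _rng(seed, "standin")
    atoms: list[Atom] = []
    serial = 0

    def add(kind, name, resname, chain, resseq, xyz, element):
        nonlocal serial
        serial += 1
        atoms.append(
            Atom(
                record_kind=kind, serial=serial, name=name, altloc="",
                resname=resname, chain=chain, resseq=resseq, icode="",
                x=_q(xyz[0]), y=_q(xyz[1]), z=_q(xyz[2]), element=element,
            )
        )

    his_spec = [
        ("A", 17, np.array([1.0, 0, 0])),
        ("A", 27, np.array([-1.0, 0, 0])),
        ("C", 87, np.array([0, 1.0, 0])),
        ("C", 91, np.array([0, -1.0, 0])),
        ("C", 99, np.array([0, 0, 1.0])),
        ("C", 101, np.array([0, 0, -1.0])),
    ]
    taken: list[np.ndarray] = []
    residues: dict[str, list[tuple[int, str, np.ndarray, np.ndarray | None]]] = {
        "A": [], "C": []
    }
    for chain, resseq, d in his_spec:
        residues[chain].append((resseq, "HIS", d * 6.4, d * 2.2))
        taken.append(d * 6.4)
    d95 = np.array([1.0, 1.0, 0]) / np.sqrt(2.0)
    residues["C"].append((95, "HIS", d95 * 8.5, d95 * 5.0))
    taken.append(d95 * 8.5)
    # decoy Cα scaffold per chain (non-His, outside the census radius)
    for chain, base in (("A", 1), ("C", 60)):
        for i in range(10):
            p = _place_decoy(rng, taken)
            taken.append(p)
            residues[chain].append((base + i, "ALA", p, None))
    for chain in ("A", "C"):
        for resseq, resname, ca, ne2 in sorted(residues[chain]):
            add("ATOM", "CA", resname, chain, resseq, ca, "C")
            if ne2 is not None:
                add("ATOM", "NE2", resname, chain, resseq, ne2, "N")
    add("HETATM", "ZN", "ZN", "A", 901, np.zeros(3), "ZN")
    add("HETATM", "CA", "CA", "A", 902, np.array([12.0, 0, 12.0]), "CA")
    add("HETATM", "CA", "CA", "C", 903, np.array([-12.0, 0, -12.0]), "CA")
    return Structure(id="synthetic_calprotectin_reference", atoms=atoms)


def synthetic_icn_like_pair(seed: int = 0) -> tuple[SequenceRecord, SequenceRecord]:
    """Synthetic stand-in for the icn/icn2 paralog pair.

    Arithmetic emulation only (not the database sequences): two length-111
    proteins differing at exactly 14 positions, 8 of them at the termini
    (four at each end), mirroring the published divergence pattern; expected
    global-alignment identity is 97/111 ≈ 87.4%.
    """
    rng = _rng(seed, "standin")
    alphabet = np.array(list(AMINO_ACIDS))
    base = rng.choice(alphabet, size=111)
    other = base.copy()
    terminal = [0, 1, 2, 3, 107, 108, 109, 110]
    internal = sorted(rng.choice(np.arange(20, 90), size=6, replace=False))
    for pos in terminal + list(internal):
        choices = [a for a in AMINO_ACIDS if a != other[pos]]
        other[pos] = rng.choice(choices)
    return (
        SequenceRecord(id="icn_like", description="synthetic stand-in",
                       residues="".join(base)),
        SequenceRecord(id="icn2_like", description="synthetic stand-in",
                       residues="".join(other)),
    )


def write_truth(truth: dict, path: str | Path) -> None:
    """Write a generator's truth record as structured text (JSON)."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
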