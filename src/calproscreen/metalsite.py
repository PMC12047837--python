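"""Histidine census and coordination screen around a reference metal ion.

The screen asks a simple geometric question of every dimer model: after
rigid-body superposition onto a Zn-bound reference dimer, how many histidine
alpha-carbons fall within a cutoff (default 9 Å, inclusive) of the reference
zinc? A high-affinity transition-metal site of the calprotectin type needs six
coordinating histidines, so models with only a handful of histidines anywhere
near the site cannot form one, even allowing generous conformational slack.

Coordination-distance detection (default 3 Å over standard protein donor
atoms) identifies the residues that directly chelate a metal in a single
structure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .pdb import Atom, Structure
from .superpose import Superposition, SuperpositionError, superpose

logger = logging.getLogger("calproscreen")

#: side-chain/backbone atoms that commonly donate to a bound metal
DEFAULT_DONOR_ATOMS = frozenset(
    {"ND1", "NE2", "OD1", "OD2", "OE1", "OE2", "SG", "O"}
)


class MetalSiteError(ValueError):
    pass


@dataclass
class MetalSiteCensus:
    model_id: str
    cutoff: float
    n_his: int
    per_residue: list[tuple[str, int, float]]  # (chain, resseq, distance) for every His

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_residue, columns=["chain", "resseq", "distance"])
        df.insert(0, "model_id", self.model_id)
        df["within_cutoff"] = df["distance"] <= self.cutoff
        return df


@dataclass
class CoordinationSite:
    metal_element: str
    metal_xyz: np.ndarray
    residues: list[tuple[str, str, int, str, float]]  # chain, resname, resseq, donor atom, distance

    def residue_ids(self) -> list[tuple[str, int]]:
        seen = []
        for chain, _, resseq, _, _ in self.residues:
            if (chain, resseq) not in seen:
                seen.append((chain, resseq))
        return seen


@dataclass
class DimerPlan:
    monomer_ids: list[str]
    pairs: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ScreenHistogram:
    counts: dict[int, int]
    total_models: int

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.counts)
        return pd.DataFrame(
            {"n_his": keys, "n_models": [self.counts[k] for k in keys]}
        )


@dataclass
class ScreenResult:
    censuses: list[MetalSiteCensus]
    histogram: ScreenHistogram
    superpositions: dict[str, Superposition]
    failures: dict[str, str] = field(default_factory=dict)


def find_metal(structure: Structure, element: str = "ZN", serial: int | None = None) -> Atom:
    """Locate the (single) metal ion of the given element in a structure."""
    ions = [a for a in structure.metal_ions() if a.element.upper() == element.upper()]
    if serial is not None:
        ions = [a for a in ions if a.serial == serial]
    if not ions:
        raise MetalSiteError(f"no {element} ion found in {structure.id!r}")
    if len(ions) > 1:
        serials = [a.serial for a in ions]
        raise MetalSiteError(
            f"{structure.id!r} has {len(ions)} {element} ions (serials {serials}); "
            f"specify which by serial"
        )
    return ions[0]


def count_his_near_metal(
    model: Structure,
    metal_xyz,
    cutoff: float = 9.0,
    atom_mode: str = "CA",
) -> MetalSiteCensus:
    """Census of histidines near a metal position.

    Distances are Euclidean from each histidine's Cα (or, with
    ``atom_mode="any"``, its nearest atom) to ``metal_xyz``; the count is over
    distances ≤ cutoff (inclusive). Histidines lacking the required atom are
    skipped with a logged warning.
    """
    metal_xyz = np.asarray(metal_xyz, dtype=float)
    if not np.all(np.isfinite(metal_xyz)) or metal_xyz.shape != (3,):
        raise MetalSiteError("metal position must be a finite 3-vector")
    per_residue: list[tuple[str, int, float]] = []
    for res in model.residues(polymer_only=True):
        if res.resname != "HIS":
            continue
        if atom_mode == "CA":
            ca = res.atom("CA")
            if ca is None:
                logger.warning(
                    "model %s: HIS %s%d lacks a CA atom; skipped",
                    model.id, res.chain, res.resseq,
                )
                continue
            dist = float(np.linalg.norm(ca.xyz - metal_xyz))
        elif atom_mode == "any":
            dist = min(
                float(np.linalg.norm(a.xyz - metal_xyz)) for a in res.atoms
            )
        else:
            raise MetalSiteError(f"unknown atom_mode {atom_mode!r}")
        per_residue.append((res.chain, res.resseq, dist))
    n_his = sum(1 for _, _, d in per_residue if d <= cutoff)
    return MetalSiteCensus(
        model_id=model.id, cutoff=cutoff, n_his=n_his, per_residue=per_residue
    )


def detect_coordinating_residues(
    structure: Structure,
    metal: Atom | None = None,
    element: str = "ZN",
    cutoff: float = 3.0,
    donor_atoms: frozenset[str] = DEFAULT_DONOR_ATOMS,
) -> CoordinationSite:
    """Residues with a donor atom within coordination distance of a metal.

    Returns one entry per (residue, donor atom) within the cutoff, sorted by
    distance.
    """
    if metal is None:
        metal = find_metal(structure, element=element)
    mx = metal.xyz
    hits: list[tuple[str, str, int, str, float]] = []
    for res in structure.residues(polymer_only=True):
        for a in res.atoms:
            if a.name not in donor_atoms:
                continue
            d = float(np.linalg.norm(a.xyz - mx))
            if d <= cutoff:
                hits.append((res.chain, res.resname, res.resseq, a.name, d))
    hits.sort(key=lambda h: h[4])
    return CoordinationSite(
        metal_element=metal.element, metal_xyz=mx, residues=hits
    )


def enumerate_dimers(monomer_ids: list[str], ordered: bool = True) -> DimerPlan:
    """All homo- and heterodimer pairings of a monomer set.

    Ordered mode (default) yields every (i, j) including i == j — n² pairs
    for n monomers; unordered mode yields the n(n+1)/2 combinations with
    repetition.
    """
    if not monomer_ids:
        raise MetalSiteError("empty monomer list")
    if len(set(monomer_ids)) != len(monomer_ids):
        raise MetalSiteError("monomer ids must be unique")
    if ordered:
        pairs = list(itertools.product(monomer_ids, repeat=2))
    else:
        pairs = list(itertools.combinations_with_replacement(monomer_ids, 2))
    return DimerPlan(monomer_ids=list(monomer_ids), pairs=pairs)


def screen_models(
    models: list[Structure],
    reference: Structure,
    metal: Atom | None = None,
    cutoff: float | None = None,
    config: RunConfig | None = None,
    ref_chains: tuple[str, str] | None = None,
) -> ScreenResult:
    """Superpose each model onto the reference and census His near its metal.

    Each two-chain model is fitted under both chain-pairing assignments and
    the lower-RMSD fit kept (the assignment is logged). Models are moved into
    the reference frame; the census uses the reference's own metal position.
    Models that fail superposition are recorded and excluded from the
    histogram.
    """
    config = config or RunConfig()
    if cutoff is None:
        cutoff = config.cutoff_his
    if metal is None:
        metal = find_metal(reference)
    if ref_chains is None:
        ids = reference.chain_ids
        if len(ids) < 2:
            raise MetalSiteError("reference must have two polymer chains")
        ref_chains = (ids[0], ids[1])

    censuses: list[MetalSiteCensus] = []
    superpositions: dict[str, Superposition] = {}
    failures: dict[str, str] = {}
    for model in models:
        try:
            chains = model.chain_ids
            if len(chains) == 1:
                maps = [{chains[0]: ref_chains[0]}, {chains[0]: ref_chains[1]}]
            else:
                c0, c1 = chains[0], chains[1]
                maps = [
                    {c0: ref_chains[0], c1: ref_chains[1]},
                    {c0: ref_chains[1], c1: ref_chains[0]},
                ]
            fits = []
            for cm in maps:
                try:
                    fits.append((superpose(model, reference, chain_map=cm), cm))
                except SuperpositionError:
                    continue
            if not fits:
                raise SuperpositionError("no chain-pairing assignment could be fitted")
            sup, chosen = min(fits, key=lambda fc: fc[0].rmsd)
            logger.info(
                "model %s: chain map %s kept (rmsd %.3f Å over %d pairs)",
                model.id, chosen, sup.rmsd, sup.n_pairs_used,
            )
            placed = sup.apply(model)
            censuses.append(
                count_his_near_metal(placed, metal.xyz, cutoff=cutoff)
            )
            superpositions[model.id] = sup
        except (SuperpositionError, MetalSiteError) as exc:
            failures[model.id] = str(exc)
            logger.warning("model %s failed superposition: %s", model.id, exc)

    counts: dict[int, int] = {}
    for c in censuses:
        counts[c.n_his] = counts.get(c.n_his, 0) + 1
    histogram = ScreenHistogram(counts=counts, total_models=len(censuses))
    return ScreenResult(
        censuses=censuses,
        histogram=histogram,
        superpositions=superpositions,
        failures=failures,
    )


def write_screen_outputs(result: ScreenResult, out_dir: str | Path) -> None:
    """Emit the per-model census, per-residue distances and histogram CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in result.censuses:
        sup = result.superpositions.get(c.model_id)
        rows.append(
            {
                "model_id": c.model_id,
                "rmsd": sup.rmsd if sup else np.nan,
                "n_pairs_used": sup.n_pairs_used if sup else 0,
                "n_his": c.n_his,
            }
        )
    pd.DataFrame(rows).to_csv(out / "census.csv", index=False)
    if result.censuses:
        pd.concat([c.to_frame() for c in result.censuses]).to_csv(
            out / "per_residue.csv", index=False
        )
    result.histogram.to_frame().to_csv(out / "histogram.csv", index=False)
    if result.failures:
        pd.DataFrame(
            [{"model_id": k, "reason": v} for k, v in result.failures.items()]
        ).to_csv(out / "failures.csv", index=False)
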