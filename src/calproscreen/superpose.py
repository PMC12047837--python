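"""Rigid-body superposition of dimer models onto a reference structure.

Cα atoms are paired chain-by-chain through sequence alignment, then fitted by
the Kabsch algorithm (SVD least squares, determinant-corrected so the result
is a proper rotation). An iterative trim loop drops badly fitting pairs
(residual beyond ``reject_factor`` × current RMSD) for up to ``max_cycles``
rounds, mimicking the refinement step of common structure viewers; pass
``all_pairs=True`` to fit every aligned pair once with no trimming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pdb import Atom, Structure
from .seqident import global_align
from .fasta import SequenceRecord


class SuperpositionError(ValueError):
    pass


@dataclass
class Superposition:
    rotation: np.ndarray        # 3x3 proper rotation
    translation: np.ndarray     # 3-vector, Å
    rmsd: float                 # over retained pairs, Å
    n_pairs_used: int
    pairing: list[tuple[Atom, Atom]]  # (mobile, reference) pairs retained

    def apply(self, structure: Structure) -> Structure:
        """Map a structure into the reference frame (R @ x + t)."""
        return structure.transformed(self.rotation, self.translation)


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping points P onto Q.

    Returns (R, t, rmsd) with ``R @ p + t ≈ q``; R is a proper rotation
    (det +1). Raises on fewer than 3 points or degenerate (collinear) sets.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("point sets must both be (n, 3)")
    if len(P) < 3:
        raise SuperpositionError(f"need at least 3 point pairs, got {len(P)}")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    P0 = P - cp
    Q0 = Q - cq
    H = P0.T @ Q0
    U, s, Vt = np.linalg.svd(H)
    # collinear point sets leave a rotation axis undetermined
    scale = max(s[0], 1.0)
    if s[1] / scale < 1e-10:
        raise SuperpositionError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def _ca_pairs_for_chain(
    mobile: Structure, ref: Structure, mobile_chain: str, ref_chain: str
) -> list[tuple[Atom, Atom]]:
    mseq, mres = mobile.chain_sequence(mobile_chain)
    rseq, rres = ref.chain_sequence(ref_chain)
    if not mseq or not rseq:
        return []
    aln = global_align(
        SequenceRecord(id=f"m:{mobile_chain}", residues=mseq),
        SequenceRecord(id=f"r:{ref_chain}", residues=rseq),
    )
    pairs: list[tuple[Atom, Atom]] = []
    i = j = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            ca_m = mres[i].atom("CA")
            ca_r = rres[j].atom("CA")
            if ca_m is not None and ca_r is not None:
                pairs.append((ca_m, ca_r))
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    return pairs


def superpose(
    mobile: Structure,
    reference: Structure,
    chain_map: dict[str, str] | None = None,
    max_cycles: int = 5,
    reject_factor: float = 2.0,
    all_pairs: bool = False,
) -> Superposition:
    """Superpose ``mobile`` onto ``reference`` over sequence-aligned Cα pairs.

    ``chain_map`` maps mobile chain ids to reference chain ids; by default
    chains are paired in file order. Outlier pairs are trimmed iteratively
    unless ``all_pairs`` is set.
    """
    if chain_map is None:
        mc, rc = mobile.chain_ids, reference.chain_ids
        chain_map = dict(zip(mc, rc))
    pairs: list[tuple[Atom, Atom]] = []
    for m_chain, r_chain in chain_map.items():
        pairs.extend(_ca_pairs_for_chain(mobile, reference, m_chain, r_chain))
    if len(pairs) < 3:
        raise SuperpositionError(
            f"only {len(pairs)} alignable Cα pairs for chain map {chain_map}"
        )
    P = np.array([a.xyz for a, _ in pairs])
    Q = np.array([b.xyz for _, b in pairs])
    keep = np.ones(len(pairs), dtype=bool)
    R, t, rmsd = kabsch(P, Q)
    if not all_pairs:
        for _ in range(max_cycles):
            resid = np.linalg.norm((P[keep] @ R.T + t) - Q[keep], axis=1)
            if rmsd <= 0:
                break
            bad = resid > reject_factor * rmsd
            if not bad.any():
                break
            idx = np.flatnonzero(keep)
            if keep.sum() - bad.sum() < 3:
                break
            keep[idx[bad]] = False
            R, t, rmsd = kabsch(P[keep], Q[keep])
    retained = [p for p, k in zip(pairs, keep) if k]
    return Superposition(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_pairs_used=int(keep.sum()),
        pairing=retained,
    )
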