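"""Rigid superposition of a variant structure onto its parent scaffold.

Cα RMSD after optimal rigid-body superposition is the standard check that a
selected variant retains the parent fold.  The rotation is obtained with the
Kabsch SVD construction including the reflection correction, so the returned
matrix is always a proper rotation (det = +1), even for mirror-image inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateGeometryError, InputError
from .structure_model import ResKey, StructureModel


@dataclass
class ResiduePairing:
    pairs: list[tuple[ResKey, ResKey]]
    method: str
    identity_pct: float


def pair_residues(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_a: str | None = None,
    chain_b: str | None = None,
    method: str = "seq_align",
) -> ResiduePairing:
    """One-to-one Cα-bearing residue pairs between two models.

    ``seq_align`` (default) aligns the chain sequences globally, so variants
    with substitutions still pair correctly; ``by_number`` matches author
    residue numbering.
    """
    res_a = [r for r in model_a.residues(chain_a or next(iter(model_a.chains)))
             if r.atom("CA") is not None]
    res_b = [r for r in model_b.residues(chain_b or next(iter(model_b.chains)))
             if r.atom("CA") is not None]
    if len(res_a) < 3 or len(res_b) < 3:
        raise InputError("need >= 3 residues with CA in both models")

    if method == "by_number":
        index_b = {(r.seq_num, r.insertion_code): r for r in res_b}
        pairs = [(ra.key, index_b[(ra.seq_num, ra.insertion_code)].key)
                 for ra in res_a if (ra.seq_num, ra.insertion_code) in index_b]
        matched = [(ra, index_b[(ra.seq_num, ra.insertion_code)])
                   for ra in res_a if (ra.seq_num, ra.insertion_code) in index_b]
        ident = (100.0 * sum(1 for a, b in matched if a.aa == b.aa) / len(matched)
                 if matched else 0.0)
    elif method == "seq_align":
        from .conservation import _global_align

        seq_a = "".join(r.aa for r in res_a)
        seq_b = "".join(r.aa for r in res_b)
        alignment = _global_align(seq_a, seq_b)
        pairs = []
        matches = 0
        for (a0, a1), (b0, b1) in zip(*alignment.aligned):
            for ia, ib in zip(range(a0, a1), range(b0, b1)):
                pairs.append((res_a[ia].key, res_b[ib].key))
                matches += seq_a[ia] == seq_b[ib]
        ident = 100.0 * matches / len(pairs) if pairs else 0.0
    else:
        raise InputError(f"unknown pairing method {method!r}")

    if len(pairs) < 3:
        raise InputError(f"only {len(pairs)} usable residue pairs (< 3)")
    return ResiduePairing(pairs=pairs, method=method, identity_pct=ident)


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float  # Angstrom
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
            "n_atoms": self.n_atoms,
        }, indent=2) + "\n")


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares rigid transform mapping ``coords_b`` onto ``coords_a``.

    Returns the proper rotation R and translation t minimizing
    ``sum_i ||R b_i + t - a_i||^2`` and the resulting RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError("coordinate arrays must both have shape (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise InputError("need >= 3 paired points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinear/coincident point sets leave the rotation underdetermined
    if min(np.linalg.svd(a0, compute_uv=False)[1],
           np.linalg.svd(b0, compute_uv=False)[1]) < 1e-8:
        raise DegenerateGeometryError("point set is (near-)collinear")
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ca - rotation @ cb
    residuals = b0 @ rotation.T - a0
    rmsd = float(np.sqrt((residuals ** 2).sum() / n))
    return Superposition(rotation=rotation, translation=translation,
                         rmsd=rmsd, n_atoms=n)


def superpose_models(
    model_a: StructureModel,
    model_b: StructureModel,
    pairing: ResiduePairing | None = None,
    **pairing_kwargs,
) -> tuple[Superposition, ResiduePairing]:
    """Pair residues (if no pairing given) and superpose B's Cα set onto A's."""
    if pairing is None:
        pairing = pair_residues(model_a, model_b, **pairing_kwargs)
    map_a = model_a.residue_map()
    map_b = model_b.residue_map()
    ca_a = np.array([map_a[ka].atom("CA").coord for ka, _ in pairing.pairs])
    ca_b = np.array([map_b[kb].atom("CA").coord for _, kb in pairing.pairs])
    return kabsch_superpose(ca_a, ca_b), pairing
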