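"""Synthetic structures, alignments and ΔΔG matrices with planted ground truth.

The generator builds an idealized α-helical Cα trace (1.5 A rise, 2.3 A
radius, 100° twist per residue) with pseudo-Cβ atoms pointing radially
outward.  Every residue of such a bare helix is solvent-exposed, which is the
intended regime: the pipeline's surface logic is exercised while ground truth
(which residues are mutable) is planted exactly through the synthetic MSA and
ΔΔG matrix.  All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .conservation import Alignment
from .errors import InputError
from .mutability import DdgMatrix
from .structure_model import Atom, Residue, StructureModel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

HELIX_RISE = 1.5  # Angstrom per residue
HELIX_RADIUS = 2.3  # Angstrom
HELIX_TWIST_DEG = 100.0


def ca_chord_length() -> float:
    """Closed-form consecutive Cα-Cα distance of the ideal helix trace."""
    theta = np.radians(HELIX_TWIST_DEG)
    return float(np.sqrt(HELIX_RISE ** 2 + 2 * HELIX_RADIUS ** 2 * (1 - np.cos(theta))))


def synthetic_structure(n_residues: int, seed: int, sequence: str | None = None) -> StructureModel:
    """Ideal helical Cα/pseudo-Cβ model; deterministic per seed."""
    if n_residues < 5:
        raise InputError("need at least 5 residues")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n_residues))
    elif len(sequence) != n_residues:
        raise InputError("sequence length must equal n_residues")
    theta = np.radians(HELIX_TWIST_DEG)
    residues = []
    for i, aa in enumerate(sequence):
        angle = i * theta
        radial = np.array([np.cos(angle), np.sin(angle), 0.0])
        ca = HELIX_RADIUS * radial + np.array([0.0, 0.0, HELIX_RISE * i])
        atoms = [Atom("CA", "C", ca)]
        if aa != "G":
            atoms.append(Atom("CB", "C", ca + 1.5 * radial))
        residues.append(Residue("A", i + 1, "", aa, atoms))
    return StructureModel(entry_id=f"SYN{seed}", chains={"A": residues},
                          resolution=2.0, experimental_method="SYNTHETIC")


def synthetic_msa(
    ref_sequence: str,
    n_seqs: int,
    sub_prob,
    seed: int,
    ref_id: str = "ref",
) -> Alignment:
    """MSA in which each non-reference record mutates column ``j`` with
    probability ``sub_prob[j]`` (scalar broadcast) to a uniform different
    residue.  Expected identity-to-reference conservation at a column is
    100*(1 - sub_prob*(n-1)/n) for n records including the reference.
    """
    if n_seqs < 2:
        raise InputError("need at least 2 sequences")
    length = len(ref_sequence)
    probs = np.broadcast_to(np.asarray(sub_prob, dtype=float), (length,))
    if probs.min() < 0 or probs.max() > 1:
        raise InputError("substitution probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = [(ref_id, ref_sequence)]
    for s in range(1, n_seqs):
        chars = []
        for j, aa in enumerate(ref_sequence):
            if rng.random() < probs[j]:
                options = [c for c in AMINO_ACIDS if c != aa]
                chars.append(options[rng.integers(len(options))])
            else:
                chars.append(aa)
        records.append((f"seq{s}", "".join(chars)))
    return Alignment(records=records, ref_index=0)


def synthetic_ddg(
    sequence: str,
    planted_mutable: set[int],
    seed: int,
    chain_id: str = "A",
) -> DdgMatrix:
    """ΔΔG matrix with planted high-mutability positions (1-based numbers).

    Planted positions get 14-20 of their 20 values below 0.5 kcal/mol
    (mutability score >= 70%); all other positions get at most 8 below
    (score <= 40%).  The self substitution is always exactly 0.
    """
    n = len(sequence)
    for p in planted_mutable:
        if not 1 <= p <= n:
            raise InputError(f"planted position {p} outside 1..{n}")
    rng = np.random.default_rng(seed)
    positions, wt_aa, values = [], {}, {}
    for i, aa in enumerate(sequence, start=1):
        key = (chain_id, i, "")
        others = [a for a in AMINO_ACIDS if a != aa]
        if i in planted_mutable:
            n_below = int(rng.integers(14, 21))  # incl. self
        else:
            n_below = int(rng.integers(1, 9))  # self always counts
        below_others = list(rng.choice(others, size=n_below - 1, replace=False))
        row = {aa: 0.0}
        for a in others:
            if a in below_others:
                row[a] = float(rng.uniform(-1.0, 0.45))
            else:
                row[a] = float(rng.uniform(0.6, 3.0))
        positions.append(key)
        wt_aa[key] = aa
        values[key] = row
    return DdgMatrix(positions=positions, wt_aa=wt_aa, values=values, source="file")


@dataclass
class FixtureSpec:
    seed: int = 1
    n_residues: int = 60
    planted_patch: tuple[int, ...] = tuple(range(20, 30))  # 1-based, contiguous
    n_seqs: int = 50
    planted_sub_prob: float = 0.5
    background_sub_prob: float = 0.0

    def __post_init__(self):
        for p in self.planted_patch:
            if not 1 <= p <= self.n_residues:
                raise InputError("planted patch outside residue range")


def make_fixture(spec: FixtureSpec) -> tuple[StructureModel, Alignment, DdgMatrix]:
    """Structure + MSA + ΔΔG sharing one planted mutable patch."""
    model = synthetic_structure(spec.n_residues, spec.seed)
    seq = model.sequence("A")
    probs = np.full(spec.n_residues, spec.background_sub_prob)
    for p in spec.planted_patch:
        probs[p - 1] = spec.planted_sub_prob
    msa = synthetic_msa(seq, spec.n_seqs, probs, spec.seed + 1)
    ddg = synthetic_ddg(seq, set(spec.planted_patch), spec.seed + 2)
    return model, msa, ddg


def write_fixture_bundle(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write structure.pdb / msa.fasta / ddg.tsv so file readers and the CLI
    are exercised on real files, not only in-memory objects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, msa, ddg = make_fixture(spec)

    from .structure_model import write_annotated_structure

    pdb_path = out / "structure.pdb"
    write_annotated_structure(model, {}, pdb_path)

    msa_path = out / "msa.fasta"
    with msa_path.open("w") as fh:
        for rid, seq in msa.records:
            fh.write(f">{rid}\n{seq}\n")

    ddg_path = out / "ddg.tsv"
    with ddg_path.open("w") as fh:
        fh.write("position\tmutant\tddG\n")
        for key in ddg.positions:
            token = f"{ddg.wt_aa[key]}{key[0]}{key[1]}"
            for a, v in ddg.values[key].items():
                fh.write(f"{token}\t{a}\t{v:.4f}\n")
    return {"structure": pdb_path, "msa": msa_path, "ddg": ddg_path}
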