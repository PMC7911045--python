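"""Structure I/O, molecular weight, solvent accessibility, candidate filtering.

The candidate filter encodes the entry criteria used when screening the PDB for
scaffold candidates: a small (10-25 kDa) monomeric protein with a high-resolution
(<3.0 A) X-ray structure and few cysteines.  Solvent accessibility is computed
with a Shrake-Rupley numerical integration over a deterministic golden-spiral
point lattice, so results are bit-stable across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    MAX_ASA,
    RESIDUE_MASS,
    THREE_TO_ONE,
    VDW_FALLBACK,
    VDW_RADIUS,
    WATER_MASS,
)
from .errors import EmptyModelError, InputError, ParseError

#: (chain_id, author seq_num, insertion_code) — the residue key used everywhere.
ResKey = tuple[str, int, str]


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    is_polymer: bool = True

    def vdw_radius(self) -> float:
        r = VDW_RADIUS.get(self.element.upper())
        if r is None:
            warnings.warn(
                f"unknown element {self.element!r}; using fallback radius {VDW_FALLBACK} A"
            )
            r = VDW_FALLBACK
        return r


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResKey:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    entry_id: str
    chains: dict[str, list[Residue]]
    resolution: float | None = None
    experimental_method: str | None = None
    heterogens: list[str] = field(default_factory=list)  # non-polymer inventory

    def sequence(self, chain_id: str | None = None) -> str:
        residues = self.chains[self._chain(chain_id)]
        return "".join(r.aa for r in residues)

    def _chain(self, chain_id: str | None) -> str:
        if chain_id is None:
            return next(iter(self.chains))
        if chain_id not in self.chains:
            raise InputError(f"no chain {chain_id!r} in model {self.entry_id}")
        return chain_id

    def residues(self, chain_id: str | None = None) -> list[Residue]:
        if chain_id is not None:
            return list(self.chains[self._chain(chain_id)])
        return [r for ch in self.chains.values() for r in ch]

    def residue_map(self) -> dict[ResKey, Residue]:
        return {r.key: r for r in self.residues()}

    def iter_atoms(self, include_hydrogens: bool = False) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                if not include_hydrogens and atom.element.upper() == "H":
                    continue
                yield res, atom

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy of the model with ``x -> R x + t`` applied to every atom."""
        chains = {}
        for cid, residues in self.chains.items():
            chains[cid] = [
                Residue(
                    r.chain_id,
                    r.seq_num,
                    r.insertion_code,
                    r.aa,
                    [
                        Atom(a.name, a.element, rotation @ a.coord + translation,
                             a.occupancy, a.is_polymer)
                        for a in r.atoms
                    ],
                )
                for r in residues
            ]
        return StructureModel(self.entry_id, chains, self.resolution,
                              self.experimental_method, list(self.heterogens))


# ---------------------------------------------------------------------------
# Reading

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only polymer (amino-acid) residues enter the chains; waters, ions and
    ligands are collected into ``heterogens`` so they are never silently
    dropped.  Alternate locations are resolved to the highest-occupancy
    conformer (ties: first in file).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    if format not in _FORMATS:
        raise InputError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path} as {format}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    heterogens: list[str] = []
    for chain in model:
        for res in chain:
            one = THREE_TO_ONE.get(res.name.upper())
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = one is not None or (info is not None and info.is_amino_acid())
            if not is_aa:
                heterogens.append(f"{chain.name}/{res.name}/{res.seqid.num}")
                continue
            atoms = _resolve_altlocs(res)
            residue = Residue(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                insertion_code=(res.seqid.icode or " ").strip(),
                aa=one if one is not None else "X",
                atoms=atoms,
            )
            chains.setdefault(chain.name, []).append(residue)

    chains = {cid: residues for cid, residues in chains.items() if residues}
    if not chains:
        raise EmptyModelError(f"{path}: no polymer residues")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    try:
        method = st.info["_exptl.method"] or None
    except KeyError:
        method = None
    entry_id = st.name or path.stem
    return StructureModel(entry_id, chains, resolution, method, heterogens)


def _resolve_altlocs(res: gemmi.Residue) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties first in file."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for at in res:
        cand = Atom(
            name=at.name,
            element=at.element.name,
            coord=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
            occupancy=at.occ,
        )
        prev = best.get(at.name)
        if prev is None:
            best[at.name] = cand
            order.append(at.name)
        elif cand.occupancy > prev.occupancy:
            best[at.name] = cand
    return [best[n] for n in order]


# ---------------------------------------------------------------------------
# Molecular weight

def molecular_weight(sequence: str) -> float:
    """Average molecular mass of a peptide in kDa (residue masses + one water)."""
    if not sequence:
        raise InputError("empty sequence")
    total = WATER_MASS
    for i, aa in enumerate(sequence):
        mass = RESIDUE_MASS.get(aa)
        if mass is None:
            raise InputError(f"unknown amino acid {aa!r} at position {i + 1}")
        total += mass
    return total / 1000.0


# ---------------------------------------------------------------------------
# Candidate filter

@dataclass
class FilterCriteria:
    """Bounds for the scaffold-candidate filter.

    Molecular-weight bounds are inclusive; the resolution bound is strict
    (a 3.0 A structure fails a "<3.0 A" rule).  The monomer rule requires
    exactly one polymer chain with at least ``min_chain_length`` residues.
    Non-computable curation rules (toxicity, immunogenicity, literature
    solubility) are carried as free-text notes only.
    """

    mw_min_kda: float = 10.0
    mw_max_kda: float = 25.0
    resolution_max: float = 3.0
    min_chain_length: int = 50
    max_cysteines: int = 2
    notes: dict[str, str] = field(default_factory=dict)


@dataclass
class FilterVerdict:
    passed: bool
    reasons: list[str]
    metrics: dict[str, float | int | None]


def candidate_filter(model: StructureModel, criteria: FilterCriteria | None = None) -> FilterVerdict:
    criteria = criteria or FilterCriteria()
    reasons: list[str] = []

    full_sequence = "".join(model.sequence(c) for c in model.chains)
    mw = sum(RESIDUE_MASS.get(aa, 0.0) for aa in full_sequence) / 1000.0 + WATER_MASS / 1000.0
    if not (criteria.mw_min_kda <= mw <= criteria.mw_max_kda):
        reasons.append("molecular_weight")

    if model.resolution is None:
        reasons.append("resolution_unknown")
    elif not (model.resolution < criteria.resolution_max):
        reasons.append("resolution")

    long_chains = [c for c in model.chains if len(model.chains[c]) >= criteria.min_chain_length]
    if not (len(model.chains) == 1 and len(long_chains) == 1):
        reasons.append("monomer")

    n_cys = full_sequence.count("C")
    if n_cys > criteria.max_cysteines:
        reasons.append("cysteine_count")

    metrics: dict[str, float | int | None] = {
        "molecular_weight_kda": round(mw, 4),
        "resolution_angstrom": model.resolution,
        "chain_count": len(model.chains),
        "cysteine_count": n_cys,
    }
    return FilterVerdict(passed=not reasons, reasons=reasons, metrics=metrics)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)

def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere; fully deterministic."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


@dataclass
class SasaResult:
    atom_keys: list[tuple[ResKey, str]]
    atom_areas: np.ndarray  # Angstrom^2, aligned with atom_keys

    def per_residue(self) -> dict[ResKey, float]:
        out: dict[ResKey, float] = {}
        for (key, _name), area in zip(self.atom_keys, self.atom_areas):
            out[key] = out.get(key, 0.0) + float(area)
        return out


def compute_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Shrake-Rupley SASA over a golden-spiral lattice.

    A sphere of radius ``vdw + probe`` is sampled at ``n_points`` per atom; a
    sample point is accessible when it lies outside every neighbour's expanded
    sphere.  Per-atom area is the accessible fraction of ``4 pi (r+p)^2``.
    """
    if n_points < 24:
        raise InputError("n_points must be >= 24")
    pairs = list(model.iter_atoms(include_hydrogens=include_hydrogens))
    if not pairs:
        raise InputError("model has no atoms for SASA")
    centers = np.array([a.coord for _, a in pairs])
    if not np.all(np.isfinite(centers)):
        raise InputError("non-finite atom coordinates")
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        radii = np.array([a.vdw_radius() for _, a in pairs]) + probe_radius

    sphere = golden_spiral_points(n_points)
    tree = cKDTree(centers)
    max_r = radii.max()
    areas = np.empty(len(pairs))
    for i in range(len(pairs)):
        neighbors = [j for j in tree.query_ball_point(centers[i], radii[i] + max_r)
                     if j != i]
        pts = centers[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
    keys = [(res.key, atom.name) for res, atom in pairs]
    return SasaResult(atom_keys=keys, atom_areas=areas)


@dataclass
class ResidueExposure:
    sasa: float
    rsasa: float
    surface: bool


def relative_sasa(
    model: StructureModel,
    residue_sasa: Mapping[ResKey, float],
    surface_threshold: float = 0.25,
) -> dict[ResKey, ResidueExposure]:
    """Normalize per-residue SASA by the residue type's theoretical maximum."""
    mean_max = sum(MAX_ASA.values()) / len(MAX_ASA)
    out: dict[ResKey, ResidueExposure] = {}
    for res in model.residues():
        if res.key not in residue_sasa:
            continue
        max_asa = MAX_ASA.get(res.aa)
        if max_asa is None:
            warnings.warn(
                f"no max-ASA entry for residue type {res.aa!r}; using table mean"
            )
            max_asa = mean_max
        sasa = float(residue_sasa[res.key])
        rel = sasa / max_asa
        out[res.key] = ResidueExposure(sasa=sasa, rsasa=rel,
                                       surface=rel >= surface_threshold)
    return out


# ---------------------------------------------------------------------------
# Writing

def write_annotated_structure(
    model: StructureModel,
    scores: Mapping[ResKey, float],
    path: str | Path,
) -> None:
    """Write a PDB file with per-residue scores in the B-factor column.

    Unscored residues get 0.00; scores outside [0, 999.99] are clipped (with a
    warning) to keep the fixed-width column valid.
    """
    path = Path(path)
    lines: list[str] = []
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model.resolution:5.2f} ANGSTROMS.")
    serial = 1
    three = {v: k for k, v in THREE_TO_ONE.items()}
    for cid, residues in model.chains.items():
        for res in residues:
            raw = float(scores.get(res.key, 0.0))
            b = min(max(raw, 0.0), 999.99)
            if b != raw:
                warnings.warn(
                    f"score {raw} for residue {res.key} clipped to B-factor range [0, 999.99]"
                )
            resname = three.get(res.aa, "UNK")
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{'':1s}{resname:>3s} {cid[:1]}"
                    f"{res.seq_num:4d}{res.insertion_code[:1] or ' ':1s}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{b:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def write_exposure_table(
    model: StructureModel,
    exposure: Mapping[ResKey, ResidueExposure],
    path: str | Path,
) -> None:
    """Tab-separated per-residue accessibility table."""
    rows = ["chain\tseq_num\taa\tsasa\trsasa\tsurface_flag"]
    for res in model.residues():
        if res.key not in exposure:
            continue
        e = exposure[res.key]
        rows.append(
            f"{res.chain_id}\t{res.seq_num}\t{res.aa}\t{e.sasa:.3f}\t{e.rsasa:.4f}"
            f"\t{int(e.surface)}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
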