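"""Detection and completion of mutable surface patches.

Mutable residues that sit close in space form the seed of a patch (connected
components of a residue contact graph built on side-chain representative
atoms).  A patch smaller than the target window for ribosome-display libraries
(10-12 residues) is completed greedily with neighbouring surface residues of
highest mutability; oversized patches are flagged, never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import InputError
from .mutability import ResidueProfile
from .structure_model import ResKey, Residue, StructureModel


def representative_coord(residue: Residue) -> np.ndarray:
    """Cβ position (side-chain direction proxy); Cα for Gly or if Cβ is absent."""
    atom = residue.atom("CB") or residue.atom("CA")
    if atom is None:
        raise InputError(
            f"residue {residue.chain_id}{residue.seq_num}{residue.insertion_code} "
            "has neither CB nor CA"
        )
    return atom.coord


def build_contact_graph(
    model: StructureModel,
    residues: Iterable[ResKey],
    cutoff: float = 8.0,
) -> nx.Graph:
    """Undirected graph with an edge wherever representative atoms are <= cutoff apart."""
    res_map = model.residue_map()
    keys = list(residues)
    for key in keys:
        if key not in res_map:
            raise InputError(f"residue {key} not in model {model.entry_id}")
    graph = nx.Graph()
    coords = {}
    for key in keys:
        coords[key] = representative_coord(res_map[key])
        graph.add_node(key, coord=coords[key])
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if float(np.linalg.norm(coords[a] - coords[b])) <= cutoff:
                graph.add_edge(a, b)
    return graph


@dataclass
class SurfacePatch:
    seed_members: tuple[ResKey, ...]
    completion_members: tuple[ResKey, ...] = ()
    mean_mutability: float = 0.0
    sequence_span: int = 0
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    flags: tuple[str, ...] = ()

    @property
    def members(self) -> tuple[ResKey, ...]:
        return self.seed_members + self.completion_members

    @property
    def size(self) -> int:
        return len(self.members)


def _patch_stats(members: Sequence[ResKey], mutability: Mapping[ResKey, float],
                 coords: Mapping[ResKey, np.ndarray]) -> tuple[float, int, np.ndarray]:
    mean_mut = float(np.mean([mutability.get(k, 0.0) for k in members]))
    nums = [k[1] for k in members]
    span = max(nums) - min(nums) + 1
    centroid = np.mean([coords[k] for k in members], axis=0)
    return mean_mut, span, centroid


def find_patches(graph: nx.Graph, mutability: Mapping[ResKey, float]) -> list[SurfacePatch]:
    """Connected components of the mutable-residue contact graph, ranked.

    Ordering: size descending, mean mutability descending, then smallest
    residue number ascending.  Singletons are kept but flagged.
    """
    coords = {k: graph.nodes[k]["coord"] for k in graph.nodes}
    patches = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        mean_mut, span, centroid = _patch_stats(members, mutability, coords)
        flags = ("singleton",) if len(members) == 1 else ()
        patches.append(SurfacePatch(seed_members=members, mean_mutability=mean_mut,
                                    sequence_span=span, centroid=centroid, flags=flags))
    patches.sort(key=lambda p: (-p.size, -p.mean_mutability,
                                min(k[1] for k in p.members)))
    return patches


def complete_patch(
    patch: SurfacePatch,
    model: StructureModel,
    profiles: Mapping[ResKey, ResidueProfile],
    target_min: int = 10,
    target_max: int = 12,
    cutoff: float = 8.0,
) -> SurfacePatch:
    """Grow an undersized patch with neighbouring surface residues.

    While the patch is below ``target_min``, the eligible neighbour (a surface
    residue within ``cutoff`` of any current member) with the highest mutability
    is added; ties break to lower conservation, then lower residue number.
    Patches already within [target_min, target_max] are returned unchanged;
    larger ones are only flagged "oversized".
    """
    if patch.size > target_max:
        return replace(patch, flags=patch.flags + ("oversized",))
    if patch.size >= target_min:
        return patch

    res_map = model.residue_map()
    coords = {k: representative_coord(res_map[k]) for k in res_map}
    members: list[ResKey] = list(patch.members)
    added: list[ResKey] = []
    flags = tuple(f for f in patch.flags)

    while len(members) < target_min:
        member_xyz = np.array([coords[k] for k in members])
        candidates = []
        for key, p in profiles.items():
            if key in members or not p.surface or p.mutability is None:
                continue
            if key not in coords:
                continue
            dmin = float(np.min(np.linalg.norm(member_xyz - coords[key], axis=1)))
            if dmin <= cutoff:
                cons = p.conservation if p.conservation is not None else 100.0
                candidates.append((-p.mutability, cons, key[1], key))
        if not candidates:
            flags = flags + ("undersized",)
            break
        candidates.sort()
        chosen = candidates[0][3]
        members.append(chosen)
        added.append(chosen)

    mutability = {k: (profiles[k].mutability or 0.0) for k in members if k in profiles}
    mean_mut, span, centroid = _patch_stats(members, mutability, coords)
    return SurfacePatch(
        seed_members=patch.seed_members,
        completion_members=tuple(added),
        mean_mutability=mean_mut,
        sequence_span=span,
        centroid=centroid,
        flags=flags,
    )


@dataclass
class IndependenceRecord:
    patch_a: int
    patch_b: int
    disjoint: bool
    min_distance: float
    independent: bool


def patch_independence(
    patches: Sequence[SurfacePatch],
    model: StructureModel,
    min_separation: float = 8.0,
) -> list[IndependenceRecord]:
    """Pairwise independence: disjoint member sets AND min distance > separation."""
    if len(patches) < 2:
        raise InputError("need at least 2 patches for an independence report")
    res_map = model.residue_map()
    coords = {k: representative_coord(res_map[k]) for k in res_map}
    records = []
    for i in range(len(patches)):
        for j in range(i + 1, len(patches)):
            a, b = patches[i], patches[j]
            disjoint = not (set(a.members) & set(b.members))
            dmin = min(
                float(np.linalg.norm(coords[ka] - coords[kb]))
                for ka in a.members for kb in b.members
            )
            records.append(IndependenceRecord(
                patch_a=i, patch_b=j, disjoint=disjoint, min_distance=dmin,
                independent=disjoint and dmin > min_separation,
            ))
    return records


def write_patch_report(patches: Sequence[SurfacePatch],
                       profiles: Mapping[ResKey, ResidueProfile],
                       path: str | Path) -> None:
    rows = ["patch_id\tchain\tseq_num\taa\trole\tmutability_pct\tmean_mutability"
            "\tsequence_span\tflags"]
    for pid, patch in enumerate(patches, start=1):
        for key in patch.members:
            role = "seed" if key in patch.seed_members else "completion"
            p = profiles.get(key)
            mut = f"{p.mutability:.1f}" if p and p.mutability is not None else "NA"
            rows.append(f"{pid}\t{key[0]}\t{key[1]}\t{p.aa if p else 'X'}\t{role}"
                        f"\t{mut}\t{patch.mean_mutability:.1f}"
                        f"\t{patch.sequence_span}\t{','.join(patch.flags) or '-'}")
    Path(path).write_text("\n".join(rows) + "\n")


def selection_string(patch: SurfacePatch) -> str:
    """Residue selection text for molecular viewers (chain:number list)."""
    return "+".join(f"{k[0]}:{k[1]}" for k in patch.members)
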