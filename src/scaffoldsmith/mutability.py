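"""Saturation-mutagenesis ΔΔG handling and the per-position mutability score.

A position's mutability is the percentage of the 20 standard substitutions
(self included, with ΔΔG = 0) whose predicted folding free-energy change is
below a tolerance threshold, 0.5 kcal/mol by default: stabilizing mutations
(ΔΔG < 0) and slightly destabilizing ones both qualify, so the single strict
inequality ΔΔG < threshold covers both stated cases.  Scores are therefore
always multiples of 5 in [0, 100].

ΔΔG values normally come from force-field "positionscan" output files; a
documented burial-x-Grantham surrogate is provided so the full pipeline can be
exercised without external software, and its output is labelled
``source="surrogate"`` so it can never be mistaken for force-field results.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .constants import AMINO_ACIDS, GRANTHAM
from .errors import FormatError, InputError
from .structure_model import ResKey, ResidueExposure, StructureModel

SELF_DDG_WARN = 0.01  # kcal/mol; warn if a file's self-substitution exceeds this


@dataclass
class DdgMatrix:
    """L x 20 table of folding free-energy changes (kcal/mol)."""

    positions: list[ResKey]
    wt_aa: dict[ResKey, str]
    values: dict[ResKey, dict[str, float]]
    source: str = "file"  # "file" or "surrogate"

    def row(self, key: ResKey) -> dict[str, float]:
        return self.values[key]


_TOKEN_RE = re.compile(r"^([A-Z])([A-Za-z0-9])(-?\d+)([A-Z])?$")


def read_positionscan(path: str | Path) -> DdgMatrix:
    """Read a tab-separated positionscan file.

    Dialect (one header line, then one row per substitution), either::

        GA131<TAB>W<TAB>0.234        # wt G, chain A, residue 131, mutant W
        GA131W<TAB>0.234             # two-column variant, mutant in the token

    Every position must have all 20 mutants; duplicates resolve last-wins with
    a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    values: dict[ResKey, dict[str, float]] = {}
    wt_aa: dict[ResKey, str] = {}
    order: list[ResKey] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 3:
            token, mutant, ddg_text = parts
        elif len(parts) == 2:
            token, ddg_text = parts
            mutant = None
        else:
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
        m = _TOKEN_RE.match(token.strip())
        if not m:
            raise FormatError(f"{path}:{lineno}: malformed position token {token!r}")
        wt, chain, num, token_mut = m.groups()
        if mutant is None:
            mutant = token_mut
        if not mutant or mutant.upper() not in AMINO_ACIDS:
            raise FormatError(f"{path}:{lineno}: missing or invalid mutant residue")
        mutant = mutant.upper()
        try:
            ddg = float(ddg_text)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric ddG {ddg_text!r}") from exc
        key: ResKey = (chain, int(num), "")
        if key not in values:
            values[key] = {}
            wt_aa[key] = wt.upper()
            order.append(key)
        if mutant in values[key]:
            warnings.warn(f"{path}:{lineno}: duplicate row for {token} -> {mutant}; "
                          "last value wins")
        values[key][mutant] = ddg

    missing = {
        key: sorted(set(AMINO_ACIDS) - set(row))
        for key, row in values.items()
        if len(row) != 20
    }
    if missing:
        detail = "; ".join(
            f"{wt_aa[k]}{k[0]}{k[1]} missing {','.join(aas)}" for k, aas in missing.items()
        )
        raise FormatError(f"{path}: incomplete positions: {detail}")
    if not values:
        raise FormatError(f"{path}: no data rows")
    for key, row in values.items():
        self_ddg = row[wt_aa[key]]
        if abs(self_ddg) > SELF_DDG_WARN:
            warnings.warn(
                f"{path}: self-substitution ddG {self_ddg:+.3f} kcal/mol at "
                f"{wt_aa[key]}{key[0]}{key[1]} (expected 0)"
            )
    return DdgMatrix(positions=order, wt_aa=wt_aa, values=values, source="file")


def mutability_score(row: Mapping[str, float] | Sequence[float], threshold: float = 0.5) -> float:
    """Percentage of the 20 substitutions with ΔΔG strictly below ``threshold``."""
    vals = list(row.values()) if isinstance(row, Mapping) else list(row)
    if len(vals) != 20:
        raise InputError(f"expected 20 ddG values, got {len(vals)}")
    if any(isinstance(v, float) and math.isnan(v) for v in vals):
        raise InputError("NaN among ddG values")
    return 100.0 * sum(1 for v in vals if v < threshold) / 20.0


@dataclass
class MutabilityProfile:
    values: dict[ResKey, float]
    threshold: float
    source: str


def mutability_profile(matrix: DdgMatrix, threshold: float = 0.5) -> MutabilityProfile:
    values = {key: mutability_score(matrix.values[key], threshold)
              for key in matrix.positions}
    return MutabilityProfile(values=values, threshold=threshold, source=matrix.source)


def surrogate_ddg(
    model: StructureModel,
    exposure: Mapping[ResKey, ResidueExposure],
    scale: float = 1.0,
) -> DdgMatrix:
    """Burial-weighted Grantham-distance surrogate for saturation mutagenesis.

    ΔΔG(i -> a) = scale * (1 - min(rSASA_i, 1)) * D(wt_i, a) / 100 where D is
    the Grantham distance; self substitutions are exactly 0 and fully exposed
    residues score 0 for every substitution.  This is a testing surrogate with
    the right qualitative shape (buried, chemically distant substitutions are
    penalized), not a stability predictor.
    """
    positions: list[ResKey] = []
    wt_aa: dict[ResKey, str] = {}
    values: dict[ResKey, dict[str, float]] = {}
    for res in model.residues():
        if res.key not in exposure or res.aa not in AMINO_ACIDS:
            continue
        burial = 1.0 - min(exposure[res.key].rsasa, 1.0)
        row = {a: scale * burial * GRANTHAM[(res.aa, a)] / 100.0 for a in AMINO_ACIDS}
        positions.append(res.key)
        wt_aa[res.key] = res.aa
        values[res.key] = row
    if not positions:
        raise InputError("no residues with exposure data for surrogate ddG")
    return DdgMatrix(positions=positions, wt_aa=wt_aa, values=values, source="surrogate")


@dataclass
class ResidueProfile:
    """Merged per-residue record feeding patch detection."""

    key: ResKey
    aa: str
    conservation: float | None = None  # %
    mutability: float | None = None  # %
    rsasa: float | None = None
    surface: bool = False

    @property
    def mutable_inputs_complete(self) -> bool:
        return self.conservation is not None and self.mutability is not None


def build_residue_profiles(
    model: StructureModel,
    conservation: Mapping[ResKey, float],
    mutability: Mapping[ResKey, float],
    exposure: Mapping[ResKey, ResidueExposure],
) -> dict[ResKey, ResidueProfile]:
    profiles: dict[ResKey, ResidueProfile] = {}
    for res in model.residues():
        exp = exposure.get(res.key)
        profiles[res.key] = ResidueProfile(
            key=res.key,
            aa=res.aa,
            conservation=conservation.get(res.key),
            mutability=mutability.get(res.key),
            rsasa=exp.rsasa if exp else None,
            surface=exp.surface if exp else False,
        )
    return profiles


@dataclass
class SelectionResult:
    selected: set[ResKey]
    excluded_missing: list[tuple[ResKey, str]]  # (key, which score is missing)


def select_mutable(
    profiles: Mapping[ResKey, ResidueProfile],
    cons_max: float = 90.0,
    mut_min: float = 50.0,
    require_surface: bool = True,
) -> SelectionResult:
    """Residues with conservation < cons_max AND mutability > mut_min.

    Both inequalities are strict ("<90%", ">50%").  Residues missing either
    score are excluded and reported, never silently dropped.
    """
    selected: set[ResKey] = set()
    missing: list[tuple[ResKey, str]] = []
    for key, p in profiles.items():
        gaps = []
        if p.conservation is None:
            gaps.append("conservation")
        if p.mutability is None:
            gaps.append("mutability")
        if gaps:
            missing.append((key, "+".join(gaps)))
            continue
        if p.conservation < cons_max and p.mutability > mut_min and (
            p.surface or not require_surface
        ):
            selected.add(key)
    return SelectionResult(selected=selected, excluded_missing=sorted(missing))


def write_mutability_table(profile: MutabilityProfile, matrix: DdgMatrix,
                           path: str | Path) -> None:
    rows = ["chain\tseq_num\twt_aa\tscore_pct\tn_below_threshold"]
    for key in matrix.positions:
        score = profile.values[key]
        rows.append(f"{key[0]}\t{key[1]}\t{matrix.wt_aa[key]}\t{score:.1f}"
                    f"\t{round(score / 5)}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_profile_table(profiles: Mapping[ResKey, ResidueProfile], path: str | Path) -> None:
    def fmt(v):
        return "NA" if v is None else f"{v:.2f}"

    rows = ["chain\tseq_num\taa\tconservation_pct\tmutability_pct\trsasa\tsurface_flag"]
    for key in sorted(profiles):
        p = profiles[key]
        rows.append(f"{key[0]}\t{key[1]}\t{p.aa}\t{fmt(p.conservation)}"
                    f"\t{fmt(p.mutability)}\t{fmt(p.rsasa)}\t{int(p.surface)}")
    Path(path).write_text("\n".join(rows) + "\n")
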