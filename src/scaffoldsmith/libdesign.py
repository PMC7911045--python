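"""Degenerate-codon (NNK) library design and ribosome-display cassette assembly.

NNK (N = A/C/G/T, K = G/T) expands to 32 codons covering all 20 amino acids
with a single stop (TAG), which is why it is the standard choice for
saturation libraries: randomizing 10 positions yields 20^10 ≈ 1.02e13 distinct
stop-free protein variants, comfortably above the ~1e12 complexity a ribosome
display selection can sample.  All diversity arithmetic is exact integer math.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .constants import IUPAC_NT, PREFERRED_CODON
from .errors import AssemblyError, InputError


@dataclass(frozen=True)
class DegenerateCodon:
    symbols: str  # 3 IUPAC nucleotide codes

    def __post_init__(self):
        if len(self.symbols) != 3:
            raise InputError(f"codon needs 3 symbols, got {self.symbols!r}")
        for s in self.symbols.upper():
            if s not in IUPAC_NT:
                raise InputError(f"invalid IUPAC nucleotide symbol {s!r}")
        object.__setattr__(self, "symbols", self.symbols.upper())

    @property
    def expansion(self) -> tuple[str, ...]:
        """All concrete codons, in deterministic lexicographic-by-symbol order."""
        sets = [IUPAC_NT[s] for s in self.symbols]
        return tuple("".join(p) for p in itertools.product(*sets))


NNK = DegenerateCodon("NNK")


def expand_degenerate_codon(codon: DegenerateCodon | str) -> set[str]:
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    return set(codon.expansion)


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def encoded_amino_acids(codon: DegenerateCodon | str) -> tuple[Counter, int]:
    """Per-amino-acid codon counts and the stop-codon count of an expansion."""
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    counts: Counter = Counter()
    stops = 0
    for concrete in codon.expansion:
        aa = translate_codon(concrete)
        if aa == "*":
            stops += 1
        else:
            counts[aa] += 1
    return counts, stops


@dataclass
class LibraryDesign:
    scaffold_protein: str
    randomized_positions: tuple[int, ...]  # 1-based protein positions
    codons: dict[int, DegenerateCodon] = field(default_factory=dict)

    def __post_init__(self):
        self.randomized_positions = tuple(self.randomized_positions)
        n = len(self.scaffold_protein)
        if len(set(self.randomized_positions)) != len(self.randomized_positions):
            raise InputError("randomized positions must be unique")
        for pos in self.randomized_positions:
            if not 1 <= pos <= n:
                raise InputError(f"position {pos} outside scaffold length {n}")
            self.codons.setdefault(pos, NNK)

    def codon_at(self, pos: int) -> DegenerateCodon:
        return self.codons[pos]


def library_diversity(design: LibraryDesign) -> dict:
    """Exact DNA/protein diversity and the stop-free fraction of the library.

    Protein diversity counts stop-free sequences only — a clone carrying a
    stop codon is not a displayable library member.
    """
    if not design.randomized_positions:
        raise InputError("design has no randomized positions")
    dna = 1
    protein = 1
    stop_free = Fraction(1)
    for pos in design.randomized_positions:
        codon = design.codon_at(pos)
        expansion = codon.expansion
        counts, stops = encoded_amino_acids(codon)
        dna *= len(expansion)
        protein *= len(counts)
        stop_free *= Fraction(len(expansion) - stops, len(expansion))
    return {
        "dna_diversity": dna,
        "protein_diversity": protein,
        "stop_free_fraction": stop_free,
    }


# ---------------------------------------------------------------------------
# Back-translation and cassette assembly

def back_translate(protein: str, codon_table: Mapping[str, str] | None = None) -> str:
    table = codon_table or PREFERRED_CODON
    try:
        return "".join(table[aa] for aa in protein)
    except KeyError as exc:
        raise InputError(f"cannot back-translate residue {exc.args[0]!r}") from exc


# Representative element sequences for a ribosome-display cassette.  These are
# generic stand-ins assembled from public consensus parts (T7 promoter, a small
# synthetic hairpin, a canonical RBS, Strep-tag II, c-Myc tag, a fragment of the
# E. coli TolA helical spacer) — NOT any vendor's or lab's proprietary construct.
# Users supply their own sequences through CassetteConfig for real designs.
STREP_TAG_II = "WSHPQFEK"
C_MYC_TAG = "EQKLISEEDL"
TOLA_SPACER = (
    "AEKQAEAAAAAARAQAEAKAKAEAEAARKAAEEAAKQAELAAKKAAADAKKKAEAEAAKAAAEAQKKAEAAAAKAAAE"
)


@dataclass
class CassetteConfig:
    t7_promoter: str = "TAATACGACTCACTATAGGG"
    stem_loop_5p: str = "GGGAGACCGGCCTAGGCCGGTCTCCC"
    rbs: str = "TTAACTTTAAGAAGGAGATATACAT"
    strep_tag: str = STREP_TAG_II  # protein
    c_myc_tag: str = C_MYC_TAG  # protein
    tola_spacer: str = TOLA_SPACER  # protein
    stem_loop_3p: str = "GGGCGCAGTAGCGGCCGCTACTGCGCCC"
    codon_table: Mapping[str, str] | None = None
    # optional explicit DNA for the coding elements (overrides back-translation)
    strep_tag_dna: str | None = None
    c_myc_tag_dna: str | None = None
    tola_spacer_dna: str | None = None


@dataclass
class CassetteElement:
    name: str
    start: int  # 1-based inclusive, on the full cassette
    end: int
    sequence: str


@dataclass
class CassetteLayout:
    elements: list[CassetteElement]
    library_dna: str  # degenerate symbols at randomized positions
    wildtype_dna: str  # concrete back-translation of the parent scaffold
    orf_start: int  # 1-based position of the ATG
    orf_end: int


def assemble_cassette(design: LibraryDesign, config: CassetteConfig | None = None) -> CassetteLayout:
    """Assemble the ribosome-display cassette around the scaffold library ORF.

    Element order: T7 promoter, 5' stem-loop, RBS, (ATG + Strep-tag), scaffold
    ORF, c-Myc tag, TolA spacer, 3' stem-loop.  The tagged ORF must translate
    without internal stops for the wild-type scaffold and the cassette carries
    no stop codon at its end, as ribosome display requires.
    """
    config = config or CassetteConfig()
    table = config.codon_table or PREFERRED_CODON

    def bt(name: str, protein: str, dna_override: str | None) -> str:
        if dna_override is not None:
            dna = dna_override.upper()
            if len(dna) % 3:
                raise AssemblyError(f"element {name!r} DNA length not a multiple of 3")
        else:
            dna = back_translate(protein, table)
        if "*" in str(Seq(dna).translate()):
            raise AssemblyError(f"element {name!r} contains an in-frame stop codon")
        return dna

    strep_dna = bt("strep_tag", config.strep_tag, config.strep_tag_dna)
    cmyc_dna = bt("c_myc_tag", config.c_myc_tag, config.c_myc_tag_dna)
    tola_dna = bt("tolA_spacer", config.tola_spacer, config.tola_spacer_dna)

    wt_orf_dna = back_translate(design.scaffold_protein, table)
    lib_codons = []
    for i, aa in enumerate(design.scaffold_protein, start=1):
        if i in design.randomized_positions:
            lib_codons.append(design.codon_at(i).symbols)
        else:
            lib_codons.append(table[aa])
    lib_orf_dna = "".join(lib_codons)

    if str(Seq(wt_orf_dna).translate()) != design.scaffold_protein:
        raise AssemblyError("back-translated scaffold does not round-trip")

    def build(scaffold_dna: str) -> tuple[str, list[CassetteElement], int, int]:
        parts = [
            ("t7_promoter", config.t7_promoter),
            ("stem_loop_5p", config.stem_loop_5p),
            ("rbs", config.rbs),
            ("strep_tag", "ATG" + strep_dna),
            ("orf", scaffold_dna),
            ("c_myc_tag", cmyc_dna),
            ("tolA_spacer", tola_dna),
            ("stem_loop_3p", config.stem_loop_3p),
        ]
        elements = []
        pos = 0
        orf_start = orf_end = 0
        for name, seq in parts:
            elements.append(CassetteElement(name, pos + 1, pos + len(seq), seq))
            if name == "strep_tag":
                orf_start = pos + 1
            if name == "tolA_spacer":
                orf_end = pos + len(seq)
            pos += len(seq)
        return "".join(seq for _, seq in parts), elements, orf_start, orf_end

    wt_full, elements, orf_start, orf_end = build(wt_orf_dna)
    lib_full, _, _, _ = build(lib_orf_dna)

    orf_protein = str(Seq(wt_full[orf_start - 1:orf_end]).translate())
    if "*" in orf_protein:
        offender = _stop_element(elements, orf_start, wt_full, orf_protein)
        raise AssemblyError(f"in-frame stop codon inside element {offender!r}")
    return CassetteLayout(elements=elements, library_dna=lib_full,
                          wildtype_dna=wt_full, orf_start=orf_start, orf_end=orf_end)


def _stop_element(elements: Sequence[CassetteElement], orf_start: int,
                  full: str, orf_protein: str) -> str:
    idx = orf_protein.index("*")
    nt_pos = orf_start + 3 * idx  # 1-based position of the stop codon
    for el in elements:
        if el.start <= nt_pos <= el.end:
            return el.name
    return "?"


def write_cassette_annotation(layout: CassetteLayout, path: str | Path) -> None:
    """GenBank-style flat feature table (1-based inclusive coordinates)."""
    rows = [f"# cassette length {len(layout.wildtype_dna)} nt; "
            f"ORF {layout.orf_start}..{layout.orf_end}"]
    for el in layout.elements:
        rows.append(f"{el.name}\t{el.start}..{el.end}")
    rows.append("")
    rows.append(layout.library_dna)
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Sampling

def sample_variants(
    design: LibraryDesign,
    n: int,
    seed: int,
    exclude_stops: bool = True,
    error_rate: float = 0.0,
) -> tuple[list[str], list[str]]:
    """Draw ``n`` i.i.d. library members; returns (protein_seqs, orf_dna_seqs).

    Each randomized position is drawn uniformly over its codon expansion;
    with ``exclude_stops`` stop-carrying draws are rejected and redrawn.
    ``error_rate`` is an optional per-position chance of a random synthesis
    error (a uniform concrete codon regardless of the design).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    table = PREFERRED_CODON
    base_codons = [table[aa] for aa in design.scaffold_protein]
    all_codons = DegenerateCodon("NNN").expansion
    proteins, dnas = [], []
    for _ in range(n):
        codons = list(base_codons)
        for pos in design.randomized_positions:
            expansion = design.codon_at(pos).expansion
            while True:
                codon = expansion[rng.integers(len(expansion))]
                if error_rate > 0 and rng.random() < error_rate:
                    codon = all_codons[rng.integers(len(all_codons))]
                if exclude_stops and translate_codon(codon) == "*":
                    continue
                break
            codons[pos - 1] = codon
        dna = "".join(codons)
        proteins.append(str(Seq(dna).translate()))
        dnas.append(dna)
    return proteins, dnas


def write_design_json(design: LibraryDesign, path: str | Path) -> None:
    div = library_diversity(design)
    payload = {
        "scaffold_protein": design.scaffold_protein,
        "randomized_positions": list(design.randomized_positions),
        "codon_per_position": {str(p): design.codon_at(p).symbols
                               for p in design.randomized_positions},
        "dna_diversity": div["dna_diversity"],
        "protein_diversity": div["protein_diversity"],
        "stop_free_fraction": float(div["stop_free_fraction"]),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    lines = []
    for name, seq in records:
        lines.append(f">{name}")
        lines.extend(seq[i:i + 70] for i in range(0, len(seq), 70))
    Path(path).write_text("\n".join(lines) + "\n")
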