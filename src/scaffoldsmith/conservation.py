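"""Per-position conservation from a multiple sequence alignment.

The conservation statistic is identity-to-reference: for each alignment column
in which the reference (scaffold) sequence has a residue, the percentage of
records (reference included) carrying the same residue.  Gaps and 'X' in other
records count as mismatches; columns where the reference is gapped produce no
entry.  This matches a selection gate phrased as "identity conservation <90%";
column entropy is deliberately not the default statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import AlignIO

from .errors import InputError, MappingError, ParseError
from .structure_model import ResKey, StructureModel

_VALID = set("ACDEFGHIKLMNPQRSTVWY-X")


@dataclass
class Alignment:
    records: list[tuple[str, str]]  # (id, aligned sequence)
    ref_index: int = 0

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def ref_id(self) -> str:
        return self.records[self.ref_index][0]

    @property
    def ref_sequence(self) -> str:
        """Ungapped reference sequence."""
        return self.records[self.ref_index][1].replace("-", "")


def read_alignment(path: str | Path, format: str = "fasta", ref_id: str | None = None) -> Alignment:
    """Read an aligned FASTA or Clustal file; the alignment must not be ragged."""
    if format not in ("fasta", "clustal"):
        raise InputError(f"unknown alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"cannot read {path} as {format}: {exc}") from exc
    records = []
    for rec in msa:
        seq = str(rec.seq).upper().replace(".", "-")
        seq = "".join(c if c in _VALID else "X" for c in seq)
        records.append((rec.id, seq))
    if len(records) < 2:
        raise InputError(f"{path}: need >= 2 aligned records, got {len(records)}")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ParseError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    ref_index = 0
    if ref_id is not None:
        ids = [i for i, _ in records]
        if ref_id not in ids:
            raise InputError(f"reference id {ref_id!r} not in alignment")
        ref_index = ids.index(ref_id)
    return Alignment(records=records, ref_index=ref_index)


def dedupe(aln: Alignment) -> Alignment:
    """Drop records whose aligned string duplicates an earlier one.

    The reference record is always kept; any other record identical to it is
    removed even if it appears first in the file.
    """
    ref_id, ref_seq = aln.records[aln.ref_index]
    seen = {ref_seq}
    kept: list[tuple[str, str]] = []
    for i, (rid, seq) in enumerate(aln.records):
        if i == aln.ref_index:
            kept.append((rid, seq))
            continue
        if seq in seen:
            continue
        seen.add(seq)
        kept.append((rid, seq))
    new_ref = next(i for i, (rid, s) in enumerate(kept)
                   if rid == ref_id and s == ref_seq)
    return Alignment(records=kept, ref_index=new_ref)


@dataclass
class ConservationProfile:
    values: dict[int, float]  # 1-based reference position -> identity %
    ref_aa: dict[int, str] = field(default_factory=dict)
    n_sequences: int = 0
    ref_sequence: str = ""


def column_conservation(aln: Alignment) -> ConservationProfile:
    """Identity-to-reference percentage per non-gap reference position."""
    ref_seq = aln.records[aln.ref_index][1]
    n = aln.n_sequences
    values: dict[int, float] = {}
    ref_aa: dict[int, str] = {}
    pos = 0
    for col, ref_char in enumerate(ref_seq):
        if ref_char == "-":
            continue
        pos += 1
        if ref_char == "X":
            # 'X' matches nothing, not even itself
            values[pos] = 0.0
        else:
            count = sum(1 for _, s in aln.records if s[col] == ref_char)
            values[pos] = 100.0 * count / n
        ref_aa[pos] = ref_char
    return ConservationProfile(values=values, ref_aa=ref_aa, n_sequences=n,
                               ref_sequence=ref_seq.replace("-", ""))


@dataclass
class MappingResult:
    values: dict[ResKey, float]
    identity_pct: float
    n_aligned: int


def _global_align(seq_a: str, seq_b: str):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner.align(seq_a, seq_b)[0]


def map_to_structure(
    profile: ConservationProfile,
    model: StructureModel,
    chain_id: str | None = None,
    min_identity_pct: float = 50.0,
) -> MappingResult:
    """Transfer conservation onto structure residues via global alignment.

    The profile's reference sequence is aligned (Needleman-Wunsch, BLOSUM62,
    affine gaps) to the structure chain's sequence; conservation values flow
    through aligned pairs.  Structure residues without an aligned reference
    position stay unscored.
    """
    struct_seq = model.sequence(chain_id)
    residues = model.residues(chain_id if chain_id is not None
                              else next(iter(model.chains)))
    if not profile.ref_sequence:
        raise InputError("conservation profile has no reference sequence")
    alignment = _global_align(profile.ref_sequence, struct_seq)
    ref_idx, struct_idx = alignment.aligned  # blocks of aligned ranges
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(ref_idx, struct_idx):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    if not pairs:
        raise MappingError("no aligned positions between reference and structure")
    matches = sum(1 for a, b in pairs if profile.ref_sequence[a] == struct_seq[b])
    identity = 100.0 * matches / len(pairs)
    if identity < min_identity_pct:
        raise MappingError(
            f"reference/structure alignment identity {identity:.1f}% is below "
            f"{min_identity_pct:.0f}% — is this the right MSA for this structure?"
        )
    values: dict[ResKey, float] = {}
    for a, b in pairs:
        pos = a + 1  # profile positions are 1-based over the ungapped reference
        if pos in profile.values:
            values[residues[b].key] = profile.values[pos]
    return MappingResult(values=values, identity_pct=identity, n_aligned=len(pairs))


def write_conservation_table(profile: ConservationProfile, path: str | Path) -> None:
    rows = ["position\tref_aa\tconservation_pct\tn_seqs"]
    for pos in sorted(profile.values):
        rows.append(f"{pos}\t{profile.ref_aa.get(pos, 'X')}"
                    f"\t{profile.values[pos]:.2f}\t{profile.n_sequences}")
    Path(path).write_text("\n".join(rows) + "\n")
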