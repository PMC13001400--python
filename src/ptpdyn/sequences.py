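"""Sequence identity and residue correspondence between PTPs.

Identity is reported the way common aligners report it: identical columns over
alignment length, where terminal gap columns are excluded and internal gap
columns count as mismatches (both conventions configurable).  For exact
reproduction of an external aligner's number, its alignment can be supplied
verbatim (``given_alignment``); otherwise an internal global aligner
(BLOSUM62, affine gaps, open 10 / extend 0.5) is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import biotite.sequence as bioseq
import biotite.sequence.align as bioalign
import biotite.sequence.io.fasta as fasta

_MATRIX = bioalign.SubstitutionMatrix.std_protein_matrix()  # BLOSUM62

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZUO")


@dataclass
class AlignmentMap:
    """One-to-one residue correspondence between two proteins.

    ``pairs`` holds (residue id in A, residue id in B) for every alignment
    column where both sequences are non-gap, ordered by A.  Residue ids are
    sequence positions offset by the per-protein start id (author numbering).
    """

    pairs: list[tuple[int, int]]
    coverage: float
    id_a: str = "A"
    id_b: str = "B"

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("alignment map must be one-to-one")
        if a_side != sorted(a_side):
            raise ValueError("pairs must be ordered by the A residue id")

    def a_to_b(self) -> dict[int, int]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[int, int]:
        return {b: a for a, b in self.pairs}

    def reversed(self) -> "AlignmentMap":
        pairs = sorted(((b, a) for a, b in self.pairs))
        cov = self.coverage  # coverage is defined w.r.t. A; keep as metadata
        return AlignmentMap(pairs, cov, self.id_b, self.id_a)

    @classmethod
    def identity(cls, residue_ids) -> "AlignmentMap":
        pairs = [(int(r), int(r)) for r in residue_ids]
        return cls(pairs, 1.0)


def _validate_sequence(seq: str, label: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError(f"sequence {label} is empty")
    bad = set(seq.replace("-", "")) - AA_ALPHABET
    if bad:
        raise ValueError(f"sequence {label} contains non-amino-acid symbols: {sorted(bad)}")
    return seq


def _align_global(seq_a: str, seq_b: str, gap_open: float = 10.0, gap_extend: float = 0.5):
    sa = bioseq.ProteinSequence(seq_a.replace("X", "X"))
    sb = bioseq.ProteinSequence(seq_b)
    ali = bioalign.align_optimal(
        sa, sb, _MATRIX, gap_penalty=(-abs(gap_open), -abs(gap_extend)), terminal_penalty=False
    )[0]
    ga, gb = bioalign.get_symbols(ali)
    to_char = lambda col: "".join("-" if s is None else str(s) for s in col)
    return to_char(ga), to_char(gb)


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    mode: str = "global_alignment",
    *,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    exclude_terminal_gaps: bool = True,
    internal_gaps_as_mismatch: bool = True,
) -> float:
    """Percent sequence identity between two protein sequences.

    Parameters
    ----------
    mode : {'global_alignment', 'given_alignment'}
        In ``given_alignment`` mode the inputs are pre-aligned rows (equal
        length, ``-`` for gaps) and are used verbatim; in ``global_alignment``
        mode they are raw sequences aligned internally.

    Returns
    -------
    float
        100 * identical columns / counted columns, where terminal gap columns
        are excluded and internal gap columns count in the denominator (both
        behaviors configurable).
    """
    seq_a = _validate_sequence(seq_a, "A")
    seq_b = _validate_sequence(seq_b, "B")
    if mode == "given_alignment":
        if len(seq_a) != len(seq_b):
            raise ValueError(
                f"given alignment rows differ in length ({len(seq_a)} vs {len(seq_b)})"
            )
        row_a, row_b = seq_a, seq_b
    elif mode == "global_alignment":
        row_a, row_b = _align_global(
            seq_a.replace("-", ""), seq_b.replace("-", ""), gap_open, gap_extend
        )
    else:
        raise ValueError(f"unknown identity mode {mode!r}")

    n_cols = len(row_a)
    start, stop = 0, n_cols
    if exclude_terminal_gaps:
        # terminal gap run: leading/trailing columns where either row is gapped
        start = 0
        while start < n_cols and (row_a[start] == "-" or row_b[start] == "-"):
            start += 1
        stop = n_cols
        while stop > start and (row_a[stop - 1] == "-" or row_b[stop - 1] == "-"):
            stop -= 1
    identical = 0
    counted = 0
    for i in range(start, stop):
        a, b = row_a[i], row_b[i]
        if a == "-" or b == "-":
            if internal_gaps_as_mismatch:
                counted += 1
            continue
        counted += 1
        if a == b:
            identical += 1
    if counted == 0:
        raise ValueError("no aligned columns to compare")
    return 100.0 * identical / counted


def read_fasta(path) -> dict[str, str]:
    """Read a (plain or aligned) FASTA file into an ordered id -> sequence dict."""
    f = fasta.FastaFile.read(str(path))
    return {header.split()[0]: str(seq).upper() for header, seq in f.items()}


def write_fasta(path, sequences: dict[str, str]) -> None:
    f = fasta.FastaFile()
    for name, seq in sequences.items():
        f[name] = seq
    f.write(str(path))


def build_alignment_map(
    alignment: dict[str, str] | str,
    id_a: str,
    id_b: str,
    start_a: int = 1,
    start_b: int = 1,
) -> AlignmentMap:
    """Residue correspondence from an aligned FASTA.

    Parameters
    ----------
    alignment : dict or path
        Aligned sequences (equal length, ``-`` gaps) keyed by id, or a path to
        an aligned FASTA file.
    start_a, start_b : int
        Author-numbering residue id of the first residue of each sequence.
    """
    if not isinstance(alignment, dict):
        alignment = read_fasta(alignment)
    for sid in (id_a, id_b):
        if sid not in alignment:
            raise KeyError(f"id {sid!r} not present in alignment")
    row_a, row_b = alignment[id_a], alignment[id_b]
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    pairs: list[tuple[int, int]] = []
    pos_a, pos_b = start_a - 1, start_b - 1
    n_a = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-":
            pos_a += 1
            n_a += 1
        if cb != "-":
            pos_b += 1
        if ca != "-" and cb != "-":
            pairs.append((pos_a, pos_b))
    coverage = len(pairs) / n_a if n_a else 0.0
    if not pairs:
        warnings.warn(f"alignment of {id_a!r} and {id_b!r} shares no columns", stacklevel=2)
    return AlignmentMap(pairs, coverage, id_a, id_b)
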