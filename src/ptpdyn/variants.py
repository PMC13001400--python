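"""Oncogenic-variant tables, hotspot calling and SPM overlay.

A hotspot is a residue position carrying two or more *distinct* reported
amino-acid substitutions (report counts are metadata, not the criterion).
Hotspots are then classified against an allosteric shortest-path map by
structural proximity: on the SPM itself, within a strict closest-heavy-atom
cutoff of an SPM residue (default < 4 A), or beyond it (>= 4 A).

The accepted CSV dialect is a minimal COSMIC-export subset with header
``gene,position,wt_aa,alt_aa,count``.  Positions use the numbering of the
database snapshot they came from; the structure they are classified against
must share that numbering (checked through wild-type residue names when the
structure provides them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ptpdyn.ensemble import CoordinateEnsemble

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

CSV_COLUMNS = ["gene", "position", "wt_aa", "alt_aa", "count"]


@dataclass
class VariantTable:
    """Rows of (position, wild-type aa, alternate aa, report count)."""

    data: pd.DataFrame
    gene: str = ""
    numbering: str = "author"

    def __post_init__(self) -> None:
        missing = set(CSV_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        if len(self.data):
            if (self.data["position"] <= 0).any():
                raise ValueError("positions must be positive integers")
            for col in ("wt_aa", "alt_aa"):
                bad = set(self.data[col]) - AA_ALPHABET
                if bad:
                    raise ValueError(f"non-standard amino acids in {col}: {sorted(bad)}")

    @classmethod
    def from_rows(cls, rows, gene: str = "", numbering: str = "author") -> "VariantTable":
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        df["position"] = df["position"].astype(int)
        df["count"] = df["count"].astype(int)
        return cls(df, gene=gene, numbering=numbering)

    @classmethod
    def from_csv(cls, path, numbering: str = "author") -> "VariantTable":
        df = pd.read_csv(path)
        gene = str(df["gene"].iloc[0]) if len(df) else ""
        df["position"] = df["position"].astype(int)
        df["count"] = df["count"].astype(int)
        return cls(df[CSV_COLUMNS], gene=gene, numbering=numbering)

    def to_csv(self, path) -> None:
        # canonical ordering so regeneration under a fixed seed is byte-identical
        out = self.data.sort_values(["position", "alt_aa"], kind="mergesort")
        out.to_csv(path, index=False, lineterminator="\n")

    def check_numbering(self, ensemble: CoordinateEnsemble) -> list[int]:
        """Positions whose wild-type residue disagrees with the structure.

        Only positions present in the structure with a translatable residue
        name are checked; returns the list of mismatching positions.
        """
        atoms = ensemble.atoms.drop_duplicates(subset=["res_id"])
        res_name = {
            int(r): AA3_TO_1.get(str(n).upper())
            for r, n in zip(atoms["res_id"], atoms["res_name"])
        }
        mismatches = []
        for pos, wt in zip(self.data["position"], self.data["wt_aa"]):
            known = res_name.get(int(pos))
            if known is not None and known != wt:
                mismatches.append(int(pos))
        return sorted(set(mismatches))


def hotspot_positions(table: VariantTable, min_distinct: int = 2) -> set[int]:
    """Positions with at least ``min_distinct`` distinct substitutions."""
    if len(table.data) == 0:
        return set()
    counts = table.data.groupby("position")["alt_aa"].nunique()
    return set(counts.index[counts >= min_distinct].astype(int).tolist())


@dataclass
class HotspotClassification:
    """Per-position proximity class relative to the SPM."""

    table: pd.DataFrame  # position, class, distance_A, nearest_spm_residue
    cutoff: float
    unclassifiable: list[int] = field(default_factory=list)

    def classes(self) -> dict[int, str]:
        return dict(zip(self.table["position"].astype(int), self.table["class"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n")


def classify_vs_spm(
    positions,
    spm_residues,
    structure: CoordinateEnsemble,
    cutoff: float = 4.0,
    heavy_only: bool = True,
    frame: int = 0,
) -> HotspotClassification:
    """Classify positions as on / near / far from the SPM.

    ``on_spm`` when the position is itself an SPM residue (distance 0 by
    convention); otherwise ``near_spm`` when the minimum closest-atom distance
    to any SPM residue is strictly below ``cutoff`` and ``far_spm`` when it is
    at or above it.  Hydrogens are excluded by default (crystal structures
    typically lack them).  Positions absent from the structure are reported as
    unclassifiable, never silently dropped.
    """
    spm_set = set(int(r) for r in spm_residues)
    atoms = structure.atoms
    res_ids = atoms["res_id"].to_numpy()
    keep = np.ones(len(atoms), bool)
    if heavy_only:
        keep &= atoms["element"].to_numpy() != "H"
    coords = structure.coords[frame]
    spm_mask = keep & np.isin(res_ids, list(spm_set))
    spm_coords = coords[spm_mask]
    spm_rids = res_ids[spm_mask]
    rows = []
    unclassifiable = []
    for pos in sorted(set(int(p) for p in positions)):
        if pos in spm_set:
            rows.append((pos, "on_spm", 0.0, pos))
            continue
        pos_mask = keep & (res_ids == pos)
        if not pos_mask.any():
            unclassifiable.append(pos)
            rows.append((pos, "unclassifiable", np.nan, -1))
            continue
        if spm_coords.shape[0] == 0:
            rows.append((pos, "far_spm", np.inf, -1))
            continue
        d = np.linalg.norm(
            coords[pos_mask][:, None, :] - spm_coords[None, :, :], axis=2
        )
        flat = int(np.argmin(d))
        dmin = float(d.ravel()[flat])
        nearest = int(spm_rids[flat % spm_coords.shape[0]])
        cls = "near_spm" if dmin < cutoff else "far_spm"
        rows.append((pos, cls, dmin, nearest))
    table = pd.DataFrame(rows, columns=["position", "class", "distance_A", "nearest_spm_residue"])
    return HotspotClassification(table, cutoff, unclassifiable)
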